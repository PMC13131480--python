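"""Weighted-ensemble bookkeeping: binning, resampling, the run loop,
genealogy analysis, and multi-run combination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wepath.pcoord import Embedding2D
from wepath.structures import Conformation
from wepath.we_engine import (
    IterationRecord,
    MabBinMapper,
    RadialBinMapper,
    Walker,
    WeRun,
    WeRunConfig,
    combine_runs,
    detect_first_pathway,
    mab_assign,
    radial_assign,
    resample,
    run_we,
    weighted_histogram_2d,
)

from .conftest import random_conformation


def make_walkers(pcoords, weights, conf):
    return [
        Walker(id=i, parent_id=-1, conformation=conf, weight=w, pcoord=p)
        for i, (p, w) in enumerate(zip(pcoords, weights))
    ]


@pytest.fixture
def conf(rng):
    return random_conformation(rng, 5)


class TestMabAssign:
    def test_single_walker_single_bin(self):
        labels = mab_assign([0.5], [1.0])
        assert list(labels) == [0]

    def test_all_equal_pcoords_single_bin(self):
        labels = mab_assign([1.0] * 4, [0.25] * 4)
        assert set(labels) == {0}

    def test_leading_and_trailing_get_boundary_bins(self):
        p = [0.1, 0.3, 0.5, 0.7, 0.9]
        labels = mab_assign(p, [0.2] * 5, n_bins=5, n_bottleneck=0)
        assert labels[0] == 5  # trailing
        assert labels[-1] == 6  # leading
        assert all(0 <= l < 5 for l in labels[1:-1])

    def test_bottleneck_at_largest_log_weight_jump(self):
        # ascending pcoords with weights dropping sharply after the third
        p = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        w = [0.25, 0.5, 0.2, 0.0999, 1e-4, 5e-5]
        labels = mab_assign(p, w, n_bins=5, n_bottleneck=1)
        # largest increase of -ln(w) is from walker 3 (0.0999) to 4 (1e-4)
        jumps = -np.diff(np.log(w))
        assert np.argmax(jumps) == 3
        assert labels[3] == 5 + 2

    def test_direction_flips_leading_edge(self):
        p = [0.1, 0.5, 0.9]
        fwd = mab_assign(p, [1 / 3] * 3, n_bins=3, n_bottleneck=0, direction=+1)
        bwd = mab_assign(p, [1 / 3] * 3, n_bins=3, n_bottleneck=0, direction=-1)
        assert fwd[2] == 4 and fwd[0] == 3  # leading is the max going forward
        assert bwd[0] == 4 and bwd[2] == 3  # leading is the min going backward

    def test_tied_jumps_pick_lowest_pcoord(self):
        p = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        w = np.array([4.0, 2.0, 1.0, 4.0, 2.0, 1.0])
        w = (w / w.sum()).tolist()
        labels = mab_assign(p, w, n_bins=3, n_bottleneck=1)
        # -ln w jumps of ln(2) occur at indices 0->1, 1->2, 3->4, 4->5;
        # the tie resolves to the lowest-progress candidate (index 1, since
        # index 0 is the trailing boundary walker)
        assert labels[1] == 3 + 2


class TestRadialAssign:
    @pytest.mark.parametrize(
        "point, bin_", [((1.0, 0.0), 0), ((np.cos(np.radians(7)), np.sin(np.radians(7))), 1),
                        ((0.0, 1.0), 17), ((1.0, 1.0), 9)],
    )
    def test_boundaries(self, point, bin_):
        assert radial_assign([point])[0] == bin_


class TestResample:
    def test_split_single_walker_to_target(self, conf, rng):
        w = 0.375
        walkers = make_walkers([0.5], [w], conf)
        ids = itertools.count(100)
        out = resample({0: walkers}, 5, rng, ids)
        assert len(out) == 5
        assert sum(x.weight for x in out) == pytest.approx(w, abs=1e-15)
        assert all(w / 8 <= x.weight <= w / 2 for x in out)

    def test_merge_seven_equal_to_five(self, conf, rng):
        walkers = make_walkers(np.linspace(0, 1, 7), [1 / 7] * 7, conf)
        ids = itertools.count(100)
        out = resample({0: walkers}, 5, rng, ids)
        assert len(out) == 5
        assert sum(x.weight for x in out) == pytest.approx(1.0, abs=1e-15)

    def test_merge_survivor_unbiased(self, conf):
        """Over many seeds each walker survives a full merge-down with
        probability equal to its weight (the statistically exact rule)."""
        weights = np.array([0.5, 0.3, 0.2])
        n_trials = 4000
        counts = np.zeros(3)
        for seed in range(n_trials):
            walkers = make_walkers([0.1, 0.2, 0.3], weights, conf)
            rng = np.random.default_rng(seed)
            out = resample({0: walkers}, 1, rng, itertools.count(100))
            counts[out[0].id] += 1
            assert out[0].weight == pytest.approx(1.0, abs=1e-15)
        freq = counts / n_trials
        se = np.sqrt(weights * (1 - weights) / n_trials)
        assert np.all(np.abs(freq - weights) < 3.5 * se)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_weight_conserved_random_scenarios(self, seed):
        """Randomized bins/weights/targets conserve total weight to 1e-12."""
        rng = np.random.default_rng(seed)
        conf = random_conformation(rng, 4)
        n = int(rng.integers(1, 20))
        weights = rng.random(n) + 1e-6
        weights /= weights.sum()
        bins = rng.integers(0, 4, n)
        binned = {}
        for i, (w, b) in enumerate(zip(weights, bins)):
            binned.setdefault(int(b), []).append(
                Walker(id=i, parent_id=-1, conformation=conf, weight=float(w),
                       pcoord=float(i))
            )
        target = int(rng.integers(1, 8))
        out = resample(binned, target, rng, itertools.count(1000))
        assert abs(sum(w.weight for w in out) - 1.0) < 1e-12
        assert len(out) == target * len(binned)


class _CountingPropagator:
    """Deterministic no-op propagator that counts invocations."""

    def __init__(self):
        self.calls = 0

    def __call__(self, conf, rng):
        self.calls += 1
        return conf


class TestRunWe:
    def test_zero_iterations(self, conf):
        run = run_we(_CountingPropagator(), conf, lambda c: 0.0,
                     MabBinMapper(), WeRunConfig(n_iterations=0, seed=1))
        assert run.iterations == []
        assert len(run.initial_walkers) == 1
        assert run.initial_walkers[0].weight == 1.0

    def test_noop_propagator_splits_to_target_count(self, conf):
        run = run_we(_CountingPropagator(), conf, lambda c: 1.0,
                     MabBinMapper(), WeRunConfig(n_iterations=4, seed=1))
        for rec in run.iterations:
            # constant pcoord -> one bin -> exactly target_count walkers
            assert len(rec.resampled) == 5
            assert sum(w.weight for w in rec.resampled) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_weight_sum_every_iteration(self, hinge_we_run):
        for rec in hinge_we_run.iterations:
            assert sum(w.weight for w in rec.walkers) == pytest.approx(
                1.0, abs=1e-12
            )
            assert sum(w.weight for w in rec.resampled) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_bit_for_bit_reproducible(self, small_hinge_endpoints):
        from wepath.adaptive_anm import generate_pathway
        from wepath.pcoord import build_polyline, embed, progress
        from wepath.toy_system import make_brownian_propagator, make_double_basin

        a, b = small_hinge_endpoints
        pot = make_double_basin(a, b)
        e = Embedding2D(a, b)
        pl = build_polyline(generate_pathway(a, b), e)
        prop = make_brownian_propagator(pot, n_steps=10, temperature=1.0)
        pfn = lambda c: progress(embed(c, e), pl).value
        cfg = WeRunConfig(n_iterations=3, seed=42)
        r1 = run_we(prop, a, pfn, MabBinMapper(), cfg)
        r2 = run_we(prop, a, pfn, MabBinMapper(), cfg)
        for rec1, rec2 in zip(r1.iterations, r2.iterations):
            assert [w.id for w in rec1.walkers] == [w.id for w in rec2.walkers]
            assert [w.weight for w in rec1.walkers] == [
                w.weight for w in rec2.walkers
            ]
            np.testing.assert_array_equal(
                np.stack([w.conformation.coords for w in rec1.walkers]),
                np.stack([w.conformation.coords for w in rec2.walkers]),
            )

    def test_hdf5_round_trip(self, hinge_we_run, tmp_path):
        from wepath.we_io import read_run_hdf5

        path = tmp_path / "run.h5"
        hinge_we_run.to_hdf5(path)
        back = read_run_hdf5(path)
        assert back.config == hinge_we_run.config
        assert len(back.iterations) == len(hinge_we_run.iterations)
        for r1, r2 in zip(hinge_we_run.iterations, back.iterations):
            assert [w.id for w in r1.walkers] == [w.id for w in r2.walkers]
            np.testing.assert_allclose(
                [w.weight for w in r1.walkers], [w.weight for w in r2.walkers]
            )
        assert detect_first_pathway(back) == detect_first_pathway(hinge_we_run)


class TestStatisticalExactness1D:
    """The engine is generic over the walker payload, so a 1D double-well
    Brownian particle gives a cheap, high-power unbiasedness check: WE
    recycled flux and well population must match a 10^5-trajectory
    brute-force ensemble following the same propagate/teleport chain."""

    H, DT, KT, NSTEPS = 2.0, 1e-3, 0.7, 100
    TARGET, X0 = 0.9, -1.0

    def _force(self, x):
        return -4 * self.H * x * (x * x - 1)

    def _propagate(self, x, rng):
        x = float(x)
        for _ in range(self.NSTEPS):
            x += self.DT * self._force(x) + np.sqrt(
                2 * self.KT * self.DT
            ) * rng.standard_normal()
        return x

    def test_flux_and_population_match_brute_force(self):
        n_iter, n_bf, n_we = 20, 100_000, 24
        x = np.full(n_bf, self.X0)
        rng = np.random.default_rng(5)
        hits = np.zeros(n_bf)
        for _ in range(n_iter):
            for _ in range(self.NSTEPS):
                x += self.DT * self._force(x) + np.sqrt(
                    2 * self.KT * self.DT
                ) * rng.standard_normal(n_bf)
            hit = x > self.TARGET
            hits += hit
            x[hit] = self.X0
        flux_bf = hits.mean()
        flux_bf_se = hits.std(ddof=1) / np.sqrt(n_bf)
        pop_bf = (x > 0).mean()
        pop_bf_se = np.sqrt(pop_bf * (1 - pop_bf) / n_bf)

        flux_we, pop_we = [], []
        for seed in range(n_we):
            cfg = WeRunConfig(n_iterations=n_iter, seed=seed, recycle=True)
            run = run_we(self._propagate, self.X0, float, MabBinMapper(),
                         cfg, target_state=lambda x: x > self.TARGET)
            flux_we.append(run.flux_trace().sum())
            pop_we.append(sum(w.weight for w in run.ensemble()
                              if w.conformation > 0))
        flux_we = np.array(flux_we)
        pop_we = np.array(pop_we)
        flux_sigma = np.hypot(flux_bf_se, flux_we.std(ddof=1) / np.sqrt(n_we))
        pop_sigma = np.hypot(pop_bf_se, pop_we.std(ddof=1) / np.sqrt(n_we))
        assert abs(flux_we.mean() - flux_bf) < 3 * flux_sigma
        assert abs(pop_we.mean() - pop_bf) < 3 * pop_sigma


class TestDetectFirstPathway:
    def _synthetic_run(self, conf, flag_iteration, n_walkers=5, tau=100.0,
                       n_iterations=4):
        cfg = WeRunConfig(n_iterations=n_iterations, tau=tau)
        roots = [Walker(id=i, parent_id=-1, conformation=conf,
                        weight=1 / n_walkers, pcoord=0.0)
                 for i in range(n_walkers)]
        run = WeRun(config=cfg, initial_walkers=roots)
        next_id = n_walkers
        prev = roots
        for it in range(1, n_iterations + 1):
            cur = []
            for w in prev:
                cur.append(Walker(id=next_id, parent_id=w.id,
                                  conformation=conf, weight=w.weight,
                                  pcoord=0.0, iteration=it,
                                  flagged=(it == flag_iteration and
                                           len(cur) == 0)))
                next_id += 1
            run.iterations.append(IterationRecord(
                iteration=it, walkers=cur, bin_labels=np.zeros(len(cur), int),
                resampled=[Walker(**vars(w)) for w in cur], flux=0.0,
            ))
            prev = cur
        return run

    def test_no_flag_returns_none(self, conf):
        run = self._synthetic_run(conf, flag_iteration=0)
        assert detect_first_pathway(run) is None

    def test_aggregate_time_arithmetic(self, conf):
        """5 walkers per iteration, flag at iteration 3, tau=100 -> 1500."""
        run = self._synthetic_run(conf, flag_iteration=3)
        assert detect_first_pathway(run) == pytest.approx(1500.0)

    def test_matches_exhaustive_genealogy_scan(self, conf):
        run = self._synthetic_run(conf, flag_iteration=2)
        # oracle: scan every root-to-flag chain by brute force
        index = run.walker_index()
        best = None
        for rec in run.iterations:
            for w in rec.walkers:
                if not w.flagged:
                    continue
                chain_ok = True
                x = w
                seen = 0
                while x.parent_id != -1 and seen < 10_000:
                    x = index[x.parent_id]
                    seen += 1
                if chain_ok:
                    t = sum(len(r.walkers) * run.config.tau
                            for r in run.iterations
                            if r.iteration <= rec.iteration)
                    best = t if best is None else min(best, t)
            if best is not None:
                break
        assert detect_first_pathway(run) == best

    def test_dangling_parent_raises(self, conf):
        run = self._synthetic_run(conf, flag_iteration=2)
        run.iterations[1].walkers[0].parent_id = 99999
        with pytest.raises(ValueError, match="genealogy"):
            detect_first_pathway(run)


class TestCombineRuns:
    def test_single_run_unchanged(self, hinge_we_run):
        merged = combine_runs([hinge_we_run])
        orig = hinge_we_run.ensemble()
        assert [w.weight for w in merged] == [w.weight for w in orig]

    def test_two_runs_halved(self, hinge_we_run):
        merged = combine_runs([hinge_we_run, hinge_we_run])
        assert sum(w.weight for w in merged) == pytest.approx(1.0, abs=1e-12)
        orig = hinge_we_run.ensemble()
        assert merged[0].weight == pytest.approx(orig[0].weight / 2)

    def test_six_runs_total_unity(self, hinge_we_run):
        merged = combine_runs([hinge_we_run] * 6)
        assert sum(w.weight for w in merged) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_runs([])


class TestWeightedHistogram:
    def test_single_walker_single_cell(self, conf):
        e = Embedding2D(conf, conf.with_coords(conf.coords + 3.0))
        w = Walker(id=0, parent_id=-1, conformation=conf, weight=1.0)
        hist, neg_ln, _, _ = weighted_histogram_2d([w], e, 5, 5)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1
        assert np.nanmin(neg_ln) == pytest.approx(0.0)

    def test_matches_naive_accumulation(self, rng):
        base = random_conformation(rng, 5)
        other = base.with_coords(base.coords + 5.0)
        e = Embedding2D(base, other)
        walkers = [
            Walker(id=i, parent_id=-1,
                   conformation=base.with_coords(
                       base.coords + rng.standard_normal((5, 3))),
                   weight=1 / 8)
            for i in range(8)
        ]
        hist, _, xe, ye = weighted_histogram_2d(walkers, e, 6, 6)
        from wepath.pcoord import embed as embed_fn

        naive = np.zeros((6, 6))
        for w in walkers:
            x, y = embed_fn(w.conformation, e)
            i = min(np.searchsorted(xe, x, side="right") - 1, 5)
            j = min(np.searchsorted(ye, y, side="right") - 1, 5)
            naive[i, j] += w.weight
        np.testing.assert_allclose(hist, naive / naive.sum(), atol=1e-12)
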