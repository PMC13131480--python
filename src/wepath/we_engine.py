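"""Weighted-ensemble driver: propagation, binning, split/merge resampling,
genealogy, flux accounting, and multi-run combination.

Each iteration propagates every walker for a fixed interval, recomputes the
progress coordinate, assigns walkers to bins, and resamples each bin to a
target trajectory count by splitting high-weight walkers and merging
low-weight ones.  Weights are exact: the total statistical weight of the
ensemble is 1 at every iteration boundary, which is what makes the method
statistically exact.  Bin mappers are pluggable; the minimal adaptive
binning (MAB) mapper reproduces the adaptive scheme with dedicated
leading/trailing boundary bins and a bottleneck bin, and the radial mapper
reproduces the conventional fixed 5-degree angular binning control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .pcoord import radial_angle
from .structures import Conformation

__all__ = [
    "Walker",
    "WeRunConfig",
    "IterationRecord",
    "WeRun",
    "MabBinMapper",
    "RadialBinMapper",
    "FixedBinMapper",
    "mab_assign",
    "radial_assign",
    "resample",
    "run_we",
    "detect_first_pathway",
    "combine_runs",
    "weighted_histogram_2d",
]

_WEIGHT_TOL = 1e-12


@dataclass
class Walker:
    """One trajectory segment with its statistical weight and genealogy.

    ``parent_id`` refers to the walker (in the previous iteration) this one
    continues from; -1 marks an initial walker.
    """

    id: int
    parent_id: int
    conformation: Conformation
    weight: float
    pcoord: object = None  # scalar progress, or (rmsdA, rmsdB) pair
    iteration: int = 0
    flagged: bool = False  # reached the target state this iteration


@dataclass(frozen=True)
class WeRunConfig:
    """Configuration of one WE run.

    ``tau`` is bookkeeping time per iteration (the toy propagator's
    100-step interval stands in for 100 ps); ``target_count`` is the number
    of trajectories kept per occupied bin; ``n_mab_bins``/``n_bottleneck``
    configure the MAB mapper; ``direction`` orients the progress coordinate
    ("AB" or "BA"); ``recycle`` teleports target-reaching walkers back to
    the initial state while recording their weight as flux.
    """

    n_iterations: int = 150
    tau: float = 100.0
    target_count: int = 5
    n_mab_bins: int = 5
    n_bottleneck: int = 1
    direction: str = "AB"
    seed: int = 0
    recycle: bool = False

    def __post_init__(self):
        if self.n_iterations < 0 or self.target_count < 1:
            raise ValueError("n_iterations >= 0 and target_count >= 1 required")
        if self.direction not in ("AB", "BA"):
            raise ValueError("direction must be 'AB' or 'BA'")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be in [0, 2^31)")


# ---------------------------------------------------------------------------
# Bin mappers


def mab_assign(pcoords, weights, n_bins: int = 5, n_bottleneck: int = 1,
               direction: int = +1):
    """Minimal adaptive binning of scalar progress values.

    The leading walker (furthest along ``direction``) and trailing walker
    each get a dedicated boundary bin; the span between the extreme values
    is cut into ``n_bins`` equal-width linear bins; and walking through the
    walkers sorted along the progress direction, the walker immediately
    preceding the largest increase of -ln(weight) gets a dedicated
    bottleneck bin (ties: lowest progress).  Boundary status takes
    precedence over bottleneck.  All-equal progress values collapse to a
    single bin.

    Returns integer labels: 0..n_bins-1 linear, n_bins trailing,
    n_bins+1 leading, n_bins+2.. bottleneck.
    """
    p = np.asarray(pcoords, float).reshape(-1)
    w = np.asarray(weights, float).reshape(-1)
    n = len(p)
    if n == 0:
        raise ValueError("no walkers to assign")
    signed = direction * p
    lo, hi = signed.min(), signed.max()
    if hi - lo < 1e-15:
        return np.zeros(n, dtype=int)
    labels = np.minimum(
        (n_bins * (signed - lo) / (hi - lo)).astype(int), n_bins - 1
    )
    trailing = int(np.argmin(signed))
    leading = int(np.argmax(signed))
    labels[trailing] = n_bins
    labels[leading] = n_bins + 1

    if n_bottleneck > 0 and n > 1:
        order = np.argsort(signed, kind="stable")
        neg_log_w = -np.log(np.maximum(w[order], 1e-300))
        jumps = np.diff(neg_log_w)  # increase toward progress direction
        candidates = []  # (-jump, signed pcoord, walker index) for sorting
        for k in np.argsort(-jumps, kind="stable"):
            idx = int(order[k])
            if jumps[k] <= 0:
                break
            if idx in (trailing, leading):
                continue
            candidates.append((idx, jumps[k]))
        # ties in jump size: lowest progress wins
        candidates.sort(key=lambda c: (-c[1], signed[c[0]]))
        for j, (idx, _) in enumerate(candidates[:n_bottleneck]):
            labels[idx] = n_bins + 2 + j
    return labels


def radial_assign(points):
    """Fixed radial binning of 2D RMSD points: one bin per 5 degrees.

    18 bins cover [0, 90] degrees; the 90-degree boundary falls in the last
    bin.
    """
    angles = np.array([radial_angle(pt) for pt in points])
    return np.minimum((angles / 5.0).astype(int), 17)


class MabBinMapper:
    """Adaptive mapper over the scalar progress coordinate."""

    kind = "mab"

    def __init__(self, n_bins: int = 5, n_bottleneck: int = 1, direction: int = +1):
        self.n_bins = n_bins
        self.n_bottleneck = n_bottleneck
        self.direction = direction

    def assign(self, walkers):
        return mab_assign(
            [w.pcoord for w in walkers],
            [w.weight for w in walkers],
            self.n_bins,
            self.n_bottleneck,
            self.direction,
        )

    def is_linear_bin(self, label: int) -> bool:
        """True for the equal-width bins (not boundary, not bottleneck)."""
        return 0 <= label < self.n_bins


class RadialBinMapper:
    """Fixed 5-degree angular bins over the 2D RMSD plane (control setup)."""

    kind = "radial"

    def assign(self, walkers):
        return radial_assign([w.pcoord for w in walkers])


class FixedBinMapper:
    """Fixed linear bins over a scalar progress coordinate."""

    kind = "fixed"

    def __init__(self, edges):
        self.edges = np.asarray(edges, float)

    def assign(self, walkers):
        p = np.array([w.pcoord for w in walkers], float)
        return np.searchsorted(self.edges, p, side="right")


# ---------------------------------------------------------------------------
# Resampling


def _split_once(group, id_counter):
    """Split the largest-weight walker (ties: lowest id) into two halves.

    Both children carry half the parent's weight and record the split
    walker's id as their parent.
    """
    donor = max(group, key=lambda w: (w.weight, -w.id))
    group.remove(donor)
    half = donor.weight * 0.5
    for _ in range(2):
        child = replace(donor, id=next(id_counter), parent_id=donor.id,
                        weight=half)
        group.append(child)
    return donor


def _merge_once(group, rng):
    """Merge the two smallest-weight walkers; survivor chosen by weight."""
    ordered = sorted(group, key=lambda w: (w.weight, w.id))
    a, b = ordered[0], ordered[1]
    total = a.weight + b.weight
    survivor = a if rng.random() < a.weight / total else b
    loser = b if survivor is a else a
    group.remove(loser)
    survivor.weight = total


def resample(binned, target_count: int, rng, id_counter, archive=None):
    """Resample each bin to exactly ``target_count`` walkers.

    ``binned`` maps bin label -> list of walkers (consumed).  Bins with too
    few walkers split their largest-weight member repeatedly (children get
    half the weight each and inherit the split walker's parent id); bins
    with too many repeatedly merge their two smallest-weight members, the
    survivor chosen with probability proportional to weight and carrying
    the summed weight.  Per-bin total weight is conserved exactly;
    ``id_counter`` supplies fresh walker ids for split children, and
    ``archive`` (if given) collects split intermediates so multi-level
    splits keep an unbroken genealogy.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    out = []
    for label in sorted(binned):
        group = list(binned[label])
        while len(group) < target_count:
            donor = _split_once(group, id_counter)
            if archive is not None:
                archive.append(donor)
        while len(group) > target_count:
            _merge_once(group, rng)
        out.extend(group)
    return out


# ---------------------------------------------------------------------------
# The run loop


@dataclass
class IterationRecord:
    """State of one WE iteration: walkers after propagation, their bins,
    the recycled flux, and the post-resampling walker set that starts the
    next iteration."""

    iteration: int
    walkers: list  # post-propagation Walkers (the set propagated this iter)
    bin_labels: np.ndarray
    resampled: list  # post-resampling Walkers (start of next iteration)
    flux: float
    split_archive: list = field(default_factory=list)  # intermediate splits


@dataclass
class WeRun:
    """Full record of a WE run: per-iteration tables plus genealogy index."""

    config: WeRunConfig
    initial_walkers: list
    iterations: list = field(default_factory=list)

    def walker_index(self):
        """Map id -> Walker over all recorded walkers (for genealogy)."""
        index = {w.id: w for w in self.initial_walkers}
        for rec in self.iterations:
            for w in rec.walkers:
                index[w.id] = w
            for w in rec.resampled:  # split children live here
                index.setdefault(w.id, w)
            for w in rec.split_archive:  # intermediates of multi-level splits
                index.setdefault(w.id, w)
        return index

    def ensemble(self, iteration: int = -1):
        """Walker set at one iteration boundary (post-propagation)."""
        if not self.iterations:
            return list(self.initial_walkers)
        return list(self.iterations[iteration].walkers)

    def flux_trace(self):
        return np.array([rec.flux for rec in self.iterations])

    def to_hdf5(self, path) -> None:
        """Persist the run (config, per-iteration tables, coordinates)."""
        import h5py

        def dump(group, walkers, labels=None):
            if not walkers:
                for name, shape in (("ids", (0,)), ("parent_ids", (0,)),
                                    ("weights", (0,)), ("pcoords", (0, 1)),
                                    ("flags", (0,)), ("coords", (0, 0, 3))):
                    group.create_dataset(name, shape=shape)
                if labels is not None:
                    group.create_dataset("bins", shape=(0,))
                return
            group.create_dataset("ids", data=[w.id for w in walkers])
            group.create_dataset("parent_ids", data=[w.parent_id for w in walkers])
            group.create_dataset("weights", data=[w.weight for w in walkers])
            pc = np.array([np.atleast_1d(np.asarray(w.pcoord, float))
                           if w.pcoord is not None else [np.nan]
                           for w in walkers])
            group.create_dataset("pcoords", data=pc)
            group.create_dataset("flags", data=[w.flagged for w in walkers])
            group.create_dataset(
                "coords", data=np.stack([w.conformation.coords for w in walkers])
            )
            if labels is not None:
                group.create_dataset("bins", data=np.asarray(labels))

        with h5py.File(path, "w") as fh:
            fh.attrs["config"] = json.dumps(vars(self.config) | {})
            fh.attrs["residue_labels"] = json.dumps(
                list(self.initial_walkers[0].conformation.residue_labels)
            )
            dump(fh.create_group("initial"), self.initial_walkers)
            for rec in self.iterations:
                g = fh.create_group(f"iterations/{rec.iteration:06d}")
                g.attrs["flux"] = rec.flux
                dump(g.create_group("propagated"), rec.walkers, rec.bin_labels)
                dump(g.create_group("resampled"), rec.resampled)
                dump(g.create_group("split_archive"), rec.split_archive)

    def summary_table(self):
        """Per-iteration summary rows (iteration, n_walkers, pcoord range,
        weight sum, flux) as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for rec in self.iterations:
            scalars = [w.pcoord for w in rec.walkers
                       if np.ndim(w.pcoord) == 0 and w.pcoord is not None]
            rows.append(
                dict(
                    iteration=rec.iteration,
                    n_walkers=len(rec.walkers),
                    weight_sum=sum(w.weight for w in rec.walkers),
                    pcoord_min=min(scalars) if scalars else np.nan,
                    pcoord_max=max(scalars) if scalars else np.nan,
                    flux=rec.flux,
                )
            )
        return pd.DataFrame(rows)


def _counter(start=0):
    k = start
    while True:
        yield k
        k += 1


def _substream(seed: int, iteration: int, slot: int) -> np.random.Generator:
    """Counter-style substream so propagation order cannot change results."""
    return np.random.default_rng([seed, iteration, slot])


def run_we(
    propagator,
    initial: Conformation,
    pcoord_fn,
    mapper,
    config: WeRunConfig,
    target_state=None,
) -> WeRun:
    """Run the WE loop: propagate, flag/recycle, bin, resample, record.

    ``propagator(conf, rng) -> conf`` advances one walker by the fixed
    interval; ``pcoord_fn(conf)`` returns the walker's progress coordinate
    (scalar for MAB/fixed mappers, 2D RMSD pair for the radial mapper);
    ``target_state(conf) -> bool``, if given, flags walkers that reached
    the target (recycled to the initial state when ``config.recycle``).
    Each walker draws noise from its own (seed, iteration, id) substream,
    so runs are reproducible bit-for-bit regardless of evaluation order.
    """
    ids = _counter()
    root = Walker(
        id=next(ids), parent_id=-1, conformation=initial, weight=1.0,
        pcoord=pcoord_fn(initial), iteration=0,
    )
    run = WeRun(config=config, initial_walkers=[root])
    current = [root]

    for it in range(1, config.n_iterations + 1):
        propagated = []
        flux = 0.0
        for w in sorted(current, key=lambda x: x.id):
            rng_w = _substream(config.seed, it, w.id)
            conf = propagator(w.conformation, rng_w)
            flagged = bool(target_state(conf)) if target_state else False
            if flagged:
                flux += w.weight
                if config.recycle:
                    conf = initial
            propagated.append(
                Walker(
                    id=next(ids), parent_id=w.id, conformation=conf,
                    weight=w.weight, pcoord=pcoord_fn(conf), iteration=it,
                    flagged=flagged,
                )
            )
        total = sum(w.weight for w in propagated)
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"weight drift at iteration {it}: sum={total!r}")
        labels = np.asarray(mapper.assign(propagated))
        binned = {}
        for w, lab in zip(propagated, labels):
            binned.setdefault(int(lab), []).append(replace(w))
        rng_r = _substream(config.seed, it, 2**20)
        archive = []
        resampled = resample(binned, config.target_count, rng_r, ids, archive)
        resampled.sort(key=lambda w: w.id)
        run.iterations.append(
            IterationRecord(
                iteration=it, walkers=propagated, bin_labels=labels,
                resampled=resampled, flux=flux, split_archive=archive,
            )
        )
        current = resampled
    return run


# ---------------------------------------------------------------------------
# Analysis


def detect_first_pathway(run: WeRun, tau: float | None = None):
    """Aggregate simulation time at the first continuous initial-to-target
    trajectory, or None if no walker was ever flagged.

    The flagged walker's genealogy is walked back to a root (a dangling
    parent raises); the returned time is ``sum over iterations up to and
    including the flagging one of n_walkers * tau``.
    """
    tau = run.config.tau if tau is None else tau
    index = run.walker_index()
    for rec in run.iterations:
        flagged = [w for w in rec.walkers if w.flagged]
        if not flagged:
            continue
        w = min(flagged, key=lambda x: x.id)
        while w.parent_id != -1:
            if w.parent_id not in index:
                raise ValueError(
                    f"corrupted genealogy: walker {w.id} has dangling parent "
                    f"{w.parent_id}"
                )
            w = index[w.parent_id]
        aggregate = sum(
            len(r.walkers) * tau for r in run.iterations
            if r.iteration <= rec.iteration
        )
        return aggregate
    return None


def combine_runs(runs, iteration: int = -1):
    """Merge the walker ensembles of independent runs at one iteration.

    Every walker's weight is divided by the number of runs, so the merged
    ensemble again carries total weight 1 (the multi-run normalization used
    when pooling independent simulations).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to combine")
    merged = []
    for run in runs:
        for w in run.ensemble(iteration):
            merged.append(replace(w, weight=w.weight / len(runs)))
    return merged


def weighted_histogram_2d(walkers, embedding, n_bins_x: int = 40,
                          n_bins_y: int = 40, extent=None):
    """Weighted 2D histogram of an ensemble in the 2D RMSD plane.

    Returns ``(P, neg_ln_P, x_edges, y_edges)`` where P sums to 1 over
    occupied cells and -ln(P) is masked (NaN) on empty cells.
    """
    from .pcoord import embed

    walkers = list(walkers)
    if not walkers:
        raise ValueError("empty ensemble")
    pts = np.array([embed(w.conformation, embedding) for w in walkers])
    weights = np.array([w.weight for w in walkers], float)
    hist, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=[n_bins_x, n_bins_y],
        range=extent, weights=weights,
    )
    total = hist.sum()
    if total > 0:
        hist = hist / total
    with np.errstate(divide="ignore"):
        neg_ln = np.where(hist > 0, -np.log(np.where(hist > 0, hist, 1.0)), np.nan)
    return hist, neg_ln, xe, ye
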