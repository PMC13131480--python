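"""Adaptive ANM pathway generation between two endpoint conformations.

Starting from energy-minimized endpoints A0 and B0, the two frontiers are
deformed toward each other along the minimal set of soft ANM modes whose
cumulative squared overlap with the current deformation vector exceeds a
threshold.  The network is rebuilt on every moved conformer (the adaptive
step), and cycles alternate sides (A first) until the frontiers meet
(fitted RMSD below ``meet_rmsd``, default 1.5 Å) or the number of
intermediate milestones reaches ``max_intermediates`` (default 40).
The result is a deterministic coarse-grained milestone pathway
A0, A1, ..., Ak, Bk, ..., B1, B0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import anm
from .structures import Conformation, rmsd, superpose

__all__ = [
    "AanmParams",
    "AanmPathway",
    "deformation_vector",
    "select_modes",
    "aanm_step",
    "generate_pathway",
    "max_bond_strain",
]

logger = logging.getLogger(__name__)

# Minimum gap reduction (Å) for a step to count as progress; below this the
# mode subset is widened by one before retrying.
_PROGRESS_EPS = 0.01


@dataclass(frozen=True)
class AanmParams:
    """Tunable parameters of the adaptive pathway search.

    overlap_threshold : cumulative squared-overlap level that the selected
        soft-mode prefix must reach, in (0, 1].
    step_rmsd : maximum RMSD displacement per deformation step (Å); keeps
        each move inside the harmonic regime of the current network.
    meet_rmsd : frontier "meeting" criterion (Å).
    max_intermediates : upper bound on the milestone count M.
    n_modes : soft modes computed per rebuilt network (None: min(20, 3N-6)).
    rc, gamma : forwarded to the ANM builder.
    """

    overlap_threshold: float = 0.5
    step_rmsd: float = 2.0
    meet_rmsd: float = 1.5
    max_intermediates: int = 40
    n_modes: int | None = None
    rc: float = anm.DEFAULT_CUTOFF
    gamma: float = anm.DEFAULT_GAMMA

    def __post_init__(self):
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        for name in ("step_rmsd", "meet_rmsd", "rc", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_intermediates < 0:
            raise ValueError("max_intermediates must be non-negative")


@dataclass(frozen=True)
class AanmPathway:
    """Ordered milestone pathway A0...Ak, Bk...B0 with generation metadata.

    ``M`` counts intermediates (milestones excluding the two endpoints);
    ``final_gap`` is the fitted RMSD between the last A-side and B-side
    frontiers; ``converged`` means the meeting criterion was satisfied.
    """

    milestones: tuple  # of Conformation
    sides: tuple  # "A" / "B" per milestone
    cycle_index: tuple  # generation cycle per milestone (0 for endpoints)
    params: AanmParams
    converged: bool
    final_gap: float

    @property
    def M(self) -> int:
        return len(self.milestones) - 2

    def __post_init__(self):
        if len(self.milestones) < 2:
            raise ValueError("pathway needs at least the two endpoints")


def max_bond_strain(milestones) -> float:
    """Largest relative deviation of milestone Cα-Cα virtual bonds from the
    average bond length of the two endpoints (first and last milestone)."""
    milestones = list(milestones)
    ref = np.mean([
        np.linalg.norm(np.diff(milestones[0].coords, axis=0), axis=1).mean(),
        np.linalg.norm(np.diff(milestones[-1].coords, axis=0), axis=1).mean(),
    ])
    worst = 0.0
    for m in milestones:
        bonds = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
        worst = max(worst, float(np.max(np.abs(bonds - ref))) / ref)
    return worst


def deformation_vector(source: Conformation, target: Conformation) -> np.ndarray:
    """3N deformation vector from ``source`` toward ``target``.

    The target is first superposed onto the source so the vector contains
    only internal deformation: ``|d| = sqrt(N) * rmsd(source, target)``.
    """
    source.assert_comparable(target)
    _, fitted = superpose(target, source)
    return (fitted.coords - source.coords).reshape(-1)


def select_modes(model: anm.AnmModel, d: np.ndarray, threshold: float):
    """Smallest ascending-frequency mode prefix reaching the overlap threshold.

    Returns ``(indices, saturated)``: 0-based indices ``[0..m-1]`` of the
    selected prefix, and a flag set when even all retained modes fail to
    reach the threshold (all are then returned).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    spectrum = anm.mode_overlaps(model, d)
    reached = np.nonzero(spectrum.cumulative >= threshold)[0]
    if len(reached) == 0:
        return list(range(model.n_modes)), True
    m = int(reached[0]) + 1
    return list(range(m)), False


def aanm_step(
    conf: Conformation,
    model: anm.AnmModel,
    d: np.ndarray,
    subset,
    step_rmsd: float,
) -> Conformation:
    """Deform ``conf`` along the projection of ``d`` onto the mode subset.

    The raw displacement is ``sum_k (u_k . d) u_k`` over the subset, scaled
    by ``s = min(1, step_rmsd * sqrt(N) / |delta|)`` so the step RMSD never
    exceeds ``step_rmsd`` and never overshoots the projection of ``d``.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty mode subset")
    d = np.asarray(d, float)
    u = model.eigenvectors[subset]  # (k, 3N)
    delta = u.T @ (u @ d)
    norm = np.linalg.norm(delta)
    if norm <= 1e-9 * np.linalg.norm(d):
        raise ValueError("stalled step: deformation orthogonal to mode subset")
    s = min(1.0, step_rmsd * np.sqrt(conf.n_atoms) / norm)
    return conf.with_coords(conf.coords + s * delta.reshape(-1, 3))


def generate_pathway(
    A0: Conformation, B0: Conformation, params: AanmParams | None = None
) -> AanmPathway:
    """Generate the milestone pathway between endpoints A0 and B0.

    Cycles alternate sides, A first: the A frontier is deformed toward the
    current B frontier along its selected soft modes, then the B frontier
    toward the new A frontier.  The network is rebuilt on every moved
    conformer.  A step that reduces the frontier gap by less than 0.01 Å
    widens the mode subset by one and retries; if all retained modes are
    exhausted without progress the search terminates unconverged.  The
    algorithm is deterministic: identical inputs give identical pathways.
    """
    params = params or AanmParams()
    A0.assert_comparable(B0)

    n_modes = params.n_modes or anm.default_n_modes(A0)
    a_side = [A0]
    b_side = [B0]
    a_cycles = [0]
    b_cycles = [0]
    gap = rmsd(a_side[-1], b_side[-1], fit=True)

    converged = gap < params.meet_rmsd
    cycle = 0
    stalled = False
    while not converged and not stalled:
        cycle += 1
        for side, other in (("A", "B"), ("B", "A")):
            n_intermediates = (len(a_side) - 1) + (len(b_side) - 1)
            if converged or n_intermediates >= params.max_intermediates:
                break
            frontier = a_side[-1] if side == "A" else b_side[-1]
            opposite = b_side[-1] if side == "A" else a_side[-1]
            model = anm.build_anm(frontier, params.rc, params.gamma, n_modes)
            d = deformation_vector(frontier, opposite)
            subset, saturated = select_modes(model, d, params.overlap_threshold)
            # widen the subset until the step makes real progress on the gap
            while True:
                new_conf = aanm_step(frontier, model, d, subset, params.step_rmsd)
                new_gap = rmsd(new_conf, opposite, fit=True)
                if gap - new_gap >= _PROGRESS_EPS:
                    break
                if saturated or len(subset) >= model.n_modes:
                    stalled = True
                    break
                subset = list(range(len(subset) + 1))
                saturated = len(subset) >= model.n_modes
            if stalled:
                break
            new_conf = new_conf.with_coords(
                new_conf.coords,
                name=f"{side}{len(a_side if side == 'A' else b_side)}",
            )
            if side == "A":
                a_side.append(new_conf)
                a_cycles.append(cycle)
            else:
                b_side.append(new_conf)
                b_cycles.append(cycle)
            gap = new_gap
            if gap < params.meet_rmsd:
                converged = True
        else:
            continue
        break

    milestones = tuple(a_side + list(reversed(b_side)))
    sides = tuple(["A"] * len(a_side) + ["B"] * len(b_side))
    cycles = tuple(a_cycles + list(reversed(b_cycles)))
    strain = max_bond_strain(milestones)
    if strain > 0.25:
        # harmonic-validity monitor: mode steps should not stretch the chain
        logger.warning(
            "milestone virtual bonds deviate up to %.0f%% from the endpoint "
            "average; consider a smaller step_rmsd", 100 * strain,
        )
    return AanmPathway(
        milestones=milestones,
        sides=sides,
        cycle_index=cycles,
        params=params,
        converged=converged,
        final_gap=gap,
    )
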