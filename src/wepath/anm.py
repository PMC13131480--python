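"""Anisotropic network models on Cα traces.

The ANM places identical harmonic springs (constant ``gamma``) between all
Cα pairs within a distance cutoff ``rc``.  Its 3N x 3N Hessian has exactly
six zero eigenvalues (rigid-body translations and rotations) when the
contact graph is connected and the structure is non-degenerate; the
remaining eigenvectors are the normal modes, and the low-frequency ("soft")
modes describe the collective motions that dominate functional transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures import Conformation

__all__ = [
    "AnmModel",
    "ModeSpectrum",
    "DEFAULT_CUTOFF",
    "DEFAULT_GAMMA",
    "contact_pairs",
    "build_hessian",
    "decompose",
    "build_anm",
    "mode_overlaps",
    "write_modes_nmd",
]

DEFAULT_CUTOFF = 15.0  # Å
DEFAULT_GAMMA = 1.0  # spring constant, energy/Å² (units absorbed)

# Eigenvalues below this fraction of the largest are treated as rigid-body
# zero modes; scale-free so it works for any gamma.
ZERO_MODE_REL_TOL = 1e-8


@dataclass(frozen=True)
class AnmModel:
    """Eigendecomposition of an ANM Hessian with rigid-body modes removed.

    ``eigenvectors`` has one unit 3N-vector per row, sorted by ascending
    eigenvalue; ``eigenvalues`` are strictly positive.
    """

    conformation: Conformation
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray  # (m,)
    eigenvectors: np.ndarray  # (m, 3N)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class ModeSpectrum:
    """Per-mode squared overlaps of a deformation with the normal modes."""

    squared_overlaps: np.ndarray  # (m,), non-negative
    cumulative: np.ndarray  # running sums, non-decreasing


def contact_pairs(coords: np.ndarray, cutoff: float):
    """Index pairs (i < j) within ``cutoff`` Å, via a k-d tree."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def _check_connected(n: int, pairs: np.ndarray, cutoff: float) -> None:
    if len(pairs) == 0:
        raise ValueError(
            f"no contacts at cutoff {cutoff} Å; increase the cutoff"
        )
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"contact graph has {n_comp} components at cutoff {cutoff} Å; "
            "increase the cutoff to connect the network"
        )


def build_hessian(
    conf: Conformation,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian.

    For a contact pair (i, j) at distance r the off-diagonal 3x3
    superelement is ``-(gamma / r^2) * outer(dr, dr)`` with ``dr`` the
    separation vector; diagonal superelements are minus the row sums, so
    uniform translations are exact null vectors.

    Raises
    ------
    ValueError
        If the contact graph is disconnected at ``cutoff``.
    """
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")
    coords = conf.coords
    n = conf.n_atoms
    pairs = contact_pairs(coords, cutoff)
    _check_connected(n, pairs, cutoff)

    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        dr = coords[j] - coords[i]
        block = -(gamma / (dr @ dr)) * np.outer(dr, dr)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def decompose(
    hessian: np.ndarray,
    n_modes="all",
    conformation: Conformation | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> AnmModel:
    """Eigendecompose an ANM Hessian, discarding the six rigid-body modes.

    Exactly six eigenvalues must fall below the zero tolerance
    (``1e-8 * max eigenvalue``); fewer signals a degenerate (e.g. collinear
    or planar) structure and more signals a disconnected network — both are
    rejected.  Modes are sorted by ascending eigenvalue and the first
    ``n_modes`` retained.
    """
    vals, vecs = scipy.linalg.eigh(hessian)
    tol = ZERO_MODE_REL_TOL * float(np.max(np.abs(vals)))
    n_zero = int(np.sum(np.abs(vals) < tol))
    if n_zero != 6:
        raise ValueError(
            f"expected 6 rigid-body zero modes, found {n_zero}: the network "
            "is degenerate (collinear/planar coordinates) or disconnected"
        )
    if np.min(vals) < -tol:
        raise ValueError("Hessian is not positive semidefinite")
    vals = vals[6:]
    vecs = vecs[:, 6:]
    if n_modes != "all":
        k = int(n_modes)
        if k < 1:
            raise ValueError("n_modes must be positive or 'all'")
        vals = vals[:k]
        vecs = vecs[:, :k]
    return AnmModel(
        conformation=conformation,
        cutoff=cutoff,
        gamma=gamma,
        eigenvalues=vals.copy(),
        eigenvectors=vecs.T.copy(),
    )


def build_anm(
    conf: Conformation,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    n_modes="all",
) -> AnmModel:
    """Build the Hessian for ``conf`` and return its retained normal modes.

    ``n_modes`` defaults to all 3N-6 internal modes; pathway generation
    typically retains ``min(20, 3N-6)`` soft modes.
    """
    hessian = build_hessian(conf, cutoff, gamma)
    return decompose(hessian, n_modes, conformation=conf, cutoff=cutoff, gamma=gamma)


def default_n_modes(conf: Conformation) -> int:
    """Default soft-mode count: min(20, 3N-6)."""
    return min(20, 3 * conf.n_atoms - 6)


def mode_overlaps(model: AnmModel, d: np.ndarray) -> ModeSpectrum:
    """Squared overlaps of a deformation vector with each normal mode.

    ``squared_overlaps[k] = (u_k . d_hat)^2`` for the unit deformation
    ``d_hat``; the cumulative sums reach 1 when the deformation lies in the
    span of the retained modes (always true for internal deformations when
    all 3N-6 modes are retained).
    """
    d = np.asarray(d, float).reshape(-1)
    if d.shape[0] != model.eigenvectors.shape[1]:
        raise ValueError(
            f"deformation length {d.shape[0]} does not match 3N = "
            f"{model.eigenvectors.shape[1]}"
        )
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero deformation vector")
    overlaps = (model.eigenvectors @ (d / norm)) ** 2
    return ModeSpectrum(squared_overlaps=overlaps, cumulative=np.cumsum(overlaps))


def write_modes_nmd(model: AnmModel, path) -> None:
    """Export modes as NMD-style plain text (one vector per line)."""
    with open(path, "w") as fh:
        if model.conformation is not None:
            fh.write("coordinates " + " ".join(
                f"{x:.3f}" for x in model.conformation.flat()) + "\n")
        for k, (lam, vec) in enumerate(zip(model.eigenvalues, model.eigenvectors)):
            fh.write(f"mode {k + 1} {lam:.6g} " + " ".join(
                f"{x:.6f}" for x in vec) + "\n")
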