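"""One-dimensional progress coordinate from a milestone pathway.

A milestone pathway is embedded into the 2D plane whose axes are the fitted
RMSD to endpoint A and to endpoint B.  The embedded milestones define a
midpoint polyline: its vertices are the embedded A endpoint, the midpoints
of consecutive embedded milestones, and the embedded B endpoint — M
intermediates give M+3 vertices and M+2 segments.  Any conformation is then
scored as Progress = X + F, where X is the index of the nearest polyline
segment and F the fractional projection along it.  This compresses the
high-dimensional pathway into a single interpretable scalar for
weighted-ensemble binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import Conformation, rmsd

__all__ = [
    "Embedding2D",
    "ProgressPolyline",
    "ProgressValue",
    "embed",
    "build_polyline",
    "progress",
    "radial_angle",
]

_MERGE_TOL = 1e-9  # consecutive polyline vertices closer than this collapse


@dataclass(frozen=True)
class Embedding2D:
    """The 2D RMSD plane defined by reference endpoints A and B."""

    refA: Conformation
    refB: Conformation

    def __post_init__(self):
        self.refA.assert_comparable(self.refB)


@dataclass(frozen=True)
class ProgressValue:
    """Progress = X + F: nearest segment index plus fractional projection.

    F is in [0, 1); a conformation sitting exactly on a shared vertex is
    reported as the start of the following segment, except the terminal
    vertex, which reports the full value M+2 (F = 1 on the last segment).
    """

    X: int
    F: float

    @property
    def value(self) -> float:
        return self.X + self.F


class ProgressPolyline:
    """Midpoint polyline in the 2D RMSD plane.

    Parameters
    ----------
    vertices : (K, 2) array
        Ordered polyline vertices; K = M + 3 for M intermediates.
    source : optional
        The pathway the polyline was built from (provenance only).
    """

    def __init__(self, vertices, source=None):
        vertices = np.asarray(vertices, float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 2:
            raise ValueError("vertices must be a (K>=2, 2) array")
        seg = np.diff(vertices, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) < _MERGE_TOL):
            raise ValueError("polyline has degenerate (zero-length) segments")
        self.vertices = vertices
        self.source = source

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    @property
    def M(self) -> int:
        """Intermediate count implied by the vertex count (K - 3)."""
        return len(self.vertices) - 3

    def reversed(self) -> "ProgressPolyline":
        """The same polyline traversed B-to-A (direction-specific view)."""
        return ProgressPolyline(self.vertices[::-1].copy(), source=self.source)

    def to_table(self, path) -> None:
        """Persist as a plain-text table: index, x (Å), y (Å)."""
        with open(path, "w") as fh:
            fh.write("# progress polyline vertices: index x_rmsdA y_rmsdB (Å)\n")
            for i, (x, y) in enumerate(self.vertices):
                fh.write(f"{i} {x:.6f} {y:.6f}\n")

    @classmethod
    def from_table(cls, path) -> "ProgressPolyline":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                _, x, y = line.split()
                rows.append((float(x), float(y)))
        return cls(np.array(rows))


def embed(conf: Conformation, e: Embedding2D) -> np.ndarray:
    """Locate a conformation in the 2D RMSD plane: (RMSD to A, RMSD to B)."""
    return np.array([rmsd(conf, e.refA, fit=True), rmsd(conf, e.refB, fit=True)])


def build_polyline(pathway, e: Embedding2D) -> ProgressPolyline:
    """Midpoint polyline of an embedded milestone pathway.

    Vertices are [p_0, (p_0+p_1)/2, ..., (p_M+p_{M+1})/2, p_{M+1}] for
    embedded milestones p_i.  Consecutive vertices closer than 1e-9 are
    merged (M adjusts accordingly).
    """
    milestones = list(pathway.milestones)
    if len(milestones) < 2:
        raise ValueError("pathway must contain at least two milestones")
    points = np.array([embed(c, e) for c in milestones])
    mids = 0.5 * (points[:-1] + points[1:])
    vertices = np.vstack([points[:1], mids, points[-1:]])
    keep = [vertices[0]]
    for v in vertices[1:]:
        if np.linalg.norm(v - keep[-1]) >= _MERGE_TOL:
            keep.append(v)
    if len(keep) < 2:
        raise ValueError("all milestones embed to a single point")
    return ProgressPolyline(np.array(keep), source=pathway)


def progress(point, polyline: ProgressPolyline) -> ProgressValue:
    """Progress value of a 2D point against the polyline.

    X is the segment with minimal point-to-segment distance (ties go to the
    lowest index); F is the clamped fractional projection onto it.  F = 1
    folds into (X+1, 0) except on the final segment, where the terminal
    vertex reports the full value M+2.
    """
    p = np.asarray(point, float).reshape(2)
    v = polyline.vertices
    seg = v[1:] - v[:-1]  # (S, 2)
    seg_len2 = np.sum(seg * seg, axis=1)
    t = np.clip(np.sum((p - v[:-1]) * seg, axis=1) / seg_len2, 0.0, 1.0)
    closest = v[:-1] + t[:, None] * seg
    dist2 = np.sum((closest - p) ** 2, axis=1)
    x = int(np.argmin(dist2))  # argmin returns the lowest index on ties
    f = float(t[x])
    if f >= 1.0:
        if x < polyline.n_segments - 1:
            return ProgressValue(X=x + 1, F=0.0)
        return ProgressValue(X=x, F=1.0)  # terminal vertex: value = M+2
    return ProgressValue(X=x, F=f)


def radial_angle(point) -> float:
    """Polar angle (degrees) of a 2D RMSD point, clamped to [0, 90].

    x is the RMSD to A, y the RMSD to B; the origin (both zero) is defined
    as 45 degrees by the equidistance convention.
    """
    x, y = float(point[0]), float(point[1])
    if x == 0.0 and y == 0.0:
        return 45.0
    return float(np.clip(math.degrees(math.atan2(y, x)), 0.0, 90.0))
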