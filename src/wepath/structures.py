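"""Cα structure container, PDB I/O, optimal superposition and RMSD.

Everything downstream (elastic network models, pathway generation, the
progress coordinate, weighted-ensemble bookkeeping) operates on ordered
Cα coordinate sets in Å.  Two conformations are *comparable* when they
have the same number of residues with identical residue labels in the
same order; every pairwise operation requires comparability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Conformation",
    "SuperpositionResult",
    "ComparabilityError",
    "read_pdb",
    "write_pdb_trajectory",
    "superpose",
    "rmsd",
]

# Canonical residue label: "<chain>:<resname>:<resid><icode>", e.g. "A:GLY:12".
_LABEL_RE = re.compile(r"^(?P<chain>[^:]*):(?P<resname>[^:]*):(?P<resid>-?\d+)(?P<icode>\D?)$")


class ComparabilityError(ValueError):
    """Raised when two conformations cannot be compared residue-by-residue."""


@dataclass(frozen=True)
class Conformation:
    """An ordered set of Cα coordinates with residue labels.

    Parameters
    ----------
    residue_labels : tuple of str
        One identifier per residue, in chain order.  Labels written by
        :func:`read_pdb` and the toy-system generator follow the canonical
        ``"chain:resname:resid"`` form so they survive a PDB round trip.
    coords : (N, 3) float array
        Cα positions in Å.
    name : str
        Free-text tag carried through transformations.
    """

    residue_labels: tuple
    coords: np.ndarray
    name: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError(f"need at least 3 residues, got {coords.shape[0]}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        labels = tuple(str(x) for x in self.residue_labels)
        if len(labels) != coords.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {coords.shape[0]} coordinate rows"
            )
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_labels", labels)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Coordinates as a 3N vector (x1, y1, z1, x2, ...)."""
        return self.coords.reshape(-1)

    def with_coords(self, coords, name: str | None = None) -> "Conformation":
        """Copy of this conformation with new coordinates (labels kept)."""
        return replace(
            self, coords=np.asarray(coords, float).reshape(self.n_atoms, 3),
            name=self.name if name is None else name,
        )

    def assert_comparable(self, other: "Conformation") -> None:
        if self.n_atoms != other.n_atoms:
            raise ComparabilityError(
                f"residue counts differ: {self.n_atoms} vs {other.n_atoms}"
            )
        for i, (a, b) in enumerate(zip(self.residue_labels, other.residue_labels)):
            if a != b:
                raise ComparabilityError(
                    f"residue label mismatch at position {i}: {a!r} vs {b!r}"
                )


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform from a Kabsch fit: x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, after applying the transform to the mobile set


def read_pdb(path, chain=None, model=None) -> Conformation:
    """Read the Cα trace of one model from a PDB file.

    Keeps only atoms named ``CA``; for alternate locations the highest
    occupancy (ties: first altloc id) is kept.  Atoms are ordered by chain,
    then residue number and insertion code.  ``model`` is 1-based and
    defaults to the first model.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1 if model is None else int(model),
                              altloc="occupancy")
    mask = atoms.atom_name == "CA"
    if chain is not None:
        mask &= atoms.chain_id == str(chain)
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError(f"no CA atoms found in {path}"
                         + (f" (chain {chain})" if chain else ""))
    order = np.lexsort((ca.ins_code, ca.res_id, ca.chain_id))
    ca = ca[order]
    labels = [
        f"{c}:{rn}:{ri}{ic}"
        for c, rn, ri, ic in zip(ca.chain_id, ca.res_name, ca.res_id, ca.ins_code)
    ]
    if len(set(labels)) != len(labels):
        dup = next(l for i, l in enumerate(labels) if l in labels[:i])
        raise ValueError(f"duplicate CA for residue {dup!r} after altloc resolution")
    if len(labels) < 3:
        raise ValueError(f"fewer than 3 CA atoms in {path}")
    import os
    return Conformation(tuple(labels), ca.coord, name=os.path.basename(str(path)))


def _labels_to_fields(labels):
    chains, resnames, resids, icodes = [], [], [], []
    for i, lab in enumerate(labels):
        m = _LABEL_RE.match(lab)
        if m:
            chains.append(m["chain"] or "A")
            resnames.append(m["resname"] or "GLY")
            resids.append(int(m["resid"]))
            icodes.append(m["icode"])
        else:  # non-canonical label: sequential fallback
            chains.append("A")
            resnames.append("GLY")
            resids.append(i + 1)
            icodes.append("")
    return chains, resnames, resids, icodes


def write_pdb_trajectory(confs, path) -> None:
    """Write conformations as a multi-MODEL PDB file.

    All conformations must be mutually comparable; coordinates round-trip
    through :func:`read_pdb` to PDB precision (3 decimals).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    confs = list(confs)
    if not confs:
        raise ValueError("no conformations to write")
    first = confs[0]
    for c in confs[1:]:
        first.assert_comparable(c)
    n = first.n_atoms
    chains, resnames, resids, icodes = _labels_to_fields(first.residue_labels)
    template = struc.AtomArray(n)
    template.chain_id = np.array(chains, dtype="U4")
    template.res_name = np.array(resnames, dtype="U5")
    template.res_id = np.array(resids, dtype=int)
    template.ins_code = np.array(icodes, dtype="U1")
    template.atom_name = np.full(n, "CA", dtype="U6")
    template.element = np.full(n, "C", dtype="U2")
    template.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([template] * len(confs))
    stack.coord = np.stack([c.coords for c in confs])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Least-squares rigid fit of mobile onto reference (SVD Kabsch).

    Reflections are suppressed by flipping the sign of the smallest
    singular vector, so the returned rotation always has det = +1.
    """
    pc = mobile_xyz.mean(axis=0)
    qc = ref_xyz.mean(axis=0)
    h = (mobile_xyz - pc).T @ (ref_xyz - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    moved = mobile_xyz @ rot.T + trans
    dev = moved - ref_xyz
    value = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    return rot, trans, value, moved


def superpose(mobile: Conformation, reference: Conformation):
    """Optimally superpose ``mobile`` onto ``reference``.

    Returns
    -------
    (SuperpositionResult, Conformation)
        The rigid transform (proper rotation, no reflection even for
        mirror-image inputs) and the transformed mobile conformation.
    """
    mobile.assert_comparable(reference)
    rot, trans, value, moved = _kabsch(mobile.coords, reference.coords)
    result = SuperpositionResult(rotation=rot, translation=trans, rmsd=value)
    return result, mobile.with_coords(moved)


def rmsd(a: Conformation, b: Conformation, fit: bool = True) -> float:
    """RMSD between comparable conformations, in Å.

    With ``fit=True`` the global minimum over rigid transforms (symmetric
    in its arguments); with ``fit=False`` the raw coordinate deviation.
    """
    a.assert_comparable(b)
    if fit:
        return superpose(a, b)[0].rmsd
    dev = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
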