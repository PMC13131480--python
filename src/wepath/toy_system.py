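"""Desk-scale two-state toy system: hinge endpoints, double-basin elastic
potential, and an overdamped Brownian propagator.

The generator builds a hinge "protein": two rigid arms of Cα beads joined at
a hinge bead, with the inter-arm angle open in state A and closed in state
B.  Each arm winds helically around a straight axis (exact 3.8 Å virtual
bonds) so the bead network is genuinely three-dimensional — a literally
collinear or planar trace would make the elastic-network Hessian degenerate.

The landscape is a smooth exponential mixture of two single-basin
elastic-network potentials, one per endpoint, giving a two-state surface
with a barrier whose soft directions align with the hinge motion.  Dynamics
are overdamped Langevin (Brownian) in reduced units; one step of dt = 1e-3
toy-time plays the role of ~1 ps, so a 100-step propagation interval stands
in for the 100 ps interval between resampling events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anm import contact_pairs, _check_connected
from .structures import Conformation

__all__ = [
    "HingeSpec",
    "DoubleBasinPotential",
    "make_hinge_endpoints",
    "make_double_basin",
    "basin_energy",
    "basin_gradient",
    "brownian_propagate",
    "brownian_propagate_batch",
    "make_brownian_propagator",
]

# Helical wobble of each arm off its axis: tilt of successive bond vectors.
_WOBBLE_DEG = 15.0
_TWIST_DEG = 120.0  # phase advance of the wobble per bead


@dataclass(frozen=True)
class HingeSpec:
    """Geometry of the two-state hinge fixture.

    Two arms of ``n_per_arm`` beads each flank a central hinge bead
    (N = 2 * n_per_arm + 1).  The inter-arm axis angle is ``open_angle``
    for endpoint A and ``closed_angle`` for endpoint B.  ``noise`` adds
    seeded Gaussian jitter (Å) to both endpoints.
    """

    n_per_arm: int = 10
    bond_length: float = 3.8
    open_angle: float = 140.0
    closed_angle: float = 70.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 5:
            raise ValueError("n_per_arm must be >= 5")
        for a in (self.open_angle, self.closed_angle):
            if not (0.0 < a < 180.0):
                raise ValueError("angles must be in (0, 180) degrees")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


def _arm_positions(axis: np.ndarray, n: int, bond: float) -> np.ndarray:
    """Bead positions of one rigid arm starting at the origin hinge.

    Each bond vector has exact length ``bond`` and tilts by a fixed wobble
    angle off the straight arm axis, with the tilt azimuth advancing by a
    fixed twist per bead — a helical zigzag around the axis.
    """
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    alpha = math.radians(_WOBBLE_DEG)
    pos = np.zeros(3)
    out = []
    for i in range(n):
        phi = math.radians(_TWIST_DEG) * i
        step = bond * (
            math.cos(alpha) * axis
            + math.sin(alpha) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        pos = pos + step
        out.append(pos)
    return np.array(out)


def _hinge_coords(spec: HingeSpec, angle_deg: float) -> np.ndarray:
    half = math.radians(angle_deg) / 2.0
    axis1 = np.array([math.cos(half), math.sin(half), 0.0])
    axis2 = np.array([math.cos(half), -math.sin(half), 0.0])
    arm1 = _arm_positions(axis1, spec.n_per_arm, spec.bond_length)
    arm2 = _arm_positions(axis2, spec.n_per_arm, spec.bond_length)
    # order: arm1 tip -> hinge -> arm2 tip, so the chain is contiguous
    return np.vstack([arm1[::-1], np.zeros((1, 3)), arm2])


def make_hinge_endpoints(spec: HingeSpec | None = None):
    """Build the comparable open (A) and closed (B) hinge endpoints."""
    spec = spec or HingeSpec()
    n_total = 2 * spec.n_per_arm + 1
    labels = tuple(f"A:GLY:{i + 1}" for i in range(n_total))
    coords_a = _hinge_coords(spec, spec.open_angle)
    coords_b = _hinge_coords(spec, spec.closed_angle)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        coords_a = coords_a + spec.noise * rng.standard_normal(coords_a.shape)
        coords_b = coords_b + spec.noise * rng.standard_normal(coords_b.shape)
    return (
        Conformation(labels, coords_a, name="hinge-open"),
        Conformation(labels, coords_b, name="hinge-closed"),
    )


@dataclass(frozen=True)
class DoubleBasinPotential:
    """Smooth two-basin mixture of endpoint elastic-network potentials.

    Each basin is ``V_X(R) = (gamma/2) * sum_{(i,j) in contacts_X}
    (r_ij - r_ij^X)^2`` over the pairs within ``rc`` of endpoint X, with
    native distances taken from that endpoint.  The mixture
    ``V = -(1/beta_mix) * ln(exp(-beta_mix V_A) + exp(-beta_mix V_B))``
    approaches min(V_A, V_B) as ``beta_mix`` grows.
    """

    pairs_a: np.ndarray  # (Pa, 2) int
    dists_a: np.ndarray  # (Pa,) native distances, Å
    pairs_b: np.ndarray
    dists_b: np.ndarray
    inc_a: np.ndarray  # (N, Pa) signed incidence matrix (+1 on j, -1 on i)
    inc_b: np.ndarray
    gamma: float = 1.0
    beta_mix: float = 5.0
    n_atoms: int = 0


def make_double_basin(
    endpoint_a: Conformation,
    endpoint_b: Conformation,
    rc: float = 10.0,
    gamma: float = 1.0,
    beta_mix: float = 5.0,
) -> DoubleBasinPotential:
    """Build the double-basin potential from two comparable endpoints."""
    endpoint_a.assert_comparable(endpoint_b)
    n = endpoint_a.n_atoms
    pot = {}
    for tag, conf in (("a", endpoint_a), ("b", endpoint_b)):
        pairs = contact_pairs(conf.coords, rc)
        _check_connected(n, pairs, rc)
        d = np.linalg.norm(conf.coords[pairs[:, 1]] - conf.coords[pairs[:, 0]], axis=1)
        inc = np.zeros((n, len(pairs)))
        inc[pairs[:, 1], np.arange(len(pairs))] = 1.0
        inc[pairs[:, 0], np.arange(len(pairs))] = -1.0
        pot[f"pairs_{tag}"] = pairs
        pot[f"dists_{tag}"] = d
        pot[f"inc_{tag}"] = inc
    return DoubleBasinPotential(gamma=gamma, beta_mix=beta_mix, n_atoms=n, **pot)


def _single_basin(coords, pairs, dists0, inc, gamma):
    """Energy and gradient of one elastic basin; coords is (..., N, 3)."""
    dr = coords[..., pairs[:, 1], :] - coords[..., pairs[:, 0], :]  # (..., P, 3)
    r = np.linalg.norm(dr, axis=-1)
    dev = r - dists0
    energy = 0.5 * gamma * np.sum(dev * dev, axis=-1)
    # dV/dR_i = gamma * sum_j (r_ij - r0)(R_i - R_j)/r_ij, accumulated as a
    # signed-incidence matmul so batches of structures vectorize
    coef = (gamma * dev / r)[..., None] * dr  # per-pair force, (..., P, 3)
    grad = np.matmul(inc, coef)
    return energy, grad


def _mixture(coords, potential):
    ea, ga = _single_basin(
        coords, potential.pairs_a, potential.dists_a, potential.inc_a, potential.gamma
    )
    eb, gb = _single_basin(
        coords, potential.pairs_b, potential.dists_b, potential.inc_b, potential.gamma
    )
    beta = potential.beta_mix
    # log-sum-exp guarded mixture and softmax basin weights
    m = np.minimum(ea, eb)
    za = np.exp(-beta * (ea - m))
    zb = np.exp(-beta * (eb - m))
    energy = m - np.log(za + zb) / beta
    wa = za / (za + zb)
    grad = wa[..., None, None] * ga + (1.0 - wa)[..., None, None] * gb
    return energy, grad


def basin_energy(conf: Conformation, potential: DoubleBasinPotential) -> float:
    """Double-basin energy of a conformation (reduced units)."""
    return float(_mixture(conf.coords, potential)[0])


def basin_gradient(conf: Conformation, potential: DoubleBasinPotential) -> np.ndarray:
    """Analytic 3N gradient of the double-basin energy."""
    return _mixture(conf.coords, potential)[1].reshape(-1)


def brownian_propagate_batch(
    coords: np.ndarray,
    potential: DoubleBasinPotential,
    dt: float,
    n_steps: int,
    temperature: float,
    friction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance a (B, N, 3) batch of structures by overdamped Langevin steps.

    R <- R - (dt/friction) grad V + sqrt(2 kT dt / friction) xi, with xi
    standard normal per coordinate.  Deterministic given the rng state.
    """
    coords = np.array(coords, float)
    sigma = math.sqrt(2.0 * temperature * dt / friction)
    blow_up = 1e6
    for _ in range(n_steps):
        _, grad = _mixture(coords, potential)
        coords -= (dt / friction) * grad
        if sigma > 0:
            coords += sigma * rng.standard_normal(coords.shape)
        if not np.all(np.isfinite(coords)) or np.max(np.abs(coords)) > blow_up:
            raise FloatingPointError(
                "Brownian integration blew up; reduce dt or the temperature"
            )
    return coords


def brownian_propagate(
    conf: Conformation,
    potential: DoubleBasinPotential,
    dt: float,
    n_steps: int,
    temperature: float,
    friction: float,
    rng: np.random.Generator,
) -> Conformation:
    """Propagate one conformation; see :func:`brownian_propagate_batch`."""
    # stability guard: RMS single-step thermal displacement must stay well
    # below the bond length for the harmonic network to make sense
    sigma = math.sqrt(2.0 * temperature * dt / friction)
    if sigma >= 0.5 * 3.8:
        raise ValueError(
            f"dt too large: single-step RMS displacement {sigma:.3g} Å "
            "exceeds half a virtual bond"
        )
    out = brownian_propagate_batch(
        conf.coords[None], potential, dt, n_steps, temperature, friction, rng
    )
    return conf.with_coords(out[0])


def make_brownian_propagator(
    potential: DoubleBasinPotential,
    n_steps: int = 100,
    dt: float = 1e-3,
    temperature: float = 1.0,
    friction: float = 1.0,
):
    """Propagator callable ``(conf, rng) -> conf`` for the WE engine.

    The default 100 steps of dt = 1e-3 is the toy analogue of a 100 ps
    propagation interval.
    """

    def propagator(conf: Conformation, rng: np.random.Generator) -> Conformation:
        return brownian_propagate(
            conf, potential, dt, n_steps, temperature, friction, rng
        )

    propagator.n_steps = n_steps
    propagator.dt = dt
    propagator.temperature = temperature
    propagator.friction = friction
    propagator.potential = potential
    return propagator
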