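"""Coarse-grained chromosome polymer energy model.

One bead per genomic bin, connected by FENE bonds with an angle term that
favors locally straight chains, a bounded soft-core excluded-volume
interaction that permits chain crossing (mimicking topoisomerase activity),
spherical confinement at fixed volume fraction, and a data-derived restraint
term linear in smooth pairwise contact indicators:

    V(r | S) = V_FENE + V_angle + V_hardcore + V_softcore + V_confine
               + sum_{|i-j|>1} alpha_ij * P(r_ij)

with P(r) = [1 + tanh(mu * (r_c - r))] / 2.  A positive alpha penalizes
contact formation for that pair; a negative alpha rewards it.  All energies
are in units of epsilon and lengths in units of sigma (reduced units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

#: bead count and confinement radius of the full-scale reference system
#: (chr14 long arm at 100 kb: 857 beads confined at 9.7 sigma gives a 10%
#: chromosome volume fraction).
REFERENCE_N = 857
REFERENCE_RC = 9.7

_SOFTCORE_R0_DEFAULT = 1.0 / ((1.0 + math.sqrt(2.0)) / 2.0) ** (1.0 / 6.0)


class OverstretchedBondError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension."""

    def __init__(self, bond_index: int, length: float, r0: float):
        self.bond_index = bond_index
        super().__init__(
            f"bond {bond_index} has length {length:.4f} >= R0 = {r0} "
            "(FENE divergence)"
        )


def confinement_radius(n_beads: int) -> float:
    """Confinement radius preserving the reference density for any chain size.

    Scales the reference radius by (N / N_ref)^(1/3) so the bead volume
    fraction inside the sphere is the same for desk-scale chains as for the
    full 857-bead system.
    """
    return REFERENCE_RC * (n_beads / REFERENCE_N) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PolymerParams:
    """Force-field constants in reduced units (energies in eps, lengths in sigma).

    ``r_contact`` is the midpoint of the smooth contact indicator; it is a
    distinct parameter from the FENE maximum extension even though both
    default to 1.5 sigma.
    """

    eps: float = 1.0
    sigma: float = 1.0
    Kb: float = 30.0          # FENE stiffness, eps / sigma^2
    R0_fene: float = 1.5      # FENE maximum bond extension, sigma
    Ka: float = 2.0           # angle stiffness, eps
    Rc: float = REFERENCE_RC  # confinement radius, sigma
    mu: float = 3.0           # contact-indicator steepness, 1 / sigma
    r_contact: float = 1.5    # contact-indicator midpoint, sigma
    softcore_r0: float = _SOFTCORE_R0_DEFAULT  # plateau crossover, sigma
    k_wall: float = 50.0      # confinement wall stiffness, eps / sigma^2

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.softcore_r0 >= 2.0 ** (1.0 / 6.0) * self.sigma:
            raise ValueError("softcore_r0 must lie below the LJ cutoff 2^(1/6) sigma")

    @property
    def lj_cutoff(self) -> float:
        """Distance beyond which excluded-volume terms vanish."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    def with_rc_for(self, n_beads: int) -> "PolymerParams":
        """Copy with the confinement radius rescaled to ``n_beads``."""
        d = asdict(self)
        d["Rc"] = confinement_radius(n_beads)
        return PolymerParams(**d)


@dataclass
class Conformation:
    """An N x 3 array of bead coordinates (sigma units) on a segment."""

    positions: np.ndarray
    segment: object = None  # SegmentSpec, optional for toy conformations

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError(f"positions must be N x 3, got {x.shape}")
        if x.shape[0] < 2:
            raise ValueError("conformation needs at least two beads")
        if not np.isfinite(x).all():
            raise ValueError("positions contain non-finite values")
        self.positions = x

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


def validate_alpha(alpha: np.ndarray, n_beads: int | None = None) -> np.ndarray:
    """Check a restraint-strength matrix: square, symmetric, finite, and zero
    on the diagonal and the bonded (|i-j| = 1) pairs."""
    a = np.asarray(alpha, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("alpha must be a square matrix")
    if n_beads is not None and a.shape[0] != n_beads:
        raise ValueError(f"alpha size {a.shape[0]} does not match {n_beads} beads")
    if not np.isfinite(a).all():
        raise ValueError("alpha contains non-finite entries")
    if not np.allclose(a, a.T, atol=1e-12, rtol=0.0):
        raise ValueError("alpha must be symmetric")
    n = a.shape[0]
    idx = np.arange(n)
    if not np.allclose(a[idx, idx], 0.0) or not np.allclose(a[idx[:-1], idx[:-1] + 1], 0.0):
        raise ValueError("alpha must vanish on the diagonal and bonded pairs")
    return a


def zero_alpha(n_beads: int) -> np.ndarray:
    return np.zeros((n_beads, n_beads), dtype=float)


# ---------------------------------------------------------------------------
# scalar / vectorized potential terms
# ---------------------------------------------------------------------------

def eval_vlj(r, eps: float = 1.0, sigma: float = 1.0):
    """Shifted Lennard-Jones: 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps.

    Zero at its minimum r = 2^(1/6) sigma; equals 2 eps at the soft-core
    crossover r0 = sigma / ((1 + sqrt(2))/2)^(1/6).
    """
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("distance must be positive")
    s6 = (sigma / r) ** 6
    out = 4.0 * eps * (s6 * s6 - s6) + eps
    return out if out.ndim else float(out)


def _dvlj_dr(r, eps: float = 1.0, sigma: float = 1.0):
    s6 = (sigma / r) ** 6
    return -24.0 * eps * (2.0 * s6 * s6 - s6) / r


def eval_fene(r, params: PolymerParams = PolymerParams()):
    """FENE bond energy -0.5 Kb R0^2 ln[1 - (r/R0)^2]; diverges at r = R0."""
    r = np.asarray(r, dtype=float)
    R0 = params.R0_fene
    if (r < 0).any():
        raise ValueError("bond length must be non-negative")
    if (r >= R0).any():
        bad = int(np.argmax(np.asarray(r) >= R0))
        raise OverstretchedBondError(bad, float(np.atleast_1d(r)[bad]), R0)
    out = -0.5 * params.Kb * R0 ** 2 * np.log(1.0 - (r / R0) ** 2)
    return out if out.ndim else float(out)


def eval_hardcore(r, params: PolymerParams = PolymerParams()):
    """Purely repulsive (WCA-style) excluded volume for bonded neighbors:
    shifted LJ below its minimum, zero beyond."""
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("distance must be positive")
    out = np.where(r <= params.lj_cutoff, eval_vlj(r, params.eps, params.sigma), 0.0)
    return out if out.ndim else float(out)


def eval_angle(theta, params: PolymerParams = PolymerParams()):
    """Angle energy Ka [1 - cos(theta - pi)]: zero for a straight chain
    (theta = pi), maximal 2 Ka for a fully folded one (theta = 0)."""
    theta = np.asarray(theta, dtype=float)
    if (theta < 0).any() or (theta > np.pi + 1e-12).any():
        raise ValueError("theta must lie in [0, pi]")
    out = params.Ka * (1.0 - np.cos(theta - np.pi))
    return out if out.ndim else float(out)


def eval_softcore(r, params: PolymerParams = PolymerParams()):
    """Bounded excluded volume for non-bonded pairs.

    Plateau branch 2 eps (1 + tanh[0.5 V_LJ(r)/eps - 1]) for r <= r0, the
    shifted LJ for r0 < r <= 2^(1/6) sigma, zero beyond; continuous at both
    joins, with a finite maximum of 4 eps at full overlap so chains can pass
    through each other.
    """
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ValueError("distance must be positive")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    out = np.zeros_like(r)
    r0, cut = params.softcore_r0, params.lj_cutoff
    low = r <= r0
    mid = (r > r0) & (r <= cut)
    if low.any():
        vlj = eval_vlj(r[low], params.eps, params.sigma)
        out[low] = 2.0 * params.eps * (1.0 + np.tanh(0.5 * vlj / params.eps - 1.0))
    if mid.any():
        out[mid] = eval_vlj(r[mid], params.eps, params.sigma)
    return float(out[0]) if scalar else out


def eval_contact_prob(r, params: PolymerParams = PolymerParams()):
    """Smooth contact indicator P(r) = [1 + tanh(mu (r_c - r))] / 2."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distance must be non-negative")
    out = 0.5 * (1.0 + np.tanh(params.mu * (params.r_contact - r)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# conformation-level energies
# ---------------------------------------------------------------------------

def _pair_distances(x: np.ndarray):
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)), diff


def eval_restraint(conf: Conformation, alpha: np.ndarray,
                   params: PolymerParams = PolymerParams()) -> float:
    """Restraint energy sum_{|i-j|>1} alpha_ij P(r_ij) (each pair once)."""
    x = conf.positions
    a = validate_alpha(alpha, x.shape[0])
    dist, _ = _pair_distances(x)
    n = x.shape[0]
    iu = np.triu_indices(n, k=2)
    return float(np.sum(a[iu] * eval_contact_prob(dist[iu], params)))


def eval_confinement(conf: Conformation, params: PolymerParams = PolymerParams()) -> float:
    """Half-harmonic spherical wall: k_wall (|r| - Rc)^2 per bead outside Rc."""
    radii = np.linalg.norm(conf.positions, axis=1)
    over = np.maximum(radii - params.Rc, 0.0)
    return float(params.k_wall * np.sum(over ** 2))


def total_energy_forces(conf: Conformation, alpha: np.ndarray | None = None,
                        params: PolymerParams = PolymerParams()):
    """Energy breakdown and analytic forces for a conformation.

    Returns ``(breakdown, forces)`` where ``breakdown`` maps term names
    (fene, angle, hardcore, softcore, confinement, restraint, total) to
    energies and ``forces`` is the exact negative gradient, N x 3.

    This is the reference (vectorized NumPy) implementation; the compiled
    kernel used by the integrator is tested against it.
    """
    x = conf.positions
    n = x.shape[0]
    if alpha is None:
        alpha = zero_alpha(n)
    a = validate_alpha(alpha, n)
    forces = np.zeros_like(x)
    breakdown: dict[str, float] = {}

    # --- bonds: FENE + hard core on (i, i+1)
    bond_vec = x[1:] - x[:-1]
    bond_len = np.linalg.norm(bond_vec, axis=1)
    if (bond_len >= params.R0_fene).any():
        bad = int(np.argmax(bond_len >= params.R0_fene))
        raise OverstretchedBondError(bad, float(bond_len[bad]), params.R0_fene)
    breakdown["fene"] = float(np.sum(eval_fene(bond_len, params)))
    # dV/dr = Kb r / (1 - (r/R0)^2)
    dfene = params.Kb * bond_len / (1.0 - (bond_len / params.R0_fene) ** 2)
    in_cut = bond_len <= params.lj_cutoff
    breakdown["hardcore"] = float(
        np.sum(eval_vlj(bond_len[in_cut], params.eps, params.sigma))
    )
    dhc = np.where(in_cut, _dvlj_dr(bond_len, params.eps, params.sigma), 0.0)
    fmag = (dfene + dhc) / bond_len  # force per unit bond vector
    fb = fmag[:, None] * bond_vec
    forces[:-1] += fb
    forces[1:] -= fb

    # --- angles on (i-1, i, i+1): V = Ka (1 + cos theta)
    if n >= 3:
        u = x[:-2] - x[1:-1]   # center -> previous
        v = x[2:] - x[1:-1]    # center -> next
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        breakdown["angle"] = float(params.Ka * np.sum(1.0 + cos_t))
        # grad of cos(theta) wrt the end points; V = Ka (1 + cos)
        gu = (v / nv[:, None] - cos_t[:, None] * u / nu[:, None]) / nu[:, None]
        gv = (u / nu[:, None] - cos_t[:, None] * v / nv[:, None]) / nv[:, None]
        f_prev = -params.Ka * gu
        f_next = -params.Ka * gv
        np.add.at(forces, np.arange(n - 2), f_prev)
        np.add.at(forces, np.arange(2, n), f_next)
        np.add.at(forces, np.arange(1, n - 1), -(f_prev + f_next))
    else:
        breakdown["angle"] = 0.0

    # --- non-bonded pairs |i-j| >= 2: soft core + restraint
    dist, diff = _pair_distances(x)
    iu, ju = np.triu_indices(n, k=2)
    r = dist[iu, ju]
    dv = np.zeros_like(r)  # dV/dr accumulated over both terms

    sc_energy = 0.0
    low = r <= params.softcore_r0
    mid = (r > params.softcore_r0) & (r <= params.lj_cutoff)
    if low.any():
        vlj = eval_vlj(r[low], params.eps, params.sigma)
        u_arg = 0.5 * vlj / params.eps - 1.0
        sc_energy += float(np.sum(2.0 * params.eps * (1.0 + np.tanh(u_arg))))
        e = np.exp(-2.0 * np.abs(u_arg))  # sech^2 without cosh overflow
        sech2 = 4.0 * e / (1.0 + e) ** 2
        dv[low] += sech2 * _dvlj_dr(r[low], params.eps, params.sigma)
    if mid.any():
        sc_energy += float(np.sum(eval_vlj(r[mid], params.eps, params.sigma)))
        dv[mid] += _dvlj_dr(r[mid], params.eps, params.sigma)
    breakdown["softcore"] = sc_energy

    apair = a[iu, ju]
    t = np.tanh(params.mu * (params.r_contact - r))
    breakdown["restraint"] = float(np.sum(apair * 0.5 * (1.0 + t)))
    dv += apair * (-0.5 * params.mu) * (1.0 - t ** 2)

    fpair = (-dv / r)[:, None] * diff[iu, ju]  # force on bead iu
    np.add.at(forces, iu, fpair)
    np.add.at(forces, ju, -fpair)

    # --- confinement
    radii = np.linalg.norm(x, axis=1)
    over = radii - params.Rc
    outside = over > 0
    breakdown["confinement"] = float(params.k_wall * np.sum(over[outside] ** 2))
    if outside.any():
        fmag_c = -2.0 * params.k_wall * over[outside] / radii[outside]
        forces[outside] += fmag_c[:, None] * x[outside]

    breakdown["total"] = float(sum(breakdown.values()))
    return breakdown, forces
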