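"""Langevin dynamics of the chromosome polymer and diffusion diagnostics.

Integration uses the BAOAB splitting of underdamped Langevin dynamics with
unit bead mass: a velocity half-kick, a half-drift, an exact
Ornstein-Uhlenbeck velocity update, another half-drift, and a closing
half-kick.  With the default friction (10 / tau) and time step (0.0005 tau)
the scheme is deeply stable and samples the target Boltzmann distribution to
high accuracy.  All randomness (initial Maxwell velocities and the
per-step thermal noise) comes from one ``numpy`` generator seeded per run,
so identical seeds give bitwise-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .polymer import Conformation, PolymerParams, OverstretchedBondError, zero_alpha

_NOISE_CHUNK = 2000  # steps of pre-generated Gaussian noise per kernel call


class IntegrationError(RuntimeError):
    """Numerical blow-up or non-finite coordinates during integration."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"integration failed at step {step}: {message}")


@dataclass(frozen=True)
class DynamicsParams:
    """Integrator settings in reduced units."""

    dt: float = 0.0005    # time step, tau
    gamma: float = 10.0   # friction coefficient, 1 / tau
    T: float = 1.0        # temperature, energy units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.T < 0:
            raise ValueError("T must be non-negative")


@dataclass
class Trajectory:
    """Time-ordered conformations on a (typically log-spaced) snapshot grid."""

    frames: np.ndarray            # (n_frames, N, 3)
    times: np.ndarray             # snapshot times in tau, strictly increasing
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, N, 3)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length must match frame count")
        if self.times.size > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def conformation(self, i: int) -> Conformation:
        return Conformation(self.frames[i].copy())


def log_snapshot_times(t_min: float, t_max: float, n: int = 60,
                       include_zero: bool = False) -> np.ndarray:
    """Logarithmically spaced snapshot times on [t_min, t_max]."""
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    times = np.geomspace(t_min, t_max, n)
    if include_zero:
        times = np.concatenate(([0.0], times))
    return times


def maxwell_velocities(n_beads: int, T: float, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at temperature T (unit mass)."""
    if T == 0:
        return np.zeros((n_beads, 3))
    return rng.normal(0.0, np.sqrt(T), size=(n_beads, 3))


def run_langevin(start: Conformation, alpha: np.ndarray | None,
                 params: PolymerParams, dyn: DynamicsParams, duration: float,
                 snapshot_times: np.ndarray | None = None,
                 velocities: np.ndarray | None = None,
                 provenance: dict | None = None,
                 return_velocities: bool = False):
    """Integrate Langevin dynamics for ``duration`` tau and record snapshots.

    Snapshots are taken at the integration step nearest each requested time
    (time 0 records the initial conformation).  Raises
    :class:`OverstretchedBondError` on FENE divergence and
    :class:`IntegrationError` if coordinates leave a 10 Rc ball or go
    non-finite.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    x = np.array(start.positions, dtype=float)
    n = x.shape[0]
    if alpha is None:
        alpha = zero_alpha(n)
    n_steps = max(1, int(round(duration / dyn.dt)))
    if snapshot_times is None:
        snapshot_times = log_snapshot_times(duration / 100.0, duration)
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    snap_steps = np.clip(np.round(snapshot_times / dyn.dt).astype(np.int64), 0, n_steps)
    if (np.diff(snap_steps) <= 0).any():
        raise ValueError("snapshot times must map to distinct, increasing steps")

    rng = np.random.default_rng(dyn.seed)
    v = maxwell_velocities(n, dyn.T, rng) if velocities is None else np.array(velocities)

    p = params
    g_table, g_inv_h, _ = _kernels.restraint_force_table(p.mu, p.r_contact)
    args = (p.eps, p.sigma, p.Kb, p.R0_fene, p.Ka, p.Rc, p.mu, p.r_contact,
            p.softcore_r0, p.k_wall, g_table, g_inv_h)
    f = np.empty_like(x)
    status = _kernels.pair_forces(x, alpha, *args, f)
    if status != _kernels.OK:
        raise OverstretchedBondError(status, float(np.linalg.norm(
            x[status + 1] - x[status])), p.R0_fene)

    frames = np.empty((snapshot_times.size, n, 3))
    out_i = 0
    while out_i < snap_steps.size and snap_steps[out_i] == 0:
        frames[out_i] = x
        out_i += 1

    blowup_r2 = (10.0 * p.Rc) ** 2
    step = 0
    while step < n_steps:
        n_chunk = min(_NOISE_CHUNK, n_steps - step)
        # stop chunks on snapshot boundaries so frames land on exact steps
        upcoming = snap_steps[(snap_steps > step) & (snap_steps <= step + n_chunk)]
        boundaries = np.unique(np.concatenate((upcoming, [step + n_chunk])))
        noise = rng.standard_normal((n_chunk, n, 3))
        used = 0
        for b in boundaries:
            sub = noise[used:b - step]
            used = b - step
            bond, substep = _kernels.baoab_chunk(
                x, v, f, alpha, *args, dyn.dt, dyn.gamma, dyn.T, sub)
            if bond != _kernels.OK:
                raise OverstretchedBondError(bond, float(np.linalg.norm(
                    x[bond + 1] - x[bond])), p.R0_fene)
            while out_i < snap_steps.size and snap_steps[out_i] == b:
                frames[out_i] = x
                out_i += 1
        step += n_chunk
        if not np.isfinite(x).all():
            raise IntegrationError(step, "non-finite coordinates")
        if (np.einsum("ij,ij->i", x, x) > blowup_r2).any():
            raise IntegrationError(step, "coordinates beyond 10 Rc")

    prov = dict(provenance or {})
    prov.setdefault("seed", dyn.seed)
    traj = Trajectory(frames, snap_steps * dyn.dt, prov)
    if return_velocities:
        return traj, v
    return traj


@dataclass
class MsdFit:
    """Power-law fit MSD ~ alpha_coef * t^beta over a time window."""

    alpha_coef: float
    beta: float
    fit_window: tuple


def compute_msd(trajs, per_locus: bool = False):
    """Time- and ensemble-averaged mean squared displacement per lag time.

    Requires a uniform snapshot grid shared by all trajectories.  Returns
    ``(lags, msd)`` with msd averaged over time origins, loci and
    trajectories; with ``per_locus`` the msd array is (n_lags, N).
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    times = trajs[0].times
    if times.size < 2:
        raise ValueError("trajectories must have at least two frames")
    dt_grid = np.diff(times)
    if not np.allclose(dt_grid, dt_grid[0], rtol=1e-6, atol=1e-12):
        raise ValueError("compute_msd requires a uniform snapshot grid")
    for t in trajs[1:]:
        if t.times.shape != times.shape or not np.allclose(t.times, times):
            raise ValueError("all trajectories must share the snapshot grid")

    n_frames = times.size
    lags = np.arange(1, n_frames) * dt_grid[0]
    acc = np.zeros((n_frames - 1, trajs[0].n_beads))
    counts = np.zeros(n_frames - 1)
    for t in trajs:
        for k in range(1, n_frames):
            disp = t.frames[k:] - t.frames[:-k]
            acc[k - 1] += (disp ** 2).sum(axis=2).mean(axis=0)
            counts[k - 1] += 1
    msd = acc / counts[:, None]
    return (lags, msd) if per_locus else (lags, msd.mean(axis=1))


def fit_msd_powerlaw(lags: np.ndarray, msd: np.ndarray, window: tuple) -> MsdFit:
    """Least-squares line in log-log coordinates over ``window = (t_lo, t_hi)``."""
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    lo, hi = window
    sel = (lags >= lo) & (lags <= hi)
    if sel.sum() < 5:
        raise ValueError("fit window must contain at least 5 points")
    if lags[sel].max() / lags[sel].min() < 10.0:
        raise ValueError("fit window must span at least one decade")
    if (msd[sel] <= 0).any():
        raise ValueError("MSD must be positive inside the fit window")
    beta, log_a = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)
    return MsdFit(alpha_coef=float(np.exp(log_a)), beta=float(beta),
                  fit_window=(float(lo), float(hi)))
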