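"""Maximum-entropy fitting of pairwise restraints to a target contact map.

The effective potential of a cell state S is the generic polymer potential
plus a restraint term linear in smooth contact indicators,
``V(r|S) = V_polymer + sum alpha_ij P_ij(r)``.  The alphas are the Lagrange
multipliers of the constraints <P_ij> = f_ij and are found by the standard
dual ascent: alternate short Langevin sampling under the current potential
with the first-order update ``alpha += eta (<P> - f)``.  Over-contacted
pairs (<P> > f) thus acquire positive alpha (a contact penalty) and
under-contacted pairs a negative one, until the simulated ensemble's
contact map reproduces the target.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .dynamics import DynamicsParams, run_langevin
from .maps import ContactMap
from .polymer import (Conformation, PolymerParams, eval_contact_prob,
                      validate_alpha, zero_alpha)
from .segments import SegmentSpec


class FitDivergenceError(RuntimeError):
    """The sweep-to-sweep deviation kept growing; try a smaller eta."""


@dataclass
class FitReport:
    """Agreement between a simulated ensemble's contact map and its target."""

    pearson_raw: float
    pearson_log: float
    max_abs_dev: float
    n_sweeps: int

    def __post_init__(self) -> None:
        for r in (self.pearson_raw, self.pearson_log):
            if np.isfinite(r) and not -1.0 <= r <= 1.0 + 1e-12:
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class Landscape:
    """A fitted effective energy landscape: restraints + force-field constants."""

    alpha: np.ndarray
    params: PolymerParams
    target_id: str = ""
    fit_report: FitReport | None = None
    final_conformation: Conformation | None = None
    segment: SegmentSpec | None = None
    final_pool: list | None = None  # last sampling-chain endpoints

    def __post_init__(self) -> None:
        self.alpha = validate_alpha(self.alpha)

    @property
    def n_beads(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class MaxEntSchedule:
    """Dual-ascent schedule.

    Each sweep advances a pool of ``n_chains`` independent Langevin chains
    (each continuing from its last frame), discards ``burn_in`` tau per
    chain and records ``samples_per_chain`` conformations spaced
    ``sample_spacing`` tau apart.  The update uses the running mean of the
    last ``estimate_window`` sweeps' contact maps -- the pool and the
    window both damp the glue/unglue oscillations a single noisy chain
    produces.  ``eta`` decays geometrically per sweep; iteration stops at
    ``tol`` Pearson correlation (raw scale) or after ``sweeps`` sweeps.
    """

    eta: float = 1.5
    eta_decay: float = 0.98
    sweeps: int = 30
    n_chains: int = 4
    samples_per_chain: int = 6
    sample_spacing: float = 0.5
    burn_in: float = 3.0
    pre_equilibrate: float = 5.0  # tau under the bare polymer before sweep 1
    estimate_window: int = 3
    tol: float = 0.95
    alpha_max: float = 30.0
    divergence_patience: int = 8

    def __post_init__(self) -> None:
        if min(self.eta, self.sweeps, self.n_chains, self.samples_per_chain,
               self.estimate_window) <= 0:
            raise ValueError("schedule entries must be positive")


def allowed_pair_mask(n: int) -> np.ndarray:
    """Boolean mask of restrainable pairs: |i - j| > 1 (upper and lower)."""
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :]) > 1


def contact_matrix(conf: Conformation, params: PolymerParams) -> np.ndarray:
    """Smooth contact-indicator matrix of one conformation (diagonal = 1)."""
    d = squareform(pdist(conf.positions))
    p = eval_contact_prob(np.maximum(d, 0.0), params)
    np.fill_diagonal(p, 1.0)
    return p


def estimate_contact_map(ensemble, params: PolymerParams,
                         segment: SegmentSpec | None = None) -> ContactMap:
    """Ensemble-mean contact map <P_ij> over a set of conformations."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must contain at least one conformation")
    n = ensemble[0].n_beads
    for c in ensemble:
        if c.n_beads != n:
            raise ValueError("all conformations must have the same size")
    mean_p = np.zeros((n, n))
    for c in ensemble:
        mean_p += contact_matrix(c, params)
    mean_p /= len(ensemble)
    mean_p = 0.5 * (mean_p + mean_p.T)
    if segment is None:
        segment = ensemble[0].segment or SegmentSpec.desk_scale(n)
    return ContactMap(np.clip(mean_p, 0.0, 1.0), segment)


def update_alphas(alpha: np.ndarray, estimated: ContactMap, target: ContactMap,
                  eta: float, alpha_max: float | None = None) -> np.ndarray:
    """One dual-ascent step: alpha' = alpha + eta (<P> - f) on allowed pairs."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    a = validate_alpha(alpha)
    if estimated.n_bins != target.n_bins or a.shape[0] != target.n_bins:
        raise ValueError("alpha / map size mismatch")
    diff = estimated.probs - target.probs
    if not np.isfinite(diff).all():
        raise ValueError("non-finite contact probabilities")
    new = a + eta * diff * allowed_pair_mask(a.shape[0])
    if alpha_max is not None:
        new = np.clip(new, -alpha_max, alpha_max)
    return 0.5 * (new + new.T)


def compare_maps(estimated: ContactMap, target: ContactMap,
                 n_sweeps: int = 0) -> FitReport:
    """Raw and log-scale Pearson correlation plus the largest deviation,
    computed over the restrainable pairs (|i - j| > 1).

    The log-scale correlation removes pairs where either map is zero.
    """
    mask = np.triu(allowed_pair_mask(target.n_bins))
    est = estimated.probs[mask]
    tgt = target.probs[mask]
    pearson_raw = float(stats.pearsonr(est, tgt)[0]) if est.size > 1 else np.nan
    pos = (est > 0) & (tgt > 0)
    if pos.sum() > 1:
        pearson_log = float(stats.pearsonr(np.log(est[pos]), np.log(tgt[pos]))[0])
    else:
        pearson_log = np.nan
    return FitReport(pearson_raw, pearson_log,
                     float(np.abs(est - tgt).max()), n_sweeps)


def initial_conformation(n: int, params: PolymerParams,
                         rng: np.random.Generator) -> Conformation:
    """Random-walk chain with unit bond length folded into the confinement
    sphere (bonds start at sigma, so no FENE overstretch)."""
    x = np.zeros((n, 3))
    pos = np.zeros(3)
    for i in range(1, n):
        step = rng.standard_normal(3)
        step *= params.sigma / np.linalg.norm(step)
        cand = pos + step
        # reflect drifting ends back toward the centre of the sphere
        if np.linalg.norm(cand) > 0.85 * params.Rc:
            step = -step
            cand = pos + step
        pos = cand
        x[i] = pos
    x -= x.mean(axis=0)
    return Conformation(x)


def target_hash(target: ContactMap) -> str:
    return hashlib.sha256(np.ascontiguousarray(target.probs).tobytes()).hexdigest()[:16]


def fit_landscape(target: ContactMap, params: PolymerParams | None = None,
                  schedule: MaxEntSchedule = MaxEntSchedule(),
                  seed: int = 0, dyn: DynamicsParams | None = None,
                  start: Conformation | None = None,
                  target_id: str = "",
                  verbose: bool = False) -> Landscape:
    """Fit restraint strengths so the simulated ensemble reproduces ``target``.

    The confinement radius is rescaled to the target's bead count (fixed
    volume fraction) unless explicit ``params`` are supplied.
    """
    n = target.n_bins
    if params is None:
        params = PolymerParams().with_rc_for(n)
    if dyn is None:
        dyn = DynamicsParams()
    rng = np.random.default_rng(seed)
    if start is not None:
        pool = [start] * schedule.n_chains
    else:
        pool = [initial_conformation(n, params, rng)
                for _ in range(schedule.n_chains)]
        if schedule.pre_equilibrate > 0:
            for c in range(schedule.n_chains):
                eq = run_langevin(
                    pool[c], None, params,
                    DynamicsParams(dyn.dt, dyn.gamma, dyn.T,
                                   int(rng.integers(2 ** 31))),
                    schedule.pre_equilibrate,
                    snapshot_times=[schedule.pre_equilibrate])
                pool[c] = eq.conformation(0)
    alpha = zero_alpha(n)

    sweep_duration = schedule.burn_in + schedule.samples_per_chain * schedule.sample_spacing
    sample_times = schedule.burn_in + schedule.sample_spacing * np.arange(
        1, schedule.samples_per_chain + 1)

    report = None
    worsening = 0
    prev_dev = np.inf
    history: list[np.ndarray] = []
    for sweep in range(schedule.sweeps):
        ensemble = []
        for c in range(schedule.n_chains):
            chain_seed = int(rng.integers(2 ** 31))
            traj = run_langevin(pool[c], alpha, params,
                                DynamicsParams(dyn.dt, dyn.gamma, dyn.T, chain_seed),
                                sweep_duration, snapshot_times=sample_times)
            pool[c] = traj.conformation(traj.n_frames - 1)
            ensemble.extend(traj.conformation(i) for i in range(traj.n_frames))
        estimated = estimate_contact_map(ensemble, params, target.segment)
        history.append(estimated.probs)
        history = history[-schedule.estimate_window:]
        smoothed = np.clip(np.mean(history, axis=0), 0.0, 1.0)
        estimated = ContactMap(0.5 * (smoothed + smoothed.T), target.segment)
        report = compare_maps(estimated, target, sweep + 1)
        if verbose:
            print(f"sweep {sweep + 1}: pearson={report.pearson_raw:.4f} "
                  f"max|dP|={report.max_abs_dev:.4f}")
        if report.max_abs_dev > prev_dev:
            worsening += 1
            if worsening >= schedule.divergence_patience:
                raise FitDivergenceError(
                    f"max |<P> - f| grew for {worsening} consecutive sweeps; "
                    "reduce eta")
        else:
            worsening = 0
        prev_dev = report.max_abs_dev
        if report.pearson_raw >= schedule.tol:
            break
        eta = schedule.eta * schedule.eta_decay ** sweep
        alpha = update_alphas(alpha, estimated, target, eta, schedule.alpha_max)

    return Landscape(alpha, params, target_id or target_hash(target), report,
                     pool[0], target.segment, list(pool))


def sample_ensemble(landscape: Landscape, n_samples: int, seed: int = 0,
                    dyn: DynamicsParams | None = None,
                    burn_in: float = 5.0, spacing: float = 0.5,
                    start: Conformation | None = None):
    """Fresh equilibrium conformations under a fitted landscape.

    Samples are split across the landscape's final chain pool (when
    available) so the ensemble is not one long autocorrelated chain.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if dyn is None:
        dyn = DynamicsParams()
    rng = np.random.default_rng(seed)
    if start is not None:
        starts = [start]
    elif landscape.final_pool:
        starts = list(landscape.final_pool)
    elif landscape.final_conformation is not None:
        starts = [landscape.final_conformation]
    else:
        starts = [initial_conformation(landscape.n_beads, landscape.params, rng)]
    per_chain = -(-n_samples // len(starts))  # ceil split
    out = []
    for s in starts:
        k = min(per_chain, n_samples - len(out))
        if k <= 0:
            break
        times = burn_in + spacing * np.arange(1, k + 1)
        traj = run_langevin(s, landscape.alpha, landscape.params,
                            DynamicsParams(dyn.dt, dyn.gamma, dyn.T,
                                           int(rng.integers(2 ** 31))),
                            burn_in + spacing * k, snapshot_times=times)
        out.extend(traj.conformation(i) for i in range(traj.n_frames))
    return out


def validate_fit(landscape: Landscape, target: ContactMap, n_samples: int = 40,
                 seed: int = 0, dyn: DynamicsParams | None = None) -> FitReport:
    """Re-simulate under the landscape and score the fresh ensemble's map."""
    if n_samples < 2:
        raise ValueError("validation needs at least two samples")
    ensemble = sample_ensemble(landscape, n_samples, seed=seed, dyn=dyn)
    estimated = estimate_contact_map(ensemble, landscape.params, target.segment)
    sweeps = landscape.fit_report.n_sweeps if landscape.fit_report else 0
    return compare_maps(estimated, target, sweeps)
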