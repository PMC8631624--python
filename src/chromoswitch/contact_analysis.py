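"""Contact-map statistics of the structural transition.

Covers the scaling curve P(l) and its log-log slope, frame-to-frame
contact-difference matrices and their reduction to discrete transition
stages, similarity to reference (cell-state) maps, observed/expected
enhancement, A/B compartment calling, insulation scores and TAD-boundary
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform

from .maps import ContactMap, CompartmentProfile, GeneDensityTrack

LOCAL_RANGE_BP = 2_000_000  # local / non-local contact threshold (2 Mb)


class DegenerateCompartmentError(RuntimeError):
    """Correlation matrix carries no plaid signal; compartments undefined."""


# ---------------------------------------------------------------------------
# P(l) scaling
# ---------------------------------------------------------------------------

def contact_prob_curve(cmap: ContactMap):
    """Mean contact probability at each genomic separation.

    Returns ``(l_bp, p)`` where ``l_bp`` are separations in bp (one per bin
    offset 1..n-1) and ``p`` the mean over the corresponding off-diagonal.
    """
    n = cmap.n_bins
    res = cmap.segment.resolution_bp
    l_bp = np.arange(1, n) * float(res)
    p = np.array([np.mean(np.diagonal(cmap.probs, k)) for k in range(1, n)])
    return l_bp, p


def fit_pl_slope(l_bp: np.ndarray, p: np.ndarray, band: tuple) -> float:
    """Log-log slope of P(l) over ``band = (lo_bp, hi_bp)`` (inclusive)."""
    l_bp = np.asarray(l_bp, dtype=float)
    p = np.asarray(p, dtype=float)
    sel = (l_bp >= band[0]) & (l_bp <= band[1])
    if sel.sum() < 4:
        raise ValueError("band must contain at least 4 points")
    if (p[sel] <= 0).any():
        raise ValueError("P(l) must be positive inside the band")
    slope = np.polyfit(np.log(l_bp[sel]), np.log(p[sel]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# frame-difference matrices
# ---------------------------------------------------------------------------

def _range_mask(n: int, resolution_bp: int, range_filter: str) -> np.ndarray:
    """Pairs entering the sums: off-diagonal, filtered by |i-j| vs 2 Mb."""
    idx = np.arange(n)
    sep_bp = np.abs(idx[:, None] - idx[None, :]) * float(resolution_bp)
    if range_filter == "total":
        mask = sep_bp > 0
    elif range_filter == "local":
        mask = (sep_bp > 0) & (sep_bp < LOCAL_RANGE_BP)
    elif range_filter == "nonlocal":
        mask = sep_bp >= LOCAL_RANGE_BP
    else:
        raise ValueError(f"unknown range filter {range_filter!r}")
    return mask


def delta_p_frames(maps, range_filter: str = "total",
                   normalize: bool = True) -> np.ndarray:
    """Pairwise contact-difference matrix between time frames.

    Raw entry (I, J) is ``sum |P^I - P^J| / sum P^I`` over the selected
    pairs (asymmetric: the denominator belongs to frame I); with
    ``normalize`` the matrix is min-max rescaled to [0, 1].
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least two frames")
    n = maps[0].n_bins
    mask = _range_mask(n, maps[0].segment.resolution_bp, range_filter)
    stack = np.stack([m.probs[mask] for m in maps])
    denom = stack.sum(axis=1)
    if (denom == 0).all():
        raise ValueError("every frame has zero total contact in the selected range")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.abs(stack[:, None, :] - stack[None, :, :]).sum(axis=2) / denom[:, None]
    if not normalize:
        return raw  # rows of an all-zero frame are inf/NaN (their denominator)
    if not np.isfinite(raw).all():
        raise ValueError("a frame has zero total contact; cannot normalize")
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)


def delta_p_reference(maps, reference: ContactMap,
                      range_filter: str = "total") -> np.ndarray:
    """Per-frame contact difference to a reference map:
    ``sum |P^t - P^S| / sum P^t`` over the selected pairs."""
    maps = list(maps)
    n = maps[0].n_bins
    if reference.n_bins != n:
        raise ValueError("reference size mismatch")
    mask = _range_mask(n, maps[0].segment.resolution_bp, range_filter)
    ref = reference.probs[mask]
    out = np.empty(len(maps))
    for t, m in enumerate(maps):
        cur = m.probs[mask]
        denom = cur.sum()
        if denom == 0:
            raise ValueError(f"frame {t} has zero total contact in range")
        out[t] = np.abs(cur - ref).sum() / denom
    return out


# ---------------------------------------------------------------------------
# stage reduction
# ---------------------------------------------------------------------------

@dataclass
class StageAssignment:
    """Contiguous time blocks ("stages") of the transition."""

    n_stages: int
    frame_to_stage: np.ndarray        # stage index (0-based) per frame
    dendrograms: dict = field(default_factory=dict)  # linkage per range

    @property
    def boundaries(self) -> np.ndarray:
        """Frame indices where a new stage begins (excluding frame 0)."""
        return np.flatnonzero(np.diff(self.frame_to_stage)) + 1

    def stage_midframes(self) -> np.ndarray:
        """Representative (middle) frame index per stage."""
        return np.array([
            int(np.flatnonzero(self.frame_to_stage == s).mean())
            for s in range(self.n_stages)])


def _contiguous_blocks(labels: np.ndarray) -> np.ndarray:
    """Frame indices where the cluster label changes (block starts)."""
    return np.flatnonzero(np.diff(labels)) + 1


def cluster_stages(delta_local: np.ndarray, delta_nonlocal: np.ndarray,
                   n_stages: int = 8) -> StageAssignment:
    """Reduce a transition to ``n_stages`` contiguous time blocks.

    Each difference matrix is clustered hierarchically (average linkage on
    the symmetrized matrix, cut to ``n_stages`` clusters); the change points
    of both label sequences are pooled (the product partition) and adjacent
    blocks are merged -- smallest mean inter-block difference first, earlier
    pair on ties -- until exactly ``n_stages`` blocks remain.
    """
    dl = np.asarray(delta_local, dtype=float)
    dn = np.asarray(delta_nonlocal, dtype=float)
    if dl.shape != dn.shape or dl.ndim != 2 or dl.shape[0] != dl.shape[1]:
        raise ValueError("difference matrices must be square and congruent")
    n_frames = dl.shape[0]
    if n_stages > n_frames:
        raise ValueError("more stages than frames")

    dendrograms = {}
    cuts = []
    for name, mat in (("local", dl), ("nonlocal", dn)):
        sym = 0.5 * (mat + mat.T)
        np.fill_diagonal(sym, 0.0)
        link = average(squareform(sym, checks=False))
        dendrograms[name] = link
        cuts.append(fcluster(link, t=n_stages, criterion="maxclust"))

    change = set()
    for labels in cuts:
        change.update(_contiguous_blocks(labels).tolist())
    starts = sorted({0} | change)
    blocks = [np.arange(s, e) for s, e in
              zip(starts, starts[1:] + [n_frames])]

    combined = 0.5 * (dl + dl.T) / 2 + 0.5 * (dn + dn.T) / 2
    while len(blocks) > n_stages:
        costs = [combined[np.ix_(blocks[i], blocks[i + 1])].mean()
                 for i in range(len(blocks) - 1)]
        i = int(np.argmin(costs))  # argmin takes the earliest tie
        blocks[i] = np.concatenate([blocks[i], blocks.pop(i + 1)])

    frame_to_stage = np.empty(n_frames, dtype=int)
    for s, b in enumerate(blocks):
        frame_to_stage[b] = s
    return StageAssignment(len(blocks), frame_to_stage, dendrograms)


def dendrogram_split_time(delta: np.ndarray, times: np.ndarray) -> float:
    """Time of the first boundary when the difference matrix is cut in two.

    Used to compare how early the local vs the non-local contact pattern
    separates into its two principal clusters.
    """
    sym = 0.5 * (delta + delta.T)
    np.fill_diagonal(sym, 0.0)
    labels = fcluster(average(squareform(sym, checks=False)), t=2,
                      criterion="maxclust")
    change = _contiguous_blocks(labels)
    if change.size == 0:
        return float(times[-1])
    return float(times[change[0]])


# ---------------------------------------------------------------------------
# observed / expected and compartments
# ---------------------------------------------------------------------------

def obs_over_exp(cmap: ContactMap) -> np.ndarray:
    """Distance-normalized matrix P_ij / mean-at-distance(|i-j|).

    Distance bins whose mean is zero yield NaN (masked downstream).
    """
    n = cmap.n_bins
    p = cmap.probs
    expected = np.empty(n)
    for k in range(n):
        expected[k] = np.mean(np.diagonal(p, k))
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    exp_mat = expected[sep]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, p / exp_mat, np.nan)
    return oe


def call_compartments(cmap: ContactMap,
                      genes: GeneDensityTrack | None = None) -> CompartmentProfile:
    """A/B compartments from PC1 of the correlation of obs/exp.

    The sign is oriented so that compartment A (positive) has the higher
    mean gene density; with no gene track the orientation is arbitrary (the
    leading eigenvector's as computed).
    """
    if cmap.n_bins < 10:
        raise ValueError("compartment calling needs at least 10 bins")
    oe = obs_over_exp(cmap)
    np.fill_diagonal(oe, np.nan)
    if np.nanstd(oe) < 1e-8:
        raise DegenerateCompartmentError(
            "obs/exp matrix is constant (distance-only map); no plaid signal")
    corr = pd.DataFrame(oe).corr().to_numpy()  # pairwise-complete Pearson
    finite = np.isfinite(corr)
    if not finite.any() or np.nanstd(corr) < 1e-10:
        raise DegenerateCompartmentError(
            "obs/exp correlation matrix is constant; no compartment signal")
    corr = np.where(finite, corr, 0.0)
    corr = 0.5 * (corr + corr.T)
    w, v = np.linalg.eigh(corr)
    pc1 = v[:, -1]
    if genes is not None:
        if genes.n_bins != cmap.n_bins:
            raise ValueError("gene track size mismatch")
        a_mean = genes.density[pc1 > 0].mean() if (pc1 > 0).any() else -np.inf
        b_mean = genes.density[pc1 <= 0].mean() if (pc1 <= 0).any() else -np.inf
        if b_mean > a_mean:
            pc1 = -pc1
    return CompartmentProfile(pc1)


# ---------------------------------------------------------------------------
# insulation and TAD boundaries
# ---------------------------------------------------------------------------

@dataclass
class InsulationTrack:
    """Sliding-square insulation scores and their boundary calls."""

    scores: np.ndarray      # per-bin log2 insulation; NaN on masked edges
    boundaries: np.ndarray  # bin indices of qualifying local minima
    window_bins: int


def insulation_score(cmap: ContactMap, window_bins: int = 5,
                     prominence: float = 0.1) -> InsulationTrack:
    """Sliding-square insulation: mean contact crossing each bin within a
    ``window_bins``-sized square, log2-normalized by its chromosome-wide
    mean.  Boundaries are local minima with at least ``prominence`` depth.
    Edge bins (within one window) are masked NaN.
    """
    n = cmap.n_bins
    w = int(window_bins)
    if w < 1:
        raise ValueError("window_bins must be >= 1")
    if n <= 2 * w:
        raise ValueError("map too small for this window")
    raw = np.full(n, np.nan)
    p = cmap.probs
    for i in range(w, n - w):
        raw[i] = p[i - w:i, i + 1:i + 1 + w].mean()
    valid = np.isfinite(raw) & (raw > 0)
    mean_val = raw[valid].mean()
    scores = np.full(n, np.nan)
    scores[valid] = np.log2(raw[valid] / mean_val)

    interior = scores[w:n - w]
    peaks, _ = find_peaks(-interior, prominence=prominence)
    return InsulationTrack(scores, peaks + w, w)


def tad_boundary_overlap(a, b, tol_bins: int = 1) -> dict:
    """Greedy nearest matching of two sorted boundary lists within a
    tolerance; each boundary is used at most once.

    Returns counts N_a, N_b, N_overlap and the two fractions
    N_overlap / N_a and N_overlap / N_b (NaN when a list is empty).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    pairs = [(abs(int(x) - int(y)), i, j)
             for i, x in enumerate(a) for j, y in enumerate(b)
             if abs(int(x) - int(y)) <= tol_bins]
    pairs.sort()
    used_a, used_b = set(), set()
    n_ol = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n_ol += 1
    return {
        "n_a": int(a.size), "n_b": int(b.size), "n_overlap": n_ol,
        "frac_a": n_ol / a.size if a.size else float("nan"),
        "frac_b": n_ol / b.size if b.size else float("nan"),
    }
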