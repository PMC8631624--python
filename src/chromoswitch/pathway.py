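"""Transition-pathway construction, contact-evolution PCA and hysteresis.

Forward (normal -> cancer) and reverse (cancer -> normal) transitions are
projected into one plane -- either a pair of structural order parameters or
the two leading principal components of the band-restricted obs/exp
contact evolution, fitted jointly on both directions plus the reference
endpoints so the paths are directly comparable.  The area of the loop the
two mean paths enclose (the hysteresis loop area omega) quantifies the
irreversibility of the transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class PathwayProjection:
    """Per-run and ensemble-mean series of an order-parameter pair."""

    per_run: np.ndarray       # (n_runs, n_frames, 2), NaN where undefined
    mean_path: np.ndarray     # (n_frames, 2)
    times: np.ndarray
    stage_markers: np.ndarray | None = None  # frame indices of stage midpoints


def project_pathways(series, times, stage_midframes=None) -> PathwayProjection:
    """Stack per-run order-parameter series and form the pointwise mean.

    ``series`` is an iterable of (n_frames, 2) arrays (one per run); NaN
    entries are masked from the mean with a warning-free nanmean.
    """
    runs = [np.asarray(s, dtype=float) for s in series]
    if not runs:
        raise ValueError("need at least one run")
    shape = runs[0].shape
    if shape[1] != 2:
        raise ValueError("each series must be (n_frames, 2)")
    for s in runs:
        if s.shape != shape:
            raise ValueError("all runs must share the frame grid")
    per_run = np.stack(runs)
    with np.errstate(invalid="ignore"):
        mean_path = np.nanmean(per_run, axis=0)
    times = np.asarray(times, dtype=float)
    if times.shape != (shape[0],):
        raise ValueError("times length mismatch")
    markers = None if stage_midframes is None else np.asarray(stage_midframes, int)
    return PathwayProjection(per_run, mean_path, times, markers)


def _band_vector(matrices, iu, ju):
    return np.stack([m[iu, ju] for m in matrices])


def pca_contact_evolution(series_fwd, series_rev, band_bins: tuple,
                          endpoints: dict | None = None,
                          n_components: int = 2,
                          extra_series: dict | None = None) -> dict:
    """Joint 2-D PCA of the band-restricted obs/exp contact evolution.

    ``series_fwd`` / ``series_rev`` are time-ordered obs/exp matrices (mean
    over runs per frame); ``band_bins = (lo, hi)`` keeps pairs with
    lo <= |i - j| < hi.  Entries undefined (NaN) in any frame are dropped.
    The PCs are fitted on both directions plus the endpoint references, so
    all paths share one plane.  ``extra_series`` (name -> list of matrices)
    are projected into that plane without influencing the fit (used e.g.
    for split-half null paths).  Returns a dict with 2-D coordinates per
    series and endpoint, plus the fitted PCA object.
    """
    fwd = [np.asarray(m, dtype=float) for m in series_fwd]
    rev = [np.asarray(m, dtype=float) for m in series_rev]
    if len(fwd) + len(rev) < 2:
        raise ValueError("need at least two frames overall")
    n = fwd[0].shape[0] if fwd else rev[0].shape[0]
    lo, hi = band_bins
    iu, ju = np.triu_indices(n, k=1)
    sel = (ju - iu >= lo) & (ju - iu < hi)
    if not sel.any():
        raise ValueError(f"band {band_bins} selects no pairs")
    iu, ju = iu[sel], ju[sel]

    endpoints = endpoints or {}
    all_mats = fwd + rev + list(endpoints.values())
    rows = _band_vector(all_mats, iu, ju)
    defined = np.isfinite(rows).all(axis=0)
    if not defined.any():
        raise ValueError("no pair is defined in every frame")
    rows = rows[:, defined]

    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(rows)
    n_f, n_r = len(fwd), len(rev)
    out = {
        "forward": coords[:n_f],
        "reverse": coords[n_f:n_f + n_r],
        "pca": pca,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    for k, name in enumerate(endpoints):
        out[name] = coords[n_f + n_r + k]
    for name, series in (extra_series or {}).items():
        rows_x = _band_vector([np.asarray(m, float) for m in series], iu, ju)
        rows_x = np.where(np.isfinite(rows_x), rows_x, 0.0)[:, defined]
        out[name] = pca.transform(rows_x)
    return out


def hysteresis_area(forward: np.ndarray, reverse: np.ndarray) -> float:
    """Loop area omega enclosed by the forward and reverse paths.

    The cycle runs along the forward path then back along the reversed
    reverse path; omega is the absolute signed (shoelace) area of that
    closed polygon.  Zero when the paths coincide; invariant to rotation;
    scales quadratically with the coordinates.
    """
    f = np.asarray(forward, dtype=float)
    r = np.asarray(reverse, dtype=float)
    for p in (f, r):
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise ValueError("paths must be (n >= 2, 2) arrays")
    cycle = np.vstack([f, r[::-1]])
    x, y = cycle[:, 0], cycle[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return float(abs(0.5 * np.sum(x * y2 - x2 * y)))


@dataclass
class HysteresisResult:
    band: tuple
    forward_path: np.ndarray
    reverse_path: np.ndarray
    omega: float


def hysteresis_by_band(series_fwd, series_rev, bands, endpoints=None) -> list:
    """PCA + loop area for each genomic-distance band (in bins)."""
    results = []
    for band in bands:
        proj = pca_contact_evolution(series_fwd, series_rev, band, endpoints)
        omega = hysteresis_area(proj["forward"], proj["reverse"])
        results.append(HysteresisResult(tuple(band), proj["forward"],
                                        proj["reverse"], omega))
    return results


def default_pca_bands(n_bins: int, resolution_bp: int,
                      segment_span_bp: float | None = None) -> list:
    """Genomic-distance bands for the contact-evolution PCA, in bins.

    The full-scale bands (<2, 2-5, 5-10, 10-15, 15-20, 20-40, >40 Mb on an
    85.6 Mb segment) are rescaled proportionally to the actual segment
    length, then converted to bin offsets.
    """
    reference_span = 85_600_000.0
    span = segment_span_bp if segment_span_bp is not None \
        else (n_bins - 1) * float(resolution_bp)
    scale = span / reference_span
    edges_mb = [0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 40.0, np.inf]
    edges_bins = [e * 1e6 * scale / resolution_bp for e in edges_mb]
    bands = []
    for lo, hi in zip(edges_bins[:-1], edges_bins[1:]):
        lo_b = max(1, int(np.ceil(lo))) if lo > 0 else 1
        hi_b = n_bins if not np.isfinite(hi) else max(lo_b + 1, int(np.ceil(hi)))
        if lo_b < n_bins:
            bands.append((lo_b, hi_b))
    return bands
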