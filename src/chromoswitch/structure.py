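"""Conformation-level order parameters.

Shape descriptors derive from the gyration tensor
``S = (1/N) sum (r_i - r_mean)(r_i - r_mean)^T`` with eigenvalues
lam1 >= lam2 >= lam3:

* ``Rg = sqrt(lam1 + lam2 + lam3)``
* asphericity ``Delta = (3/2) sum (lam_i - lam_mean)^2 / (sum lam_i)^2``
  (0 for a sphere, 1 for a rod),
* prolateness ``S_shape = 27 prod (lam_i - lam_mean) / (sum lam_i)^3``
  (negative = oblate, positive = prolate; range [-1/4, 2]).

The fraction of native contacts Q scores a conformation's internal
distances against a reference ensemble's mean distances with a Gaussian
kernel of width 0.5 sigma.  Radial densities are measured from the center
of the confinement sphere in 20 equal shells of width Rc / 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .maps import CompartmentProfile, GeneDensityTrack
from .polymer import Conformation

Q_KERNEL_WIDTH = 0.5  # sigma of the Gaussian contact kernel, in bead sigma
N_SHELLS = 20

# default genomic-distance bands for Q, in bp: local and long-range
Q_BAND_LOCAL = (0, 2_000_000)
Q_BAND_LONG = (10_000_000, 15_000_000)


@dataclass
class ShapeDescriptors:
    Rg: float
    Delta: float
    S_shape: float
    pa_extensions: tuple  # extents along PA1 >= PA2 >= PA3


def shape_descriptors(conf: Conformation) -> ShapeDescriptors:
    """Gyration-tensor shape descriptors of one conformation.

    ``pa_extensions`` are max-minus-min bead coordinates projected on the
    principal axes, ordered by decreasing eigenvalue.
    """
    x = conf.positions - conf.positions.mean(axis=0)
    n = x.shape[0]
    gyr = x.T @ x / n
    lam, vec = np.linalg.eigh(gyr)       # ascending
    lam = lam[::-1]
    vec = vec[:, ::-1]
    tr = lam.sum()
    rg = float(np.sqrt(tr))
    mean_l = tr / 3.0
    dev = lam - mean_l
    delta = float(1.5 * np.sum(dev ** 2) / tr ** 2) if tr > 0 else 0.0
    s_shape = float(27.0 * np.prod(dev) / tr ** 3) if tr > 0 else 0.0
    proj = x @ vec
    ext = tuple(float(proj[:, k].max() - proj[:, k].min()) for k in range(3))
    return ShapeDescriptors(rg, delta, s_shape, ext)


def mean_pairwise_distances(ensemble) -> np.ndarray:
    """Ensemble-average internal distance matrix (the Q reference)."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    acc = np.zeros(ensemble[0].n_beads * (ensemble[0].n_beads - 1) // 2)
    for c in ensemble:
        acc += pdist(c.positions)
    return squareform(acc / len(ensemble))


def _band_pairs(n: int, band, resolution_bp: int | None):
    """Upper-triangle pair indices with |i - j| inside ``band``.

    ``band`` is None (all pairs), or a (lo, hi) genomic-distance range --
    interpreted in bins, or in bp when ``resolution_bp`` is given.
    """
    iu, ju = np.triu_indices(n, k=1)
    if band is None:
        return iu, ju
    lo, hi = band
    sep = ju - iu
    if resolution_bp is not None:
        sep = sep * float(resolution_bp)
    sel = (sep >= lo) & (sep < hi)
    if not sel.any():
        raise ValueError(f"band {band} selects no pairs")
    return iu[sel], ju[sel]


def q_native(conf: Conformation, reference_means: np.ndarray,
             band=None, resolution_bp: int | None = None,
             kernel_width: float = Q_KERNEL_WIDTH) -> float:
    """Fraction of native contacts Q in [0, 1].

    ``Q = mean over band pairs of exp[-(r_ij - <r_ij>)^2 / (2 w^2)]`` with
    w = 0.5 sigma; <r_ij> comes from the reference ensemble of the end
    state.  Invariant to rigid motions of ``conf``.
    """
    ref = np.asarray(reference_means, dtype=float)
    n = conf.n_beads
    if ref.shape != (n, n):
        raise ValueError("reference mean-distance matrix size mismatch")
    iu, ju = _band_pairs(n, band, resolution_bp)
    d = squareform(pdist(conf.positions))
    dev = d[iu, ju] - ref[iu, ju]
    return float(np.mean(np.exp(-dev ** 2 / (2.0 * kernel_width ** 2))))


@dataclass
class RadialProfile:
    """Shell-binned density of loci about the confinement center."""

    rho: np.ndarray
    shell_edges: np.ndarray
    subset: str = "all"

    @property
    def shell_mid(self) -> np.ndarray:
        return 0.5 * (self.shell_edges[:-1] + self.shell_edges[1:])


def radial_profile(ensemble, Rc: float, subset=None,
                   subset_name: str | None = None,
                   n_shells: int = N_SHELLS) -> RadialProfile:
    """Radial density rho(r) = n(r) / (N_tot 4 pi r^2 dr), dr = Rc / n_shells.

    ``subset`` restricts or weights the counted loci: a
    :class:`CompartmentProfile` label value (+1 / -1) via ``(profile, label)``,
    a boolean mask, or a :class:`GeneDensityTrack` (gene-weighted density).
    Counts are averaged over the ensemble and normalized by the counted
    weight, so the unweighted profile integrates to 1 exactly.  Beads beyond
    the outermost shell are binned into it (with a warning beyond 2 Rc).
    """
    if Rc <= 0:
        raise ValueError("Rc must be positive")
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    n = ensemble[0].n_beads
    weights = np.ones(n)
    name = subset_name or "all"
    if subset is not None:
        if isinstance(subset, GeneDensityTrack):
            weights = subset.density.astype(float)
            name = subset_name or "gene"
        elif isinstance(subset, tuple) and isinstance(subset[0], CompartmentProfile):
            profile, label = subset
            weights = (profile.labels == label).astype(float)
            name = subset_name or ("A" if label > 0 else "B")
        else:
            weights = np.asarray(subset, dtype=float)
        if weights.shape != (n,):
            raise ValueError("subset size mismatch")
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("subset selects no loci")

    edges = np.linspace(0.0, Rc, n_shells + 1)
    dr = edges[1] - edges[0]
    counts = np.zeros(n_shells)
    for c in ensemble:
        r = np.linalg.norm(c.positions, axis=1)
        if (r > 2.0 * Rc).any():
            warnings.warn("bead found beyond 2 Rc; binned to outer shell")
        shell = np.minimum((r / dr).astype(int), n_shells - 1)
        np.add.at(counts, shell, weights)
    counts /= len(ensemble)
    mid = 0.5 * (edges[:-1] + edges[1:])
    rho = counts / (total_w * 4.0 * np.pi * mid ** 2 * dr)
    return RadialProfile(rho, edges, name)


def radial_profile_diff(profile_t: RadialProfile, profile_s: RadialProfile,
                        Rc: float | None = None) -> float:
    """Integrated absolute density difference
    ``int_0^Rc |rho_t - rho_s| dr / Rc`` (Riemann sum on the shared shells).
    Symmetric in its arguments."""
    if profile_t.shell_edges.shape != profile_s.shell_edges.shape or \
            not np.allclose(profile_t.shell_edges, profile_s.shell_edges):
        raise ValueError("radial profiles must share the shell grid")
    edges = profile_t.shell_edges
    if Rc is None:
        Rc = float(edges[-1])
    dr = np.diff(edges)
    return float(np.sum(np.abs(profile_t.rho - profile_s.rho) * dr) / Rc)
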