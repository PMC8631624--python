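"""Seeded synthetic Hi-C-like inputs for desk-scale runs.

Generates contact-probability matrices with the hallmarks of real
chromosome contact maps: a power-law decay of contact probability with
genomic distance, a plaid (checkerboard) A/B compartment pattern, enhanced
diagonal TAD blocks, and multiplicative noise.  A "state triplet" bundles a
normal-like map, a cancer-like map with a larger compartment-A fraction,
and an ES-like reference whose contact-probability curve lies below both
(the open, stem-cell-like polymer state).  Gene-density tracks follow the
compartments: A bins are gene-rich.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import ContactMap, CompartmentProfile, GeneDensityTrack
from .segments import SegmentSpec


def make_compartment_profile(n_bins: int, a_fraction: float,
                             rng: np.random.Generator,
                             segment_len: tuple = (8, 15)) -> CompartmentProfile:
    """Blocky A/B profile: contiguous segments of 8-15 bins, each labelled A
    with probability ``a_fraction``."""
    if not 0 <= a_fraction <= 1:
        raise ValueError("a_fraction must lie in [0, 1]")
    labels = np.empty(n_bins)
    i = 0
    while i < n_bins:
        length = int(rng.integers(segment_len[0], segment_len[1] + 1))
        labels[i:i + length] = 1.0 if rng.random() < a_fraction else -1.0
        i += length
    return CompartmentProfile(labels)


def _check_tads(tad_blocks, n_bins: int):
    blocks = [(int(a), int(b)) for a, b in (tad_blocks or [])]
    prev_end = -1
    for a, b in sorted(blocks):
        if not (0 <= a < b <= n_bins):
            raise ValueError(f"TAD block ({a}, {b}) out of range for {n_bins} bins")
        if a < prev_end:
            raise ValueError("TAD blocks must not overlap")
        prev_end = b
    return sorted(blocks)


def random_tad_blocks(n_bins: int, rng: np.random.Generator,
                      block_len: tuple = (6, 12)) -> list:
    """Tile the segment with non-overlapping diagonal blocks."""
    blocks = []
    i = 0
    while i < n_bins - block_len[0]:
        length = int(rng.integers(block_len[0], block_len[1] + 1))
        blocks.append((i, min(i + length, n_bins)))
        i += length
    return blocks


def make_target_map(n_bins: int, decay_exponent: float = 1.0,
                    compartment: CompartmentProfile | None = None,
                    plaid_strength: float = 0.0,
                    tad_blocks=None, tad_boost: float = 0.6,
                    amplitude: float = 0.8, noise_level: float = 0.0,
                    seed: int = 0, resolution_bp: int = 100_000) -> ContactMap:
    """Build one synthetic contact map.

    The noise-free construction is
    ``P_ij = amplitude * |i-j|^(-decay_exponent) * (1 + plaid * a_i a_j) * tad(i, j)``
    where ``a`` is the +/-1 compartment profile and ``tad`` multiplies
    intra-block pairs by ``1 + tad_boost``.  Truncated-Gaussian
    multiplicative noise is applied to the upper triangle, the matrix is
    symmetrized and clipped to [0, 1], and the diagonal is pinned to 1.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must lie in (0, 1]")
    if not 0 <= plaid_strength < 1:
        raise ValueError("plaid_strength must lie in [0, 1)")
    blocks = _check_tads(tad_blocks, n_bins)

    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        p = amplitude * dist ** (-decay_exponent)
    np.fill_diagonal(p, 1.0)

    if compartment is not None:
        if compartment.n_bins != n_bins:
            raise ValueError("compartment profile size mismatch")
        a = compartment.labels.astype(float)
        p = p * (1.0 + plaid_strength * np.outer(a, a))
    for lo, hi in blocks:
        p[lo:hi, lo:hi] *= 1.0 + tad_boost

    if noise_level > 0:
        iu = np.triu_indices(n_bins, k=1)
        factor = np.maximum(1.0 + noise_level * rng.standard_normal(iu[0].size), 0.0)
        p[iu] *= factor
        p = np.triu(p, k=1)
        p = p + p.T
    else:
        p = np.triu(p, k=1)
        p = p + p.T
    p = np.clip(p, 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    segment = SegmentSpec.desk_scale(n_bins, resolution_bp)
    return ContactMap(p, segment)


@dataclass(frozen=True)
class TripletConfig:
    """Generation settings for the normal / cancer / ES-like state triplet.

    Amplitudes order the P(l) curves (ES lowest, cancer slightly below
    normal); the cancer state carries a strictly larger compartment-A
    fraction than the normal state.
    """

    a_frac_normal: float = 0.40
    a_frac_cancer: float = 0.60
    a_frac_es: float = 0.50
    amplitude_normal: float = 0.80
    amplitude_cancer: float = 0.72
    amplitude_es: float = 0.40
    decay_exponent: float = 1.0
    plaid_strength: float = 0.30
    tad_boost: float = 0.6
    tad_boost_es: float = 0.2
    noise_level: float = 0.05
    resolution_bp: int = 100_000
    band_bins: tuple = (5, 70)  # decay band (in bins) used for the ordering check

    def __post_init__(self) -> None:
        if not self.a_frac_cancer > self.a_frac_normal:
            raise ValueError("cancer state must have a larger A fraction than normal")
        if not (self.amplitude_es < self.amplitude_cancer < self.amplitude_normal):
            raise ValueError("amplitudes must order ES < cancer < normal")


@dataclass
class StateTriplet:
    normal: ContactMap
    cancer: ContactMap
    es: ContactMap
    profile_normal: CompartmentProfile
    profile_cancer: CompartmentProfile
    profile_es: CompartmentProfile

    def __iter__(self):
        yield from (self.normal, self.cancer, self.es)


def make_state_triplet(n_bins: int, seed: int = 0,
                       config: TripletConfig = TripletConfig()) -> StateTriplet:
    """Generate the three-state benchmark sharing one bin grid.

    Guarantees by construction: the cancer profile has strictly more A bins
    than the normal profile, and the ES map's mean P(l) over the config band
    lies strictly below both other maps'.
    """
    rng = np.random.default_rng(seed)
    prof_n = make_compartment_profile(n_bins, config.a_frac_normal, rng)
    prof_c = make_compartment_profile(n_bins, config.a_frac_cancer, rng)
    prof_e = make_compartment_profile(n_bins, config.a_frac_es, rng)
    # enforce strict A-count ordering between cancer and normal
    while int((prof_c.labels > 0).sum()) <= int((prof_n.labels > 0).sum()):
        b_bins = np.flatnonzero(prof_c.labels < 0)
        if b_bins.size == 0:
            raise ValueError("cannot make cancer A fraction exceed normal")
        flip = int(rng.choice(b_bins))
        ev = prof_c.eigvec.copy()
        ev[flip] = abs(ev[flip])
        prof_c = CompartmentProfile(ev)

    tads = random_tad_blocks(n_bins, rng)

    def build(profile, amplitude, boost, sub_seed):
        return make_target_map(
            n_bins, config.decay_exponent, profile, config.plaid_strength,
            tads, boost, amplitude, config.noise_level, seed=sub_seed,
            resolution_bp=config.resolution_bp)

    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    normal = build(prof_n, config.amplitude_normal, config.tad_boost, sub[0])
    cancer = build(prof_c, config.amplitude_cancer, config.tad_boost, sub[1])
    es = build(prof_e, config.amplitude_es, config.tad_boost_es, sub[2])

    lo, hi = config.band_bins
    hi = min(hi, n_bins - 1)

    def band_mean(cmap):
        vals = [np.mean(np.diagonal(cmap.probs, k)) for k in range(lo, hi + 1)]
        return float(np.mean(vals))

    if not (band_mean(es) < band_mean(cancer) and band_mean(es) < band_mean(normal)):
        raise RuntimeError("ES-like map failed the low-P(l) ordering; "
                           "widen the amplitude gap in TripletConfig")
    return StateTriplet(normal, cancer, es, prof_n, prof_c, prof_e)


def make_gene_density(profile: CompartmentProfile, mean_A: float = 8.0,
                      mean_B: float = 1.0, seed: int = 0) -> GeneDensityTrack:
    """Poisson gene counts per bin with compartment-dependent means
    (A bins are gene-dense)."""
    if mean_A < 0 or mean_B < 0:
        raise ValueError("gene-density means must be non-negative")
    rng = np.random.default_rng(seed)
    means = np.where(profile.labels > 0, mean_A, mean_B)
    return GeneDensityTrack(rng.poisson(means).astype(float))
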