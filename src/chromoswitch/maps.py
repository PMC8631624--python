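"""Contact-probability matrices and per-bin genomic tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import SegmentSpec

DIAG_VALUE = 1.0  # fixed main-diagonal convention; excluded from fits/analyses


@dataclass
class ContactMap:
    """Symmetric matrix of pairwise contact probabilities on a binned segment.

    ``probs`` is an ``n x n`` symmetric array with entries in [0, 1]; the main
    diagonal is pinned to :data:`DIAG_VALUE` and carries no information.
    """

    probs: np.ndarray
    segment: SegmentSpec
    diag_value: float = DIAG_VALUE

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {p.shape}")
        if p.shape[0] != self.segment.n_beads:
            raise ValueError(
                f"matrix size {p.shape[0]} does not match segment bead count "
                f"{self.segment.n_beads}"
            )
        if not np.isfinite(p).all():
            raise ValueError("contact matrix contains non-finite entries")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("contact probabilities must lie in [0, 1]")
        if not np.allclose(p, p.T, atol=1e-12, rtol=0.0):
            raise ValueError("contact matrix must be symmetric")
        np.fill_diagonal(p, self.diag_value)
        self.probs = p

    @property
    def n_bins(self) -> int:
        return self.probs.shape[0]

    def offdiag(self) -> np.ndarray:
        """Copy with the diagonal zeroed (for sums that exclude it)."""
        out = self.probs.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def __eq__(self, other: object) -> bool:  # bitwise equality for round-trips
        if not isinstance(other, ContactMap):
            return NotImplemented
        return self.segment == other.segment and np.array_equal(self.probs, other.probs)


@dataclass
class CompartmentProfile:
    """Per-bin A/B compartment assignment.

    ``eigvec`` holds the real values (typically PC1 of the obs/exp
    correlation matrix) whose signs define the labels: +1 = A, -1 = B.
    """

    eigvec: np.ndarray
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.eigvec, dtype=float)
        if v.ndim != 1:
            raise ValueError("eigvec must be one-dimensional")
        self.eigvec = v
        labels = np.sign(v).astype(int)
        labels[labels == 0] = 1  # ties assigned to A
        self.labels = labels

    @property
    def n_bins(self) -> int:
        return self.eigvec.size

    @property
    def a_fraction(self) -> float:
        return float(np.mean(self.labels > 0))

    def flipped(self) -> "CompartmentProfile":
        return CompartmentProfile(-self.eigvec)


@dataclass
class GeneDensityTrack:
    """Per-bin gene counts (non-negative)."""

    density: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 1:
            raise ValueError("density must be one-dimensional")
        if (d < 0).any() or not np.isfinite(d).all():
            raise ValueError("gene density must be finite and non-negative")
        self.density = d

    @property
    def n_bins(self) -> int:
        return self.density.size
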