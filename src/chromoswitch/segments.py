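"""Genomic segment bookkeeping for binned chromosome models.

A chromosome segment is discretized into fixed-width bins; each bin becomes
one bead of the coarse-grained polymer.  Bin counting is inclusive at both
ends: the bead count for [start, end] at resolution ``res`` is
``floor(end/res) - floor(start/res) + 1``, so both the bin containing the
start coordinate and the bin containing the end coordinate are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidSegmentError(ValueError):
    """Raised when a segment specification cannot define a bead chain."""


@dataclass(frozen=True)
class SegmentSpec:
    """A binned genomic interval.

    Parameters
    ----------
    chrom_label
        Chromosome name, e.g. ``"chr14"``.
    start_bp, end_bp
        Interval endpoints in base pairs, ``end_bp > start_bp``.
    resolution_bp
        Bin width in base pairs (one bin = one bead).
    """

    chrom_label: str
    start_bp: int
    end_bp: int
    resolution_bp: int

    def __post_init__(self) -> None:
        if self.resolution_bp <= 0:
            raise InvalidSegmentError(f"resolution_bp must be positive, got {self.resolution_bp}")
        if self.end_bp <= self.start_bp:
            raise InvalidSegmentError(
                f"end_bp ({self.end_bp}) must exceed start_bp ({self.start_bp})"
            )
        if self.n_beads < 2:
            raise InvalidSegmentError("segment must span at least two beads")

    @property
    def n_beads(self) -> int:
        """Number of beads (bins), inclusive of both endpoint bins."""
        res = self.resolution_bp
        return self.end_bp // res - self.start_bp // res + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    def bin_start_bp(self, i: int) -> int:
        """Left edge (bp) of bin ``i`` (0-based bead index)."""
        return (self.start_bp // self.resolution_bp + i) * self.resolution_bp

    def bins_for_bp(self, distance_bp: float) -> float:
        """Convert a genomic distance in bp to bin units."""
        return distance_bp / self.resolution_bp

    @classmethod
    def desk_scale(cls, n_bins: int, resolution_bp: int = 100_000,
                   chrom_label: str = "chrSyn") -> "SegmentSpec":
        """Segment with exactly ``n_bins`` beads starting at coordinate 0."""
        return cls(chrom_label, 0, (n_bins - 1) * resolution_bp, resolution_bp)


def segment_to_beads(segment: SegmentSpec) -> int:
    """Bead count of a segment (inclusive fence-post convention)."""
    return segment.n_beads
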