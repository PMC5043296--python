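"""Strand-aware genomic intervals.

All coordinates inside the toolkit are 0-based half-open; GFF3 (1-based,
inclusive) and BED (0-based, half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", "?")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence.

    ``chrom`` carries the subgenome prefix ("A"/"B") for allotetraploid
    references. ``strand`` is "+", "-" or "?" (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bases between the interval hulls; 0 when they overlap or abut.

        Raises if the intervals sit on different sequences.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end
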