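"""Subgenome-diagnostic fragments and assembly accuracy scoring.

The two subgenomes of a recent allotetraploid differ by sparse substitutions.
Tiling one subgenome into fixed-length fragments and keeping only those with a
unique single-mismatch placement in the other subgenome yields fragments that
diagnose subgenome of origin: an assembled transcript containing such a
fragment verbatim must derive from the fragment's own subgenome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .intervals import GenomicInterval
from .io import reverse_complement

DEFAULT_TILE_LEN = 100


@dataclass(frozen=True)
class DiagnosticFragment:
    """A tile unique to one subgenome up to exactly one mismatch."""

    id: str
    origin: str  # "A" or "B"
    source: GenomicInterval
    sequence: str
    opposite_hit: GenomicInterval


@dataclass
class AccuracyReport:
    """Per-subgenome counts of diagnostic fragments hitting transcripts."""

    origin: str
    n_mapped_to_transcripts: int
    n_correct: int
    n_ambiguous: int

    @property
    def pct_correct(self) -> float:
        if self.n_mapped_to_transcripts == 0:
            return float("nan")
        return 100.0 * self.n_correct / self.n_mapped_to_transcripts


def tile_genome(
    sequences: dict[str, str], tile_len: int = DEFAULT_TILE_LEN
) -> list[tuple[GenomicInterval, str]]:
    """Cut each chromosome into non-overlapping tiles of ``tile_len``.

    The trailing partial tile is discarded, as is any tile containing N.
    """
    if tile_len < 20:
        raise ValueError("tile_len must be >= 20")
    tiles = []
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        for start in range(0, len(seq) - tile_len + 1, tile_len):
            tile = seq[start : start + tile_len]
            if "N" in tile:
                continue
            tiles.append((GenomicInterval(chrom, start, start + tile_len, "+"), tile))
    return tiles


def _hamming_capped(a: str, b: str, cap: int) -> int:
    """Hamming distance with N matching nothing; returns cap+1 once exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > cap:
                return d
    return d


class _SeedIndex:
    """Exact k-mer position index over one strand of a genome."""

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    self.index[kmer].append((chrom, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _candidate_placements(tile, seed_offsets, seed_indexes, genome, tile_len):
    """All placements sharing an exact seed with the tile (pigeonhole-complete
    for distances <= number_of_seeds - 1)."""
    candidates = set()
    for off, length in seed_offsets:
        for chrom, pos in seed_indexes[length].lookup(tile[off : off + length]):
            start = pos - off
            if 0 <= start <= len(genome[chrom]) - tile_len:
                candidates.add((chrom, start))
    return candidates


def find_diagnostic_fragments(
    tiles: list[tuple[GenomicInterval, str]],
    genome_y: dict[str, str],
    origin: str,
    required_mismatches: int = 1,
) -> list[DiagnosticFragment]:
    """Keep tiles with exactly one placement at ``required_mismatches``
    mismatches in the opposite genome and none closer.

    A placement is a full-length ungapped alignment on either strand of Y.
    A tile is diagnostic iff exactly one placement has Hamming distance equal
    to ``required_mismatches``, and no placement (including that one's
    competitors) has a smaller distance, and no second placement ties it.
    Implemented by seed-and-verify: the tile is split into
    ``required_mismatches + 1`` exact seeds, so every placement within the
    distance budget is surfaced by at least one exact seed match (pigeonhole);
    the scheme is therefore equivalent to an exhaustive Hamming scan.
    """
    if not tiles or not genome_y:
        raise ValueError("tiles and opposite genome must be non-empty")
    tile_len = len(tiles[0][1])
    n_seeds = required_mismatches + 1
    base = tile_len // n_seeds
    seed_offsets = []
    pos = 0
    for i in range(n_seeds):
        length = base + (1 if i < tile_len % n_seeds else 0)
        seed_offsets.append((pos, length))
        pos += length
    lengths = {length for _, length in seed_offsets}
    seed_indexes = {k: _SeedIndex(genome_y, k) for k in lengths}

    diagnostics = []
    for source, tile in tiles:
        hits: list[tuple[str, int, str, int]] = []  # chrom, start, strand, dist
        too_close = False
        for strand, query in (("+", tile), ("-", reverse_complement(tile))):
            for chrom, start in _candidate_placements(
                query, seed_offsets, seed_indexes, genome_y, tile_len
            ):
                d = _hamming_capped(
                    query, genome_y[chrom][start : start + tile_len],
                    required_mismatches,
                )
                if d < required_mismatches:
                    too_close = True
                    break
                if d == required_mismatches:
                    hits.append((chrom, start, strand, d))
            if too_close:
                break
        if too_close or len(hits) != 1:
            continue
        chrom, start, strand, _ = hits[0]
        diagnostics.append(
            DiagnosticFragment(
                id=f"{origin}|{source.chrom}:{source.start}-{source.end}",
                origin=origin,
                sequence=tile,
                source=source,
                opposite_hit=GenomicInterval(chrom, start, start + tile_len, strand),
            )
        )
    return diagnostics


def infer_subgenome_label(name: str) -> str:
    """Subgenome label from a sequence id: its leading 'A' or 'B'."""
    if name[:1] in ("A", "B"):
        return name[0]
    raise ValueError(f"cannot infer subgenome label for {name!r}")


def score_assembly_accuracy(
    diagnostics: list[DiagnosticFragment],
    transcripts: dict[str, str],
    labels: dict[str, str] | None = None,
) -> dict[str, AccuracyReport]:
    """Count diagnostic fragments mapping to same- vs opposite-label transcripts.

    A fragment maps to a transcript iff it or its reverse complement occurs as
    an exact substring. Fragments hitting no transcript are excluded; a
    fragment hitting at least one transcript of the opposite subgenome label
    is ambiguous, otherwise correct.
    """
    if labels is None:
        labels = {name: infer_subgenome_label(name) for name in transcripts}
    for name in transcripts:
        if name not in labels or labels[name] not in ("A", "B"):
            raise ValueError(f"transcript {name!r} lacks an A/B label")
    reports = {
        g: AccuracyReport(g, 0, 0, 0) for g in sorted({f.origin for f in diagnostics})
    }
    for frag in diagnostics:
        rc = reverse_complement(frag.sequence)
        hit_labels = {
            labels[name]
            for name, seq in transcripts.items()
            if frag.sequence in seq or rc in seq
        }
        if not hit_labels:
            continue
        report = reports[frag.origin]
        report.n_mapped_to_transcripts += 1
        if hit_labels - {frag.origin}:
            report.n_ambiguous += 1
        else:
            report.n_correct += 1
    return reports
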