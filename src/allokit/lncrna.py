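"""Long non-coding RNA identification and classification.

Candidates pass an ordered filter cascade — minimum length (200 nt, the
lncRNA convention), no ORF at the initial cutoff (100 aa), no known-protein
hit, minimum mean expression (2 FPKM), no ORF longer than 80 aa, and low
coding potential (Fickett TESTCODE score) — then are classed as pri-miRNA
(a miRNA hairpin aligns at > 80% identity over > 90% of the hairpin) or,
positionally against the gene annotation, as exonic, intronic or intergenic
(> 200 bp from any gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval
from .io import AnnotationSet, reverse_complement
from .pairing import _alignment_stats, _nucleotide_aligner, find_longest_orf

DEFAULT_MIN_LENGTH = 200
DEFAULT_INITIAL_ORF_AA = 100
DEFAULT_ORF_CUTOFF_AA = 80
DEFAULT_FICKETT_CUTOFF = 0.95
DEFAULT_MIN_MEAN_FPKM = 2.0
DEFAULT_HAIRPIN_IDENTITY = 0.8
DEFAULT_HAIRPIN_COVERAGE = 0.9
DEFAULT_MIN_GENE_DISTANCE = 200

STAGES = (
    "length",
    "orf_initial",
    "protein_hit",
    "expression",
    "orf_refined",
    "coding_potential",
)


# ---------------------------------------------------------------------------
# Fickett TESTCODE score
#
# Published lookup tables for the TESTCODE statistic: for each base, a
# position parameter (asymmetry of base usage across the three codon-frame
# positions, max/(min+1)) and a composition parameter (base fraction) are
# mapped through probability tables and combined with fixed weights.

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def _lookup(value: float, thresholds: tuple[float, ...]) -> int:
    for i, t in enumerate(thresholds):
        if value >= t:
            return i
    return len(thresholds) - 1


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE coding-potential score of a nucleotide sequence."""
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    score = 0.0
    for base in "ACGT":
        phase_counts = [sequence[i::3].count(base) for i in range(3)]
        position_param = max(phase_counts) / (min(phase_counts) + 1.0)
        score += (
            _POSITION_PROB[base][_lookup(position_param, _POSITION_THRESHOLDS)]
            * _POSITION_WEIGHT[base]
        )
        content = sequence.count(base) / len(sequence)
        score += (
            _CONTENT_PROB[base][_lookup(content, _CONTENT_THRESHOLDS)]
            * _CONTENT_WEIGHT[base]
        )
    return score


# ---------------------------------------------------------------------------
# coding assessment and the filter cascade


@dataclass(frozen=True)
class CodingAssessment:
    transcript_id: str
    longest_orf_aa: int
    fickett: float
    verdict: str  # coding | noncoding


def assess_coding(
    sequence: str,
    transcript_id: str = "",
    orf_cutoff_aa: int = DEFAULT_ORF_CUTOFF_AA,
    fickett_cutoff: float = DEFAULT_FICKETT_CUTOFF,
) -> CodingAssessment:
    """Coding verdict from the longest 6-frame ORF and the Fickett score.

    Coding iff the longest ORF exceeds ``orf_cutoff_aa`` amino acids or the
    Fickett score reaches ``fickett_cutoff``. Sequences shorter than 200 nt
    are rejected (not "long" non-coding candidates).
    """
    if len(sequence) < DEFAULT_MIN_LENGTH:
        raise ValueError(
            f"sequence of {len(sequence)} nt is below the {DEFAULT_MIN_LENGTH} nt "
            "lncRNA length convention"
        )
    orf = find_longest_orf(sequence, transcript_id, min_len_aa=1)
    longest = len(orf.protein) if orf else 0
    score = fickett_score(sequence)
    verdict = (
        "coding" if longest > orf_cutoff_aa or score >= fickett_cutoff
        else "noncoding"
    )
    return CodingAssessment(transcript_id, longest, score, verdict)


@dataclass
class LncRNACall:
    """A candidate's ordered filter trail and (if it survived) final class."""

    transcript_id: str
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)
    lnc_class: str | None = None  # pri_miRNA | exonic | intronic | intergenic
    position: GenomicInterval | None = None

    @property
    def passed_all(self) -> bool:
        return all(ok for _, ok in self.filter_trail) and len(
            self.filter_trail
        ) == len(STAGES)

    @property
    def rejected_at(self) -> str | None:
        for stage, ok in self.filter_trail:
            if not ok:
                return stage
        return None


def filter_candidates(
    transcripts: dict[str, str],
    fpkm: pd.DataFrame,
    protein_hits: set[str] | None = None,
    min_mean_fpkm: float = DEFAULT_MIN_MEAN_FPKM,
    initial_orf_cutoff_aa: int = DEFAULT_INITIAL_ORF_AA,
    orf_cutoff_aa: int = DEFAULT_ORF_CUTOFF_AA,
    fickett_cutoff: float = DEFAULT_FICKETT_CUTOFF,
) -> list[LncRNACall]:
    """Run the filter cascade, stopping each candidate at its first failure.

    Stages, in order: length (>= 200 nt), orf_initial (no ORF of
    ``initial_orf_cutoff_aa`` or more), protein_hit (absent from the
    known-protein hit table), expression (mean FPKM over all libraries >=
    ``min_mean_fpkm``), orf_refined (longest ORF <= ``orf_cutoff_aa``),
    coding_potential (Fickett score below ``fickett_cutoff``).
    """
    protein_hits = protein_hits or set()
    calls = []
    for transcript_id in sorted(transcripts):
        seq = transcripts[transcript_id]
        call = LncRNACall(transcript_id)
        calls.append(call)

        ok = len(seq) >= DEFAULT_MIN_LENGTH
        call.filter_trail.append(("length", ok))
        if not ok:
            continue
        orf = find_longest_orf(seq, transcript_id, min_len_aa=1)
        longest = len(orf.protein) if orf else 0
        ok = longest < initial_orf_cutoff_aa
        call.filter_trail.append(("orf_initial", ok))
        if not ok:
            continue
        ok = transcript_id not in protein_hits
        call.filter_trail.append(("protein_hit", ok))
        if not ok:
            continue
        if transcript_id not in fpkm.index:
            raise KeyError(f"no FPKM row for candidate {transcript_id!r}")
        ok = float(fpkm.loc[transcript_id].mean()) >= min_mean_fpkm
        call.filter_trail.append(("expression", ok))
        if not ok:
            continue
        ok = longest <= orf_cutoff_aa
        call.filter_trail.append(("orf_refined", ok))
        if not ok:
            continue
        ok = fickett_score(seq) < fickett_cutoff
        call.filter_trail.append(("coding_potential", ok))
    return calls


# ---------------------------------------------------------------------------
# pri-miRNA hairpin matching


@dataclass(frozen=True)
class HairpinMatch:
    transcript_id: str
    hairpin_id: str
    identity: float
    hairpin_coverage: float


def match_hairpins(
    candidates: dict[str, str],
    hairpins: dict[str, str],
    min_identity: float = DEFAULT_HAIRPIN_IDENTITY,
    min_coverage: float = DEFAULT_HAIRPIN_COVERAGE,
) -> list[HairpinMatch]:
    """Local-align each miRNA hairpin against each candidate, both
    orientations; matches require identity > ``min_identity`` and hairpin
    coverage > ``min_coverage``.
    """
    aligner = _nucleotide_aligner()
    matches = []
    for transcript_id in sorted(candidates):
        seq = candidates[transcript_id]
        for hairpin_id in sorted(hairpins):
            hp = hairpins[hairpin_id]
            best = None
            for target in (seq, reverse_complement(seq)):
                alignments = aligner.align(target, hp)
                try:
                    alignment = alignments[0]
                except IndexError:
                    continue
                identity, qstart, qend, _, _ = _alignment_stats(alignment)
                coverage = (qend - qstart) / len(hp)
                if best is None or (identity, coverage) > best:
                    best = (identity, coverage)
            if best and best[0] > min_identity and best[1] > min_coverage:
                matches.append(
                    HairpinMatch(transcript_id, hairpin_id, best[0], best[1])
                )
    return matches


# ---------------------------------------------------------------------------
# positional classification


def classify_position(
    position: GenomicInterval,
    annotation: AnnotationSet,
    min_distance: int = DEFAULT_MIN_GENE_DISTANCE,
) -> str:
    """Positional lncRNA class against the gene annotation.

    Precedence: exonic (overlaps >= 1 exon, strand-blind), intronic
    (overlaps >= 1 mRNA without touching an exon), intergenic (nearest gene
    more than ``min_distance`` bases away), else unclassified.
    """
    chroms = {iv.chrom for _, iv in annotation.genes}
    if position.chrom not in chroms:
        raise ValueError(f"chromosome {position.chrom!r} absent from annotation")
    if any(position.overlaps(iv) for _, iv in annotation.exons):
        return "exonic"
    if any(position.overlaps(iv) for _, _, iv in annotation.mrnas):
        return "intronic"
    distances = [
        position.distance(iv)
        for _, iv in annotation.genes
        if iv.chrom == position.chrom
    ]
    if distances and min(distances) > min_distance:
        return "intergenic"
    return "unclassified"


# ---------------------------------------------------------------------------
# end-to-end


def run_lncrna_pipeline(
    transcripts: dict[str, str],
    fpkm: pd.DataFrame,
    positions: dict[str, GenomicInterval],
    annotation: AnnotationSet,
    hairpins: dict[str, str],
    protein_hits: set[str] | None = None,
    min_identity: float = DEFAULT_HAIRPIN_IDENTITY,
    min_coverage: float = DEFAULT_HAIRPIN_COVERAGE,
    min_distance: int = DEFAULT_MIN_GENE_DISTANCE,
    **cascade_kwargs,
) -> list[LncRNACall]:
    """Filter cascade, then pri-miRNA matching (which takes precedence), then
    positional classification of the survivors."""
    calls = filter_candidates(
        transcripts, fpkm, protein_hits, **cascade_kwargs
    )
    survivors = {
        c.transcript_id: transcripts[c.transcript_id]
        for c in calls
        if c.passed_all
    }
    matched = {
        m.transcript_id
        for m in match_hairpins(survivors, hairpins, min_identity, min_coverage)
    }
    for call in calls:
        if not call.passed_all:
            continue
        call.position = positions.get(call.transcript_id)
        if call.transcript_id in matched:
            call.lnc_class = "pri_miRNA"
        elif call.position is not None:
            call.lnc_class = classify_position(
                call.position, annotation, min_distance
            )
    return calls
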