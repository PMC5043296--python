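"""Reciprocal-best-hit homeolog pairing between subgenome transcript sets.

A transcript pair (a, b) across the A and B subgenomes is called homeologous
when each is the other's best local-alignment hit at three levels — full cDNA,
predicted ORF protein, and predicted CDS — with cDNA hits filtered at >= 80%
identity and >= 80% query coverage. Ka/Ks for each pair is estimated with
NG86 on a protein-guided codon alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .kaks import KaKsResult, estimate_ka_ks

DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ATG-initiated ORF found in a 6-frame scan of a transcript.

    ``start``/``end`` are 0-based half-open on the forward transcript
    sequence; ``cds`` is the coding nucleotide sequence in reading
    orientation (reverse-complemented for minus-strand ORFs).
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    protein: str
    cds: str


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    identity: float
    coverage: float
    score: float


@dataclass(frozen=True)
class HomeologPair:
    a_id: str
    b_id: str
    identity: float
    coverage: float
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None


# ---------------------------------------------------------------------------
# ORF prediction


def _orfs_in_frame(seq: str, frame: int) -> list[tuple[int, int, str]]:
    """(start, end, protein) of ATG..stop/end ORFs in one frame of ``seq``."""
    from .kaks import translate_codon

    orfs = []
    n_codons = (len(seq) - frame) // 3
    codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
    i = 0
    while i < n_codons:
        if codons[i] == "ATG":
            protein = []
            j = i
            while j < n_codons:
                aa = translate_codon(codons[j]) if "N" not in codons[j] else "X"
                if aa is None:  # stop codon terminates the ORF
                    break
                protein.append(aa)
                j += 1
            orfs.append((frame + 3 * i, frame + 3 * j, "".join(protein)))
            i = j + 1
        else:
            i += 1
    return orfs


def find_longest_orf(
    sequence: str, transcript_id: str = "", min_len_aa: int = 100
) -> OpenReadingFrame | None:
    """Longest ATG-initiated ORF over all six frames, or None if shorter
    than ``min_len_aa`` amino acids.

    Ties prefer the plus strand, then the lower frame, then the leftmost
    start.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    sequence = sequence.upper()
    rc = str(Seq(sequence).reverse_complement())
    best: OpenReadingFrame | None = None
    for strand, seq in (("+", sequence), ("-", rc)):
        for frame in range(3):
            for start, end, protein in _orfs_in_frame(seq, frame):
                if strand == "+":
                    fwd_start, fwd_end = start, end
                else:
                    fwd_start, fwd_end = len(seq) - end, len(seq) - start
                candidate = OpenReadingFrame(
                    transcript_id=transcript_id,
                    strand=strand,
                    frame=frame,
                    start=fwd_start,
                    end=fwd_end,
                    protein=protein,
                    cds=seq[start:end],
                )
                if best is None or len(protein) > len(best.protein):
                    best = candidate
    if best is None or len(best.protein) < min_len_aa:
        return None
    return best


# ---------------------------------------------------------------------------
# cross-subgenome similarity


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


from functools import lru_cache


@lru_cache(maxsize=65536)
def _cached_local_alignment(
    seq1: str, seq2: str, protein: bool
) -> tuple[float, float, tuple[int, int], tuple[int, int]] | None:
    """(score, identity, span1, span2) of the best local alignment, or None
    when no positive-scoring alignment exists. Cached so the reverse
    direction (and identical CDS/cDNA sequences) reuse the matrix fill."""
    aligner = _protein_aligner() if protein else _nucleotide_aligner()
    alignments = aligner.align(seq1, seq2)
    try:
        alignment = alignments[0]
    except IndexError:
        return None
    identity, qstart, qend, sstart, send = _alignment_stats(alignment)
    return alignment.score, identity, (sstart, send), (qstart, qend)


def _alignment_stats(alignment) -> tuple[float, int, int, int, int]:
    """(identity, qstart, qend, sstart, send) of a pairwise local alignment.

    Identity is matching columns over all alignment columns, gap columns
    included; the query span covers gapped columns inside the local block.
    """
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    t_blocks, q_blocks = alignment.aligned
    qstart, qend = q_blocks[0][0], q_blocks[-1][1]
    sstart, send = t_blocks[0][0], t_blocks[-1][1]
    return identity, qstart, qend, sstart, send


def cross_subgenome_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    protein: bool = False,
) -> list[SimilarityHit]:
    """All-vs-all local alignment of queries against subjects with
    identity / query-coverage thresholds.

    Hits are sorted per query by score, ties broken by identity then
    subject id.
    """
    hits: list[SimilarityHit] = []
    for query_id, query_seq in queries.items():
        for subject_id, subject_seq in subjects.items():
            if query_seq <= subject_seq:
                result = _cached_local_alignment(query_seq, subject_seq, protein)
                query_span = result[2] if result else None
            else:
                result = _cached_local_alignment(subject_seq, query_seq, protein)
                query_span = result[3] if result else None
            if result is None:
                continue
            score, identity = result[0], result[1]
            coverage = (query_span[1] - query_span[0]) / len(query_seq)
            if identity >= min_identity and coverage >= min_coverage:
                hits.append(
                    SimilarityHit(query_id, subject_id, identity, coverage, score)
                )
    hits.sort(key=lambda h: (h.query, -h.score, -h.identity, h.subject))
    return hits


def best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query (score, then identity, then subject id)."""
    best: dict[str, SimilarityHit] = {}
    for hit in sorted(hits, key=lambda h: (-h.score, -h.identity, h.subject)):
        best.setdefault(hit.query, hit)
    return best


def reciprocal_best_pairs(
    hits_ab: list[SimilarityHit],
    hits_ba: list[SimilarityHit],
    orf_hits_ab: list[SimilarityHit],
    orf_hits_ba: list[SimilarityHit],
    cds_hits_ab: list[SimilarityHit],
    cds_hits_ba: list[SimilarityHit],
) -> list[HomeologPair]:
    """Pairs reciprocal-best at all three levels (cDNA, ORF protein, CDS).

    cDNA-level identity and coverage (A as query) are carried on the pair.
    """
    levels = [
        (best_hits(hits_ab), best_hits(hits_ba)),
        (best_hits(orf_hits_ab), best_hits(orf_hits_ba)),
        (best_hits(cds_hits_ab), best_hits(cds_hits_ba)),
    ]
    cdna_ab, cdna_ba = levels[0]
    pairs = []
    for a_id, hit in sorted(cdna_ab.items()):
        b_id = hit.subject
        reciprocal = all(
            a_id in ab
            and ab[a_id].subject == b_id
            and b_id in ba
            and ba[b_id].subject == a_id
            for ab, ba in levels
        )
        if reciprocal:
            pairs.append(
                HomeologPair(a_id, b_id, hit.identity, hit.coverage)
            )
    return pairs


# ---------------------------------------------------------------------------
# codon alignment


def _global_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def codon_align(
    orf_a: OpenReadingFrame, orf_b: OpenReadingFrame
) -> list[tuple[str, str]]:
    """Protein-guided codon alignment of two ORFs.

    The proteins are globally aligned (BLOSUM62, affine gaps) and the
    alignment is back-threaded onto the coding nucleotides; columns
    containing a gap are discarded.
    """
    aligner = _global_protein_aligner()
    alignment = aligner.align(orf_a.protein, orf_b.protein)[0]
    blocks_a, blocks_b = alignment.aligned
    codons = []
    for (a_start, a_end), (b_start, b_end) in zip(blocks_a, blocks_b):
        for offset in range(a_end - a_start):
            i, j = a_start + offset, b_start + offset
            codons.append(
                (orf_a.cds[3 * i : 3 * i + 3], orf_b.cds[3 * j : 3 * j + 3])
            )
    if not codons:
        raise ValueError("no aligned codons remain after gap removal")
    return codons


# ---------------------------------------------------------------------------
# end-to-end pairing


def pair_homeologs(
    transcripts_a: dict[str, str],
    transcripts_b: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_orf_aa: int = 100,
) -> list[HomeologPair]:
    """Full pipeline: ORF prediction, three-level RBH pairing, NG86 Ka/Ks.

    Transcripts lacking an ORF of at least ``min_orf_aa`` amino acids are
    ineligible for pairing.
    """
    orfs_a = {
        name: orf
        for name, seq in transcripts_a.items()
        if (orf := find_longest_orf(seq, name, min_orf_aa)) is not None
    }
    orfs_b = {
        name: orf
        for name, seq in transcripts_b.items()
        if (orf := find_longest_orf(seq, name, min_orf_aa)) is not None
    }
    eligible_a = {name: transcripts_a[name] for name in orfs_a}
    eligible_b = {name: transcripts_b[name] for name in orfs_b}
    prot_a = {name: orf.protein for name, orf in orfs_a.items()}
    prot_b = {name: orf.protein for name, orf in orfs_b.items()}
    cds_a = {name: orf.cds for name, orf in orfs_a.items()}
    cds_b = {name: orf.cds for name, orf in orfs_b.items()}

    kwargs = dict(min_identity=min_identity, min_coverage=min_coverage)
    pairs = reciprocal_best_pairs(
        cross_subgenome_hits(eligible_a, eligible_b, **kwargs),
        cross_subgenome_hits(eligible_b, eligible_a, **kwargs),
        cross_subgenome_hits(prot_a, prot_b, protein=True, **kwargs),
        cross_subgenome_hits(prot_b, prot_a, protein=True, **kwargs),
        cross_subgenome_hits(cds_a, cds_b, **kwargs),
        cross_subgenome_hits(cds_b, cds_a, **kwargs),
    )
    annotated = []
    for pair in pairs:
        result = estimate_pair_kaks(orfs_a[pair.a_id], orfs_b[pair.b_id])
        annotated.append(
            HomeologPair(
                pair.a_id,
                pair.b_id,
                pair.identity,
                pair.coverage,
                ka=result.ka,
                ks=result.ks,
                ka_ks=result.ka_ks,
            )
        )
    return annotated


def estimate_pair_kaks(
    orf_a: OpenReadingFrame, orf_b: OpenReadingFrame
) -> KaKsResult:
    return estimate_ka_ks(codon_align(orf_a, orf_b))
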