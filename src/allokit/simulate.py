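"""Synthetic allotetraploid data with known ground truth.

Generates the full input surface of the toolkit — two subgenomes diverged by
a configurable substitution rate, multi-exon homeologous gene pairs at
homologous coordinates, negative-binomial counts over a tissues x replicates
design with planted bias and dominance, junction tables with planted
exon-skip / alternative-donor / alternative-acceptor / NAGNAG events plus
sub-threshold decoys, and planted lncRNA loci of every positional class with
miRNA hairpin matches — together with a TruthSet so every downstream stage
has a planted-truth test surface.

All generators are deterministic for a fixed config seed; each stage draws
from its own seeded stream so stages can be invoked independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import AnnotationSet, JunctionRecord, SampleSheet, reverse_complement
from .kaks import _STOPS

BASES = np.array(list("ACGT"))

# the 22 tissues / developmental stages of the reference design, in their
# three developmental groups
DEFAULT_TISSUES: tuple[tuple[str, str], ...] = (
    ("seedling_leaf", "vegetative"),
    ("mainstem_leaf", "vegetative"),
    ("lateral_leaf", "vegetative"),
    ("vegetative_shoot_tip", "vegetative"),
    ("root", "vegetative"),
    ("nodule", "vegetative"),
    ("reproductive_shoot_tip", "reproductive"),
    ("perianth", "reproductive"),
    ("gynoecium", "reproductive"),
    ("androecium", "reproductive"),
    ("aerial_gynophore_tip", "reproductive"),
    ("subterranean_gynophore_tip", "reproductive"),
    ("pattee1_pod", "reproductive"),
    ("pattee1_stalk", "reproductive"),
    ("pattee3_pod", "reproductive"),
    ("pattee5_pericarp", "seed"),
    ("pattee5_seed", "seed"),
    ("pattee6_pericarp", "seed"),
    ("pattee6_seed", "seed"),
    ("pattee7_seed", "seed"),
    ("pattee8_seed", "seed"),
    ("pattee10_seed", "seed"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic allotetraploid.

    Defaults mirror the reference design: 22 tissues in three developmental
    groups with 3 biological replicates, ~2% subgenome divergence, NB counts
    with dispersion 0.1 around a mean of 100, planted log2 = 2 bias in a
    tenth of the pairs. Genome and pair counts are desk-scale.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 120_000
    divergence: float = 0.02
    n_pairs: int = 30
    exons_per_gene: tuple[int, int] = (2, 4)
    tissues: tuple[tuple[str, str], ...] = DEFAULT_TISSUES
    replicates: int = 3
    mean_expression: float = 100.0
    dispersion: float = 0.1
    bias_fraction: float = 0.1
    bias_log2: float = 2.0
    dominance_fraction: float = 0.05
    n_exon_skip: int = 15
    n_alt_donor: int = 15
    n_alt_acceptor: int = 15
    nagnag_fraction: float = 0.3
    n_decoy_junctions: int = 20
    min_junction_reads: int = 10
    n_lncrna: tuple[tuple[str, int], ...] = (
        ("intergenic", 8),
        ("intronic", 4),
        ("exonic", 8),
        ("pri_miRNA", 4),
    )
    n_hairpins: int = 6

    def __post_init__(self) -> None:
        for name in ("bias_fraction", "dominance_fraction", "nagnag_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError(
                f"divergence must be in [0, 0.25], got {self.divergence} "
                "(the substitution model breaks beyond 0.25)"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.bias_fraction + self.dominance_fraction > 1.0:
            raise ValueError("bias and dominance fractions must sum to <= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def sample_sheet(self) -> SampleSheet:
        rows = [
            {
                "library": f"{tissue}_r{rep}",
                "tissue": tissue,
                "replicate": rep,
                "group": group,
            }
            for tissue, group in self.tissues
            for rep in range(1, self.replicates + 1)
        ]
        return SampleSheet(pd.DataFrame(rows))


@dataclass
class GeneModel:
    gene_id: str
    chrom_index: int
    strand: str
    exons: list[tuple[int, int]]  # genomic, ascending

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class TruthSet:
    """Planted ground truth for every downstream stage."""

    substitutions: list[tuple[int, int, str]] = field(default_factory=list)
    # (chrom index, position, lineage "A"/"B")
    pairs: list[tuple[str, str]] = field(default_factory=list)
    bias_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    # pair id -> tissue -> category
    as_events: list[dict] = field(default_factory=list)
    lnc_classes: dict[str, str] = field(default_factory=dict)
    lnc_first_fail: dict[str, str] = field(default_factory=dict)
    hairpin_matches: list[tuple[str, str]] = field(default_factory=list)
    protein_hits: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["protein_hits"] = sorted(self.protein_hits)
        return json.dumps(payload, indent=1, default=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# subgenomes


def simulate_subgenomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Two subgenomes from a common ancestor by per-base substitutions.

    Each substituted site is assigned to one lineage, so the realized A-B
    divergence is Binomial(L, divergence) per chromosome and the process is
    symmetric between lineages.
    """
    rng = config.rng(1)
    a_seqs: dict[str, str] = {}
    b_seqs: dict[str, str] = {}
    truth = TruthSet()
    for c in range(config.n_chroms):
        ancestor = rng.integers(0, 4, size=config.chrom_len)
        a = ancestor.copy()
        b = ancestor.copy()
        hit = rng.random(config.chrom_len) < config.divergence
        positions = np.flatnonzero(hit)
        lineages = rng.integers(0, 2, size=positions.size)  # 0 -> A, 1 -> B
        shifts = rng.integers(1, 4, size=positions.size)
        for pos, lineage, shift in zip(positions, lineages, shifts):
            target = a if lineage == 0 else b
            target[pos] = (target[pos] + shift) % 4
            truth.substitutions.append(
                (c, int(pos), "A" if lineage == 0 else "B")
            )
        a_seqs[f"A{c + 1}"] = "".join(BASES[a])
        b_seqs[f"B{c + 1}"] = "".join(BASES[b])
    return a_seqs, b_seqs, truth


# ---------------------------------------------------------------------------
# gene models


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA, ``n_codons`` codons total."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = _random_sequence(rng, 3)
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _mutate_cds_base(
    rng: np.random.Generator, cds: list[str], index: int, other_base: str
) -> bool:
    """Substitute one CDS base avoiding stop creation and the start/stop
    codons; returns False when no safe base exists."""
    codon_index = index // 3
    if codon_index == 0 or codon_index == len(cds) // 3 - 1:
        return False
    offset = index % 3
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    current = cds[index]
    choices = [b for b in "ACGT" if b != current and b != other_base]
    rng.shuffle(choices)
    for base in choices:
        mutant = codon.copy()
        mutant[offset] = base
        if "".join(mutant) not in _STOPS:
            cds[index] = base
            return True
    return False


def simulate_gene_models(
    config: SimulationConfig,
    genomes: tuple[dict[str, str], dict[str, str]],
    truth: TruthSet,
) -> tuple[AnnotationSet, dict[str, str], dict[str, str], list[GeneModel]]:
    """Plant homeologous multi-exon gene pairs at homologous coordinates.

    Coding sequences (ATG-initiated, stop-terminated, stop-free) are written
    into both subgenomes at identical coordinates; subgenome substitutions
    falling inside exons are re-applied at the CDS level, avoiding stop
    creation so every planted transcript keeps a full-length ORF. Genes are
    confined to the first 60% of each chromosome (the remainder hosts splice
    loci). Returns the annotation (both subgenomes), labeled transcripts,
    updated genome sequences, and the gene models; pairs and per-gene truth
    are appended to ``truth``.
    """
    rng = config.rng(2)
    a_seqs = {k: list(v) for k, v in genomes[0].items()}
    b_seqs = {k: list(v) for k, v in genomes[1].items()}
    subs_by_chrom: dict[int, dict[int, str]] = {}
    for c, pos, lineage in truth.substitutions:
        subs_by_chrom.setdefault(c, {})[pos] = lineage

    gene_region_end = int(0.6 * config.chrom_len)
    models: list[GeneModel] = []
    chrom_index, cursor = 0, 250
    for g in range(config.n_pairs):
        lo, hi = config.exons_per_gene
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = [3 * int(rng.integers(52, 71)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(300, 451)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(800, 1400))
        while cursor + gap + span > gene_region_end:
            chrom_index += 1
            cursor = 250
            if chrom_index >= config.n_chroms:
                raise ValueError(
                    "chromosomes too short for the requested gene pairs"
                )
        start = cursor + gap
        exons = []
        pos = start
        for i, length in enumerate(exon_lens):
            exons.append((pos, pos + length))
            pos += length + (intron_lens[i] if i < n_exons - 1 else 0)
        cursor = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(f"g{g + 1:04d}", chrom_index, strand, exons))

    annotation = AnnotationSet()
    transcripts_a: dict[str, str] = {}
    transcripts_b: dict[str, str] = {}
    for model in models:
        total = sum(e - s for s, e in model.exons)
        cds = _random_cds(rng, total // 3)
        cds_a, cds_b = list(cds), list(cds)
        chrom_subs = subs_by_chrom.get(model.chrom_index, {})
        # genomic offset within the concatenated exons -> CDS index
        offset = 0
        for s, e in model.exons:
            for pos in range(s, e):
                lineage = chrom_subs.get(pos)
                if lineage is not None:
                    concat_index = offset + (pos - s)
                    if model.strand == "+":
                        cds_index = concat_index
                    else:
                        cds_index = total - 1 - concat_index
                    target = cds_a if lineage == "A" else cds_b
                    other = cds_b if lineage == "A" else cds_a
                    _mutate_cds_base(rng, target, cds_index, other[cds_index])
            offset += e - s
        for cds_copy, seqs, prefix in (
            (cds_a, a_seqs, "A"),
            (cds_b, b_seqs, "B"),
        ):
            chrom = f"{prefix}{model.chrom_index + 1}"
            genomic = (
                "".join(cds_copy)
                if model.strand == "+"
                else reverse_complement("".join(cds_copy))
            )
            offset = 0
            for s, e in model.exons:
                seqs[chrom][s:e] = list(genomic[offset : offset + (e - s)])
                offset += e - s
            gene_id = f"{prefix}_{model.gene_id}"
            mrna_id = f"{gene_id}.t1"
            iv = GenomicInterval(chrom, model.start, model.end, model.strand)
            annotation.genes.append((gene_id, iv))
            annotation.mrnas.append((mrna_id, gene_id, iv))
            for s, e in model.exons:
                annotation.exons.append(
                    (mrna_id, GenomicInterval(chrom, s, e, model.strand))
                )
            transcript = "".join(cds_copy)
            if prefix == "A":
                transcripts_a[mrna_id] = transcript
            else:
                transcripts_b[mrna_id] = transcript
        truth.pairs.append((f"A_{model.gene_id}.t1", f"B_{model.gene_id}.t1"))
    annotation = AnnotationSet(
        genes=annotation.genes, mrnas=annotation.mrnas, exons=annotation.exons
    )
    genomes_out_a = {k: "".join(v) for k, v in a_seqs.items()}
    genomes_out_b = {k: "".join(v) for k, v in b_seqs.items()}
    return annotation, {**transcripts_a, **transcripts_b}, {
        **genomes_out_a,
        **genomes_out_b,
    }, models


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimulationConfig,
    pairs: list[tuple[str, str]],
    truth: TruthSet,
    lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts for every pair over the tissue design.

    A ``bias_fraction`` of pairs gets a planted log2 ratio of
    ``bias_log2`` (split symmetrically around the mean) in every tissue; a
    ``dominance_fraction`` gets one copy silenced (mu = 0). Labels per pair
    and tissue are recorded in ``truth``.
    """
    rng = config.rng(3)
    sheet = config.sample_sheet()
    libs = sheet.libraries
    n_pairs = len(pairs)
    order = rng.permutation(n_pairs)
    n_biased = int(round(config.bias_fraction * n_pairs))
    n_dominant = int(round(config.dominance_fraction * n_pairs))
    biased = set(order[:n_biased])
    dominant = set(order[n_biased : n_biased + n_dominant])

    def nb(mu: float, size: int) -> np.ndarray:
        if mu <= 0:
            return np.zeros(size, dtype=np.int64)
        if config.dispersion < 1e-8:
            return rng.poisson(mu, size=size)
        shape = 1.0 / config.dispersion
        p = shape / (shape + mu)
        return rng.negative_binomial(shape, p, size=size)

    half = 2.0 ** (config.bias_log2 / 2.0)
    rows = {}
    for i, (a_id, b_id) in enumerate(pairs):
        pair_id = f"{a_id}~{b_id}"
        if i in biased:
            toward_a = bool(rng.random() < 0.5)
            mu_a = config.mean_expression * (half if toward_a else 1.0 / half)
            mu_b = config.mean_expression * (1.0 / half if toward_a else half)
            label = "A_biased" if toward_a else "B_biased"
        elif i in dominant:
            toward_a = bool(rng.random() < 0.5)
            mu_a = config.mean_expression if toward_a else 0.0
            mu_b = 0.0 if toward_a else config.mean_expression
            label = "A_dominant" if toward_a else "B_dominant"
        else:
            mu_a = mu_b = config.mean_expression
            label = "balanced"
        truth.bias_labels[pair_id] = {t: label for t, _ in config.tissues}
        rows[a_id] = nb(mu_a, len(libs))
        rows[b_id] = nb(mu_b, len(libs))
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=libs)
    if lengths is None:
        lengths = {tid: 1000 for tid in counts.index}
    length_series = pd.Series(
        {tid: lengths[tid] for tid in counts.index}, name="length"
    )
    return counts, length_series


# ---------------------------------------------------------------------------
# splice junctions


def _junction_counts(
    rng: np.random.Generator, n_libs: int, min_reads: int, supported: bool
) -> tuple[int, ...]:
    base = rng.integers(0, 4, size=n_libs)
    if supported:
        hot = int(rng.integers(0, n_libs))
        base[hot] = int(rng.integers(min_reads, 4 * min_reads))
    else:
        base = np.minimum(base, min_reads - 1)
    return tuple(int(x) for x in base)


def simulate_junctions(
    config: SimulationConfig,
    genomes: dict[str, str],
    truth: TruthSet,
) -> tuple[list[JunctionRecord], dict[str, str]]:
    """Plant splice events in the gene-free tail of each chromosome.

    Every planted event's member junctions clear the support threshold in at
    least one library; NAGNAG-planted acceptor pairs sit exactly 3 bp apart
    with the genomic window edited to match .AG.AG; decoy junctions stay
    below threshold everywhere and never enter the truth set.
    """
    rng = config.rng(4)
    genomes = {k: v for k, v in genomes.items()}
    n_libs = len(config.tissues) * config.replicates
    chroms = sorted(genomes)
    region_start = int(0.62 * config.chrom_len)
    region_end = int(0.95 * config.chrom_len)
    stride = 800
    slots = []
    for chrom in chroms:
        for pos in range(region_start, region_end - stride, stride):
            slots.append((chrom, pos))
    rng.shuffle(slots)
    n_acceptor_nagnag = int(round(config.nagnag_fraction * config.n_alt_acceptor))
    plan = (
        ["exon_skip"] * config.n_exon_skip
        + ["alt_donor"] * config.n_alt_donor
        + ["nagnag"] * n_acceptor_nagnag
        + ["alt_acceptor"] * (config.n_alt_acceptor - n_acceptor_nagnag)
        + ["decoy"] * config.n_decoy_junctions
    )
    if len(plan) > len(slots):
        raise ValueError("chromosomes too short for the requested splice loci")

    junctions: list[JunctionRecord] = []

    def emit(chrom, start, end, strand, supported=True):
        junctions.append(
            JunctionRecord(
                chrom,
                start,
                end,
                strand,
                _junction_counts(
                    rng, n_libs, config.min_junction_reads, supported
                ),
            )
        )

    for kind, (chrom, base) in zip(plan, slots):
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "exon_skip":
            s = base + int(rng.integers(0, 50))
            e1 = s + int(rng.integers(80, 150))
            s2 = e1 + int(rng.integers(60, 120))
            e = s2 + int(rng.integers(80, 150))
            emit(chrom, s, e1, strand)
            emit(chrom, s2, e, strand)
            emit(chrom, s, e, strand)
            truth.as_events.append(
                {
                    "event_class": "exon_skip",
                    "chrom": chrom,
                    "strand": strand,
                    "members": [[chrom, s, e1], [chrom, s2, e], [chrom, s, e]],
                    "skipped_exon": [e1, s2],
                    "nagnag": False,
                }
            )
        elif kind == "decoy":
            s = base + int(rng.integers(0, 50))
            e = s + int(rng.integers(80, 200))
            emit(chrom, s, e, strand, supported=False)
        else:
            is_nagnag = kind == "nagnag"
            event_class = "alt_acceptor" if kind != "alt_donor" else "alt_donor"
            delta = 3 if is_nagnag else int(rng.integers(4, 31))
            length = int(rng.integers(100, 200))
            s = base + int(rng.integers(0, 50))
            # which intron boundary varies depends on class and strand
            acceptor_varies = event_class == "alt_acceptor"
            end_varies = acceptor_varies == (strand != "-")
            if end_varies:
                j1 = (s, s + length)
                j2 = (s, s + length + delta)
            else:
                j1 = (s + delta, s + length + delta)
                j2 = (s, s + length + delta)
            emit(chrom, j1[0], j1[1], strand)
            emit(chrom, j2[0], j2[1], strand)
            motif = None
            if is_nagnag:
                seq = list(genomes[chrom])
                if end_varies:  # plus-strand acceptor: window [e1-3, e1+3)
                    e_small = min(j1[1], j2[1])
                    seq[e_small - 3 : e_small + 3] = list("TAGCAG")
                else:  # minus-strand acceptor: window [s1, s1+6), mirrored
                    s_small = min(j1[0], j2[0])
                    seq[s_small : s_small + 6] = list(
                        reverse_complement("TAGCAG")
                    )
                genomes[chrom] = "".join(seq)
                motif = "TAGCAG"
            truth.as_events.append(
                {
                    "event_class": event_class,
                    "chrom": chrom,
                    "strand": strand,
                    "members": [
                        [chrom, j1[0], j1[1]],
                        [chrom, j2[0], j2[1]],
                    ],
                    "skipped_exon": None,
                    "nagnag": is_nagnag,
                    "motif": motif,
                }
            )
    return junctions, genomes


# ---------------------------------------------------------------------------
# non-coding candidates


def _noncoding_sequence(
    rng: np.random.Generator,
    length: int,
    max_orf_aa: int = 60,
    max_fickett: float = 0.90,
) -> str:
    """Random sequence with longest 6-frame ORF <= ``max_orf_aa`` and a
    Fickett TESTCODE score below ``max_fickett`` (safely noncoding)."""
    from .lncrna import fickett_score

    for _ in range(100):
        seq = _repair_orfs(list(_random_sequence(rng, length)), rng, None,
                           max_orf_aa)
        if seq is not None and fickett_score(seq) < max_fickett:
            return seq
    raise RuntimeError("could not draw a noncoding sequence")


def _repair_orfs(
    seq: list[str],
    rng: np.random.Generator,
    protected: tuple[int, int] | None,
    max_orf_aa: int,
) -> str | None:
    """Mutate bases inside long ORFs until none exceeds ``max_orf_aa``,
    never touching the ``protected`` span; None when repair fails."""
    from .pairing import find_longest_orf

    for _ in range(200):
        orf = find_longest_orf("".join(seq), min_len_aa=1)
        if orf is None or len(orf.protein) <= max_orf_aa:
            return "".join(seq)
        candidates = [
            p
            for p in range(orf.start, orf.end)
            if protected is None or not protected[0] <= p < protected[1]
        ]
        if not candidates:  # ORF trapped inside the protected span
            return "".join(seq)
        rng.shuffle(candidates)
        pos = candidates[0]
        seq[pos] = "T" if seq[pos] != "T" else "A"
    return None


def simulate_noncoding(
    config: SimulationConfig,
    annotation: AnnotationSet,
    models: list[GeneModel],
    truth: TruthSet,
) -> tuple[dict[str, str], dict[str, GenomicInterval], dict[str, str], pd.DataFrame]:
    """Planted lncRNA candidates of every class plus stage-failure decoys.

    Positional candidates are placed against the planted gene annotation
    (intergenic > 200 bp from any gene, intronic inside an intron, exonic
    overlapping an exon); pri-miRNA candidates embed a hairpin verbatim.
    One decoy per cascade stage is emitted so first-failure accounting has a
    planted truth. Returns (candidate sequences, candidate positions,
    hairpin library, candidate FPKM matrix).
    """
    rng = config.rng(5)
    sheet = config.sample_sheet()
    libs = sheet.libraries
    n_lnc = dict(config.n_lncrna)

    hairpins = {
        f"hp{i + 1:03d}": _random_sequence(rng, int(rng.integers(100, 140)))
        for i in range(config.n_hairpins)
    }

    candidates: dict[str, str] = {}
    positions: dict[str, GenomicInterval] = {}
    fpkm_rows: dict[str, np.ndarray] = {}

    genes_sorted = sorted(
        ((gid, iv) for gid, iv in annotation.genes), key=lambda x: (x[1].chrom, x[1].start)
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for _, iv in genes_sorted:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    def expressed(mean: float) -> np.ndarray:
        return np.full(len(libs), mean) * rng.uniform(0.8, 1.2, size=len(libs))

    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:03d}"

    # intergenic: midpoints of inter-gene gaps, > 200 bp from both neighbors
    intergenic_slots = []
    for chrom, ivs in by_chrom.items():
        for left, right in zip(ivs, ivs[1:]):
            gap = right.start - left.end
            length = 300
            if gap > 2 * 201 + length + 20:
                start = left.end + (gap - length) // 2
                intergenic_slots.append(GenomicInterval(chrom, start, start + length))
    rng.shuffle(intergenic_slots)
    for slot in intergenic_slots[: n_lnc.get("intergenic", 0)]:
        name = new_id("lnc_intergenic_")
        candidates[name] = _noncoding_sequence(rng, len(slot))
        positions[name] = slot
        truth.lnc_classes[name] = "intergenic"
        fpkm_rows[name] = expressed(5.0)

    # intronic: inside an intron, clear of both flanking exons
    intron_slots = []
    for model in models:
        for prefix in ("A", "B"):
            chrom = f"{prefix}{model.chrom_index + 1}"
            for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
                if s2 - e1 >= 240:
                    start = e1 + 10
                    intron_slots.append(
                        GenomicInterval(chrom, start, start + 210)
                    )
    rng.shuffle(intron_slots)
    for slot in intron_slots[: n_lnc.get("intronic", 0)]:
        name = new_id("lnc_intronic_")
        candidates[name] = _noncoding_sequence(rng, len(slot))
        positions[name] = slot
        truth.lnc_classes[name] = "intronic"
        fpkm_rows[name] = expressed(5.0)

    # exonic: straddling an exon boundary
    exonic_slots = []
    for model in models:
        for prefix in ("A", "B"):
            chrom = f"{prefix}{model.chrom_index + 1}"
            s, e = model.exons[0]
            exonic_slots.append(GenomicInterval(chrom, max(0, s - 50), s + 250))
    rng.shuffle(exonic_slots)
    for slot in exonic_slots[: n_lnc.get("exonic", 0)]:
        name = new_id("lnc_exonic_")
        candidates[name] = _noncoding_sequence(rng, len(slot))
        positions[name] = slot
        truth.lnc_classes[name] = "exonic"
        fpkm_rows[name] = expressed(5.0)

    # pri-miRNA: embed a hairpin verbatim; position intergenic-like so the
    # hairpin match's precedence over positional classes is exercised
    hairpin_ids = sorted(hairpins)
    for i in range(n_lnc.get("pri_miRNA", 0)):
        if i >= len(hairpin_ids) or n_lnc.get("intergenic", 0) + i >= len(
            intergenic_slots
        ):
            break
        hp_id = hairpin_ids[i % len(hairpin_ids)]
        hp = hairpins[hp_id]
        name = new_id("lnc_primirna_")
        from .lncrna import fickett_score

        protected = (100, 100 + len(hp))
        for _ in range(100):
            raw = _random_sequence(rng, 100) + hp + _random_sequence(rng, 120)
            repaired = _repair_orfs(list(raw), rng, protected, 60)
            if repaired is not None and fickett_score(repaired) < 0.90:
                break
        else:
            raise RuntimeError("could not build a pri-miRNA candidate")
        candidates[name] = repaired
        slot = intergenic_slots[n_lnc.get("intergenic", 0) + i]
        positions[name] = slot
        truth.lnc_classes[name] = "pri_miRNA"
        truth.hairpin_matches.append((name, hp_id))
        fpkm_rows[name] = expressed(5.0)

    # decoys: one first-failure per cascade stage
    decoys = {
        "decoy_length": (_random_sequence(rng, 150), 5.0),
        "decoy_orf_initial": (
            "".join(["ATG"] + [_nonstop_codon(rng) for _ in range(110)] + ["TAA"]),
            5.0,
        ),
        "decoy_protein_hit": (_noncoding_sequence(rng, 300), 5.0),
        "decoy_expression": (_noncoding_sequence(rng, 300), 0.5),
        "decoy_orf_refined": (_mid_orf_decoy(rng), 5.0),
        "decoy_coding_potential": ("GTC" * 90, 5.0),
    }
    stage_of = {
        "decoy_length": "length",
        "decoy_orf_initial": "orf_initial",
        "decoy_protein_hit": "protein_hit",
        "decoy_expression": "expression",
        "decoy_orf_refined": "orf_refined",
        "decoy_coding_potential": "coding_potential",
    }
    for name, (seq, mean) in decoys.items():
        candidates[name] = seq
        truth.lnc_first_fail[name] = stage_of[name]
        fpkm_rows[name] = expressed(mean)
    truth.protein_hits.add("decoy_protein_hit")

    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=libs)
    return candidates, positions, hairpins, fpkm


def _mid_orf_decoy(rng: np.random.Generator) -> str:
    """A sequence whose longest 6-frame ORF is between 81 and 99 aa: passes
    the initial 100-aa screen but fails the refined 80-aa cutoff."""
    from .pairing import find_longest_orf

    for _ in range(50):
        core = "".join(["ATG"] + [_nonstop_codon(rng) for _ in range(89)] + ["TAA"])
        seq = _pad_noncoding(rng, core)
        longest = len(find_longest_orf(seq, min_len_aa=1).protein)
        if 80 < longest < 100:
            return seq
    raise RuntimeError("could not build a mid-length ORF decoy")


def _nonstop_codon(rng: np.random.Generator) -> str:
    while True:
        codon = _random_sequence(rng, 3)
        if codon not in _STOPS and codon != "ATG":
            return codon


def _pad_noncoding(rng: np.random.Generator, core: str, total: int = 320) -> str:
    """Pad a planted ORF with stop-rich flanks up to ``total`` nt without
    extending the ORF."""
    if len(core) >= total:
        return core
    pad = total - len(core)
    left = ("TAA" * 40)[: pad // 2]
    right = ("TAA" * 40)[: pad - len(left)]
    return left + core + right


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    annotation: AnnotationSet
    transcripts: dict[str, str]
    counts: pd.DataFrame
    lengths: pd.Series
    junctions: list[JunctionRecord]
    lnc_candidates: dict[str, str]
    lnc_positions: dict[str, GenomicInterval]
    lnc_fpkm: pd.DataFrame
    hairpins: dict[str, str]
    sheet: SampleSheet
    truth: TruthSet

    @property
    def genome(self) -> dict[str, str]:
        return {**self.genome_a, **self.genome_b}


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage and assemble the full dataset + truth."""
    a_seqs, b_seqs, truth = simulate_subgenomes(config)
    annotation, transcripts, genomes, models = simulate_gene_models(
        config, (a_seqs, b_seqs), truth
    )
    lengths = {tid: len(seq) for tid, seq in transcripts.items()}
    counts, length_series = simulate_counts(config, truth.pairs, truth, lengths)
    junctions, genomes = simulate_junctions(config, genomes, truth)
    candidates, positions, hairpins, lnc_fpkm = simulate_noncoding(
        config, annotation, models, truth
    )
    genome_a = {k: v for k, v in genomes.items() if k.startswith("A")}
    genome_b = {k: v for k, v in genomes.items() if k.startswith("B")}
    return SyntheticDataset(
        config=config,
        genome_a=genome_a,
        genome_b=genome_b,
        annotation=annotation,
        transcripts=transcripts,
        counts=counts,
        lengths=length_series,
        junctions=junctions,
        lnc_candidates=candidates,
        lnc_positions=positions,
        lnc_fpkm=lnc_fpkm,
        hairpins=hairpins,
        sheet=config.sample_sheet(),
        truth=truth,
    )
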