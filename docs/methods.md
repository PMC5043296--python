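# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the design
decisions taken where the problem left the design open.

## Coordinates and formats

All internal coordinates are 0-based half-open on named sequences, with the
subgenome encoded as the leading "A"/"B" of the sequence id. GFF3 (1-based
inclusive) and BED are converted at the I/O boundary and round-trip exactly.
Splice-junction records store the *intron*: `start` is the first intronic
base, `end` one past the last. Sequences are uppercased on read and
restricted to A/C/G/T/N; N never matches any base in comparisons. Fractional
upstream count estimates are rounded half-to-even at ingestion.

## Subgenome-diagnostic fragments

Each subgenome is tiled into non-overlapping 100-bp fragments (trailing
partial tiles and N-containing tiles dropped). A tile is *diagnostic* when,
over all full-length ungapped placements on either strand of the opposite
subgenome, exactly one placement has Hamming distance 1 and none has
distance 0 (a 0-mismatch tile is by definition non-diagnostic, and a second
placement at distance ≤ 1 destroys uniqueness). The implementation splits
each tile into two exact seeds and verifies candidates from a k-mer index;
by pigeonhole every placement within the one-mismatch budget contains an
exact seed, so the scheme is equivalent to the exhaustive scan, which the
tests run as an independent oracle on small genomes. Accuracy scoring calls
a fragment *mapped* when it (or its reverse complement) occurs verbatim in a
transcript; fragments hitting no transcript leave the denominator, and a
fragment hitting any opposite-label transcript is ambiguous. On clean
truth-labeled synthetic transcripts both subgenomes score 100% correct.

## Homeolog pairing

ORFs are predicted by a 6-frame scan requiring an ATG start and running to a
stop codon or the sequence end (a deliberate simplification; partial ORFs
without a start are not considered). Cross-subgenome similarity uses
Smith–Waterman local alignment (nucleotide: match +1, mismatch −2, gap open
−5, extend −2; protein: BLOSUM62, open −11, extend −1). Identity is matching
columns over all alignment columns, coverage is the query span of the local
alignment over query length; the 80/80 thresholds are applied
query-relative. A pair requires reciprocal best hits simultaneously at the
cDNA, ORF-protein and CDS levels; ties break by score, then identity, then
subject id. Alignments are cached on the (unordered) sequence pair, so both
directions and coinciding cDNA/CDS sequences reuse one matrix fill.

Ka/Ks uses Nei–Gojobori (1986): fractional synonymous-site counting per
codon position averaged over both sequences, with single-base changes that
create a stop counted as nonsynonymous (so N = 3L − S); pairwise codon
differences averaged with equal weight over minimal mutational pathways,
excluding pathways through stop codons (all-paths fallback when every
pathway is excluded); Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`,
undefined at `p ≥ 3/4`, and the ratio additionally undefined at `Ks = 0`.
The codon alignment is protein-guided (global BLOSUM62 alignment
back-threaded onto nucleotides, gap columns dropped). NG86 was chosen over
a transition/transversion-weighted codon model because every downstream use
is a rank comparison between groups, which NG86 preserves; the tests verify
exact agreement with an independent mutation-enumeration oracle.

## Expression bias

FPKM = count·10⁹ / (length·library total). Transcripts under 1 FPKM in all
libraries are dropped. For each pair and tissue the two copies' replicate
counts are compared by a two-sided Wald test of `log(μ_A/μ_B) = 0` under a
negative-binomial model with variance `μ + αμ²`: group means are the sample
means (unit size factors — both homeologs are quantified in the same
libraries, so library depth cancels), and `SE² = (1/μ̂_A + α)/n_A +
(1/μ̂_B + α)/n_B` by the delta method. The per-pair dispersion is a method-
of-moments estimate averaged over the two copies; because a 3-replicate
moment estimate is far too noisy for a calibrated Wald test, each pair's
dispersion is floored by the *median* estimate across all pairs in the call
(cross-gene information sharing, the same idea dispersion shrinkage serves
in standard differential-expression tools) and by a global floor of 0.01.
At the reference conditions (μ = 100, α = 0.1, 3 replicates, 2000 pairs)
this gives an empirical type-I rate of ~0.05 at p < 0.05, sensitivity
~0.97 for 4-fold planted bias after BH, and empirical FDR ~0.05.

Benjamini–Hochberg correction is applied across pairs within each tissue.
Calls use the precedence: `not_expressed` (both copies' mean FPKM < 1);
complete dominance (one copy < 1 FPKM in *every* replicate, the other's
mean ≥ 1 — an expression rule, not a test, because a zero-mean group breaks
a log-link Wald statistic); significant bias (padj < 0.05, direction by the
ratio sign); else balanced. Per-tissue summary percentages use the expressed
pairs (sum of the five expressed categories) as denominator. Constitutive
bias requires same-direction bias (dominance included) in every tissue where
the pair is expressed and expression in at least two tissues;
constitutive-balanced pairs are never biased anywhere.

Window tracks rank reciprocal-mapping loci by position and report A-/B-
biased fractions in 50-locus windows advancing by 10; chromosomes with fewer
than 50 loci yield one whole-chromosome window, and a trailing partial
window covers loci beyond the last full window. Group comparisons of Ks and
Ka/Ks use the two-sided Wilcoxon rank-sum test (exact enumeration when both
groups have ≤ 10 untied values, otherwise the tie- and continuity-corrected
normal approximation); the groups are unpaired, so the rank-sum rather than
the signed-rank form is the appropriate test.

## Alternative splicing

After the ≥ 10-read filter, events are mined per (chromosome, strand):
every junction triplet {(s,e₁), (s₂,e), (s,e)} with e₁ < s₂ is one
exon-skip event with skipped exon [e₁, s₂); every remaining unordered pair
sharing a start (or an end) with the other boundary varying is one
shared-boundary event. The two pairs inside each skip triplet are consumed
and excluded from pair enumeration, which makes the three class counts
additive. Donor/acceptor labels are assigned strand-aware — the varying
boundary on the intron's 5′ side is an alternative donor, on the 3′ side an
alternative acceptor; unknown strand is treated as plus — and the
strand-blind coordinate grouping (shared_start / shared_end) is retained in
the output so genomic-coordinate accounting stays available. Output order is
independent of input order.

NAGNAG candidates are acceptor events whose two acceptors sit exactly 3 bp
apart. The 6-nt window spans the last three intronic bases of both forms:
plus strand `genome[e₁−3, e₁+3)`; minus strand the reverse complement of
`genome[s₁, s₁+6)`. The motif test is the regular expression `.AG.AG`.

Usage per tissue pools replicate counts: for exon skipping, retention
support is the mean of the two inner junction counts and skip support the
outer count; for shared-boundary pairs, form 1 is the proximal (shorter
intron) form. The categorical value is `both` when both forms have support
in the tissue, `first_only`/`second_only`/`none` otherwise; the numeric
inclusion proportion is form1/(form1+form2), missing when unsupported.
Preference is `log2((form1+pc)/(form2+pc))`, emitted only when both terms
are positive (pseudocount default 0). Clustering is agglomerative with
Euclidean distance and average linkage on inclusion proportions, rows
imputed with their own mean, all-missing rows dropped.

## Long non-coding RNAs

The cascade runs in a fixed order and each candidate stops at its first
failure, so rejected totals decompose exactly by stage: length (≥ 200 nt,
the lncRNA convention), orf_initial (no ORF ≥ 100 aa), protein_hit (absent
from the supplied known-protein table), expression (mean FPKM ≥ 2 over all
libraries), orf_refined (longest ORF ≤ 80 aa), coding_potential (Fickett
TESTCODE score < 0.95). The Fickett score uses the published position and
composition lookup tables; it stands in for an externally trained logistic
coding-potential model as a defined, reproducible rule — it is a behavioral
stand-in, not a reimplementation of any tool's training. Survivors matching
a miRNA hairpin (local alignment, either orientation, identity > 0.8 and
hairpin coverage > 0.9) are classed pri-miRNA, which takes precedence over
position. Positional classes are strand-blind: exonic on any exon overlap
(sense or antisense), else intronic on any mRNA overlap, else intergenic
when the nearest gene is more than 200 bp away (closed-hull gap), else
unclassified (reported but excluded from class counts).

## Co-expression networks

Replicate-averaged FPKM per tissue is z-scored across each developmental
group's tissues with the sample (n−1) standard deviation; zero-variance
genes are dropped. The SOM is classical online Kohonen training on a
hexagonal grid (odd rows shifted half a column, rows √3/2 apart): codebook
initialized by sampling input profiles, best-matching unit by Euclidean
distance, Gaussian neighborhood with radius decaying linearly from the 2/3
quantile of grid distances to 0, learning rate decaying linearly 0.05 → 0.01
over 100 passes, all seeded and deterministic. These training knobs are
declared defaults — the grid shapes (3×2, 5×4, 4×3) are the substantive
parameters, giving 6/20/12 unit capacities per group. Genes are assigned to
their nearest codebook vector, ties to the lowest unit index. Quantization
error is recorded per epoch; it is non-increasing up to a small early-epoch
wobble from the wide initial neighborhood (tests allow 5% of the initial
error per step). Curation of "physiologically relevant" units is a human
step by design: the package emits all units with per-unit profile summaries.

Enrichment is the hypergeometric upper tail P(X ≥ k) for k term genes among
the n annotated genes of a unit, against a background of all genes retained
by the group's z-scoring, BH-corrected across terms within the unit; terms
with no network gene are excluded, terms absent from the background are an
error.

## The synthetic generator

The generator emulates the study design: 22 named tissues in three
developmental groups (vegetative / reproductive / seed) with 3 replicates;
two subgenomes from a common ancestor with each substituted site assigned to
one lineage (realized divergence Binomial(L, d), symmetric, no indels — so
homologous coordinates stay exact and subgenome origin is decidable per
base); default divergence 0.02, inside the 1–3% band typical of recent
allotetraploids. Gene pairs are planted at identical coordinates with
ATG-initiated stop-free coding sequences; substitutions falling in exons are
re-applied at the CDS level avoiding stop creation, so every planted
transcript keeps a full-length ORF and pairs remain recoverable. Counts are
negative-binomial with variance μ + αμ² (μ = 100, α = 0.1 defaults);
planted-bias pairs split a log2 ratio of 2 symmetrically around the mean,
dominant pairs silence one copy (μ = 0). Junction loci are planted in the
gene-free tail of each chromosome with per-library support clearing the
read filter, NAGNAG windows edited into the genome, and sub-threshold decoys
included. Planted lncRNA candidates are constructed to pass the cascade (no
ORF > 60 aa, Fickett < 0.90) and placed per class against the planted
annotation; one decoy per cascade stage plants the first-failure truth.

Desk-scale structural sizes (2 chromosomes of 120 kb, 30 gene pairs, tens of
splice/lncRNA loci) are the package's own defaults for routine runs; the
statistical conditions (replication, dispersion, means, planted effect
sizes) are the study conditions above. The acceptance script uses 2000
pairs for the expression-bias calibration and recovery measurements.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: read-level sequencing error and coverage
nonuniformity, indel and structural divergence between subgenomes,
paralogous gene families and tandem duplicates, assembly chimerism (tested
separately with explicitly constructed chimeras), fractional
multi-mapping-derived counts (rounded at ingestion by design), alternative
isoform interference in quantification, and GC/length expression biases.
Planted-truth recovery demonstrates algorithmic correctness under the
model's assumptions, not robustness to real-data artifacts.

## Degenerate inputs and tie-breaks

Duplicate junction rows are summed with a warning. Unknown strands are "?"
and treated as plus where a strand decision is required. Untestable pairs
(all counts zero on both sides) get NaN p-values and are classified by the
expression rules alone. Empty alignments, orphan GFF3 features, unlabeled
transcripts, chromosome-less candidate positions and zero-length transcripts
raise errors rather than propagating silently. Hypergeometric p-values are
clipped to 1, BH is monotone by construction, and all stochastic components
(generator, SOM, acceptance script) run from explicit seeds.
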