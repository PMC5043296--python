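"""Independent reference implementations used only to cross-check the
package: deliberately naive, written against the textbook definitions and
sharing no code with allokit."""

from __future__ import annotations

import math
from itertools import permutations

from Bio.Seq import Seq

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# exhaustive Hamming scan for diagnostic fragments


def hamming(a: str, b: str) -> int:
    """Mismatch count; N matches nothing."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def brute_force_diagnostics(
    tiles: list[tuple[object, str]], genome_y: dict[str, str], m: int = 1
) -> dict[object, tuple[str, int, str]]:
    """source interval -> unique placement (chrom, start, strand) for tiles
    that have exactly one distance-m placement and none closer, scanning
    every full-length ungapped placement on both strands."""
    out = {}
    for source, tile in tiles:
        closer = False
        hits = []
        for strand, query in (("+", tile), ("-", revcomp(tile))):
            for chrom, seq in genome_y.items():
                for start in range(len(seq) - len(tile) + 1):
                    d = hamming(query, seq[start : start + len(tile)])
                    if d < m:
                        closer = True
                        break
                    if d == m:
                        hits.append((chrom, start, strand))
                if closer:
                    break
            if closer:
                break
        if not closer and len(hits) == 1:
            out[source] = hits[0]
    return out


# ---------------------------------------------------------------------------
# 6-frame ORF scan via Biopython translation


def longest_orf_aa(seq: str) -> int:
    """Length (aa) of the longest ATG-initiated ORF over all six frames,
    running to a stop or the sequence end."""
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            trimmed = s[frame : frame + 3 * ((len(s) - frame) // 3)]
            if not trimmed:
                continue
            protein = str(Seq(trimmed).translate())
            for chunk in protein.split("*"):
                m = chunk.find("M")
                if m != -1:
                    best = max(best, len(chunk) - m)
    return best


# ---------------------------------------------------------------------------
# NG86 by explicit enumeration


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def ng86_sites(codon: str) -> float:
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                syn += 1.0 / 3.0
    return syn


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    for order in permutations(positions):
        current = codon_a
        steps = []
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if _aa(nxt) == "*":
                hits_stop = True
            current = nxt
        all_paths.append((hits_stop, steps))
    usable = [s for stop, s in all_paths if not stop]
    fallback = not usable
    if fallback:
        usable = [s for _, s in all_paths]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if (
                _aa(before) != "*"
                and _aa(after) != "*"
                and _aa(before) == _aa(after)
            ):
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(usable), nd / len(usable)


def ng86(alignment: list[tuple[str, str]]):
    """(ka, ks) with Jukes-Cantor correction; None where undefined."""
    s_sites = sum(
        (ng86_sites(a) + ng86_sites(b)) / 2.0 for a, b in alignment
    )
    n_sites = 3 * len(alignment) - s_sites
    sd = nd = 0.0
    for a, b in alignment:
        ds, dn = ng86_differences(a, b)
        sd += ds
        nd += dn
    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return jc(pn), jc(ps), s_sites, sd, nd


# ---------------------------------------------------------------------------
# Gotoh global alignment (affine gaps), score only


def gotoh_score(a: str, b: str, sub, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> float:
    """Optimal global alignment score with affine gaps where a gap of
    length L costs gap_open + (L-1) * gap_extend (end gaps penalized)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# multiple testing and hypergeometric enumeration


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvalues[i] * n / rank)
        adjusted[i] = running
    return adjusted


def hypergeom_upper_tail(big_n: int, big_k: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    total = math.comb(big_n, n)
    acc = 0
    for i in range(k, min(big_k, n) + 1):
        acc += math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
    return acc / total
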