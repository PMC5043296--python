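"""Nei-Gojobori (1986) synonymous / nonsynonymous substitution rates.

Sites are counted fractionally per codon position (the fraction of the three
possible single-base changes that preserve the amino acid; changes creating a
stop codon count as nonsynonymous). Differences between codons are averaged
with equal weight over the minimal mutational pathways, excluding pathways
that pass through a stop codon. Proportions are corrected for multiple hits
with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; None for a stop codon."""
    if codon in _STOPS:
        return None
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Fractional count of synonymous sites in one codon (0..3)."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _CODON_TABLE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over minimal single-base mutational pathways;
    pathways through stop codons are excluded (if every pathway hits a stop,
    all pathways are used with stop-creating steps counted nonsynonymous).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0.0
        current = codon_a
        for pos in order:
            mutant = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if mutant in _STOPS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif current in _STOPS or _CODON_TABLE[mutant] == _CODON_TABLE[current]:
                # current can only be a stop in the allow_stops fallback
                if current in _STOPS:
                    nd += 1.0
                else:
                    sd += 1.0
            else:
                nd += 1.0
            current = mutant
        return sd, nd

    paths = [walk(order, False) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_positions)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None (undefined) when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float

    @property
    def ka_ks(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0.0:
            return None
        return self.ka / self.ks


def estimate_ka_ks(alignment: list[tuple[str, str]]) -> KaKsResult:
    """NG86 Ka and Ks from a gap-free codon alignment.

    ``alignment`` is a list of (codon_a, codon_b) pairs. Internal stop codons
    are an error. Ka or Ks is None when its corrected distance is undefined
    (proportion >= 3/4); the ratio is additionally None when Ks = 0.
    """
    if len(alignment) < 1:
        raise ValueError("alignment must span at least one codon")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for codon_a, codon_b in alignment:
        if codon_a in _STOPS or codon_b in _STOPS:
            raise ValueError(f"stop codon in alignment: {codon_a}/{codon_b}")
        s_sites += (synonymous_sites(codon_a) + synonymous_sites(codon_b)) / 2.0
        sd, nd = codon_differences(codon_a, codon_b)
        s_diffs += sd
        n_diffs += nd
    n_sites = 3.0 * len(alignment) - s_sites
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
    )
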