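"""Splice-junction filtering and alternative-splicing event taxonomy.

Junction tables (intron coordinates with per-library read support) are
filtered for a minimum of 10 supporting reads in at least one library, then
mined for three event classes: exon skipping (an outer junction spanning two
inner junctions over a skipped exon), and junction pairs sharing one intron
boundary with the other varying. Shared-boundary pairs are labeled
alternative donor or acceptor strand-aware, by which side (5' donor / 3'
acceptor) of the intron varies. Acceptor pairs 3 bp apart are screened for
the NAGNAG tandem-acceptor motif (.AG.AG over the 6-nt genomic window).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .intervals import GenomicInterval
from .io import JunctionRecord, SampleSheet, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
_NAGNAG = re.compile(r"^.AG.AG$")

JunctionKey = tuple[str, int, int]


@dataclass(frozen=True)
class ASEvent:
    """A classified alternative-splicing event.

    ``coordinate_class`` records the strand-blind genomic-coordinate grouping
    (shared_start / shared_end / skip); ``event_class`` is the strand-aware
    biological label (exon_skip / alt_donor / alt_acceptor). ``alternatives``
    holds the two varying coordinates for shared-boundary events.
    """

    event_id: str
    event_class: str
    coordinate_class: str
    chrom: str
    strand: str
    shared: int | None
    alternatives: tuple[int, ...]
    members: tuple[JunctionKey, ...]
    skipped_exon: GenomicInterval | None = None
    nagnag: bool = False
    motif: str | None = None


def filter_junctions(
    junctions: list[JunctionRecord], min_reads: int = DEFAULT_MIN_READS
) -> list[JunctionRecord]:
    """Keep junctions with >= min_reads support in at least one library."""
    return [j for j in junctions if j.counts and max(j.counts) >= min_reads]


def _donor_acceptor_label(coordinate_class: str, strand: str) -> str:
    """Strand-aware event label for a shared-boundary junction pair.

    On the plus strand the intron start is the 5' donor side and the intron
    end the 3' acceptor side; on the minus strand the roles swap. Unknown
    strand is treated as plus.
    """
    plus_like = strand != "-"
    if coordinate_class == "shared_start":  # the end (right) coordinate varies
        return "alt_acceptor" if plus_like else "alt_donor"
    return "alt_donor" if plus_like else "alt_acceptor"


def classify_events(junctions: list[JunctionRecord]) -> list[ASEvent]:
    """Mine filtered junctions for exon-skip, alt-donor and alt-acceptor events.

    Exon-skip triplets {(s, e1), (s2, e), (s, e)} with e1 < s2 are found
    first; the two junction pairs inside each triplet are consumed and
    excluded from shared-boundary pair enumeration, which makes the three
    class counts additive. Output is sorted and independent of input order.
    """
    by_group: dict[tuple[str, str], list[JunctionRecord]] = defaultdict(list)
    for j in junctions:
        by_group[(j.chrom, j.strand)].append(j)

    events: list[ASEvent] = []
    for (chrom, strand), group in sorted(by_group.items()):
        ends_of_start: dict[int, set[int]] = defaultdict(set)
        starts_of_end: dict[int, set[int]] = defaultdict(set)
        keys = set()
        for j in group:
            ends_of_start[j.start].add(j.end)
            starts_of_end[j.end].add(j.start)
            keys.add((j.start, j.end))

        consumed: set[frozenset[JunctionKey]] = set()
        for s, e in sorted(keys):
            outer = (chrom, s, e)
            for e1 in sorted(ends_of_start[s]):
                if e1 >= e:
                    continue
                for s2 in sorted(starts_of_end[e]):
                    if s2 <= s or e1 >= s2:
                        continue
                    inner_left = (chrom, s, e1)
                    inner_right = (chrom, s2, e)
                    consumed.add(frozenset({outer, inner_left}))
                    consumed.add(frozenset({outer, inner_right}))
                    events.append(
                        ASEvent(
                            event_id=f"{chrom}:{strand}:skip:{s}-{e1}:{s2}-{e}",
                            event_class="exon_skip",
                            coordinate_class="skip",
                            chrom=chrom,
                            strand=strand,
                            shared=None,
                            alternatives=(),
                            members=(inner_left, inner_right, outer),
                            skipped_exon=GenomicInterval(chrom, e1, s2, strand),
                        )
                    )

        for s in sorted(ends_of_start):
            ends = sorted(ends_of_start[s])
            for i in range(len(ends)):
                for k in range(i + 1, len(ends)):
                    pair = frozenset({(chrom, s, ends[i]), (chrom, s, ends[k])})
                    if pair in consumed:
                        continue
                    events.append(
                        ASEvent(
                            event_id=f"{chrom}:{strand}:ss:{s}:{ends[i]}:{ends[k]}",
                            event_class=_donor_acceptor_label("shared_start", strand),
                            coordinate_class="shared_start",
                            chrom=chrom,
                            strand=strand,
                            shared=s,
                            alternatives=(ends[i], ends[k]),
                            members=((chrom, s, ends[i]), (chrom, s, ends[k])),
                        )
                    )
        for e in sorted(starts_of_end):
            starts = sorted(starts_of_end[e])
            for i in range(len(starts)):
                for k in range(i + 1, len(starts)):
                    pair = frozenset({(chrom, starts[i], e), (chrom, starts[k], e)})
                    if pair in consumed:
                        continue
                    events.append(
                        ASEvent(
                            event_id=f"{chrom}:{strand}:se:{e}:{starts[i]}:{starts[k]}",
                            event_class=_donor_acceptor_label("shared_end", strand),
                            coordinate_class="shared_end",
                            chrom=chrom,
                            strand=strand,
                            shared=e,
                            alternatives=(starts[i], starts[k]),
                            members=((chrom, starts[i], e), (chrom, starts[k], e)),
                        )
                    )
    events.sort(key=lambda ev: ev.event_id)
    return events


def detect_nagnag(
    events: list[ASEvent], genome: dict[str, str]
) -> list[ASEvent]:
    """Flag acceptor-side events whose two acceptors are exactly 3 bp apart
    and whose 6-nt genomic window matches .AG.AG.

    Plus strand (acceptor = intron end, e1 < e2 = e1 + 3): the window is
    genome[e1-3, e1+3). Minus strand (acceptor = intron start, s1 < s2 =
    s1 + 3): the reverse complement of genome[s1, s1+6).
    """
    flagged = []
    for event in events:
        if event.event_class != "alt_acceptor" or len(event.alternatives) != 2:
            flagged.append(event)
            continue
        c1, c2 = sorted(event.alternatives)
        if c2 - c1 != 3:
            flagged.append(event)
            continue
        seq = genome.get(event.chrom)
        if event.strand == "-":
            lo, hi = c1, c1 + 6
        else:
            lo, hi = c1 - 3, c1 + 3
        if seq is None or lo < 0 or hi > len(seq):
            logger.warning("NAGNAG window out of bounds for %s", event.event_id)
            flagged.append(event)
            continue
        motif = seq[lo:hi]
        if event.strand == "-":
            motif = reverse_complement(motif)
        flagged.append(
            replace(event, nagnag=bool(_NAGNAG.match(motif)), motif=motif)
        )
    return flagged


# ---------------------------------------------------------------------------
# usage, preference, clustering


def _form_supports(
    event: ASEvent, counts_by_key: dict[JunctionKey, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-library support for form 1 (retention / proximal) and form 2
    (skip / distal).

    For exon skipping, retention support is the mean of the two inner
    junction counts and skip support the outer junction count. For
    shared-boundary pairs, the proximal form is the shorter intron (the
    varying boundary closer to the shared one).
    """
    if event.event_class == "exon_skip":
        inner_left, inner_right, outer = event.members
        form1 = (counts_by_key[inner_left] + counts_by_key[inner_right]) / 2.0
        form2 = counts_by_key[outer].astype(float)
    else:
        lengths = [key[2] - key[1] for key in event.members]
        proximal, distal = (
            (event.members[0], event.members[1])
            if lengths[0] <= lengths[1]
            else (event.members[1], event.members[0])
        )
        form1 = counts_by_key[proximal].astype(float)
        form2 = counts_by_key[distal].astype(float)
    return form1, form2


def usage_profile(
    events: list[ASEvent],
    junctions: list[JunctionRecord],
    sheet: SampleSheet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue usage of each event.

    Returns (categories, proportions): categories in
    {both, first_only, second_only, none}; proportions are the inclusion
    proportion form1/(form1+form2) pooled over the tissue's replicates
    (NaN when unsupported).
    """
    counts_by_key = {j.key: np.asarray(j.counts) for j in junctions}
    lib_index = {lib: i for i, lib in enumerate(sheet.libraries)}
    tissues = sheet.tissues
    cat_rows, num_rows = [], []
    for event in events:
        form1, form2 = _form_supports(event, counts_by_key)
        cat_row, num_row = {}, {}
        for tissue in tissues:
            idx = [lib_index[lib] for lib in sheet.libraries_for_tissue(tissue)]
            f1, f2 = form1[idx], form2[idx]
            total1, total2 = f1.sum(), f2.sum()
            if total1 > 0 and total2 > 0:
                cat = "both"
            elif total1 > 0:
                cat = "first_only"
            elif total2 > 0:
                cat = "second_only"
            else:
                cat = "none"
            cat_row[tissue] = cat
            num_row[tissue] = (
                total1 / (total1 + total2) if total1 + total2 > 0 else np.nan
            )
        cat_rows.append(cat_row)
        num_rows.append(num_row)
    index = [e.event_id for e in events]
    return (
        pd.DataFrame(cat_rows, index=index),
        pd.DataFrame(num_rows, index=index),
    )


def preference_scores(
    events: list[ASEvent],
    junctions: list[JunctionRecord],
    sheet: SampleSheet,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """log2(form-1 support / form-2 support) per event and tissue.

    Scores are emitted only where both (pseudocounted) supports are
    positive; rows: event_id, tissue, value.
    """
    counts_by_key = {j.key: np.asarray(j.counts) for j in junctions}
    lib_index = {lib: i for i, lib in enumerate(sheet.libraries)}
    rows = []
    for event in events:
        form1, form2 = _form_supports(event, counts_by_key)
        for tissue in sheet.tissues:
            idx = [lib_index[lib] for lib in sheet.libraries_for_tissue(tissue)]
            t1 = form1[idx].sum() + pseudocount
            t2 = form2[idx].sum() + pseudocount
            if t1 > 0 and t2 > 0:
                rows.append(
                    {
                        "event_id": event.event_id,
                        "tissue": tissue,
                        "value": float(np.log2(t1 / t2)),
                    }
                )
    return pd.DataFrame(rows, columns=["event_id", "tissue", "value"])


@dataclass
class UsageClustering:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_usage(numeric: pd.DataFrame) -> UsageClustering:
    """Agglomerative clustering (Euclidean, average linkage) of events and
    tissues on inclusion proportions.

    Missing values are imputed with the event's (row) mean; all-missing rows
    are dropped with a warning.
    """
    matrix = numeric.copy()
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d all-missing rows", int(all_missing.sum()))
        matrix = matrix.loc[~all_missing]
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    filled = matrix.apply(lambda row: row.fillna(row.mean()), axis=1)
    row_linkage = hierarchy.linkage(pdist(filled.to_numpy()), method="average")
    col_linkage = hierarchy.linkage(pdist(filled.to_numpy().T), method="average")
    return UsageClustering(
        row_order=[matrix.index[i] for i in hierarchy.leaves_list(row_linkage)],
        col_order=[matrix.columns[i] for i in hierarchy.leaves_list(col_linkage)],
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )
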