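"""Per-tissue subgenome expression-bias classification for homeolog pairs.

For every homeolog pair and tissue, the two copies' replicate counts are
compared with a negative-binomial Wald test (size factors fixed at 1, since
both copies are measured in the same libraries); Benjamini-Hochberg
correction is applied across pairs within each tissue. Calls are then made
with the precedence: not expressed, complete dominance (one copy silenced,
FPKM < 1 in every replicate), significant bias, balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet
from .pairing import HomeologPair

CATEGORIES = (
    "A_biased",
    "B_biased",
    "A_dominant",
    "B_dominant",
    "balanced",
    "not_expressed",
)
EXPRESSED_CATEGORIES = CATEGORIES[:5]

DEFAULT_ALPHA = 0.05
DEFAULT_EXPR_FPKM = 1.0
MIN_DISPERSION = 0.01


# ---------------------------------------------------------------------------
# normalization and filtering


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM = count * 1e9 / (transcript length * library total count)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"lengths missing for transcripts {missing}")
    if (lengths <= 0).any():
        raise ValueError("zero or negative transcript length")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library with zero total count")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(totals, axis=1)


def filter_min_expression(
    fpkm: pd.DataFrame, threshold: float = 1.0
) -> pd.Index:
    """Transcripts with FPKM >= threshold in at least one library."""
    return fpkm.index[(fpkm >= threshold).any(axis=1)]


# ---------------------------------------------------------------------------
# the NB Wald test


def nb_wald_test(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided Wald test of equal NB means per pair.

    ``counts_a``/``counts_b`` are (n_pairs, n_replicates) integer arrays for
    the A and B copies over the same libraries. Group means are the ML
    estimates under unit size factors; a shared per-pair dispersion alpha
    (variance = mu + alpha mu^2) is estimated by method of moments pooled
    over the two copies and floored at 0.01. Returns (log2_ratio, p,
    untestable); untestable pairs (all counts zero in both copies) get
    p = NaN.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    mean_a = counts_a.mean(axis=1)
    mean_b = counts_b.mean(axis=1)
    untestable = (mean_a == 0) & (mean_b == 0)

    def mom_alpha(counts, mean):
        var = counts.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mean > 0, (var - mean) / mean**2, np.nan)

    stacked = np.column_stack(
        [mom_alpha(counts_a, mean_a), mom_alpha(counts_b, mean_b)]
    )
    finite = np.isfinite(stacked)
    with np.errstate(invalid="ignore"):
        alpha = np.where(
            finite.any(axis=1),
            np.nansum(np.where(finite, stacked, 0.0), axis=1)
            / np.maximum(finite.sum(axis=1), 1),
            np.nan,
        )
    # Per-pair moment estimates at 3 replicates are too noisy for a
    # calibrated Wald test; floor each pair's dispersion by the median
    # across all pairs in the call (information sharing across pairs, as
    # differential-expression NB tests do), then by the global floor.
    with np.errstate(invalid="ignore"):
        shared = np.nanmedian(alpha) if np.isfinite(alpha).any() else np.nan
    floor = max(shared, MIN_DISPERSION) if np.isfinite(shared) else MIN_DISPERSION
    alpha = np.where(np.isnan(alpha), floor, alpha)
    alpha = np.maximum(alpha, floor)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(mean_a / mean_b)
        se_ln = np.sqrt(
            (1.0 / mean_a + alpha) / n_a + (1.0 / mean_b + alpha) / n_b
        )
        z = np.log(mean_a / mean_b) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(z), p, np.nan)
    p = np.where(untestable, np.nan, p)
    return log2_ratio, p, untestable


def test_pair_bias(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[float, float]:
    """Single-pair convenience wrapper: (log2_ratio, p)."""
    counts_a = np.atleast_2d(np.asarray(counts_a))
    counts_b = np.atleast_2d(np.asarray(counts_b))
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("at least 2 replicates per copy required")
    log2_ratio, p, _ = nb_wald_test(counts_a, counts_b)
    return float(log2_ratio[0]), float(p[0])


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate."""
    pvalues = np.asarray(pvalues, dtype=float)
    padj = np.full_like(pvalues, np.nan)
    mask = ~np.isnan(pvalues)
    if mask.any():
        padj[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return padj


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class BiasCall:
    pair_id: str
    tissue: str
    category: str


def classify_bias(
    padj: float,
    log2_ratio: float,
    fpkm_a: np.ndarray,
    fpkm_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    expr_fpkm: float = DEFAULT_EXPR_FPKM,
) -> str:
    """Category for one pair in one tissue.

    Precedence: not_expressed (both copies' mean FPKM below the expression
    floor), complete dominance (one copy below the floor in every replicate
    while the other's mean is at or above it), significant bias (BH-adjusted
    p below alpha, direction from the log2 ratio), else balanced.
    """
    fpkm_a = np.asarray(fpkm_a, dtype=float)
    fpkm_b = np.asarray(fpkm_b, dtype=float)
    mean_a, mean_b = fpkm_a.mean(), fpkm_b.mean()
    if mean_a < expr_fpkm and mean_b < expr_fpkm:
        return "not_expressed"
    if (fpkm_b < expr_fpkm).all() and mean_a >= expr_fpkm:
        return "A_dominant"
    if (fpkm_a < expr_fpkm).all() and mean_b >= expr_fpkm:
        return "B_dominant"
    if not np.isnan(padj) and padj < alpha:
        return "A_biased" if log2_ratio > 0 else "B_biased"
    return "balanced"


def run_bias_analysis(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sheet: SampleSheet,
    pairs: list[HomeologPair],
    alpha: float = DEFAULT_ALPHA,
    expr_fpkm: float = DEFAULT_EXPR_FPKM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test and classify every pair in every tissue.

    Returns (tests, calls) frames; BH correction is applied across pairs
    within each tissue.
    """
    fpkm = compute_fpkm(counts, lengths)
    a_ids = [p.a_id for p in pairs]
    b_ids = [p.b_id for p in pairs]
    pair_ids = [f"{p.a_id}~{p.b_id}" for p in pairs]
    test_rows, call_rows = [], []
    for tissue in sheet.tissues:
        libs = sheet.libraries_for_tissue(tissue)
        counts_a = counts.loc[a_ids, libs].to_numpy()
        counts_b = counts.loc[b_ids, libs].to_numpy()
        fpkm_a = fpkm.loc[a_ids, libs].to_numpy()
        fpkm_b = fpkm.loc[b_ids, libs].to_numpy()
        log2_ratio, p, untestable = nb_wald_test(counts_a, counts_b)
        padj = benjamini_hochberg(p)
        for i, pair_id in enumerate(pair_ids):
            test_rows.append(
                {
                    "pair_id": pair_id,
                    "tissue": tissue,
                    "log2_ratio": log2_ratio[i],
                    "p": p[i],
                    "padj": padj[i],
                    "untestable": bool(untestable[i]),
                }
            )
            category = classify_bias(
                padj[i], log2_ratio[i], fpkm_a[i], fpkm_b[i], alpha, expr_fpkm
            )
            call_rows.append(
                {"pair_id": pair_id, "tissue": tissue, "category": category}
            )
    return pd.DataFrame(test_rows), pd.DataFrame(call_rows)


# ---------------------------------------------------------------------------
# summaries


def summarize_bias(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue category counts and percentages, plus a constitutive row.

    Percentages per tissue use the expressed pairs (sum of the five
    expressed categories) as denominator. The constitutive row counts pairs
    biased — dominance included — in the same direction in every tissue
    where they are expressed (and expressed in at least 2 tissues);
    constitutive-balanced pairs are never biased in any tissue. Constitutive
    percentages are over all pairs.
    """
    rows = []
    for tissue, sub in calls.groupby("tissue", sort=False):
        counts = sub["category"].value_counts()
        row = {"tissue": tissue}
        expressed = sum(int(counts.get(c, 0)) for c in EXPRESSED_CATEGORIES)
        for category in EXPRESSED_CATEGORIES:
            n = int(counts.get(category, 0))
            row[category] = n
            row[f"{category}_pct"] = 100.0 * n / expressed if expressed else np.nan
        row["expressed_pairs"] = expressed
        rows.append(row)

    biased_a = {"A_biased", "A_dominant"}
    biased_b = {"B_biased", "B_dominant"}
    n_const_a = n_const_b = n_never = 0
    for _, sub in calls.groupby("pair_id"):
        cats = set(sub["category"])
        expressed_cats = [c for c in sub["category"] if c != "not_expressed"]
        if not cats & (biased_a | biased_b):
            n_never += 1
        if len(expressed_cats) >= 2:
            if all(c in biased_a for c in expressed_cats):
                n_const_a += 1
            elif all(c in biased_b for c in expressed_cats):
                n_const_b += 1
    n_pairs = calls["pair_id"].nunique()
    rows.insert(
        0,
        {
            "tissue": "constitutive",
            "A_biased": n_const_a,
            "A_biased_pct": 100.0 * n_const_a / n_pairs if n_pairs else np.nan,
            "B_biased": n_const_b,
            "B_biased_pct": 100.0 * n_const_b / n_pairs if n_pairs else np.nan,
            "A_dominant": 0,
            "A_dominant_pct": 0.0,
            "B_dominant": 0,
            "B_dominant_pct": 0.0,
            "balanced": n_never,
            "balanced_pct": 100.0 * n_never / n_pairs if n_pairs else np.nan,
            "expressed_pairs": n_pairs,
        },
    )
    return pd.DataFrame(rows)


def tissue_percentages(category_counts: dict[str, int]) -> dict[str, float]:
    """Percentages of the five expressed categories for one tissue row.

    ``category_counts`` maps the five expressed categories to counts; the
    denominator is their sum (the expressed pairs).
    """
    expressed = sum(category_counts.get(c, 0) for c in EXPRESSED_CATEGORIES)
    return {
        c: 100.0 * category_counts.get(c, 0) / expressed
        for c in EXPRESSED_CATEGORIES
    }


# ---------------------------------------------------------------------------
# window track


@dataclass(frozen=True)
class WindowTrack:
    chromosome_pair: str
    window_start: int  # locus rank
    n_loci: int
    frac_a_biased: float
    frac_b_biased: float


def window_bias_track(
    loci: pd.DataFrame,
    calls: pd.DataFrame,
    tissue: str,
    window: int = 50,
    step: int = 10,
) -> list[WindowTrack]:
    """Sliding-window fractions of A-/B-biased loci along each chromosome pair.

    ``loci`` columns: pair_id, chromosome_pair, position (reciprocal-mapping
    pairs only); loci are ranked by position within each chromosome pair. If
    fewer than ``window`` loci exist on a chromosome pair, a single
    whole-chromosome window is emitted; otherwise a trailing partial window
    covers any loci beyond the last full window.
    """
    tissue_calls = calls.loc[calls["tissue"] == tissue]
    category = dict(zip(tissue_calls["pair_id"], tissue_calls["category"]))
    tracks = []
    for chrom_pair, sub in loci.groupby("chromosome_pair", sort=True):
        ordered = sub.sort_values("position")["pair_id"].tolist()
        n = len(ordered)
        if n < window:
            starts = [0]
        else:
            starts = list(range(0, n - window + 1, step))
            if starts[-1] + window < n:
                starts.append(starts[-1] + step)
        for start in starts:
            chunk = ordered[start : start + window]
            cats = [category.get(p, "not_expressed") for p in chunk]
            n_a = sum(c in ("A_biased", "A_dominant") for c in cats)
            n_b = sum(c in ("B_biased", "B_dominant") for c in cats)
            tracks.append(
                WindowTrack(
                    chromosome_pair=chrom_pair,
                    window_start=start,
                    n_loci=len(chunk),
                    frac_a_biased=n_a / len(chunk),
                    frac_b_biased=n_b / len(chunk),
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# rate comparisons


def compare_rates(
    values_biased: list[float], values_unbiased: list[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p between two groups.

    Exact enumeration when both groups have <= 10 values and no ties are
    present, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(values_biased, dtype=float)
    y = np.asarray(values_unbiased, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    if x.size <= 10 and y.size <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
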