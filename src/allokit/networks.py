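"""Developmental co-expression networks via self-organizing maps.

Replicate-averaged FPKM profiles are z-scored across the tissues of a
developmental group (vegetative, reproductive, seed), clustered on a small
hexagonal Kohonen grid (3x2, 5x4 and 4x3 grids give the three groups'
network capacities), and each grid unit's gene set is tested for GO-term
enrichment with a hypergeometric upper-tail test and Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_EPOCHS = 100
ALPHA_START, ALPHA_END = 0.05, 0.01


# ---------------------------------------------------------------------------
# z-score profiles


def zscore_profiles(
    mean_fpkm: pd.DataFrame, group_tissues: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each gene's profile across the group's tissues.

    ``mean_fpkm`` is genes x tissues (replicate-averaged). Genes with zero
    variance across the group are dropped; the rest get (x - mean) / sd with
    the sample (n-1) standard deviation. Returns (profiles, dropped gene
    ids).
    """
    if len(group_tissues) < 2:
        raise ValueError("a group needs at least 2 tissues")
    sub = mean_fpkm[group_tissues]
    sd = sub.std(axis=1, ddof=1)
    dropped = list(sub.index[sd == 0])
    kept = sub.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, dropped


def mean_fpkm_by_tissue(fpkm: pd.DataFrame, sheet) -> pd.DataFrame:
    """Average FPKM over each tissue's replicate libraries."""
    columns = {
        tissue: fpkm[sheet.libraries_for_tissue(tissue)].mean(axis=1)
        for tissue in sheet.tissues
    }
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# self-organizing map


def hexagonal_positions(rows: int, cols: int) -> np.ndarray:
    """Unit positions on a hexagonal grid: odd rows shifted by 0.5 columns,
    rows spaced sqrt(3)/2 apart."""
    positions = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            positions[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return positions


@dataclass
class SOMModel:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, n_tissues)
    tissues: list[str]
    assignment: pd.Series  # gene -> unit index
    quantization_errors: np.ndarray  # per epoch
    seed: int

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def train_som(
    profiles: pd.DataFrame,
    rows: int,
    cols: int,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
) -> SOMModel:
    """Online Kohonen training on z-score profiles.

    The codebook is initialized by sampling input profiles. Per step the
    best-matching unit (minimum Euclidean distance) pulls its grid
    neighborhood toward the sample with a Gaussian kernel; the learning rate
    decays linearly 0.05 -> 0.01 and the neighborhood radius decays linearly
    from the 2/3 quantile of grid distances to 0 over all steps.
    Deterministic for a fixed seed.
    """
    data = profiles.to_numpy(dtype=float)
    n_genes, _ = data.shape
    n_units = rows * cols
    if n_genes < n_units:
        raise ValueError(f"need at least {n_units} genes, got {n_genes}")
    rng = np.random.default_rng(seed)
    codebook = data[rng.choice(n_genes, size=n_units, replace=False)].copy()
    grid = hexagonal_positions(rows, cols)
    grid_dist = np.linalg.norm(grid[:, None, :] - grid[None, :, :], axis=2)
    radius_start = float(np.quantile(grid_dist[np.triu_indices(n_units, 1)], 2 / 3))
    total_steps = epochs * n_genes
    qe = []
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_genes)
        for idx in order:
            x = data[idx]
            frac = step / max(total_steps - 1, 1)
            alpha = ALPHA_START + (ALPHA_END - ALPHA_START) * frac
            radius = max(radius_start * (1.0 - frac), 1e-9)
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-(grid_dist[bmu] ** 2) / (2.0 * radius**2))
            codebook += (alpha * h)[:, None] * (x - codebook)
            step += 1
        dists = np.linalg.norm(data[:, None, :] - codebook[None, :, :], axis=2)
        qe.append(float(dists.min(axis=1).mean()))
    assignment = _nearest_units(codebook, data)
    return SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        tissues=list(profiles.columns),
        assignment=pd.Series(assignment, index=profiles.index),
        quantization_errors=np.asarray(qe),
        seed=seed,
    )


def _nearest_units(codebook: np.ndarray, data: np.ndarray) -> np.ndarray:
    dists = np.linalg.norm(data[:, None, :] - codebook[None, :, :], axis=2)
    # ties broken toward the lowest unit index (argmin's convention)
    return dists.argmin(axis=1)


def assign_units(model: SOMModel, profiles: pd.DataFrame) -> pd.Series:
    """Nearest-codebook unit per gene; ties go to the lowest unit index."""
    if profiles.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"profile dimension {profiles.shape[1]} does not match the model's "
            f"{model.codebook.shape[1]} tissues"
        )
    return pd.Series(
        _nearest_units(model.codebook, profiles.to_numpy(dtype=float)),
        index=profiles.index,
    )


def unit_summary(model: SOMModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of member z-profiles per unit and tissue."""
    rows = []
    for unit in range(model.n_units):
        members = profiles.loc[model.assignment[model.assignment == unit].index]
        for tissue in profiles.columns:
            values = members[tissue]
            rows.append(
                {
                    "unit": unit,
                    "tissue": tissue,
                    "n_genes": len(members),
                    "q1": values.quantile(0.25) if len(members) else np.nan,
                    "median": values.median() if len(members) else np.nan,
                    "q3": values.quantile(0.75) if len(members) else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GO enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    network: str
    term: str
    k: int  # term genes in the network
    n: int  # annotated network genes
    big_k: int  # term genes in the background
    big_n: int  # background size
    p: float
    padj: float


def enrich_go(
    network_genes: set[str],
    annotation_map: dict[str, set[str]],
    background: set[str],
    network_id: str = "",
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail GO-term enrichment with BH correction.

    ``annotation_map`` maps gene -> set of term ids; terms absent from the
    background (no annotated background gene) are an error, terms with no
    network gene are excluded.
    """
    if not network_genes <= background:
        raise ValueError("network genes must be a subset of the background")
    big_n = len(background)
    n = sum(1 for g in network_genes if annotation_map.get(g))
    term_background: dict[str, int] = {}
    term_network: dict[str, int] = {}
    for gene in background:
        for term in annotation_map.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in network_genes:
                term_network[term] = term_network.get(term, 0) + 1
    results = []
    for term in sorted(term_network):
        k = term_network[term]
        big_k = term_background.get(term, 0)
        if big_k == 0:
            raise ValueError(f"term {term!r} absent from the background")
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        results.append(
            EnrichmentResult(network_id, term, k, n, big_k, big_n, min(p, 1.0), np.nan)
        )
    if results:
        padj = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                r.network, r.term, r.k, r.n, r.big_k, r.big_n, r.p, float(q)
            )
            for r, q in zip(results, padj)
        ]
    return results
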