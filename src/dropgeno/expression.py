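"""Expression normalization, per-cell QC, cross-dataset concordance and
marker-gene efficacy scoring.

Count matrices are plain pandas DataFrames, genes x cells, matching the
market-matrix trios the pipeline reads and writes. Clustering itself is an
input (cluster labels arrive as a barcode -> cluster table); only the
computations downstream of it live here.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MITO_PATTERN = r"^MT-"
RIBO_PATTERN = r"^RP[SL]"


def _gene_mask(genes: pd.Index, explicit: Optional[Iterable[str]], pattern: str) -> np.ndarray:
    if explicit is not None:
        chosen = set(explicit)
        return genes.isin(chosen).to_numpy()
    rx = re.compile(pattern, re.IGNORECASE)
    return np.array([bool(rx.match(g)) for g in genes])


def qc_metrics(
    counts: pd.DataFrame,
    mito_genes: Optional[Iterable[str]] = None,
    ribo_genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-cell UMI totals, genes detected, and mitochondrial/ribosomal
    percentages. Gene sets default to the usual name patterns (MT-*, RPS/RPL).
    Cells with zero total counts get NaN percentages."""
    mat = counts.to_numpy()
    totals = mat.sum(axis=0).astype(float)
    mito = _gene_mask(counts.index, mito_genes, MITO_PATTERN)
    ribo = _gene_mask(counts.index, ribo_genes, RIBO_PATTERN)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mat[mito].sum(axis=0) / totals, np.nan)
        pct_ribo = np.where(totals > 0, 100.0 * mat[ribo].sum(axis=0) / totals, np.nan)
    return pd.DataFrame(
        {
            "barcode": counts.columns,
            "n_umis": totals.astype(int),
            "n_genes_detected": (mat > 0).sum(axis=0),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        }
    ).set_index("barcode")


def filter_cells(qc: pd.DataFrame, max_pct_mito: float = 5.0) -> list[str]:
    """Barcodes passing the mitochondrial filter: cells with *greater than*
    the threshold are removed, so a cell at exactly 5% is retained. Cells
    with undefined percentages (zero counts) are removed too."""
    keep = qc["pct_mito"] <= max_pct_mito
    return qc.index[keep.fillna(False)].tolist()


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """ln(1 + scale * count / cell_total), the standard log-normalization.

    Raises on zero-total cells; filter them first.
    """
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("zero-total cells present; run filter_cells first")
    return pd.DataFrame(
        np.log1p(scale * counts.to_numpy() / totals),
        index=counts.index,
        columns=counts.columns,
    )


def mean_lognorm(counts: pd.DataFrame, scale: float = 1e4) -> pd.Series:
    """Per-gene mean log-normalized expression — the expression measure the
    detection analyses stratify on."""
    return lognormalize(counts, scale).mean(axis=1)


def concordance(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    by: str = "gene",
    clusters_a: Optional[pd.Series] = None,
    clusters_b: Optional[pd.Series] = None,
) -> dict:
    """Cross-dataset expression concordance.

    by='gene': Pearson r (and r^2) of per-gene mean log-normalized
    expression between the two datasets, over the shared gene universe;
    reported both for all shared genes and restricted to genes expressed in
    both datasets. by='cluster': the cluster x cluster correlation matrix of
    per-cluster mean expression profiles (rows = clusters of A, columns =
    clusters of B).
    """
    shared = matrix_a.index.intersection(matrix_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")

    def _norm(m: pd.DataFrame) -> pd.DataFrame:
        nonzero = m.columns[m.sum(axis=0) > 0]
        if len(nonzero) < m.shape[1]:
            log.info("concordance: dropping %d zero-total cells", m.shape[1] - len(nonzero))
        return lognormalize(m[nonzero])

    a = _norm(matrix_a.loc[shared])
    b = _norm(matrix_b.loc[shared])
    if by == "gene":
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        r_all = stats.pearsonr(ma, mb).statistic
        expressed = (ma > 0) & (mb > 0)
        r_expr = (
            stats.pearsonr(ma[expressed], mb[expressed]).statistic
            if expressed.sum() >= 3
            else np.nan
        )
        return {
            "n_shared_genes": int(len(shared)),
            "r": float(r_all),
            "r2": float(r_all**2),
            "n_expressed_both": int(expressed.sum()),
            "r_expressed": float(r_expr),
            "r2_expressed": float(r_expr**2),
        }
    if by == "cluster":
        if clusters_a is None or clusters_b is None:
            raise ValueError("cluster labels required for by='cluster'")
        prof_a = a.T.groupby(clusters_a.reindex(a.columns)).mean().T
        prof_b = b.T.groupby(clusters_b.reindex(b.columns)).mean().T
        corr = pd.DataFrame(
            np.corrcoef(prof_a.T, prof_b.T)[: prof_a.shape[1], prof_a.shape[1]:],
            index=prof_a.columns,
            columns=prof_b.columns,
        )
        return {"cluster_correlation": corr}
    raise ValueError(f"unknown 'by' {by!r}")


def proportion_expressing(
    counts: pd.DataFrame,
    clusters: pd.Series,
    cpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per (gene, cluster) fraction of cells expressing at strictly more
    than ``cpm_threshold`` counts per million."""
    clusters = clusters.reindex(counts.columns)
    if clusters.isna().any():
        missing = counts.columns[clusters.isna()]
        raise ValueError(f"{len(missing)} cells without cluster label, e.g. {missing[0]}")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = counts.to_numpy() * 1e6 / totals
    above = pd.DataFrame(cpm > cpm_threshold, index=counts.index, columns=counts.columns)
    return above.T.groupby(clusters).mean().T


def marker_score(proportions: pd.Series, marked_cluster: str) -> float:
    """Marker efficacy score: sum of squared differences in expressing
    proportions divided by the sum of the differences, where differences are
    marked-cluster minus each other cluster.

    1 means perfectly binary expression in the marked cluster; 0 means
    evenly distributed or absent expression. A negative difference total
    (another cluster exceeds the marked one on balance) falls outside the
    nominal [0, 1] range; the returned score is clamped there with the raw
    value logged.
    """
    if marked_cluster not in proportions.index:
        raise KeyError(f"unknown cluster {marked_cluster!r}")
    p_k = proportions[marked_cluster]
    d = p_k - proportions.drop(marked_cluster)
    denom = d.sum()
    if denom == 0:
        return 0.0
    raw = float((d**2).sum() / denom)
    if not 0.0 <= raw <= 1.0:
        log.info("marker score %.4f outside [0,1]; clamped", raw)
    return float(np.clip(raw, 0.0, 1.0))


def top_markers_per_cluster(fold_changes: pd.DataFrame, n: int = 10) -> dict[str, list[str]]:
    """Top-n genes by average log2 fold change per cluster, from an input
    differential table with columns (cluster, gene, avg_log2fc). Ties at
    the cutoff break lexicographically by gene name."""
    out: dict[str, list[str]] = {}
    for cluster, grp in fold_changes.groupby("cluster"):
        ranked = grp.sort_values(["avg_log2fc", "gene"], ascending=[False, True])
        if len(ranked) < n:
            log.warning("cluster %s has only %d genes (< %d requested)", cluster, len(ranked), n)
        out[str(cluster)] = ranked["gene"].head(n).tolist()
    return out
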