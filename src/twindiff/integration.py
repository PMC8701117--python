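"""Methylation-expression (DM-DE) integration.

The core step links the twin methylation screen to the independent
case/control expression cohorts: for each expression cell type, a
hypomethylation threshold ``t`` on the mean within-pair delta-beta is chosen
to maximize the AUC of the binary classifier ``X = 1[delta < t]`` predicting
``Y = 1[logFC > 0]`` (for a binary predictor the AUC equals
(sensitivity + specificity) / 2, the Mann-Whitney statistic). The scan runs
on a regular grid over [-0.15, 0]; AUC ties break toward the threshold
closest to 0 (least stringent). Genes with a CpG passing the selected
threshold at a methylation p below 0.01 joined to the expression records form
the DM-DE gene set; hierarchical clustering of their log-fold-change profiles
(Euclidean distance, complete linkage) and cross-condition rank correlations
summarize the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "auc_for_threshold",
    "optimize_threshold",
    "ThresholdScan",
    "select_dmde",
    "cluster_lfc",
    "condition_correlations",
    "plot_threshold_scan",
]


def auc_for_threshold(gene_table: pd.DataFrame, t: float) -> float:
    """AUC of the binary rule 1[delta < t] for predicting 1[logFC > 0].

    ``gene_table`` needs ``mean_delta`` and ``logfc`` columns (one row per
    gene). Raises when the outcome is single-class (AUC undefined).
    """
    delta = gene_table["mean_delta"].to_numpy(dtype=float)
    y = gene_table["logfc"].to_numpy(dtype=float) > 0
    if y.all() or not y.any():
        raise ValueError("outcome has a single class; AUC undefined")
    x = delta < t
    sens = x[y].mean()
    spec = (~x[~y]).mean()
    return float((sens + spec) / 2.0)


@dataclass
class ThresholdScan:
    """Grid of candidate delta-beta thresholds with the AUC at each point."""

    cell_type: str
    thresholds: np.ndarray
    auc: np.ndarray
    selected: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "auc": self.auc})


def optimize_threshold(
    gene_table: pd.DataFrame,
    grid_lo: float = -0.15,
    grid_hi: float = 0.0,
    step: float = 0.005,
    cell_type: str = "",
) -> ThresholdScan:
    """Scan the threshold grid and select the AUC maximizer.

    The grid is regular and includes both endpoints; 0.005 steps hit all the
    published thresholds (-0.085, -0.08, -0.055). Ties break toward 0.
    """
    n_steps = round((grid_hi - grid_lo) / step)
    grid = grid_lo + step * np.arange(n_steps + 1)
    grid[-1] = grid_hi
    auc = np.array([auc_for_threshold(gene_table, t) for t in grid])
    best = np.flatnonzero(auc == auc.max())[-1]  # grid ascends toward 0
    return ThresholdScan(cell_type, grid, auc, float(grid[best]))


def select_dmde(
    dm_records: pd.DataFrame,
    de_records: pd.DataFrame,
    threshold: float,
    meth_p_max: float = 0.01,
) -> pd.DataFrame:
    """Join hypomethylated CpGs to expression records, one row per gene.

    A gene enters when it has >= 1 CpG with ``mean_delta < threshold`` and
    methylation ``p < meth_p_max``; per gene the smallest-p CpG is kept.
    Expression records join on the gene symbol; genes without an expression
    record are dropped (logged via the returned frame's size), genes with
    non-positive or missing logFC are retained but flagged ``upregulated ==
    False`` so reports can show them.
    """
    need = {"gene", "mean_delta", "p"}
    if not need.issubset(dm_records.columns):
        raise ValueError(f"DM records need columns {sorted(need)}")
    dm = dm_records[(dm_records["mean_delta"] < threshold) & (dm_records["p"] < meth_p_max)]
    dm = dm[dm["gene"] != ""]
    if dm.empty:
        return pd.DataFrame(columns=["gene"])
    best = dm.sort_values("p", kind="mergesort").groupby("gene", sort=True).head(1)
    de = de_records[de_records["gene"] != ""].set_index("gene")
    common = best["gene"][best["gene"].isin(de.index)]
    if common.empty:
        raise ValueError("no overlap between DM genes and expression records")
    out = best[best["gene"].isin(de.index)].copy()
    lfc_cols = [c for c in de.columns if c.startswith("lfc") or c == "logfc"]
    for col in lfc_cols:
        out[col] = de.loc[out["gene"], col].to_numpy()
    primary = lfc_cols[0] if lfc_cols else None
    if primary is not None:
        out["upregulated"] = out[primary].to_numpy() > 0
    return out.reset_index(drop=True)


def cluster_lfc(lfc: pd.DataFrame, k: int = 2) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage hierarchical clustering of genes by LFC profile.

    Missing (non-significant) entries are imputed as 0 before clustering.
    Returns the scipy linkage matrix and the k-cut labels indexed by gene.
    """
    if len(lfc) < 2:
        raise ValueError("need >= 2 genes to cluster")
    X = lfc.fillna(0.0).to_numpy(dtype=float)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=lfc.index, name="cluster")
    return Z, labels


def condition_correlations(
    a,
    b,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlation between two logFC columns on complete pairs.

    Entries missing (NS) in either column are dropped; needs >= 3 complete
    pairs. Rank (Spearman) correlation is the default as it reproduces the
    published within-experiment and cross-tissue coefficients; Pearson is
    available via ``method="pearson"``. Returns (r, two-sided p, n).
    """
    df = pd.DataFrame({"a": np.asarray(a, dtype=float), "b": np.asarray(b, dtype=float)}).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 complete pairs")
    if method == "pearson":
        res = stats.pearsonr(df["a"], df["b"])
    elif method == "spearman":
        res = stats.spearmanr(df["a"], df["b"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), int(len(df))


def plot_threshold_scan(scan: ThresholdScan, ax=None):
    """AUC-vs-threshold curve with the selected threshold as a vertical bar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(scan.thresholds, scan.auc, lw=1.5)
    ax.axvline(scan.selected, color="crimson", ls="--", lw=1)
    ax.set_xlabel(r"$\Delta\beta$ threshold")
    ax.set_ylabel("AUC")
    if scan.cell_type:
        ax.set_title(scan.cell_type)
    return ax
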