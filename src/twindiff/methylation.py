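"""Paired differential-methylation analysis of discordant twin pairs.

The design is an epigenome-wide paired comparison: for each CpG probe the
within-pair difference ``delta = beta_affected - beta_unaffected`` is computed
per twin pair, a one-sample (paired) t-test is run on those deltas, p-values
are corrected with the Benjamini-Hochberg step-up rule, and a site is called
differentially methylated when it clears both the FDR threshold (q < 0.05) and
an absolute effect threshold (|mean delta| > 0.085). Negative deltas mean
hypomethylation in the affected twin.

The module also implements the interferon-signature masking re-analysis: the
mean beta over the top CpG of every interferon-regulated gene in the DM set is
taken as a per-sample covariate, every probe genome-wide is residualized on it
by ordinary least squares, and the paired analysis is rerun on the residuals.
If the whole DM signature is driven by one shared latent factor, nothing
should survive this masking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, DMConfig

log = logging.getLogger(__name__)

__all__ = [
    "qc_filter_probes",
    "paired_deltas",
    "paired_ttest",
    "bh_fdr",
    "dm_table",
    "call_dm",
    "ifn_mask_reanalysis",
]


def qc_filter_probes(beta: BetaMatrix, cfg: DMConfig = DMConfig()) -> tuple[BetaMatrix, int]:
    """Drop every probe whose detection p exceeds the threshold in any sample.

    Returns the filtered matrix and the number of removed probes. Without a
    detection-p matrix the input passes through unchanged (with a warning).
    """
    if beta.detection_p is None:
        log.warning("no detection-p matrix present; QC filter is a pass-through")
        return beta, 0
    bad = (beta.detection_p.to_numpy(dtype=float) > cfg.detection_p_max).any(axis=1)
    keep = beta.probe_ids[~bad]
    removed = int(bad.sum())
    if removed:
        log.info("QC removed %d probes with detection p > %g", removed, cfg.detection_p_max)
    return beta.subset_probes(keep), removed


def paired_deltas(beta: BetaMatrix | pd.DataFrame, pairs=None) -> pd.DataFrame:
    """Per-probe per-pair delta (affected - unaffected) plus the row mean.

    Accepts either a :class:`BetaMatrix` or a raw values DataFrame with an
    explicit ``pairs`` map (the masking re-analysis operates on residual
    matrices that are no longer bounded in [0, 1]).
    """
    if isinstance(beta, BetaMatrix):
        values, pairs = beta.values, beta.pairs
    else:
        values = beta
        if pairs is None:
            raise ValueError("pairs map required with a raw matrix")
    out = {}
    for pair_id, (aff, unaff) in pairs.items():
        if aff not in values.columns or unaff not in values.columns:
            raise KeyError(f"pair {pair_id!r}: missing sample column")
        out[pair_id] = values[aff] - values[unaff]
    deltas = pd.DataFrame(out, index=values.index)
    deltas["mean_delta"] = deltas.mean(axis=1, skipna=True)
    return deltas


def paired_ttest(deltas: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Row-wise paired t-test on within-pair deltas.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``df = n - 1`` and a two-sided p
    from the t distribution. Zero-variance rows are flagged ``degenerate``:
    p = 1 when the mean is also zero, p = 0 otherwise; such rows are excluded
    from FDR correction downstream. Requires at least two pairs per row.
    """
    if isinstance(deltas, pd.DataFrame):
        d = deltas.drop(columns=["mean_delta"], errors="ignore")
        index = d.index
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(deltas, dtype=float))
        index = pd.RangeIndex(arr.shape[0])
    n = np.sum(np.isfinite(arr), axis=1)
    if np.any(n < 2):
        raise ValueError("paired t-test needs >= 2 pairs per probe")
    mean = np.nanmean(arr, axis=1)
    sd = np.nanstd(arr, axis=1, ddof=1)
    df = n - 1
    degenerate = sd <= 1e-12  # identical deltas up to float rounding
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = np.empty_like(mean)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    sign = np.sign(mean[degenerate])
    t[degenerate] = np.where(sign == 0, 0.0, np.where(sign > 0, np.inf, -np.inf))
    return pd.DataFrame(
        {"mean_delta": mean, "t": t, "df": df, "p": p, "degenerate": degenerate},
        index=index,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def dm_table(
    beta: BetaMatrix,
    manifest: pd.DataFrame | None = None,
    exclude_degenerate: bool = True,
) -> pd.DataFrame:
    """Full per-probe DM record table: deltas, mean, t, p, q, direction.

    Degenerate (zero-variance) probes get q = NaN rather than entering the
    FDR correction. Manifest columns (chrom, pos, gene, irg, relation) are
    merged in when provided.
    """
    deltas = paired_deltas(beta)
    tests = paired_ttest(deltas)
    records = pd.concat([deltas.drop(columns="mean_delta"), tests], axis=1)
    records["direction"] = np.where(records["mean_delta"] < 0, "hypo", "hyper")
    mask = ~records["degenerate"] if exclude_degenerate else np.ones(len(records), bool)
    q = np.full(len(records), np.nan)
    q[np.asarray(mask)] = bh_fdr(records.loc[mask, "p"].to_numpy())
    records["q"] = q
    if manifest is not None:
        cols = [c for c in ("chrom", "pos", "gene", "irg", "relation") if c in manifest.columns]
        records = records.join(manifest[cols], how="left")
        if "gene" in records.columns:
            records["gene"] = records["gene"].fillna("")
        if "irg" in records.columns:
            records["irg"] = records["irg"].fillna(False).astype(bool)
    records.index.name = "probe_id"
    return records


def call_dm(records: pd.DataFrame, cfg: DMConfig = DMConfig()) -> tuple[pd.DataFrame, dict]:
    """Apply the DM thresholds (strict inequalities) and summarize.

    Keeps rows with ``q < q_max`` and ``|mean_delta| > abs_delta_min``.
    Summary counts sites by direction plus unique and interferon-regulated
    gene counts when gene annotation is present.
    """
    keep = (records["q"] < cfg.q_max) & (records["mean_delta"].abs() > cfg.abs_delta_min)
    dm = records.loc[keep.fillna(False)].copy()
    summary = {
        "n_sites": int(len(dm)),
        "n_hypo": int((dm["direction"] == "hypo").sum()),
        "n_hyper": int((dm["direction"] == "hyper").sum()),
    }
    if "gene" in dm.columns:
        genes = dm["gene"].replace("", np.nan).dropna()
        summary["n_genes"] = int(genes.nunique())
        if "irg" in dm.columns:
            summary["n_irg_genes"] = int(
                dm.loc[dm["irg"], "gene"].replace("", np.nan).dropna().nunique()
            )
    return dm, summary


def _residualize(values: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """OLS-residualize every row of ``values`` on the covariate (+intercept)."""
    c = covariate.reindex(values.columns).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(c), c])
    B = values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, B.T, rcond=None)
    resid = B - (X @ coef).T
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def ifn_mask_reanalysis(
    beta: BetaMatrix,
    dm_records: pd.DataFrame,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Re-run the paired analysis after regressing out the IFN signature.

    For every interferon-regulated gene in the DM set the lowest-p CpG is
    selected; the per-sample mean beta over those CpGs is the masking
    covariate; every probe genome-wide is residualized on it and the paired
    delta / t / BH pipeline reruns on the residuals. Returns the new record
    table and the count of probes at ``q < q_max``.
    """
    if "irg" not in dm_records.columns or "gene" not in dm_records.columns:
        raise ValueError("DM records need 'irg' and 'gene' columns for masking")
    irg = dm_records[dm_records["irg"] & (dm_records["gene"] != "")]
    if irg.empty:
        raise ValueError("no interferon-regulated probes in the DM set")
    top = irg.sort_values("p").groupby("gene", sort=True).head(1)
    covariate = beta.values.loc[top.index].mean(axis=0)
    if covariate.nunique() == 1:
        log.warning("masking covariate is constant; residuals are centered betas")
    resid = _residualize(beta.values, covariate)
    deltas = paired_deltas(resid, beta.pairs)
    tests = paired_ttest(deltas)
    records = pd.concat([deltas.drop(columns="mean_delta"), tests], axis=1)
    records["direction"] = np.where(records["mean_delta"] < 0, "hypo", "hyper")
    q = np.full(len(records), np.nan)
    ok = ~records["degenerate"].to_numpy()
    q[ok] = bh_fdr(records.loc[ok, "p"].to_numpy())
    records["q"] = q
    n_sig = int((records["q"] < q_max).sum())
    return records, n_sig
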