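"""Case/control differential expression with empirical-Bayes variance shrinkage.

The moderated t-statistic borrows strength across features by shrinking each
feature's residual variance toward a common prior. Per feature, the two-group
pooled residual variance ``s^2`` with ``d`` degrees of freedom is assumed to
follow ``s^2 | sigma^2 ~ sigma^2 * chi^2_d / d`` with a scaled inverse-chi^2
prior ``sigma^2 ~ s0^2 * d0 / chi^2_{d0}``. The hyperparameters ``(d0, s0^2)``
are estimated by moment-matching the distribution of ``log s^2`` (a
digamma/trigamma inversion), the posterior variance is the degrees-of-freedom
weighted combination ``(d0*s0^2 + d*s^2) / (d0 + d)``, and the moderated t
uses ``d0 + d`` degrees of freedom. This is the standard microarray
empirical-Bayes scheme; p-values are BH-corrected.

Upstream of the test, features in the lower half of the *range* of mean
intensities (midpoint of min and max of feature means) and features without
gene annotation are discarded. Downstream, records from the native and custom
annotation runs of a study are merged at q < 0.2 keeping the single most
significant probe per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionSet
from .methylation import bh_fdr

log = logging.getLogger(__name__)

__all__ = [
    "filter_low_intensity",
    "squeeze_var",
    "moderated_t_de",
    "merge_annotations",
    "classify_activity",
    "ModeratedTParams",
]

ACTIVE_SLEDAI = 6.0


@dataclass(frozen=True)
class ModeratedTParams:
    """Estimated prior degrees of freedom and variance of the shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be nonnegative")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be positive")


def filter_low_intensity(eset: ExpressionSet) -> ExpressionSet:
    """Drop dim features (mean below the midpoint of the range of means) and
    features lacking gene annotation."""
    if len(eset.feature_ids) < 2:
        raise ValueError("need >= 2 features to define an intensity range")
    means = eset.values.mean(axis=1)
    cutoff = (means.min() + means.max()) / 2.0
    keep = (means >= cutoff) & (eset.genes != "")
    dropped = int((~keep).sum())
    if dropped:
        log.info("intensity/annotation filter dropped %d of %d features", dropped, len(keep))
    return ExpressionSet(
        eset.values.loc[keep],
        eset.genes.loc[keep],
        eset.phenotype,
        eset.annotation_source,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def squeeze_var(s_sq: np.ndarray, df: float) -> tuple[ModeratedTParams, np.ndarray]:
    """Estimate (d0, s0^2) and return the posterior (squeezed) variances.

    Falls back to full pooling (d0 = inf, all posterior variances equal the
    geometric-mean-based s0^2) when the observed log-variance spread is no
    larger than expected under a common variance, or when too few finite
    variances are available for the moment estimator.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    if ok.sum() < 2:
        log.warning("too few features for hyperparameter estimation; full pooling")
        s0 = float(np.nanmean(s_sq[ok])) if ok.any() else 1.0
        return ModeratedTParams(np.inf, s0), np.full_like(s_sq, s0)
    x = s_sq[ok]
    x = np.maximum(x, 1e-5 * np.median(x))  # offset exact zeros
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.mean(x))
    params = ModeratedTParams(d0, s0_sq)
    if np.isinf(d0):
        post = np.full_like(s_sq, s0_sq)
    else:
        post = (d0 * s0_sq + df * s_sq) / (d0 + df)
    return params, post


def classify_activity(sledai, cutoff: float = ACTIVE_SLEDAI, strict: bool = False):
    """Map SLEDAI scores to 'active'/'inactive'; missing values stay NaN.

    Active disease is SLEDAI >= 6 by default (``strict=True`` uses > 6).
    Negative scores are invalid.
    """
    s = pd.Series(sledai, dtype=float)
    if (s.dropna() < 0).any():
        raise ValueError("SLEDAI scores cannot be negative")
    out = pd.Series(np.nan, index=s.index, dtype=object)
    active = s > cutoff if strict else s >= cutoff
    out[active.fillna(False)] = "active"
    out[(~active & s.notna()).fillna(False)] = "inactive"
    n_missing = int(s.isna().sum())
    if n_missing:
        log.info("%d samples without SLEDAI excluded from stratified runs", n_missing)
    return out


def moderated_t_de(
    eset: ExpressionSet,
    condition: str = "all",
    case_group: str = "SLE",
    control_group: str = "control",
    activity_cutoff: float = ACTIVE_SLEDAI,
    strict_activity: bool = False,
) -> pd.DataFrame:
    """Per-feature moderated-t differential expression, cases minus controls.

    ``condition`` selects the case stratum: ``"all"``, ``"active"`` or
    ``"inactive"`` (by SLEDAI); controls are always the full control group.
    Returns a record table with ``logfc, t, p, q`` and the fitted prior in
    ``.attrs["params"]``.
    """
    ph = eset.phenotype.loc[eset.values.columns]
    cases = ph.index[ph["group"] == case_group]
    controls = ph.index[ph["group"] == control_group]
    if condition != "all":
        if "sledai" not in ph.columns:
            raise ValueError("activity stratification needs a 'sledai' column")
        activity = classify_activity(ph.loc[cases, "sledai"], activity_cutoff, strict_activity)
        cases = cases[(activity == condition).to_numpy()]
    n1, n2 = len(cases), len(controls)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"need >= 3 samples per group (got {n1} cases / {n2} controls)")
    df_resid = n1 + n2 - 2
    X1 = eset.values[cases].to_numpy(dtype=float)
    X2 = eset.values[controls].to_numpy(dtype=float)
    logfc = X1.mean(axis=1) - X2.mean(axis=1)
    ss = X1.var(axis=1, ddof=1) * (n1 - 1) + X2.var(axis=1, ddof=1) * (n2 - 1)
    s_sq = ss / df_resid
    params, s_post = squeeze_var(s_sq, df_resid)
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    # prior + residual df, capped at the pooled residual df across features
    # (full pooling cannot be more informative than the data that fed it)
    df_total = min(params.d0 + df_resid, len(logfc) * df_resid)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "gene": eset.genes.to_numpy(),
            "logfc": logfc,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "condition": condition,
            "annotation_source": eset.annotation_source,
        },
        index=eset.feature_ids,
    )
    out.index.name = "feature_id"
    out.attrs["params"] = params
    return out


def merge_annotations(
    native: pd.DataFrame,
    custom: pd.DataFrame | None = None,
    q_max: float = 0.2,
) -> pd.DataFrame:
    """Merge native/custom annotation runs into one record per gene.

    Keeps records with ``q < q_max`` (strict), then per gene the record with
    the smallest p; ties break toward larger |logFC|, then lexicographic
    feature id. Idempotent on its own output.
    """
    frames = [native] if custom is None else [native, custom]
    merged = pd.concat(frames, axis=0)
    merged = merged[(merged["q"] < q_max) & (merged["gene"] != "")]
    if merged.empty:
        return merged
    merged = merged.reset_index()
    merged["_abs_lfc"] = merged["logfc"].abs()
    merged = merged.sort_values(
        ["p", "_abs_lfc", "feature_id"], ascending=[True, False, True], kind="mergesort"
    )
    best = merged.groupby("gene", sort=True).head(1).drop(columns="_abs_lfc")
    return best.set_index("feature_id")
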