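"""Core in-memory containers shared across the pipeline.

The analysis revolves around two array types: a probes x samples matrix of
methylation beta-values (beta = M / (M + U), bounded in [0, 1]) with a
twin-pair map, and a features x samples matrix of log2 expression intensities
with case/control phenotype. Both are thin, validated wrappers around pandas
DataFrames so that downstream statistics stay vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "ExpressionSet", "DMConfig", "SimConfig", "GroundTruth"]


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta-values with a discordant-pair map.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids, entries in
        [0, 1].
    pairs
        Mapping ``pair_id -> (affected_sample, unaffected_sample)``. Every
        named sample must be a column of ``values``.
    detection_p
        Optional matrix of detection p-values, same shape/labels as
        ``values``.
    """

    values: pd.DataFrame
    pairs: Mapping[str, tuple[str, str]]
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta-values must lie in [0, 1]")
        cols = set(self.values.columns)
        for pair_id, members in self.pairs.items():
            if len(members) != 2:
                raise ValueError(
                    f"pair {pair_id!r} must have exactly one affected and one "
                    f"unaffected sample"
                )
            missing = [s for s in members if s not in cols]
            if missing:
                raise KeyError(f"pair {pair_id!r}: samples {missing} not in matrix")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection-p matrix shape differs from beta matrix")
            dp = self.detection_p.to_numpy(dtype=float)
            if dp.size and (np.nanmin(dp) < 0 or np.nanmax(dp) > 1):
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def subset_probes(self, probes) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probes]
        return BetaMatrix(self.values.loc[probes], dict(self.pairs), dp)


@dataclass
class ExpressionSet:
    """Log2 expression matrix plus per-sample phenotype.

    ``phenotype`` is indexed by sample id and carries at least a ``group``
    column with values ``"SLE"``/``"control"``; ``sledai`` (numeric, NaN for
    unknown) and ``cell_type`` are optional. ``genes`` maps feature id to a
    gene symbol; an empty string marks a feature without annotation.
    """

    values: pd.DataFrame
    genes: pd.Series
    phenotype: pd.DataFrame
    annotation_source: str = "native"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if "group" not in self.phenotype.columns:
            raise ValueError("phenotype must carry a 'group' column")
        missing = self.values.columns.difference(self.phenotype.index)
        if len(missing):
            raise KeyError(f"samples without phenotype: {list(missing)[:5]}")
        if self.phenotype.loc[self.values.columns, "group"].isna().any():
            raise ValueError("every sample needs a group label")
        self.genes = self.genes.reindex(self.values.index).fillna("")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def samples_in_group(self, group: str) -> list[str]:
        ph = self.phenotype.loc[self.values.columns]
        return list(ph.index[ph["group"] == group])


@dataclass(frozen=True)
class DMConfig:
    """Thresholds for calling differential methylation.

    ``detection_p_max`` is the probe-level QC threshold (a probe failing it in
    any sample is dropped); ``q_max`` and ``abs_delta_min`` are the FDR and
    effect-size thresholds for the DM call. ``raw_p_equiv`` is the raw-p
    equivalent of the FDR cut on the discovery array, kept for reporting only.
    """

    detection_p_max: float = 1.0e-5
    q_max: float = 0.05
    abs_delta_min: float = 0.085
    raw_p_equiv: float = 1.06e-7

    def __post_init__(self) -> None:
        for name in ("detection_p_max", "q_max", "abs_delta_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generators.

    The defaults emulate the study design the pipeline targets: three
    discordant twin pairs on a 450k-style array with a planted hypomethylation
    signature (mean per-pair delta-beta of -0.2 at signal probes) driven by a
    shared per-sample interferon-activity factor, and 20 SLE / 20 control
    expression samples with signal genes upregulated by 2 log2 units. Noise
    defaults represent technical-scale within-pair variation (beta-scale sd a
    few parts in a thousand): a paired design with two residual degrees of
    freedom can only reach array-wide significance when within-pair variances
    are of that order, which is what the genome-wide-significant discovery
    data themselves imply.
    """

    n_probes: int = 2000
    n_pairs: int = 3
    n_signal_probes: int = 50
    effect_delta: float = -0.2
    latent_ifn_sd: float = 0.01
    beta_noise_sd: float = 0.008
    n_cases: int = 20
    n_controls: int = 20
    planted_logfc: float = 2.0
    expr_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_pairs", "n_signal_probes", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 (paired variance undefined)")
        if self.n_signal_probes > self.n_probes:
            raise ValueError("n_signal_probes cannot exceed n_probes")
        for name in ("effect_delta", "latent_ifn_sd", "beta_noise_sd", "planted_logfc", "expr_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    signal_probes: list[str] = field(default_factory=list)
    signal_genes: list[str] = field(default_factory=list)
    islands: list = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)
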