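"""Readers and writers for the plain-text formats the pipeline consumes.

Matrices travel as TSV with features in rows and a header row of sample ids;
phenotype tables as TSV with one row per sample; probe manifests as CSV;
islands as BED (0-based half-open on disk, 1-based inclusive in memory);
networks as three-column TSV edge lists. A minimal GEO series-matrix parser
(``!``-prefixed metadata lines around a tab-separated matrix block) covers
series-matrix downloads.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ExpressionSet

log = logging.getLogger(__name__)

NS_TOKENS = ("NS", "ns", "NA", "")


# ---------------------------------------------------------------------------
# matrices and phenotype
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Features x samples numeric matrix; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_phenotype(path) -> pd.DataFrame:
    """Sample phenotype TSV indexed by ``sample_id``."""
    ph = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in ph.columns:
        raise ValueError("phenotype table needs a 'sample_id' column")
    ph = ph.set_index("sample_id")
    if "affected" in ph.columns:
        ph["affected"] = ph["affected"].astype(bool)
    return ph


def pairs_from_phenotype(pheno: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Build the pair map {pair_id -> (affected, unaffected)} from phenotype."""
    if "pair_id" not in pheno.columns or "affected" not in pheno.columns:
        raise ValueError("phenotype needs 'pair_id' and 'affected' columns")
    pairs: dict[str, tuple[str, str]] = {}
    for pair_id, grp in pheno.dropna(subset=["pair_id"]).groupby("pair_id"):
        aff = grp.index[grp["affected"]]
        unaff = grp.index[~grp["affected"]]
        if len(aff) != 1 or len(unaff) != 1:
            raise ValueError(
                f"pair {pair_id!r} must have exactly one affected and one "
                f"unaffected sample (got {len(aff)}/{len(unaff)})"
            )
        pairs[str(pair_id)] = (aff[0], unaff[0])
    return pairs


def load_beta(beta_path, pheno_path, detection_path=None) -> BetaMatrix:
    values = read_matrix_tsv(beta_path)
    pheno = read_phenotype(pheno_path)
    pairs = pairs_from_phenotype(pheno.loc[pheno.index.intersection(values.columns)])
    det = read_matrix_tsv(detection_path) if detection_path else None
    return BetaMatrix(values, pairs, det)


def load_expression(expr_path, pheno_path, annotation_source: str = "native") -> ExpressionSet:
    pheno = read_phenotype(pheno_path)
    # gene symbols may be carried as a 'gene' column of the matrix file
    raw = pd.read_csv(expr_path, sep="\t", index_col=0)
    if "gene" in raw.columns:
        genes = raw.pop("gene").astype(str)
        values = raw.astype(float)
    else:
        genes = pd.Series("", index=values.index)
    return ExpressionSet(values, genes, pheno, annotation_source)


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Probe manifest CSV: probe_id, chrom, pos, gene, irg, relation."""
    man = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    if "probe_id" not in man.columns:
        raise ValueError("manifest needs a 'probe_id' column")
    man = man.set_index("probe_id")
    if "irg" in man.columns:
        man["irg"] = man["irg"].fillna(False).astype(bool)
    for col in ("gene", "relation"):
        if col in man.columns:
            man[col] = man[col].fillna("")
    return man


def write_manifest(man: pd.DataFrame, path) -> None:
    man.to_csv(path, index_label="probe_id")


# ---------------------------------------------------------------------------
# GEO series-matrix
# ---------------------------------------------------------------------------

def read_series_matrix(path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Parse a GEO series-matrix file.

    Returns the numeric matrix block (features x samples) and a dict of the
    ``!``-prefixed metadata lines (key without the bang, list of tab-separated
    values with surrounding quotes stripped).
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if line.startswith("!"):
                key, *vals = line[1:].split("\t")
                meta.setdefault(key, []).extend(v.strip('"') for v in vals)
                continue
            if in_table:
                table_lines.append(line)
    if not table_lines:
        raise ValueError(f"{path}: no series-matrix table block found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = [str(i).strip('"') for i in df.index]
    return df.astype(float), meta


# ---------------------------------------------------------------------------
# islands (BED) and networks
# ---------------------------------------------------------------------------

def write_islands_bed(islands, path) -> None:
    """Write islands as BED; in-memory coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\tCpG_island\n")


def read_islands_bed(path):
    from .context import IslandInterval

    islands = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, *_ = line.split("\t")
            islands.append(
                IslandInterval(chrom=chrom, start=int(start) + 1, end=int(end))
            )
    return islands


def read_network_tsv(path) -> pd.DataFrame:
    """Edge list TSV (node_a, node_b, score); 0-1000 scores are normalized."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    df = df.rename(columns=dict(zip(cols, ["node_a", "node_b", "score"])))
    df["score"] = df["score"].astype(float)
    if len(df) and df["score"].max() > 1.0:
        df["score"] = df["score"] / 1000.0
    bad = df[(df["score"] < 0) | (df["score"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: {len(bad)} edges with scores outside [0, 1]")
    return df


def write_network_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path) -> None:
    payload = {
        "signal_probes": list(truth.signal_probes),
        "signal_genes": list(truth.signal_genes),
        "islands": [
            {"chrom": i.chrom, "start": i.start, "end": i.end} for i in truth.islands
        ],
        "clusters": [list(c) for c in truth.clusters],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_lfc_table(path) -> pd.DataFrame:
    """Gene/probe table with logFC columns; NS tokens become NaN."""
    return pd.read_csv(path, sep="\t", na_values=list(NS_TOKENS), keep_default_na=True)
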