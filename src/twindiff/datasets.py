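"""Packaged reference tables.

Three published result tables ship with the package as TSV fixtures: the 59
genome-wide-significant differentially methylated twin CpGs, the whole-blood
DM-DE gene table (two expression cohorts, active/inactive disease), and the
lupus-nephritis kidney DM-DE table (glomerulus / tubulointerstitium), plus the
gene-drug interaction table. Non-significant expression entries are preserved
as ``NS`` tokens on disk and load as NaN.

``load_string_edges`` returns a *synthetic* protein-association edge list
constructed to mirror the described two-cluster topology of the DM-DE network
(an interferon-inducible clique and a nucleic-acid-sensing clique centred on
DDX58); it is a stand-in for a STRING export and carries no real interaction
evidence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import NS_TOKENS, read_network_tsv

#: AUC-maximizing delta-beta thresholds per expression cell type, as published.
PUBLISHED_DELTA_THRESHOLDS: dict[str, float] = {
    "whole_blood": -0.085,
    "monocytes": -0.055,
    "b_cells": -0.08,
    "t_cells": -0.055,
}

#: Fraction of 450k array CpGs located in islands (array background).
ARRAY_ISLAND_FRACTION = 1.0 / 3.0


def _path(name: str):
    return resources.files("twindiff.data").joinpath(name)


def load_twin_dm_sites() -> pd.DataFrame:
    """The 59 differentially methylated CpGs with per-pair delta-beta."""
    with resources.as_file(_path("twin_dm_sites.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["irg"] = df["irg"].eq("IRG")
    for col in ("gene", "relation"):
        df[col] = df[col].fillna("")
    return df


def load_wholeblood_dmde() -> pd.DataFrame:
    """Whole-blood DM-DE genes with logFC in two cohorts x activity strata."""
    with resources.as_file(_path("wholeblood_dmde.tsv")) as p:
        df = pd.read_csv(p, sep="\t", na_values=list(NS_TOKENS), keep_default_na=True)
    df["irg"] = df["irg"].eq("IRG")
    df["gene"] = df["gene"].fillna("")
    return df


def load_kidney_dmde() -> pd.DataFrame:
    """Kidney DM-DE genes with glomerulus/tubulointerstitium logFC."""
    with resources.as_file(_path("kidney_dmde.tsv")) as p:
        df = pd.read_csv(p, sep="\t", na_values=list(NS_TOKENS), keep_default_na=True)
    df["irg"] = df["irg"].eq("IRG")
    df["gene"] = df["gene"].fillna("")
    return df


def load_gene_drug_table() -> pd.DataFrame:
    """Raw gene-drug table; drug cells carry ``Name^<colts> <flags>^`` tokens."""
    with resources.as_file(_path("gene_drug_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    return df


def load_string_edges() -> pd.DataFrame:
    """Synthetic stand-in for a STRING edge export over the DM-DE genes."""
    with resources.as_file(_path("string_edges_synthetic.tsv")) as p:
        return read_network_tsv(p)
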