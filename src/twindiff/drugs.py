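"""Gene-drug interaction annotation of DM-DE genes.

The drug table carries one row per gene with per-source cells (STITCH, IPA,
DGIdb) listing drug tokens of the form ``Name^<colts> <flags>^``: an integer
superscript is a CoLTS repositioning score (valid range -16 to +11), letter
superscripts are status flags (F = FDA-approved, D = ongoing trial/DiD,
G = generally regarded as safe, T = known utility in lupus therapy,
FW = approved then withdrawn). Drug names are canonicalized (trimmed,
case-folded for identity; slash variants such as "Rapamycin/Sirolimus" are a
single entity) so the same compound reached through several genes or sources
counts once in summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DrugRecord", "parse_drug_cell", "tidy_drug_table", "annotate_drugs", "rank_by_colts"]

COLTS_MIN, COLTS_MAX = -16, 11
VALID_FLAGS = {"F", "D", "G", "T", "FW"}

_TOKEN = re.compile(r"^(?P<name>[^^]+?)\s*(?:\^(?P<sup>[^^]*)\^)?\s*$")


@dataclass
class DrugRecord:
    gene: str
    drug: str
    sources: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)
    colts: int | None = None

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("drug name cannot be empty")
        if self.colts is not None and not COLTS_MIN <= self.colts <= COLTS_MAX:
            raise ValueError(f"CoLTS score {self.colts} outside [{COLTS_MIN}, {COLTS_MAX}]")

    @property
    def canonical(self) -> str:
        return canonical_name(self.drug)


def canonical_name(drug: str) -> str:
    return " ".join(drug.split()).casefold()


def parse_drug_cell(cell: str) -> list[tuple[str, int | None, set[str]]]:
    """Split a source cell into (name, colts, flags) triples.

    ``"Carfilzomib^4 F^, Oprozomib^D^"`` yields two entries; a bare name has
    no score and no flags.
    """
    out = []
    for raw in str(cell).split(","):
        raw = raw.strip()
        if not raw:
            continue
        m = _TOKEN.match(raw)
        if m is None:
            raise ValueError(f"malformed drug token: {raw!r}")
        name = m.group("name").strip()
        colts: int | None = None
        flags: set[str] = set()
        sup = m.group("sup")
        if sup:
            for tok in sup.split():
                if re.fullmatch(r"[+-]?\d+", tok):
                    colts = int(tok)
                elif tok in VALID_FLAGS:
                    flags.add(tok)
                else:
                    raise ValueError(f"unknown superscript token {tok!r} in {raw!r}")
        out.append((name, colts, flags))
    return out


def tidy_drug_table(table: pd.DataFrame, source_cols=("stitch", "ipa", "dgidb")) -> pd.DataFrame:
    """Long-format (gene, drug, source, flags, colts) from the per-source table."""
    rows = []
    for _, row in table.iterrows():
        gene = str(row["gene"]).upper()
        for src in source_cols:
            cell = row.get(src, "")
            if not str(cell).strip():
                continue
            for name, colts, flags in parse_drug_cell(cell):
                rows.append(
                    {
                        "gene": gene,
                        "drug": name,
                        "source": src.upper() if src != "dgidb" else "DGIdb",
                        "flags": " ".join(sorted(flags)),
                        "colts": colts,
                    }
                )
    return pd.DataFrame(rows)


def annotate_drugs(dmde_genes, drug_table: pd.DataFrame) -> tuple[list[DrugRecord], dict]:
    """Join DM-DE genes to the tidy drug table and summarize.

    Returns one record per (gene, drug) with sources/flags/score pooled
    across sources, plus a summary with the unique-drug count (canonical
    names) and per-flag unique-drug counts.
    """
    if drug_table.empty:
        raise ValueError("empty drug table")
    genes = {str(g).upper() for g in dmde_genes}
    sub = drug_table[drug_table["gene"].str.upper().isin(genes)]
    merged: dict[tuple[str, str], DrugRecord] = {}
    for row in sub.itertuples(index=False):
        key = (row.gene, canonical_name(row.drug))
        flags = set(str(row.flags).split()) if row.flags else set()
        colts = None if pd.isna(row.colts) else int(row.colts)
        if key in merged:
            rec = merged[key]
            rec.sources.add(row.source)
            rec.flags |= flags
            if rec.colts is None:
                rec.colts = colts
        else:
            merged[key] = DrugRecord(row.gene, row.drug, {row.source}, flags, colts)
    records = sorted(merged.values(), key=lambda r: (r.gene, r.canonical))
    by_drug: dict[str, set[str]] = {}
    for rec in records:
        by_drug.setdefault(rec.canonical, set()).update(rec.flags)
    summary = {
        "n_records": len(records),
        "n_genes": len({r.gene for r in records}),
        "n_unique_drugs": len(by_drug),
        "flag_counts": {
            flag: sum(1 for fl in by_drug.values() if flag in fl) for flag in sorted(VALID_FLAGS)
        },
        "lupus_therapy_drugs": sorted(d for d, fl in by_drug.items() if "T" in fl),
    }
    return records, summary


def rank_by_colts(records: list[DrugRecord]) -> list[DrugRecord]:
    """Descending CoLTS order; unscored records last, ties alphabetical."""
    for rec in records:
        if rec.colts is not None and not COLTS_MIN <= rec.colts <= COLTS_MAX:
            raise ValueError(f"CoLTS score {rec.colts} outside [{COLTS_MIN}, {COLTS_MAX}]")
    return sorted(
        records,
        key=lambda r: (r.colts is None, -(r.colts if r.colts is not None else 0), r.canonical),
    )
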