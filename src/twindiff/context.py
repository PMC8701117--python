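"""CpG island detection and island/shore/shelf context classification.

A CpG island is a run of sequence longer than 200 bp with GC content above
55% and an observed-to-expected CpG ratio above 0.6, where
``O/E = (#CpG * L) / (#C * #G)`` (the expectation under independence of the
Cs and Gs). The flanking 0-2 kb on either side is the shore, 2-4 kb the
shelf; "N" (north) is the lower-coordinate side, "S" the higher, irrespective
of strand, matching the 450k manifest convention. Everything further away is
open sea.

The detector follows a Takai-Jones-style scheme: slide a 200-bp window,
flag windows meeting the GC and O/E criteria, merge overlapping/adjacent
flagged windows, then trim each merged region base by base until its full
extent satisfies all criteria. Regions that cannot be trimmed to a
qualifying extent longer than 200 bp are dropped, so every reported island
re-measures as a valid island.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IslandInterval",
    "detect_islands",
    "classify_context",
    "classify_probes",
    "context_enrichment",
    "island_criteria_met",
]

CONTEXT_LABELS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

SHORE_MAX = 2000
SHELF_MAX = 4000


@dataclass(frozen=True)
class IslandInterval:
    """1-based inclusive island interval with its summary statistics."""

    chrom: str
    start: int
    end: int
    gc: float = float("nan")
    obs_exp: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _prefix_counts(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (s == ord("C")).astype(np.int64)
    is_g = (s == ord("G")).astype(np.int64)
    is_cpg = np.zeros(len(s), dtype=np.int64)
    if len(s) > 1:
        is_cpg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(is_cpg)]),
    )


def _stats(cC, cG, cCpG, i: int, j: int) -> tuple[float, float]:
    """GC fraction and O/E CpG ratio of the 0-based half-open slice [i, j)."""
    L = j - i
    nc = cC[j] - cC[i]
    ng = cG[j] - cG[i]
    # CpG dinucleotides fully inside the slice
    ncpg = cCpG[j - 1] - cCpG[i] if j - 1 > i else 0
    gc = (nc + ng) / L
    oe = (ncpg * L) / (nc * ng) if nc and ng else 0.0
    return gc, oe


def island_criteria_met(
    seq: str, start: int, end: int, min_len: int = 200, gc_min: float = 0.55, oe_min: float = 0.6
) -> bool:
    """Check the three criteria on a 1-based inclusive interval of ``seq``."""
    cC, cG, cCpG = _prefix_counts(seq)
    L = end - start + 1
    if L <= min_len:
        return False
    gc, oe = _stats(cC, cG, cCpG, start - 1, end)
    return gc > gc_min and oe > oe_min


def detect_islands(
    seq: str,
    chrom: str = "chr",
    min_len: int = 200,
    gc_min: float = 0.55,
    oe_min: float = 0.6,
    step: int = 1,
) -> list[IslandInterval]:
    """Find CpG islands in an uppercase ACGT(N) sequence.

    ``step`` > 1 trades resolution for speed by striding the window scan.
    Returned intervals are 1-based inclusive, sorted, non-overlapping, and
    each satisfies all three criteria on its full extent.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        return []
    cC, cG, cCpG = _prefix_counts(seq)

    def qualifies(i: int, j: int) -> bool:  # 0-based half-open
        gc, oe = _stats(cC, cG, cCpG, i, j)
        return gc > gc_min and oe > oe_min

    starts = [i for i in range(0, n - min_len + 1, step) if qualifies(i, i + min_len)]
    if not starts:
        return []
    # merge overlapping/adjacent flagged windows
    merged: list[list[int]] = []
    for i in starts:
        j = i + min_len
        if merged and i <= merged[-1][1]:
            merged[-1][1] = j
        else:
            merged.append([i, j])

    islands: list[IslandInterval] = []
    for i, j in merged:
        i, j = _shrink_to_qualify(cC, cG, cCpG, seq, i, j, min_len, qualifies)
        if j - i > min_len and qualifies(i, j):
            gc, oe = _stats(cC, cG, cCpG, i, j)
            islands.append(IslandInterval(chrom, i + 1, j, gc, oe))
    return islands


def _shrink_to_qualify(cC, cG, cCpG, seq, i, j, min_len, qualifies):
    """Trim [i, j) one base at a time until the whole extent qualifies.

    Each step removes the terminal base whose removal leaves the better
    (GC + O/E) score; ties trim from the right. Stops at the window size.
    """
    while j - i > min_len and not qualifies(i, j):
        gl, ol = _stats(cC, cG, cCpG, i + 1, j)
        gr, or_ = _stats(cC, cG, cCpG, i, j - 1)
        if gl + ol > gr + or_:
            i += 1
        else:
            j -= 1
    return i, j


def classify_context(pos: int, islands: list[IslandInterval]) -> str:
    """Label a 1-based position relative to a sorted island list.

    Inside an island -> ``Island``; within (0, 2 kb] of the nearest boundary
    -> shore; (2 kb, 4 kb] -> shelf; otherwise ``OpenSea``. N denotes the
    lower-coordinate side of the island. Equidistant ties go to the
    lower-coordinate island.
    """
    best = None  # (distance, island_start, side)
    for isl in islands:
        if isl.start <= pos <= isl.end:
            return "Island"
        if pos < isl.start:
            cand = (isl.start - pos, isl.start, "N")
        else:
            cand = (pos - isl.end, isl.start, "S")
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        return "OpenSea"
    d, _, side = best
    if d <= SHORE_MAX:
        return f"{side}_Shore"
    if d <= SHELF_MAX:
        return f"{side}_Shelf"
    return "OpenSea"


def classify_probes(manifest, islands_by_chrom: dict[str, list[IslandInterval]]):
    """Add/overwrite a ``relation`` column on a probe manifest."""
    labels = []
    for _, row in manifest.iterrows():
        islands = islands_by_chrom.get(str(row["chrom"]), [])
        labels.append(classify_context(int(row["pos"]), islands))
    out = manifest.copy()
    out["relation"] = labels
    return out


def context_enrichment(
    labels,
    background_island_fraction: float,
) -> dict:
    """Count context labels in a DM set and test island depletion/enrichment.

    Runs an exact two-sided binomial test of the island count against the
    array-background island fraction.
    """
    import pandas as pd

    lab = pd.Series(list(labels))
    if lab.empty:
        raise ValueError("empty DM set")
    counts = {name: int((lab == name).sum()) for name in CONTEXT_LABELS}
    counts["Unannotated"] = int((~lab.isin(CONTEXT_LABELS)).sum())
    n = int(len(lab))
    n_island = counts["Island"]
    test = stats.binomtest(n_island, n, background_island_fraction, alternative="two-sided")
    shore_shelf = sum(counts[k] for k in ("N_Shore", "S_Shore", "N_Shelf", "S_Shelf"))
    return {
        "counts": counts,
        "n": n,
        "island_fraction": n_island / n,
        "shore_shelf_count": shore_shelf,
        "shore_shelf_fraction": shore_shelf / n,
        "island_binom_p": test.pvalue,
    }
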