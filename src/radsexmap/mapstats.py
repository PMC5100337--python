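"""Chromosome-level inference: enrichment tests, Manhattan export and
SD-region localization.

Enrichment asks, per chromosome, whether loci of a target coverage class
are over-represented among the placed loci: a two-sided Fisher exact test
on [[k, K-k], [n-k, (N-K)-(n-k)]] where k of the chromosome's n placed
loci carry the class and K of all N placed loci do.  Unplaced loci are
excluded from every cell.  The SD region is localized by sliding-window
density of significantly sex-associated SNPs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import fisher_exact_two_sided
from .errors import DataError

logger = logging.getLogger(__name__)

MANHATTAN_CUTOFFS = (0.001, 0.01)  # solid / dashed reference lines
REGION_ALPHA_DEFAULT = 0.001
WINDOW_MB_DEFAULT = 2.0
MIN_HITS_DEFAULT = 3


@dataclass
class SdRegionCall:
    """A called sex-determination region."""

    chrom: str
    start: int
    end: int
    n_hits: int
    density: float  # significant SNPs per Mb
    alpha: float

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def _natural_key(label: str) -> tuple:
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", str(label)))


def chrom_enrichment(
    class_table: pd.DataFrame, target_class: str, placement: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-chromosome over-representation of a coverage class.

    ``class_table`` must carry ``locus_id`` and ``cov_class`` plus a
    ``chrom`` column (or pass ``placement`` to join one).  Returns one row
    per chromosome with ``k, K, n, N, odds_ratio, p_two_sided``, sorted by
    ascending p (ties by chromosome label).
    """
    tbl = class_table
    if "chrom" not in tbl.columns:
        if placement is None:
            raise DataError("class table has no 'chrom' column and no placement given")
        tbl = tbl.merge(placement[["locus_id", "chrom"]], on="locus_id", how="left")
    placed = tbl[tbl["chrom"].notna()]
    if len(placed) == 0:
        raise DataError("no placed loci for enrichment")
    N = len(placed)
    is_class = placed["cov_class"] == target_class
    K = int(is_class.sum())
    if K == 0:
        logger.info("target class %s absent from placed loci", target_class)
    rows = []
    for chrom, grp in placed.groupby("chrom", sort=False):
        n = len(grp)
        k = int((grp["cov_class"] == target_class).sum())
        table = np.array([[k, K - k], [n - k, (N - K) - (n - k)]])
        p = fisher_exact_two_sided(table) if K > 0 else 1.0
        num = k * ((N - K) - (n - k))
        den = (K - k) * (n - k)
        odds = np.inf if den == 0 and num > 0 else (np.nan if den == 0 else num / den)
        rows.append((chrom, k, K, n, N, odds, p))
    out = pd.DataFrame(
        rows, columns=["chrom", "k", "K", "n", "N", "odds_ratio", "p_two_sided"]
    )
    out["_key"] = out["chrom"].map(_natural_key)
    out = (
        out.sort_values(by=["p_two_sided", "_key"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return out


def manhattan_table(
    records: pd.DataFrame,
    cutoffs: tuple = MANHATTAN_CUTOFFS,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Chromosome-ordered table for a Manhattan plot of -log10 p.

    ``records`` needs ``site_id, chrom, pos, fisher_p``.  Chromosomes are
    natural-sorted and laid out with cumulative offsets (chromosome
    lengths if given, else the max position seen + 1); unplaced records
    form a trailing ``UNK`` block.  Each cutoff c adds a boolean column
    ``above_<c>`` flagging p <= c.
    """
    rec = records[records["fisher_p"].notna()].copy()
    rec["chrom"] = rec["chrom"].fillna("UNK")
    chroms = sorted([c for c in rec["chrom"].unique() if c != "UNK"], key=_natural_key)
    if "UNK" in set(rec["chrom"]):
        chroms.append("UNK")
    offsets, cum = {}, 0
    for c in chroms:
        offsets[c] = cum
        if chrom_lengths and c in chrom_lengths:
            extent = chrom_lengths[c]
        else:
            extent = int(rec.loc[rec["chrom"] == c, "pos"].max()) + 1
        cum += extent
    rec["cum_pos"] = rec["pos"] + rec["chrom"].map(offsets)
    with np.errstate(divide="ignore"):
        rec["neglog10_p"] = -np.log10(rec["fisher_p"])
    for c in cutoffs:
        rec[f"above_{c:g}"] = rec["fisher_p"] <= c
    rec["_key"] = rec["chrom"].map(
        lambda x: _natural_key(x) if x != "UNK" else (chr(0x10FFFF),)
    )
    rec = (
        rec.sort_values(by=["_key", "pos"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    cols = ["site_id", "chrom", "pos", "cum_pos", "fisher_p", "neglog10_p"]
    cols += [f"above_{c:g}" for c in cutoffs]
    return rec[cols]


def call_sd_region(
    records: pd.DataFrame,
    alpha: float = REGION_ALPHA_DEFAULT,
    window_mb: float = WINDOW_MB_DEFAULT,
    min_hits: int = MIN_HITS_DEFAULT,
    chrom_lengths: dict | None = None,
) -> SdRegionCall | None:
    """Localize the SD region by sliding-window density of significant SNPs.

    Windows of ``window_mb`` Mb slide in steps of a quarter window over
    each chromosome with placed records; windows count SNPs with
    p < ``alpha``.  The densest window seeds the call (ties: first
    chromosome in label order, then lowest start) and the interval extends
    to the union of windows overlapping it whose count stays at or above
    half the seed's.  Returns None when the best window has fewer than
    ``min_hits`` hits.
    """
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0,1), got {alpha}")
    hits = records[
        records["fisher_p"].notna()
        & (records["fisher_p"] < alpha)
        & records["chrom"].notna()
    ]
    if len(hits) == 0:
        return None
    w = int(window_mb * 1e6)
    step = max(1, w // 4)

    best = None  # (count, chrom_key, start, chrom, positions, chrom_end)
    per_chrom = {}
    for chrom, grp in hits.groupby("chrom"):
        pos = np.sort(grp["pos"].values.astype(np.int64))
        if chrom_lengths and chrom in chrom_lengths:
            end = int(chrom_lengths[chrom])
        else:
            end = int(pos.max()) + 1
        starts = np.arange(0, end, step)
        counts = np.searchsorted(pos, starts + w) - np.searchsorted(pos, starts)
        per_chrom[chrom] = (starts, counts, pos, end)
        i = int(np.argmax(counts))  # argmax returns the first (lowest start) max
        cand = (int(counts[i]), _natural_key(chrom), int(starts[i]), chrom)
        if best is None or (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2]):
            best = cand
    seed_count, _, seed_start, chrom = best
    if seed_count < min_hits:
        return None

    starts, counts, pos, chrom_end = per_chrom[chrom]
    qualify = counts >= 0.5 * seed_count
    lo, hi = seed_start, seed_start + w
    changed = True
    while changed:
        changed = False
        for s, q in zip(starts, qualify):
            if q and s < hi and lo < s + w:
                if s < lo or s + w > hi:
                    lo, hi = min(lo, int(s)), max(hi, int(s) + w)
                    changed = True
    lo = max(0, lo)
    hi = min(chrom_end, hi)
    n_in = int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
    density = n_in / ((hi - lo) / 1e6)
    return SdRegionCall(chrom, lo, hi, n_in, density, alpha)
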