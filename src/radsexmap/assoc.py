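"""Per-SNP between-sex differentiation statistics on the offspring.

Males and females are treated as two "populations": at every biallelic SNP
we count non-missing offspring alleles by sex (parents are excluded, so
the segregation signal is not diluted by one extra parent per pool),
compute Wright/Nei F_ST = (H_T - H_S)/H_T, and attach a two-sided Fisher
exact p-value on the 2x2 allele x sex table.  F_ST values are p-gated
(zeroed unless the exact test reaches ``gate_alpha``), and sites are
ranked by ascending p-value — the ranking, not the raw F_ST, drives the
downstream "top-N most significant sites" inspection.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dataio import GenotypeTable
from .errors import DataError

logger = logging.getLogger(__name__)

GATE_ALPHA_DEFAULT = 0.05
TOP_N_DEFAULT = 100

#: absolute tie tolerance when comparing table probabilities in the
#: two-sided exact test
FISHER_TIE_TOL = 1e-12

_REF_ALLELES = np.array([2, 1, 0, 0])  # index by call code (missing -> 0 via mask)
_ALT_ALLELES = np.array([0, 1, 2, 0])


def _allele_counts(calls_row: np.ndarray, idx: np.ndarray) -> tuple:
    sub = calls_row[idx]
    ok = sub >= 0
    sub = sub[ok]
    return int(_REF_ALLELES[sub].sum()), int(_ALT_ALLELES[sub].sum())


def allele_counts_by_sex(gt: GenotypeTable, site_id: str) -> np.ndarray:
    """2x2 allele counts, rows = offspring sex (M, F), cols = (ref, alt).

    Each non-missing diploid call contributes two alleles; parents are
    excluded.
    """
    i = gt.site_index(site_id)
    row = gt.calls[i]
    ref_m, alt_m = _allele_counts(row, gt.son_indices)
    ref_f, alt_f = _allele_counts(row, gt.daughter_indices)
    return np.array([[ref_m, alt_m], [ref_f, alt_f]], dtype=np.int64)


def allele_counts_all(gt: GenotypeTable) -> np.ndarray:
    """Vectorized allele counts for every site: shape (n_sites, 2, 2)."""
    sons = gt.calls[:, gt.son_indices]
    daus = gt.calls[:, gt.daughter_indices]
    out = np.empty((gt.n_sites, 2, 2), dtype=np.int64)
    for sex, sub, r in ((0, sons, 0), (1, daus, 1)):
        ok = sub >= 0
        clipped = np.where(ok, sub, 0)
        out[:, r, 0] = ((2 - clipped) * ok).sum(axis=1)
        out[:, r, 1] = (clipped * ok).sum(axis=1)
    return out


def fst_between_sexes(counts: np.ndarray) -> float:
    """Wright/Nei F_ST = (H_T - H_S)/H_T between the two sexes.

    H_S is the unweighted mean of the within-sex expected
    heterozygosities; H_T uses the unweighted mean allele frequency.
    Returns 0 when H_T = 0 (both sexes fixed for the same allele) and NaN
    when one sex has no non-missing alleles (the record is flagged and
    excluded from ranking upstream).
    """
    (ref_m, alt_m), (ref_f, alt_f) = counts
    n_m, n_f = ref_m + alt_m, ref_f + alt_f
    if n_m == 0 or n_f == 0:
        return float("nan")
    p_m = alt_m / n_m
    p_f = alt_f / n_f
    h_s = (2 * p_m * (1 - p_m) + 2 * p_f * (1 - p_f)) / 2.0
    p_bar = (p_m + p_f) / 2.0
    h_t = 2 * p_bar * (1 - p_bar)
    if h_t == 0:
        return 0.0
    return (h_t - h_s) / h_t


@lru_cache(maxsize=100_000)
def _fisher_cached(ref_m: int, alt_m: int, ref_f: int, alt_f: int) -> float:
    n_m = ref_m + alt_m
    n_f = ref_f + alt_f
    c_ref = ref_m + ref_f
    c_alt = alt_m + alt_f
    total = n_m + n_f
    if min(n_m, n_f, c_ref, c_alt) == 0:
        return 1.0
    # hypergeometric over the (M, ref) cell with fixed margins
    lo = max(0, c_ref - n_f)
    hi = min(c_ref, n_m)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, c_ref, n_m)
    p_obs = pmf[ref_m - lo]
    p = float(pmf[pmf <= p_obs + FISHER_TIE_TOL].sum())
    return min(p, 1.0)


def fisher_exact_two_sided(counts: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of non-negative ints.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability is at most that of the observed
    table (absolute tie tolerance 1e-12).  A table with any zero margin
    carries no information; by convention p = 1.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {counts.shape}")
    if (counts < 0).any():
        raise DataError("negative count in 2x2 table")
    a, b, c, d = (int(x) for x in counts.ravel())
    return _fisher_cached(a, b, c, d)


def gate_fst(fst: float, fisher_p: float, gate_alpha: float = GATE_ALPHA_DEFAULT) -> float:
    """Zero the F_ST unless the exact test reaches ``gate_alpha`` (<=)."""
    return fst if fisher_p <= gate_alpha else 0.0


def top_sites(records: pd.DataFrame, n: int = TOP_N_DEFAULT) -> pd.DataFrame:
    """The ``n`` records with smallest exact-test p-value.

    Ties are broken by larger F_ST, then by site key, so the selection is
    deterministic.  Records whose statistics are undefined (one sex
    entirely missing) are excluded.
    """
    valid = records[records["fisher_p"].notna() & records["fst"].notna()].copy()
    valid = valid.sort_values(
        by=["fisher_p", "fst", "site_id"], ascending=[True, False, True], kind="mergesort"
    )
    return valid.head(n).reset_index(drop=True)


def assoc_scan(gt: GenotypeTable, gate_alpha: float = GATE_ALPHA_DEFAULT) -> pd.DataFrame:
    """Score every site: allele counts, F_ST, exact p, gated F_ST, rank.

    Returns one row per site with columns ``site_id, locus_id, chrom, pos,
    ref_m, alt_m, ref_f, alt_f, fst, fisher_p, fst_gated, rank``.  Rank is
    1-based in ascending p order (ties as in :func:`top_sites`); sites
    with undefined statistics get rank NaN.
    """
    counts = allele_counts_all(gt)
    n = gt.n_sites
    fst = np.empty(n)
    pval = np.empty(n)
    for i in range(n):
        fst[i] = fst_between_sexes(counts[i])
        if np.isnan(fst[i]):
            pval[i] = np.nan
        else:
            pval[i] = fisher_exact_two_sided(counts[i])
    n_flagged = int(np.isnan(fst).sum())
    if n_flagged:
        logger.info("%d sites with one sex entirely missing were flagged", n_flagged)

    rec = gt.sites[["site_id", "locus_id", "chrom", "pos"]].copy()
    rec["ref_m"] = counts[:, 0, 0]
    rec["alt_m"] = counts[:, 0, 1]
    rec["ref_f"] = counts[:, 1, 0]
    rec["alt_f"] = counts[:, 1, 1]
    rec["fst"] = fst
    rec["fisher_p"] = pval
    rec["fst_gated"] = np.where(
        np.isnan(pval), np.nan, np.where(pval <= gate_alpha, fst, 0.0)
    )
    order = top_sites(rec, n=n)
    rank = pd.Series(
        np.arange(1, len(order) + 1, dtype=float), index=order["site_id"]
    )
    rec["rank"] = rec["site_id"].map(rank)
    return rec
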