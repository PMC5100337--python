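"""Coverage analysis: per-sex locus depth means and hemizygosity classes.

In an XX-XY system a Y-limited RAD locus is sequenced only in males
(expected depth about half the diploid mean, near zero in females, up to
spurious reads), while an X-limited locus deleted from the Y has twice
the coverage in females as in males.  The classifier applies the numeric
gates in a fixed order: loci with an overall mean below ``low`` (spurious
reads) or above ``high`` (likely repeat motifs) are filtered before any
class call, so a repeat-like locus can never be called male-only; then
``MALE_ONLY`` requires daughter mean < ``female_max`` and son mean >
``male_min``; ``FEMALE_BIASED`` requires a daughter/son ratio >
``ratio`` with daughter mean > ``female_max``; everything else passes as
autosome-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ROLE_OFFSPRING
from .errors import DataError

logger = logging.getLogger(__name__)

MALE_ONLY = "MALE_ONLY"
FEMALE_BIASED = "FEMALE_BIASED"
PASS = "PASS"
FILTERED_LOW = "FILTERED_LOW"
FILTERED_HIGH = "FILTERED_HIGH"

CLASSES = (MALE_ONLY, FEMALE_BIASED, PASS, FILTERED_LOW, FILTERED_HIGH)


@dataclass(frozen=True)
class DepthGates:
    """Numeric coverage gates; defaults are the study's printed values."""

    low: float = 1.0
    high: float = 500.0
    female_max: float = 2.0
    male_min: float = 5.0
    ratio: float = 1.5
    per_sex_filter: bool = False  # apply low/high to each sex mean instead of pooled


DEFAULT_GATES = DepthGates()


def sex_means(depths: pd.DataFrame, individuals: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean depth per locus over sons and daughters separately.

    Parents are excluded.  NaN entries count as missing; a locus with
    all-missing depths gets means 0 and is flagged.
    """
    off = individuals[individuals["role"] == ROLE_OFFSPRING]
    sons = off.loc[off["sex"] == "M", "id"].tolist()
    daus = off.loc[off["sex"] == "F", "id"].tolist()
    if not sons or not daus:
        raise DataError("need at least one son and one daughter")
    missing_cols = [s for s in sons + daus if s not in depths.columns]
    if missing_cols:
        raise DataError(f"depth matrix lacks offspring columns: {missing_cols}")
    mean_sons = depths[sons].mean(axis=1, skipna=True)
    mean_daus = depths[daus].mean(axis=1, skipna=True)
    all_missing = depths[sons + daus].isna().all(axis=1)
    if all_missing.any():
        logger.warning("%d loci with all-missing depths (means set to 0)", int(all_missing.sum()))
    out = pd.DataFrame(
        {
            "locus_id": depths.index,
            "mean_sons": mean_sons.fillna(0.0).values,
            "mean_daughters": mean_daus.fillna(0.0).values,
            "all_missing": all_missing.values,
        }
    )
    return out


def _ratio_fd(mean_sons: float, mean_daughters: float) -> float:
    if mean_sons > 0:
        return mean_daughters / mean_sons
    return float("inf") if mean_daughters > 0 else float("nan")


def classify_locus(
    mean_sons: float, mean_daughters: float, gates: DepthGates = DEFAULT_GATES
) -> str:
    """Coverage class of one locus from its two sex means.

    The pooled mean used by the low/high filters is the mean of the two
    sex means (the "mean of all means"); set ``gates.per_sex_filter`` to
    gate each sex mean instead.
    """
    if mean_sons < 0 or mean_daughters < 0:
        raise DataError("negative mean depth")
    if gates.per_sex_filter:
        low = min(mean_sons, mean_daughters) < gates.low
        high = max(mean_sons, mean_daughters) > gates.high
    else:
        pooled = (mean_sons + mean_daughters) / 2.0
        low = pooled < gates.low
        high = pooled > gates.high
    if low:
        return FILTERED_LOW
    if high:
        return FILTERED_HIGH
    if mean_daughters < gates.female_max and mean_sons > gates.male_min:
        return MALE_ONLY
    ratio = _ratio_fd(mean_sons, mean_daughters)
    if ratio > gates.ratio and mean_daughters > gates.female_max:
        return FEMALE_BIASED
    return PASS


def classify_table(
    means: pd.DataFrame,
    gates: DepthGates = DEFAULT_GATES,
    placement: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every locus; optionally join chromosome placement.

    Returns columns ``locus_id, mean_sons, mean_daughters, ratio_fd,
    cov_class`` (+ ``chrom, start, end`` if a placement table is given;
    unplaced loci get NaN).
    """
    out = means[["locus_id", "mean_sons", "mean_daughters"]].copy()
    out["ratio_fd"] = [
        _ratio_fd(s, d) for s, d in zip(out["mean_sons"], out["mean_daughters"])
    ]
    out["cov_class"] = [
        classify_locus(s, d, gates) for s, d in zip(out["mean_sons"], out["mean_daughters"])
    ]
    if placement is not None:
        out = out.merge(
            placement[["locus_id", "chrom", "start", "end"]], on="locus_id", how="left"
        )
    counts = out["cov_class"].value_counts().to_dict()
    logger.info("coverage classes: %s", counts)
    return out


def expectation_lines(depths: pd.DataFrame, individuals: pd.DataFrame) -> tuple:
    """Reference slopes for the daughter-vs-son coverage scatter.

    The autosomal slope is the genome-wide daughter mean over the
    genome-wide son mean (absorbing sample-size and library-size
    differences); loci limited to the homogametic chromosome (X under
    XY) should lie at twice that slope and sex-limited-under-female
    (W-type) loci at half of it.  Returns
    ``(autosomal, x_limited, w_limited)``.
    """
    off = individuals[individuals["role"] == ROLE_OFFSPRING]
    sons = off.loc[off["sex"] == "M", "id"].tolist()
    daus = off.loc[off["sex"] == "F", "id"].tolist()
    if not sons or not daus:
        raise DataError("need at least one son and one daughter")
    son_mean = float(np.nanmean(depths[sons].values))
    dau_mean = float(np.nanmean(depths[daus].values))
    if son_mean == 0:
        raise DataError("genome-wide son mean depth is zero")
    a = dau_mean / son_mean
    return (a, 2.0 * a, 0.5 * a)
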