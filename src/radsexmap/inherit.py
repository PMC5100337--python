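"""Family inheritance-pattern classification of candidate SNPs.

A SNP segregating with sex in a single cross leaves a characteristic
zygosity fingerprint: under male heterogamety (XX-XY) the father and his
sons are heterozygous while the mother and daughters are homozygous;
under female heterogamety (ZZ-ZW) the pattern mirrors.  Only the het/hom
structure matters — which homozygous allele the homogametic parent
carries is irrelevant.  Concordance is the fraction of non-missing
offspring matching the expected zygosity; missing calls are dropped from
the denominator, not counted as discordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import GenotypeTable, HET, MISSING

XY_PATTERN = "XY_PATTERN"
ZW_PATTERN = "ZW_PATTERN"
BOTH_PARENTS_HET = "BOTH_PARENTS_HET"
UNINFORMATIVE = "UNINFORMATIVE"

#: default concordance needed to call a pattern; < 1 tolerates occasional
#: sexing errors and recombinants between marker and SD locus
MIN_CONCORDANCE_DEFAULT = 0.9


@dataclass
class InheritanceCall:
    site_id: str
    pattern: str
    concordance: float
    n_informative_offspring: int


def _is_hom(call: int) -> bool:
    return call in (0, 2)


def classify_site(
    gt: GenotypeTable, site_id: str, min_concordance: float = MIN_CONCORDANCE_DEFAULT
) -> InheritanceCall:
    """Classify one site's segregation pattern.

    ``XY_PATTERN``: father het, mother hom, and (sons het, daughters hom)
    in at least ``min_concordance`` of non-missing offspring.
    ``ZW_PATTERN`` mirrors with parents and sexes swapped.  Sites where
    both parents are heterozygous are ``BOTH_PARENTS_HET``; anything else
    (including a missing parental call) is ``UNINFORMATIVE``.
    """
    i = gt.site_index(site_id)
    row = gt.calls[i]
    f = int(row[gt.father_index])
    m = int(row[gt.mother_index])
    if f == MISSING or m == MISSING:
        return InheritanceCall(site_id, UNINFORMATIVE, float("nan"), 0)
    f_het, m_het = f == HET, m == HET
    if f_het and m_het:
        return InheritanceCall(site_id, BOTH_PARENTS_HET, float("nan"), 0)
    if not f_het and not m_het:
        return InheritanceCall(site_id, UNINFORMATIVE, float("nan"), 0)

    sons = row[gt.son_indices]
    daus = row[gt.daughter_indices]
    sons = sons[sons != MISSING]
    daus = daus[daus != MISSING]
    n = len(sons) + len(daus)
    if n == 0:
        return InheritanceCall(site_id, UNINFORMATIVE, float("nan"), 0)

    if f_het:  # candidate XY: sons het, daughters hom
        matches = int((sons == HET).sum()) + int(np.isin(daus, (0, 2)).sum())
        candidate = XY_PATTERN
    else:  # mother het, candidate ZW: daughters het, sons hom
        matches = int((daus == HET).sum()) + int(np.isin(sons, (0, 2)).sum())
        candidate = ZW_PATTERN
    conc = matches / n
    pattern = candidate if conc >= min_concordance else UNINFORMATIVE
    return InheritanceCall(site_id, pattern, conc, n)


def classify_sites(
    gt: GenotypeTable,
    site_ids,
    min_concordance: float = MIN_CONCORDANCE_DEFAULT,
) -> pd.DataFrame:
    """Classify many sites; one row per site."""
    calls = [classify_site(gt, s, min_concordance) for s in site_ids]
    return pd.DataFrame(
        {
            "site_id": [c.site_id for c in calls],
            "pattern": [c.pattern for c in calls],
            "concordance": [c.concordance for c in calls],
            "n_informative_offspring": [c.n_informative_offspring for c in calls],
        }
    )


def summarize_top(calls: pd.DataFrame) -> dict:
    """Aggregate pattern counts over the top-N sites.

    Returns ``{"counts": {pattern: n}, "inferred_system": "XY"|"ZW"|None}``
    where the inference is the majority pattern among the sex-linked ones
    (None on an empty table or an exact tie).
    """
    if calls is None or len(calls) == 0:
        return {"counts": {}, "inferred_system": None}
    counts = calls["pattern"].value_counts().to_dict()
    n_xy = counts.get(XY_PATTERN, 0)
    n_zw = counts.get(ZW_PATTERN, 0)
    if n_xy == n_zw:
        inferred = None
    else:
        inferred = "XY" if n_xy > n_zw else "ZW"
    return {"counts": counts, "inferred_system": inferred}
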