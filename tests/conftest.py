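"""Shared fixtures and independent oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from radsexmap import CrossDesign, GenotypeTable, simulate_cross
from radsexmap.dataio import ROLE_FATHER, ROLE_MOTHER, ROLE_OFFSPRING


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Pure integer/rational arithmetic (math.comb + fractions): sums the
    exact probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Independent of the
    implementation under test.
    """
    (a, b), (c, d) = np.asarray(table)
    a, b, c, d = int(a), int(b), int(c), int(d)
    r0, r1 = a + b, c + d
    c0, c1 = a + c, b + d
    n = r0 + r1
    if 0 in (r0, r1, c0, c1):
        return 1.0
    denom = comb(n, c0)
    num_obs = comb(r0, a) * comb(r1, c0 - a)
    total = 0
    for k in range(max(0, c0 - r1), min(c0, r0) + 1):
        num_k = comb(r0, k) * comb(r1, c0 - k)
        if num_k <= num_obs:
            total += num_k
    return float(Fraction(total, denom))


def make_gt(father, mother, sons, daughters, site_ids=None) -> GenotypeTable:
    """Build a GenotypeTable from per-site call lists.

    ``father``/``mother`` are sequences of calls (one per site); ``sons``/
    ``daughters`` are lists of such sequences (one per individual).
    """
    father = np.atleast_1d(father)
    n_sites = len(father)
    ids = (
        ["father", "mother"]
        + [f"son{i}" for i in range(len(sons))]
        + [f"dau{i}" for i in range(len(daughters))]
    )
    cols = [father, np.atleast_1d(mother)] + [np.atleast_1d(s) for s in sons] + [
        np.atleast_1d(d) for d in daughters
    ]
    calls = np.column_stack(cols).astype(np.int8)
    if site_ids is None:
        site_ids = [f"s{i}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "locus_id": site_ids,
            "chrom": ["LG1"] * n_sites,
            "pos": np.arange(n_sites) * 1000,
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    individuals = pd.DataFrame(
        {
            "id": ids,
            "role": [ROLE_FATHER, ROLE_MOTHER] + [ROLE_OFFSPRING] * (len(sons) + len(daughters)),
            "sex": ["M", "F"] + ["M"] * len(sons) + ["F"] * len(daughters),
        }
    )
    return GenotypeTable(sites=sites, calls=calls, individuals=individuals)


@pytest.fixture(scope="session")
def small_design() -> CrossDesign:
    """A cheap but fully featured XY design for unit tests."""
    return CrossDesign(
        n_chromosomes=4,
        chrom_length_bp=10_000_000,
        loci_per_chromosome=100,
        sd_chromosome=1,
        sd_region=(2_000_000, 7_000_000),
        frac_y_limited=0.1,
        frac_x_limited_diff=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_design):
    return simulate_cross(small_design)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, fully suppressed XY cross (no noise of any kind)."""
    return simulate_cross(
        CrossDesign(
            n_chromosomes=4,
            chrom_length_bp=10_000_000,
            loci_per_chromosome=100,
            sd_chromosome=1,
            sd_region=(2_000_000, 7_000_000),
            genotyping_error=0.0,
            missing_rate=0.0,
            seed=7,
        )
    )
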