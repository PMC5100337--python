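"""Inheritance-pattern classification and its symmetry properties."""

import numpy as np
import pandas as pd
import pytest

from radsexmap import classify_site, classify_sites, summarize_top
from radsexmap.dataio import GenotypeTable
from radsexmap.errors import DataError
from radsexmap.inherit import (
    BOTH_PARENTS_HET,
    UNINFORMATIVE,
    XY_PATTERN,
    ZW_PATTERN,
)
from radsexmap.simcross import SD_LINKED

from conftest import make_gt


class TestClassifySite:
    def test_xy_pattern_perfect(self):
        # father and sons heterozygous, mother and daughters homozygous
        gt = make_gt(father=[1], mother=[0], sons=[[1], [1], [1]], daughters=[[0], [0]])
        call = classify_site(gt, "s0")
        assert call.pattern == XY_PATTERN
        assert call.concordance == 1.0
        assert call.n_informative_offspring == 5

    def test_zw_pattern_mirror(self):
        gt = make_gt(father=[0], mother=[1], sons=[[0], [0]], daughters=[[1], [1], [1]])
        call = classify_site(gt, "s0")
        assert call.pattern == ZW_PATTERN
        assert call.concordance == 1.0

    def test_both_parents_het(self):
        gt = make_gt(father=[1], mother=[1], sons=[[1]], daughters=[[0]])
        assert classify_site(gt, "s0").pattern == BOTH_PARENTS_HET

    def test_both_parents_hom_uninformative(self):
        gt = make_gt(father=[0], mother=[2], sons=[[1]], daughters=[[1]])
        assert classify_site(gt, "s0").pattern == UNINFORMATIVE

    def test_missing_parent_uninformative(self):
        gt = make_gt(father=[-1], mother=[0], sons=[[1]], daughters=[[0]])
        assert classify_site(gt, "s0").pattern == UNINFORMATIVE

    def test_hom_alt_mother_equivalent_to_hom_ref(self):
        # only the het/hom structure matters, not which homozygote
        gt = make_gt(father=[1], mother=[2], sons=[[1], [1]], daughters=[[2], [2]])
        assert classify_site(gt, "s0").pattern == XY_PATTERN

    def test_missing_offspring_dropped_from_denominator(self):
        gt = make_gt(
            father=[1], mother=[0], sons=[[1], [-1], [1]], daughters=[[0], [-1]]
        )
        call = classify_site(gt, "s0")
        assert call.n_informative_offspring == 3
        assert call.concordance == 1.0

    def test_low_concordance_uninformative(self):
        # half the sons discordant: below the 0.9 default
        gt = make_gt(
            father=[1], mother=[0], sons=[[1], [0], [1], [0]], daughters=[[0], [0]]
        )
        call = classify_site(gt, "s0", min_concordance=0.9)
        assert call.pattern == UNINFORMATIVE
        assert call.concordance == pytest.approx(4 / 6)
        # strict vs permissive threshold flips the call
        assert classify_site(gt, "s0", min_concordance=0.6).pattern == XY_PATTERN

    def test_unknown_site_raises(self):
        gt = make_gt(father=[1], mother=[0], sons=[[1]], daughters=[[0]])
        with pytest.raises(DataError, match="unknown site"):
            classify_site(gt, "missing")


def _relabel(gt: GenotypeTable) -> GenotypeTable:
    """Swap parental roles and offspring sexes (M<->F)."""
    ind = gt.individuals.copy()
    ind["role"] = ind["role"].map(
        {"father": "mother", "mother": "father", "offspring": "offspring"}
    )
    ind["sex"] = ind["sex"].map({"M": "F", "F": "M"})
    return GenotypeTable(sites=gt.sites, calls=gt.calls, individuals=ind)


class TestSymmetry:
    def test_relabeling_maps_xy_to_zw_exactly(self):
        """Sex/parent relabeling must map XY calls to ZW calls one-to-one
        on 1,000 random sites."""
        rng = np.random.default_rng(2024)
        n_sites = 1000
        calls = rng.choice([-1, 0, 1, 2], size=(n_sites, 12), p=[0.05, 0.35, 0.3, 0.3])
        gt = make_gt(
            father=calls[:, 0],
            mother=calls[:, 1],
            sons=[calls[:, j] for j in range(2, 7)],
            daughters=[calls[:, j] for j in range(7, 12)],
        )
        swapped = _relabel(gt)
        a = classify_sites(gt, gt.sites["site_id"])
        b = classify_sites(swapped, gt.sites["site_id"])
        mapping = {
            XY_PATTERN: ZW_PATTERN,
            ZW_PATTERN: XY_PATTERN,
            BOTH_PARENTS_HET: BOTH_PARENTS_HET,
            UNINFORMATIVE: UNINFORMATIVE,
        }
        assert (a["pattern"].map(mapping) == b["pattern"]).all()
        pd.testing.assert_series_equal(a["concordance"], b["concordance"])
        pd.testing.assert_series_equal(
            a["n_informative_offspring"], b["n_informative_offspring"]
        )


class TestConcordanceTracksLinkage:
    def test_concordance_matches_recombination_fraction(self):
        """On an error-free cross, mean concordance at father-informative
        sites tracks 1 - c to the SD locus within binomial noise."""
        from radsexmap import CrossDesign, simulate_cross

        sim = simulate_cross(
            CrossDesign(
                n_chromosomes=2,
                chrom_length_bp=20_000_000,
                loci_per_chromosome=400,
                sd_chromosome=0,
                sd_region=(4_000_000, 9_000_000),
                recomb_rate=2.0,
                frac_y_limited=0.0,
                frac_x_limited_diff=0.0,
                genotyping_error=0.0,
                missing_rate=0.0,
                seed=77,
            )
        )
        gt, truth = sim.genotypes, sim.truth
        f = gt.calls[:, gt.father_index]
        m = gt.calls[:, gt.mother_index]
        rec_frac = truth.snps.set_index("site_id")["rec_frac"]
        rows = []
        for i, (site, chrom) in enumerate(zip(gt.sites["site_id"], gt.sites["chrom"])):
            if chrom != "LG1" or f[i] != 1 or m[i] not in (0, 2):
                continue
            call = classify_site(gt, site, min_concordance=2.0)  # never call, just measure
            rows.append((rec_frac[site], call.concordance))
        assert len(rows) > 50
        df = pd.DataFrame(rows, columns=["c", "conc"])
        # orientation depends on phase: when the father's Y-borne allele
        # equals the mother's allele the roles of het/hom swap, giving
        # concordance c instead of 1-c; fold to the informative orientation
        df["conc"] = np.maximum(df["conc"], 1 - df["conc"])
        df["bin"] = pd.cut(df["c"], bins=[0, 0.05, 0.15, 0.3])
        for _, grp in df.groupby("bin", observed=True):
            if len(grp) < 10:
                continue
            expected = 1 - grp["c"].mean()
            se = np.sqrt(expected * (1 - expected) / (55 * len(grp))) + 0.01
            assert abs(grp["conc"].mean() - expected) < max(0.05, 4 * se)


class TestSummarize:
    def test_majority_xy(self):
        calls = pd.DataFrame(
            {"pattern": [XY_PATTERN] * 52 + [BOTH_PARENTS_HET] * 40 + [UNINFORMATIVE] * 8}
        )
        out = summarize_top(calls)
        assert out["inferred_system"] == "XY"
        assert out["counts"][XY_PATTERN] == 52

    def test_empty_no_inference(self):
        out = summarize_top(pd.DataFrame({"pattern": []}))
        assert out == {"counts": {}, "inferred_system": None}

    def test_error_free_cross_all_informative_sites_xy(self, clean_sim):
        """Every fully SD-linked father-informative site in an error-free
        XY cross must classify as the XY pattern."""
        gt, truth = clean_sim.genotypes, clean_sim.truth
        sd_loci = set(truth.loci.loc[truth.loci["true_class"] == SD_LINKED, "locus_id"])
        f = gt.calls[:, gt.father_index]
        m = gt.calls[:, gt.mother_index]
        sites = [
            s
            for i, (s, l) in enumerate(zip(gt.sites["site_id"], gt.sites["locus_id"]))
            if l in sd_loci and f[i] == 1 and m[i] in (0, 2)
        ]
        calls = classify_sites(gt, sites)
        assert len(calls) > 0
        # phase splits informative sites into XY-oriented (concordance 1)
        # and mirror-oriented (concordance 0, left uncalled); nothing in
        # between, and never a ZW call, on an error-free fully linked cross
        assert set(calls["concordance"]) <= {0.0, 1.0}
        assert (calls.loc[calls["concordance"] == 1.0, "pattern"] == XY_PATTERN).all()
        assert ZW_PATTERN not in set(calls["pattern"])
        assert (calls["pattern"] == XY_PATTERN).any()
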