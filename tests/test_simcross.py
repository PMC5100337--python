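"""Simulator: design validation, Mendelian transmission, depths, truth."""

import dataclasses

import numpy as np
import pytest

from radsexmap import CrossDesign, read_truth, simulate_cross, write_truth
from radsexmap.errors import ConfigError
from radsexmap.simcross import AUTOSOMAL, SD_LINKED, X_DIFF, Y_LIMITED


def _mendel_violations(sim):
    """Count offspring calls impossible given the parental calls.

    Allowed offspring allele-dose sums per (father, mother) call pair,
    derived by brute force over transmissible alleles.
    """
    gt = sim.genotypes
    f = gt.calls[:, gt.father_index]
    m = gt.calls[:, gt.mother_index]
    off = gt.calls[:, gt.offspring_indices]
    allowed = {  # call -> set of transmissible allele doses
        0: {0},
        1: {0, 1},
        2: {1},
    }
    bad = 0
    for i in range(gt.n_sites):
        if f[i] < 0 or m[i] < 0:
            continue
        ok = {fa + ma for fa in allowed[f[i]] for ma in allowed[m[i]]}
        row = off[i]
        bad += int(np.sum(~np.isin(row[row >= 0], list(ok))))
    return bad


class TestDesignValidation:
    def test_defaults_are_valid(self):
        CrossDesign().validate()

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"n_sons": 1, "n_daughters": 0}, "n_sons"),
            ({"depth_mean": 0}, "depth_mean"),
            ({"genotyping_error": 1.5}, "genotyping_error"),
            ({"frac_y_limited": 0.7, "frac_x_limited_diff": 0.7}, "frac_y_limited"),
            ({"sd_region": (0, 40_000_000)}, "sd_region"),
            ({"sd_chromosome": 99}, "sd_chromosome"),
            ({"system": "XO"}, "system"),
        ],
    )
    def test_invalid_designs_name_the_invariant(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            CrossDesign(**kwargs)

    def test_none_system_rejects_sex_limited_loci(self):
        with pytest.raises(ConfigError, match="NONE"):
            CrossDesign(
                system="NONE", sd_chromosome=None, sd_region=None, frac_y_limited=0.1
            )

    def test_yaml_round_trip(self, tmp_path):
        d = CrossDesign(seed=5)
        d.to_yaml(tmp_path / "d.yaml")
        assert CrossDesign.from_yaml(tmp_path / "d.yaml") == d


class TestTransmission:
    def test_mendelian_consistency_without_error(self):
        design = CrossDesign(
            n_chromosomes=3,
            chrom_length_bp=5_000_000,
            loci_per_chromosome=80,
            system="NONE",
            sd_chromosome=None,
            sd_region=None,
            frac_y_limited=0.0,
            frac_x_limited_diff=0.0,
            genotyping_error=0.0,
            missing_rate=0.0,
            seed=3,
        )
        assert _mendel_violations(simulate_cross(design)) == 0

    def test_fully_linked_sd_snps_follow_sex(self, clean_sim):
        """With full suppression and no error, father-het/mother-hom SD
        SNPs make every son heterozygous and every daughter homozygous."""
        gt = clean_sim.genotypes
        truth = clean_sim.truth
        sd_sites = set(
            truth.snps.loc[
                truth.snps["locus_id"].isin(
                    truth.loci.loc[truth.loci["true_class"] == SD_LINKED, "locus_id"]
                ),
                "site_id",
            ]
        )
        f = gt.calls[:, gt.father_index]
        m = gt.calls[:, gt.mother_index]
        informative = [
            i
            for i, s in enumerate(gt.sites["site_id"])
            if s in sd_sites and f[i] == 1 and m[i] in (0, 2)
        ]
        assert informative, "expected at least one father-informative SD SNP"
        xy_oriented = 0
        for i in informative:
            sons = gt.calls[i, gt.son_indices]
            daus = gt.calls[i, gt.daughter_indices]
            sons_het = (sons == 1).all()
            daus_hom = np.isin(daus, (0, 2)).all()
            # phase determines orientation: sons het iff the Y-borne allele
            # differs from the mother's; otherwise the mirror holds exactly
            assert (sons_het and daus_hom) or (
                np.isin(sons, (0, 2)).all() and (daus == 1).all()
            )
            xy_oriented += int(sons_het)
        assert xy_oriented > 0

    def test_parameter_forcing_no_hemizygous_loci(self):
        design = CrossDesign(
            n_chromosomes=2,
            chrom_length_bp=5_000_000,
            loci_per_chromosome=50,
            sd_chromosome=0,
            sd_region=(1_000_000, 4_000_000),
            frac_y_limited=0.0,
            frac_x_limited_diff=0.0,
            seed=9,
        )
        truth = simulate_cross(design).truth
        assert not truth.loci["true_class"].isin([Y_LIMITED, X_DIFF]).any()
        assert set(truth.loci["true_class"]) <= {SD_LINKED, AUTOSOMAL}


class TestDepthModel:
    def test_autosomal_sex_means_agree(self, small_sim):
        truth, depths, gt = small_sim.truth, small_sim.depths, small_sim.genotypes
        auto = truth.loci.loc[truth.loci["true_class"] == AUTOSOMAL, "locus_id"]
        assert len(auto) >= 200
        sons = gt.individuals.loc[
            (gt.individuals["role"] == "offspring") & (gt.individuals["sex"] == "M"), "id"
        ]
        daus = gt.individuals.loc[
            (gt.individuals["role"] == "offspring") & (gt.individuals["sex"] == "F"), "id"
        ]
        m_son = depths.loc[auto, sons].values.mean()
        m_dau = depths.loc[auto, daus].values.mean()
        assert abs(m_son - m_dau) / m_son < 0.05

    def test_y_limited_daughter_depth_near_zero(self, small_sim):
        truth, depths, gt = small_sim.truth, small_sim.depths, small_sim.genotypes
        ylim = truth.loci.loc[truth.loci["true_class"] == Y_LIMITED, "locus_id"]
        assert len(ylim) > 0
        daus = gt.individuals.loc[
            (gt.individuals["role"] == "offspring") & (gt.individuals["sex"] == "F"), "id"
        ]
        assert depths.loc[ylim, daus].values.mean() < 0.5

    def test_y_limited_snps_not_in_genotypes(self, small_sim):
        truth, gt = small_sim.truth, small_sim.genotypes
        ylim = set(truth.loci.loc[truth.loci["true_class"] == Y_LIMITED, "locus_id"])
        assert not gt.sites["locus_id"].isin(ylim).any()


class TestDeterminismAndTruth:
    def test_same_seed_bitwise_identical(self, small_design):
        a = simulate_cross(small_design)
        b = simulate_cross(small_design)
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert a.depths.equals(b.depths)
        assert a.truth.loci.equals(b.truth.loci)
        assert a.truth.snps.equals(b.truth.snps)

    def test_different_seed_differs(self, small_design):
        b = simulate_cross(dataclasses.replace(small_design, seed=43))
        a = simulate_cross(small_design)
        assert not np.array_equal(a.genotypes.calls, b.genotypes.calls)

    def test_every_locus_and_snp_has_one_truth_record(self, small_design, small_sim):
        truth = small_sim.truth
        n_loci = small_design.n_chromosomes * small_design.loci_per_chromosome
        assert len(truth.loci) == n_loci
        assert len(truth.snps) == n_loci * small_design.snps_per_locus
        assert not truth.loci["locus_id"].duplicated().any()
        assert not truth.snps["site_id"].duplicated().any()

    def test_truth_round_trip(self, small_sim, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(small_sim.truth, path)
        back = read_truth(path)
        assert back.loci.equals(small_sim.truth.loci.reset_index(drop=True))
        # rec_frac survives as float
        np.testing.assert_allclose(
            back.snps["rec_frac"].values, small_sim.truth.snps["rec_frac"].values
        )

    def test_truth_file_row_count(self, small_design, small_sim, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(small_sim.truth, path)
        n_lines = sum(1 for _ in open(path)) - 1  # header
        n_loci = small_design.n_chromosomes * small_design.loci_per_chromosome
        assert n_lines == n_loci + n_loci * small_design.snps_per_locus

    def test_sons_all_carry_same_y_allele_at_linked_snps(self, clean_sim):
        """Fully linked father-informative SD SNPs: every son received the
        same paternal (Y-borne) allele, so sons are uniform in zygosity in
        100% of error-free calls."""
        gt, truth = clean_sim.genotypes, clean_sim.truth
        sd_loci = set(truth.loci.loc[truth.loci["true_class"] == SD_LINKED, "locus_id"])
        f = gt.calls[:, gt.father_index]
        m = gt.calls[:, gt.mother_index]
        checked = 0
        for i, (site, locus) in enumerate(zip(gt.sites["site_id"], gt.sites["locus_id"])):
            if locus not in sd_loci or f[i] != 1 or m[i] not in (0, 2):
                continue
            sons = gt.calls[i, gt.son_indices]
            # mother hom: the paternal allele of every son is Y-borne and
            # identical, so all sons share one genotype
            assert len(np.unique(sons)) == 1
            checked += 1
        assert checked > 0
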