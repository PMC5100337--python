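"""Forward simulation of a two-parent RAD-seq cross with a sex chromosome.

The simulator emulates the study design the rest of the package analyzes:
a single family (father, mother, sexed sons and daughters) genotyped at
biallelic SNPs inside short RAD loci, with per-locus mean read depths.  One
chromosome pair may carry a sex-determination (SD) region in which
recombination is suppressed in the heterogametic parent.  Within that
region a configurable fraction of loci is present only on the sex-limited
haplotype (Y under XY, W under ZW; depth ~ half the diploid mean in the
heterogametic sex, near zero in the other) or deleted from it (so the
homogametic sex carries two doses and the heterogametic sex one).

Every simulated locus and SNP receives a ground-truth record, so each
downstream stage (association, inheritance classification, coverage
classing, enrichment, region calling) can be validated against the planted
architecture.

Model choices
-------------
* Meiosis: Poisson crossover count per chromosome (``recomb_rate``
  Morgans), uniform crossover positions, no interference.  Crossovers that
  fall inside the SD region of the heterogametic parent are kept with
  probability ``sd_recomb_suppression`` (0 = complete suppression).
* Offspring sex is fixed by design (``n_sons``/``n_daughters``); the
  heterogametic parent's gamete is resampled until it transmits the
  required haplotype at the SD-region midpoint (sons receive the Y under
  XY, daughters the W under ZW).
* Depths are negative binomial with mean ``depth_mean`` per diploid dose
  and dispersion ``depth_dispersion`` (Poisson as dispersion -> infinity).
  Individuals carrying zero copies of a locus still receive a small
  contamination floor (mean 0.1 reads) so that absence is noisy, as it is
  in real libraries (spurious reads, wrongly sexed individuals).
* Hemizygous loci are reported the way a diploid caller would see them:
  sex-limited (Y/W-only) loci emit no genotype rows at all, while
  one-dose (X/Z-differential) loci emit ordinary genotypes with the
  hemizygous individuals encoded as homozygous for their single allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .dataio import (
    GenotypeTable,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_OFFSPRING,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)

LOCUS_LEN = 100  # bp span of one RAD tag

# truth classes for loci
Y_LIMITED = "Y_LIMITED"
X_DIFF = "X_DIFF"
SD_LINKED = "SD_LINKED"
AUTOSOMAL = "AUTOSOMAL"

SYSTEMS = ("XY", "ZW", "NONE")

TRUTH_LOCUS_COLUMNS = ["locus_id", "chrom", "start", "end", "true_class"]
TRUTH_SNP_COLUMNS = ["site_id", "locus_id", "chrom", "pos", "rec_frac"]


@dataclass
class CrossDesign:
    """Full parameterization of a simulated family cross.

    Defaults reproduce the lab-strain study design: 28 sons and 27
    daughters from one XY pair, ten 30-Mb chromosomes, and an SD region
    spanning 6.8-20.3 Mb of one of them with fully suppressed
    recombination in the father.
    """

    n_chromosomes: int = 10
    chrom_length_bp: int = 30_000_000
    loci_per_chromosome: int = 1000
    snps_per_locus: int = 1
    n_sons: int = 28
    n_daughters: int = 27
    system: str = "XY"
    sd_chromosome: Optional[int] = 4
    sd_region: Optional[Tuple[int, int]] = (6_800_000, 20_300_000)
    recomb_rate: float = 2.0
    sd_recomb_suppression: float = 0.0
    frac_y_limited: float = 0.1
    frac_x_limited_diff: float = 0.1
    maf_range: Tuple[float, float] = (0.1, 0.5)
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    genotyping_error: float = 0.01
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.system not in SYSTEMS:
            raise ConfigError(f"system must be one of {SYSTEMS}, got {self.system!r}")
        if self.n_sons + self.n_daughters < 2:
            raise ConfigError("invariant violated: n_sons + n_daughters >= 2")
        for name in ("n_chromosomes", "chrom_length_bp", "loci_per_chromosome"):
            if getattr(self, name) < 1:
                raise ConfigError(f"invariant violated: {name} >= 1")
        if self.snps_per_locus < 0:
            raise ConfigError("invariant violated: snps_per_locus >= 0")
        if self.snps_per_locus > LOCUS_LEN:
            raise ConfigError(f"snps_per_locus cannot exceed locus length ({LOCUS_LEN})")
        if self.depth_mean <= 0:
            raise ConfigError("invariant violated: depth_mean > 0")
        if self.depth_dispersion <= 0:
            raise ConfigError("invariant violated: depth_dispersion > 0")
        for name in (
            "sd_recomb_suppression",
            "frac_y_limited",
            "frac_x_limited_diff",
            "genotyping_error",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"invariant violated: {name} in [0,1], got {v}")
        if self.frac_y_limited + self.frac_x_limited_diff > 1.0 + 1e-12:
            raise ConfigError(
                "invariant violated: frac_y_limited + frac_x_limited_diff <= 1"
            )
        if self.recomb_rate < 0:
            raise ConfigError("invariant violated: recomb_rate >= 0")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("invariant violated: 0 <= maf_range[0] <= maf_range[1] <= 1")
        if self.system == "NONE":
            if self.frac_y_limited > 0 or self.frac_x_limited_diff > 0:
                raise ConfigError(
                    "system=NONE is incompatible with nonzero frac_y_limited / "
                    "frac_x_limited_diff"
                )
        else:
            if self.sd_chromosome is None or self.sd_region is None:
                raise ConfigError(
                    f"system={self.system} requires sd_chromosome and sd_region"
                )
            if not 0 <= self.sd_chromosome < self.n_chromosomes:
                raise ConfigError("invariant violated: sd_chromosome is a valid index")
            s, e = self.sd_region
            if not (0 <= s < e <= self.chrom_length_bp):
                raise ConfigError(
                    "invariant violated: sd_region within [0, chrom_length_bp)"
                )

    # -- helpers ----------------------------------------------------------
    def chrom_labels(self) -> list:
        return [f"LG{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def sd_chrom_label(self) -> Optional[str]:
        if self.system == "NONE" or self.sd_chromosome is None:
            return None
        return f"LG{self.sd_chromosome + 1}"

    @property
    def heterogametic_parent(self) -> Optional[str]:
        return {"XY": ROLE_FATHER, "ZW": ROLE_MOTHER, "NONE": None}[self.system]

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["sd_region"] is not None:
            d["sd_region"] = list(d["sd_region"])
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrossDesign":
        d = dict(d)
        if d.get("sd_region") is not None:
            d["sd_region"] = tuple(d["sd_region"])
        if d.get("maf_range") is not None:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CrossDesign":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def chipwa_design(**overrides) -> CrossDesign:
    """The wild-caught (Chipwa) study design: 20 sons and 20 daughters."""
    return replace(CrossDesign(), n_sons=20, n_daughters=20, **overrides)


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated data.

    ``loci`` carries one row per RAD locus with its planted class; ``snps``
    one row per SNP with the recombination fraction between the SNP and the
    SD-region midpoint (Haldane map function, 0.5 on other chromosomes, NaN
    when no sex-determining system was simulated).
    """

    loci: pd.DataFrame
    snps: pd.DataFrame

    def class_of(self, locus_id: str) -> str:
        row = self.loci.loc[self.loci["locus_id"] == locus_id, "true_class"]
        if row.empty:
            raise KeyError(locus_id)
        return row.iloc[0]


@dataclass
class SimResult:
    genotypes: GenotypeTable
    depths: pd.DataFrame
    placement: pd.DataFrame
    truth: TruthTable
    design: CrossDesign = field(repr=False)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gamete_haplotypes(
    rng: np.random.Generator,
    query_pos: np.ndarray,
    length: int,
    recomb_rate: float,
    suppress: Optional[Tuple[int, int, float]] = None,
    required: Optional[Tuple[float, int]] = None,
) -> np.ndarray:
    """Simulate one gamete and return the transmitted haplotype (0/1) at
    each query position.

    ``suppress=(start, end, keep_prob)`` thins crossovers inside an
    interval; ``required=(pos, hap)`` resamples the whole gamete until the
    haplotype transmitted at ``pos`` equals ``hap`` (used to condition on
    offspring sex).
    """
    while True:
        k = rng.poisson(recomb_rate)
        xpos = np.sort(rng.uniform(0, length, size=k))
        if suppress is not None and k > 0:
            s, e, keep = suppress
            inside = (xpos >= s) & (xpos < e)
            drop = inside & (rng.random(k) >= keep)
            xpos = xpos[~drop]
        start_hap = int(rng.integers(2))
        if required is not None:
            pos, hap = required
            at = (start_hap + np.searchsorted(xpos, pos)) % 2
            if at != hap:
                continue
        return (start_hap + np.searchsorted(xpos, query_pos)) % 2


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate_cross(design: CrossDesign) -> SimResult:
    """Simulate genotypes, depths, placement and ground truth for a cross.

    Identical seeds reproduce the output bit-for-bit.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    labels = design.chrom_labels()
    L = design.chrom_length_bp
    n_off = design.n_sons + design.n_daughters

    # --- loci and SNP coordinates ---------------------------------------
    loci = []  # (locus_id, chrom_idx, start)
    snps = []  # (site_id, locus_idx, chrom_idx, pos)
    for c in range(design.n_chromosomes):
        starts = np.sort(
            rng.choice(L - LOCUS_LEN, size=design.loci_per_chromosome, replace=False)
        )
        for s in starts:
            li = len(loci)
            locus_id = f"L{li:05d}"
            loci.append((locus_id, c, int(s)))
            offsets = np.sort(rng.choice(LOCUS_LEN, size=design.snps_per_locus, replace=False))
            for j, off in enumerate(offsets):
                snps.append((f"{locus_id}_S{j}", li, c, int(s) + int(off)))

    n_loci = len(loci)
    n_snps = len(snps)
    locus_chrom = np.array([c for _, c, _ in loci])
    locus_start = np.array([s for _, _, s in loci])
    snp_chrom = np.array([c for _, _, c, _ in snps]) if n_snps else np.empty(0, dtype=int)
    snp_pos = np.array([p for _, _, _, p in snps]) if n_snps else np.empty(0, dtype=int)
    snp_locus = np.array([li for _, li, _, _ in snps]) if n_snps else np.empty(0, dtype=int)

    # --- planted locus classes ------------------------------------------
    true_class = np.array([AUTOSOMAL] * n_loci, dtype=object)
    if design.system != "NONE":
        sd0, sd1 = design.sd_region
        in_sd = (
            (locus_chrom == design.sd_chromosome)
            & (locus_start >= sd0)
            & (locus_start < sd1)
        )
        sd_idx = np.flatnonzero(in_sd)
        true_class[sd_idx] = SD_LINKED
        n_y = int(round(design.frac_y_limited * len(sd_idx)))
        n_x = int(round(design.frac_x_limited_diff * len(sd_idx)))
        perm = rng.permutation(sd_idx)
        true_class[perm[:n_y]] = Y_LIMITED
        true_class[perm[n_y : n_y + n_x]] = X_DIFF
    snp_class = true_class[snp_locus] if n_snps else np.empty(0, dtype=object)

    # --- parental haplotypes --------------------------------------------
    lo, hi = design.maf_range
    freq = rng.uniform(lo, hi, size=n_snps)
    f_h0 = (rng.random(n_snps) < freq).astype(np.int8)
    f_h1 = (rng.random(n_snps) < freq).astype(np.int8)
    m_h0 = (rng.random(n_snps) < freq).astype(np.int8)
    m_h1 = (rng.random(n_snps) < freq).astype(np.int8)
    # haplotype index 1 of the heterogametic parent is the sex-limited one
    # (Y under XY, W under ZW)

    # --- meiosis: transmitted haplotype at every SNP and locus start -----
    sexes = ["M"] * design.n_sons + ["F"] * design.n_daughters
    pat_hap_snp = np.zeros((n_snps, n_off), dtype=np.int8)
    mat_hap_snp = np.zeros((n_snps, n_off), dtype=np.int8)
    pat_hap_locus = np.zeros((n_loci, n_off), dtype=np.int8)
    mat_hap_locus = np.zeros((n_loci, n_off), dtype=np.int8)

    sd_mid = None
    if design.system != "NONE":
        sd_mid = 0.5 * (design.sd_region[0] + design.sd_region[1])

    for c in range(design.n_chromosomes):
        snp_sel = np.flatnonzero(snp_chrom == c)
        loc_sel = np.flatnonzero(locus_chrom == c)
        query = np.concatenate([snp_pos[snp_sel], locus_start[loc_sel]]).astype(float)
        n_q_snp = len(snp_sel)
        is_sd_chrom = design.system != "NONE" and c == design.sd_chromosome
        suppress = None
        if is_sd_chrom:
            suppress = (
                design.sd_region[0],
                design.sd_region[1],
                design.sd_recomb_suppression,
            )
        for o, sex in enumerate(sexes):
            for parent in ("pat", "mat"):
                het_parent = (
                    (parent == "pat" and design.system == "XY")
                    or (parent == "mat" and design.system == "ZW")
                )
                required = None
                if het_parent and is_sd_chrom:
                    if design.system == "XY":
                        want = 1 if sex == "M" else 0
                    else:
                        want = 1 if sex == "F" else 0
                    required = (sd_mid, want)
                haps = _gamete_haplotypes(
                    rng,
                    query,
                    L,
                    design.recomb_rate,
                    suppress=suppress if het_parent else None,
                    required=required,
                )
                if parent == "pat":
                    pat_hap_snp[snp_sel, o] = haps[:n_q_snp]
                    pat_hap_locus[loc_sel, o] = haps[n_q_snp:]
                else:
                    mat_hap_snp[snp_sel, o] = haps[:n_q_snp]
                    mat_hap_locus[loc_sel, o] = haps[n_q_snp:]

    # --- genotypes -------------------------------------------------------
    rows = np.arange(n_snps)[:, None]
    f_haps = np.stack([f_h0, f_h1])  # (2, n_snps)
    m_haps = np.stack([m_h0, m_h1])
    pat_allele = f_haps[pat_hap_snp, rows] if n_snps else np.zeros((0, n_off), np.int8)
    mat_allele = m_haps[mat_hap_snp, rows] if n_snps else np.zeros((0, n_off), np.int8)
    geno_off = (pat_allele + mat_allele).astype(np.int8)
    geno_father = (f_h0 + f_h1).astype(np.int8)
    geno_mother = (m_h0 + m_h1).astype(np.int8)

    # hemizygosity at X/Z-differential loci: individuals whose sex-limited
    # haplotype covers a deleted locus carry one dose and are reported as
    # homozygous for their single allele, as a diploid caller would do
    if design.system != "NONE" and n_snps:
        diff_snp = snp_class == X_DIFF
        if diff_snp.any():
            if design.system == "XY":
                hemi = diff_snp[:, None] & (pat_hap_snp == 1)
                geno_off = np.where(hemi, 2 * mat_allele, geno_off).astype(np.int8)
                geno_father = np.where(diff_snp, 2 * f_h0, geno_father).astype(np.int8)
            else:
                hemi = diff_snp[:, None] & (mat_hap_snp == 1)
                geno_off = np.where(hemi, 2 * pat_allele, geno_off).astype(np.int8)
                geno_mother = np.where(diff_snp, 2 * m_h0, geno_mother).astype(np.int8)

    calls = np.concatenate(
        [geno_father[:, None], geno_mother[:, None], geno_off], axis=1
    ).astype(np.int8)

    # drop sex-limited (Y/W-only) loci from the genotype table: a caller
    # aligned to a diploid reference never emits rows for them
    keep_snp = (
        snp_class != Y_LIMITED if n_snps else np.ones(0, dtype=bool)
    )

    # genotyping error: re-draw among the two other states
    if design.genotyping_error > 0 and calls.size:
        err = rng.random(calls.shape) < design.genotyping_error
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if design.missing_rate > 0 and calls.size:
        miss = rng.random(calls.shape) < design.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    # --- depths ----------------------------------------------------------
    # per-individual copy number of each locus, from the actually
    # transmitted haplotypes (equals the sex-based expectation under full
    # recombination suppression)
    copies = np.full((n_loci, 2 + n_off), 2, dtype=np.int8)
    if design.system != "NONE":
        lim_locus = true_class == Y_LIMITED
        diff_locus = true_class == X_DIFF
        if design.system == "XY":
            off_carries = pat_hap_locus == 1
            parent_carries = np.array([[1], [0]])  # father one Y dose, mother none
        else:
            off_carries = mat_hap_locus == 1
            parent_carries = np.array([[0], [1]])
        carrier = np.concatenate(
            [np.repeat(parent_carries.T, n_loci, axis=0).reshape(n_loci, 2), off_carries],
            axis=1,
        )
        copies[lim_locus] = carrier[lim_locus]
        copies[diff_locus] = 2 - carrier[diff_locus]

    mean = design.depth_mean / 2.0 * copies.astype(float)
    mean[copies == 0] = 0.1  # contamination floor for absent loci
    r = design.depth_dispersion
    depth_vals = rng.negative_binomial(r, r / (r + mean)).astype(float)

    # --- assemble tables --------------------------------------------------
    ids = (
        ["father", "mother"]
        + [f"son{i + 1:02d}" for i in range(design.n_sons)]
        + [f"dau{i + 1:02d}" for i in range(design.n_daughters)]
    )
    individuals = pd.DataFrame(
        {
            "id": ids,
            "role": [ROLE_FATHER, ROLE_MOTHER] + [ROLE_OFFSPRING] * n_off,
            "sex": ["M", "F"] + sexes,
        }
    )

    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4

    sites = pd.DataFrame(
        {
            "site_id": [s[0] for s in snps],
            "locus_id": [loci[s[1]][0] for s in snps],
            "chrom": [labels[c] for c in snp_chrom],
            "pos": snp_pos,
            "ref": bases[ref_idx] if n_snps else [],
            "alt": bases[alt_idx] if n_snps else [],
        }
    )
    gt = GenotypeTable(
        sites=sites[keep_snp].reset_index(drop=True),
        calls=calls[keep_snp],
        individuals=individuals,
    )

    depths = pd.DataFrame(depth_vals, index=[l[0] for l in loci], columns=ids)
    depths.index.name = "locus_id"

    placement = pd.DataFrame(
        {
            "locus_id": [l[0] for l in loci],
            "chrom": [labels[c] for c in locus_chrom],
            "start": locus_start,
            "end": locus_start + LOCUS_LEN,
        }
    )

    truth = TruthTable(
        loci=pd.DataFrame(
            {
                "locus_id": [l[0] for l in loci],
                "chrom": [labels[c] for c in locus_chrom],
                "start": locus_start,
                "end": locus_start + LOCUS_LEN,
                "true_class": true_class,
            }
        ),
        snps=pd.DataFrame(
            {
                "site_id": [s[0] for s in snps],
                "locus_id": [loci[s[1]][0] for s in snps],
                "chrom": [labels[c] for c in snp_chrom],
                "pos": snp_pos,
                "rec_frac": _rec_frac_to_sd(design, snp_chrom, snp_pos),
            }
        ),
    )
    logger.info(
        "simulated cross: %d loci, %d SNPs (%d emitted), %d offspring, system=%s",
        n_loci,
        n_snps,
        int(keep_snp.sum()),
        n_off,
        design.system,
    )
    return SimResult(gt, depths, placement, truth, design)


def _rec_frac_to_sd(design: CrossDesign, snp_chrom: np.ndarray, snp_pos: np.ndarray) -> np.ndarray:
    """Haldane recombination fraction between each SNP and the SD midpoint.

    Genetic distance accumulates at ``recomb_rate / chrom_length_bp``
    Morgans per bp, scaled by the suppression multiplier inside the SD
    region of the heterogametic parent.  SNPs on other chromosomes are
    unlinked (0.5); with no SD system the fraction is undefined (NaN).
    """
    n = len(snp_pos)
    if design.system == "NONE":
        return np.full(n, np.nan)
    sd0, sd1 = design.sd_region
    mid = 0.5 * (sd0 + sd1)
    rate = design.recomb_rate / design.chrom_length_bp
    out = np.full(n, 0.5)
    on_sd = snp_chrom == design.sd_chromosome
    for i in np.flatnonzero(on_sd):
        a, b = sorted((float(snp_pos[i]), mid))
        inside = max(0.0, min(b, sd1) - max(a, sd0))
        d = rate * ((b - a - inside) + design.sd_recomb_suppression * inside)
        out[i] = 0.5 * (1.0 - np.exp(-2.0 * d))
    return out


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTable, path) -> None:
    """Write the truth table as a single TSV: one row per locus and per SNP."""
    loci = truth.loci.copy()
    loci.insert(0, "record", "locus")
    loci["site_id"] = ""
    loci["pos"] = ""
    loci["rec_frac"] = ""
    snps = truth.snps.copy()
    snps.insert(0, "record", "snp")
    snps["start"] = ""
    snps["end"] = ""
    snps["true_class"] = ""
    cols = [
        "record",
        "locus_id",
        "site_id",
        "chrom",
        "start",
        "end",
        "pos",
        "true_class",
        "rec_frac",
    ]
    pd.concat([loci[cols], snps[cols]], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "site_id": str, "chrom": str})
    loci = df[df["record"] == "locus"]
    snps = df[df["record"] == "snp"]
    loci = pd.DataFrame(
        {
            "locus_id": loci["locus_id"].values,
            "chrom": loci["chrom"].values,
            "start": loci["start"].astype(np.int64).values if len(loci) else [],
            "end": loci["end"].astype(np.int64).values if len(loci) else [],
            "true_class": loci["true_class"].values,
        }
    )
    snps = pd.DataFrame(
        {
            "site_id": snps["site_id"].values,
            "locus_id": snps["locus_id"].values,
            "chrom": snps["chrom"].values,
            "pos": snps["pos"].astype(np.int64).values if len(snps) else [],
            "rec_frac": snps["rec_frac"].astype(float).values if len(snps) else [],
        }
    )
    return TruthTable(loci=loci, snps=snps)
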