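"""Readers, writers and in-memory containers for the pipeline's tables.

Genotypes travel as VCF (read with :mod:`cyvcf2`, written with
:mod:`pysam`) together with a sample-sex TSV; per-locus read depths as a
locus x individual TSV matrix; locus placements as BED (chrom, start, end,
locus_id).  All coordinates are 0-based, half-open.  Reads are
gzip-transparent (``.gz`` paths work everywhere).

Genotype calls are encoded as ``int8``: 0 = hom ref, 1 = het,
2 = hom alt, -1 = missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

# genotype call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_OFFSPRING = "offspring"

SITE_COLUMNS = ["site_id", "locus_id", "chrom", "pos", "ref", "alt"]
INDIVIDUAL_COLUMNS = ["id", "role", "sex"]


@dataclass
class GenotypeTable:
    """Diploid genotypes of a two-parent family at biallelic RAD SNPs.

    Attributes
    ----------
    sites:
        One row per SNP: ``site_id, locus_id, chrom, pos, ref, alt``.
        ``chrom`` may be NaN for unplaced loci.
    calls:
        ``(n_sites, n_individuals)`` int8 matrix of genotype codes, columns
        ordered as ``individuals``.
    individuals:
        One row per sample: ``id, role, sex`` with exactly one father and
        one mother, every offspring sexed M or F.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    individuals: pd.DataFrame
    _site_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ind = self.individuals
        n_fathers = int((ind["role"] == ROLE_FATHER).sum())
        n_mothers = int((ind["role"] == ROLE_MOTHER).sum())
        if n_fathers != 1:
            raise DataError(f"expected exactly one father, found {n_fathers}")
        if n_mothers != 1:
            raise DataError(f"expected exactly one mother, found {n_mothers}")
        off = ind[ind["role"] == ROLE_OFFSPRING]
        if len(off) == 0:
            raise DataError("genotype table contains zero offspring")
        if not off["sex"].isin(["M", "F"]).all():
            bad = off.loc[~off["sex"].isin(["M", "F"]), "id"].tolist()
            raise DataError(f"offspring without a valid sex (M/F): {bad}")
        if self.calls.shape != (len(self.sites), len(ind)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(ind)} individuals"
            )
        if len(self.sites) and (self.sites["pos"] < 0).any():
            raise DataError("negative SNP position")
        self._site_index = {s: i for i, s in enumerate(self.sites["site_id"])}

    # -- convenience accessors -------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list:
        return self.individuals["id"].tolist()

    @property
    def father_index(self) -> int:
        return int(np.flatnonzero(self.individuals["role"] == ROLE_FATHER)[0])

    @property
    def mother_index(self) -> int:
        return int(np.flatnonzero(self.individuals["role"] == ROLE_MOTHER)[0])

    @property
    def offspring_indices(self) -> np.ndarray:
        return np.flatnonzero(self.individuals["role"] == ROLE_OFFSPRING)

    @property
    def son_indices(self) -> np.ndarray:
        m = (self.individuals["role"] == ROLE_OFFSPRING) & (self.individuals["sex"] == "M")
        return np.flatnonzero(m)

    @property
    def daughter_indices(self) -> np.ndarray:
        m = (self.individuals["role"] == ROLE_OFFSPRING) & (self.individuals["sex"] == "F")
        return np.flatnonzero(m)

    def site_index(self, site_id: str) -> int:
        try:
            return self._site_index[site_id]
        except KeyError:
            raise DataError(f"unknown site: {site_id}") from None


# ---------------------------------------------------------------------------
# sex table
# ---------------------------------------------------------------------------

def read_sex_table(path) -> pd.DataFrame:
    """Read the sample-sex TSV (columns ``sample_id, role, sex``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "sex"}
    if not required.issubset(df.columns):
        raise DataError(f"sex table {path} must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample ids in sex table: {dup}")
    for role in (ROLE_FATHER, ROLE_MOTHER):
        n = int((df["role"] == role).sum())
        if n > 1:
            raise DataError(f"sex table lists {n} samples with role '{role}'")
    return df


def write_sex_table(individuals: pd.DataFrame, path) -> None:
    out = individuals.rename(columns={"id": "sample_id"})
    out[["sample_id", "role", "sex"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes (VCF)
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path, sex_table_path) -> GenotypeTable:
    """Load a VCF plus sample-sex table into a :class:`GenotypeTable`.

    Multi-allelic records are skipped (a count is logged).  Every VCF sample
    must appear in the sex table; the table may list extra samples.
    """
    import cyvcf2

    sex = read_sex_table(sex_table_path).set_index("sample_id")
    vcf = cyvcf2.VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in sex.index:
            raise DataError(f"VCF sample '{s}' missing from sex table")

    rows, call_rows = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        site_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        locus_id = site_id.rsplit("_S", 1)[0] if "_S" in site_id else site_id
        chrom = v.CHROM if v.CHROM not in (".", "UNK") else np.nan
        rows.append((site_id, locus_id, chrom, v.POS - 1, v.REF, v.ALT[0]))
        gts = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                gts[j] = a + b
        call_rows.append(gts)
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, vcf_path)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = (
        np.vstack(call_rows) if call_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    individuals = pd.DataFrame(
        {
            "id": samples,
            "role": [sex.loc[s, "role"] for s in samples],
            "sex": [sex.loc[s, "sex"] for s in samples],
        }
    )
    return GenotypeTable(sites=sites, calls=calls, individuals=individuals)


_GT_TUPLES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_genotypes(gt: GenotypeTable, vcf_path, contig_lengths: dict | None = None) -> None:
    """Write a :class:`GenotypeTable` as an uncompressed VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = gt.sites["chrom"].fillna("UNK")
    seen = list(dict.fromkeys(chroms))
    for c in seen:
        length = None if contig_lengths is None else contig_lengths.get(c)
        if length is None:
            length = int(gt.sites.loc[chroms == c, "pos"].max()) + 1000 if len(gt.sites) else 1000
        header.contigs.add(str(c), length=int(length))
    for s in gt.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for i, row in enumerate(gt.sites.itertuples(index=False)):
            chrom = row.chrom if isinstance(row.chrom, str) else "UNK"
            rec = out.new_record(
                contig=chrom,
                start=int(row.pos),
                alleles=(row.ref, row.alt),
                id=row.site_id,
            )
            for j, s in enumerate(gt.sample_ids):
                rec.samples[s]["GT"] = _GT_TUPLES[int(gt.calls[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# depth matrix
# ---------------------------------------------------------------------------

def read_depths(path) -> pd.DataFrame:
    """Read a locus x individual mean-depth TSV (first column = locus_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        logger.warning("depth matrix %s is empty", path)
        return df
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        line = int(np.flatnonzero(bad.any(axis=1))[0]) + 2  # +1 header, +1 1-based
        raise DataError(f"non-numeric depth value at line {line} of {path}")
    if (numeric < 0).any().any():
        line = int(np.flatnonzero((numeric < 0).any(axis=1))[0]) + 2
        raise DataError(f"negative depth at line {line} of {path}")
    numeric.index.name = "locus_id"
    return numeric


def write_depths(depths: pd.DataFrame, path) -> None:
    out = depths.copy()
    out.index.name = "locus_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# locus placement (BED)
# ---------------------------------------------------------------------------

def read_placement(path) -> pd.DataFrame:
    """Read a BED3+name file into a placement table.

    Returns a DataFrame with columns ``locus_id, chrom, start, end``.  Loci
    absent from the file are treated as unplaced by downstream joins.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "locus_id"],
        dtype={"chrom": str, "locus_id": str},
        comment="#",
    )
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            s, e = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise DataError(f"malformed BED interval at line {i + 1} of {path}") from None
        if s >= e:
            raise DataError(f"BED start >= end at line {i + 1} of {path}")
        if s < 0:
            raise DataError(f"negative BED start at line {i + 1} of {path}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df[["locus_id", "chrom", "start", "end"]]


def write_placement(placement: pd.DataFrame, path) -> None:
    placement[["chrom", "start", "end", "locus_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame, path) -> None:
    """Write any results DataFrame as a TSV with a header row."""
    records.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
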