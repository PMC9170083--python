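"""Readers/writers for the toolkit's file formats.

Formats: allelic-expression TSV (sample_id, locus, allele, copy, condition,
tpm), a minimal VCF v4.2 subset (biallelic sites, GT only, unphased), a
BED-like TSS table, HLA typing tables and reference haplotype tables.
All readers validate and reject rather than silently coerce; gzip inputs
are accepted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXPRESSION_COLUMNS = ["sample_id", "locus", "allele", "copy", "condition", "tpm"]
VALID_CONDITIONS = {"fresh", "unstim", "stim"}


class ValidationError(ValueError):
    """Input-table validation failure; message lists offending rows."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix.

    dosages holds alt-allele counts as floats with NaN for missing calls;
    variant ids are canonicalized to "chrom:pos:ref:alt".  Missing dosages
    are never imputed here — mean imputation happens only inside the eQTL
    scan.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns chrom, pos, ref, alt, id
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants")
        if self.variants["id"].duplicated().any():
            dupes = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate variant ids: {dupes}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError("variant positions not sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return int(idx[0])

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, computed on non-missing calls."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_RR, n_RA, n_AA) at variant j over non-missing calls."""
        col = self.dosages[:, j]
        col = col[~np.isnan(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(list(self.sample_ids),
                              self.variants.loc[mask].reset_index(drop=True),
                              self.dosages[:, mask])


def canonical_variant_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


# -- expression tables --------------------------------------------------------

def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an allelic-expression table; raises ValidationError whose
    message cites offending file rows (1-based, header = row 1)."""
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    df = df[EXPRESSION_COLUMNS].copy()
    problems: list[str] = []

    def rows(mask) -> str:
        return ", ".join(str(i + 2) for i in df.index[mask][:10])

    tpm = pd.to_numeric(df["tpm"], errors="coerce")
    bad = tpm.isna() | (tpm <= 0)
    if bad.any():
        problems.append(f"non-positive or non-numeric tpm at row(s) {rows(bad)}")
    df["tpm"] = tpm
    df["copy"] = pd.to_numeric(df["copy"], errors="coerce")
    bad = ~df["copy"].isin([1, 2])
    if bad.any():
        problems.append(f"copy not in {{1,2}} at row(s) {rows(bad)}")
    bad = ~df["condition"].isin(VALID_CONDITIONS)
    if bad.any():
        problems.append(f"unknown condition at row(s) {rows(bad)}")

    sizes = df.groupby(["sample_id", "locus", "condition"]).size()
    wrong = sizes[sizes != 2]
    for key, k in wrong.items():
        problems.append(f"{key}: {k} allele records (expected 2)")
    # allele names must be stable across conditions within a sample/locus
    names = (df.groupby(["sample_id", "locus", "condition"])["allele"]
               .apply(lambda s: tuple(sorted(s))))
    for (sample, locus), grp in names.groupby(level=[0, 1]):
        if grp.nunique() > 1:
            problems.append(f"({sample}, {locus}): allele names differ across conditions")

    if problems:
        raise ValidationError("; ".join(problems))
    df["copy"] = df["copy"].astype(int)
    return df


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_expression(df)


def write_expression_table(df: pd.DataFrame, path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


# -- VCF ----------------------------------------------------------------------

def read_vcf_minimal(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a GenotypeMatrix via cyvcf2.

    Alt-allele dosage per call; ./. becomes NaN; multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {v.CHROM}:{v.POS} (ALT={v.ALT})")
        # with gts012=True: 0/1/2 = dosage, 3 = unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    variants = pd.DataFrame({
        "chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
        "id": [canonical_variant_id(c, p, r, a)
               for c, p, r, a in zip(chroms, poss, refs, alts)],
    })
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosages)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the GT-only VCF v4.2 subset (unphased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, var in gm.variants.iterrows():
            calls = [_GT.get(d, "./.") if not np.isnan(d) else "./."
                     for d in gm.dosages[:, j]]
            fh.write(f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['ref']}"
                     f"\t{var['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# -- auxiliary tables ---------------------------------------------------------

def read_tss_table(path) -> pd.DataFrame:
    """TSS table: columns gene, chrom, tss (1-based), strand; one row per
    gene; indexed by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("gene", "chrom", "tss", "strand") if c not in df.columns]
    if missing:
        raise ValidationError(f"TSS table missing column(s): {missing}")
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate gene in TSS table")
    return df.set_index("gene")


def write_tss_table(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


def read_typing_table(path) -> pd.DataFrame:
    """HLA typing: columns sample_id, locus, allele1, allele2."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "locus", "allele1", "allele2")
               if c not in df.columns]
    if missing:
        raise ValidationError(f"typing table missing column(s): {missing}")
    if df.duplicated(["sample_id", "locus"]).any():
        raise ValidationError("duplicate (sample_id, locus) in typing table")
    return df


def read_haplotype_table(path, loci=("A", "B", "C", "DRB1")) -> pd.DataFrame:
    """Reference haplotype table: one allele column per locus + frequency."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (*loci, "frequency") if c not in df.columns]
    if missing:
        raise ValidationError(f"haplotype table missing column(s): {missing}")
    return df
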