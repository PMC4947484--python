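"""Data model and I/O for SNP genotypes, deletion calls and phenotypes.

The central objects are:

* :class:`SnpGenotypeMatrix` — a samples x SNPs alt-allele dosage matrix
  (float, ``NaN`` = missing) plus per-SNP metadata;
* deletion calls — a ``pandas.Series`` of deletion-allele dosages (0/1/2,
  ``NaN`` = missing) indexed by sample id, with the three-state string
  labels ``wt/wt``, ``wt/del``, ``del/del`` mapped bijectively to 0/1/2;
* :class:`PhenotypeTable` / :class:`Cohort` — the joined analysis table.

Coordinates are 1-based throughout (VCF convention); region strings are
``chrom:start-end`` with inclusive ends.  TSV files are tab-separated,
UTF-8, header required; ``NA`` or an empty field means missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import DataError, ValidationError, VcfParseError

logger = logging.getLogger(__name__)

#: Bijective map between three-state deletion genotype labels and
#: deletion-allele dosage.
LABEL_TO_DOSAGE = {"wt/wt": 0, "wt/del": 1, "del/del": 2}
DOSAGE_TO_LABEL = {v: k for k, v in LABEL_TO_DOSAGE.items()}
#: Fixed category order used in every confusion matrix / report.
GENOTYPE_LABELS = ("wt/wt", "wt/del", "del/del")

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identifier, 1-based position and alleles."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"SNP {self.snp_id}: position must be positive")


@dataclass
class SnpGenotypeMatrix:
    """Alt-allele dosage matrix (samples x SNPs) with variant metadata.

    ``dosages`` is a float DataFrame indexed by sample id with one column
    per SNP id; entries are 0/1/2 or NaN.  ``variants`` is indexed by SNP
    id with columns ``chrom``, ``pos``, ``ref``, ``alt``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValidationError("duplicate sample ids in genotype matrix")
        if self.dosages.columns.has_duplicates:
            raise ValidationError("duplicate SNP ids in genotype matrix")
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValidationError("dosage columns and variant table disagree")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    @property
    def n_snps(self) -> int:
        return len(self.dosages.columns)

    def records(self) -> list[SnpRecord]:
        return [
            SnpRecord(sid, str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            for sid, row in self.variants.iterrows()
        ]

    def restrict(self, snp_ids: list[str]) -> "SnpGenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.dosages.columns]
        if missing:
            raise DataError(f"SNPs absent from matrix: {', '.join(missing)}")
        return SnpGenotypeMatrix(
            dosages=self.dosages[snp_ids].copy(),
            variants=self.variants.loc[snp_ids].copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample age, sex, case/control phenotype, population, ethnicity."""

    table: pd.DataFrame
    missing_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in phenotype table")
        bad_age = self.table["age"].dropna() < 0
        if bad_age.any():
            offenders = list(self.table.index[self.table["age"] < 0])
            raise ValidationError(f"negative age for samples: {offenders}")


@dataclass
class Cohort:
    """SNP genotypes, deletion calls and phenotypes joined on sample id."""

    snp_matrix: SnpGenotypeMatrix
    deletion_calls: pd.Series
    phenotypes: PhenotypeTable
    drop_report: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return self.snp_matrix.samples

    @property
    def n_samples(self) -> int:
        return self.snp_matrix.n_samples


def _parse_region(region: str) -> tuple[str, int, int]:
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValidationError(f"malformed region string {region!r}") from exc
    if start <= 0 or end < start:
        raise ValidationError(f"invalid region bounds in {region!r}")
    return chrom, start, end


def read_snp_vcf(path: str, region: str | None = None) -> SnpGenotypeMatrix:
    """Read biallelic SNP records from a VCF 4.x file into a dosage matrix.

    Dosage is the per-sample count of alt alleles in the GT field; phased
    and unphased genotypes are treated identically.  ``./.`` and half-calls
    become missing.  Non-biallelic or non-SNP records are skipped with a
    logged count.  ``region`` (``chrom:start-end``, inclusive) filters by
    position while streaming, so no index file is needed.
    """
    bounds = _parse_region(region) if region is not None else None
    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise FileNotFoundError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    snp_ids: list[str] = []
    meta: list[tuple[str, int, str, str]] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            if len(var.ALT) != 1:
                n_skipped += 1
                continue
            ref, alt = var.REF, var.ALT[0]
            if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                n_skipped += 1
                continue
            if bounds is not None:
                chrom, start, end = bounds
                if var.CHROM != chrom or not (start <= var.POS <= end):
                    continue
            snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            col = np.full(len(samples), np.nan)
            for i, gt in enumerate(var.genotypes):
                a, b = gt[0], gt[1]
                if a >= 0 and b >= 0:
                    col[i] = a + b
            snp_ids.append(snp_id)
            meta.append((var.CHROM, var.POS, ref, alt))
            columns.append(col)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad records
        raise VcfParseError(
            f"malformed VCF near record {record_no + 1} of {path}: {exc}"
        ) from exc

    if n_skipped:
        logger.info("read_snp_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError("duplicate SNP ids in VCF")
    dosages = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=snp_ids,
    )
    variants = pd.DataFrame(
        meta, index=pd.Index(snp_ids, name="snp_id"), columns=["chrom", "pos", "ref", "alt"]
    )
    return SnpGenotypeMatrix(dosages=dosages, variants=variants)


def read_deletion_calls(path: str) -> pd.Series:
    """Read a deletion-call TSV (``sample_id<TAB>genotype``) into dosages.

    Genotype labels must be ``wt/wt``, ``wt/del``, ``del/del`` or ``NA``
    (missing); any other label, or a duplicated sample id, is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "genotype"}
    if not required.issubset(df.columns):
        raise ValidationError(f"deletion-call TSV must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicated sample ids in deletion calls: {dups}")
    dosage = []
    for row_no, (sid, label) in enumerate(zip(df["sample_id"], df["genotype"]), start=2):
        if label in ("NA", ""):
            dosage.append(np.nan)
        elif label in LABEL_TO_DOSAGE:
            dosage.append(float(LABEL_TO_DOSAGE[label]))
        else:
            raise ValidationError(
                f"unknown deletion genotype {label!r} for sample {sid} (line {row_no})"
            )
    return pd.Series(dosage, index=pd.Index(df["sample_id"], name="sample_id"), name="dosage")


def write_deletion_calls(calls: pd.Series, path: str, source: str | None = None) -> None:
    """Write deletion-allele dosages as a genotype-label TSV.

    With ``source`` set (e.g. ``"imputed"``), an extra ``source`` column is
    appended to distinguish imputed from experimentally determined calls.
    """
    labels = [
        "NA" if pd.isna(d) else DOSAGE_TO_LABEL[int(d)] for d in calls.to_numpy()
    ]
    out = pd.DataFrame({"sample_id": calls.index, "genotype": labels})
    if source is not None:
        out["source"] = source
    out.to_csv(path, sep="\t", index=False)


_SEX_VALUES = {"male", "female"}
_PHENOTYPE_VALUES = {"case", "control"}


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read the phenotype/covariate TSV (sample_id, age, sex, phenotype,
    population, ethnicity); empty fields and ``NA`` become missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "age", "sex", "phenotype", "population", "ethnicity"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"phenotype TSV missing columns: {missing_cols}")
    df = df.set_index(pd.Index(df["sample_id"], name="sample_id"))

    def _clean(col: str, allowed: set[str] | None) -> pd.Series:
        s = df[col].mask(df[col].isin(("", "NA")))
        if allowed is not None:
            bad = s.dropna()[~s.dropna().isin(allowed)]
            if len(bad):
                raise ValidationError(
                    f"invalid {col} value(s): {sorted(bad.unique())} "
                    f"(allowed: {sorted(allowed)})"
                )
        return s

    table = pd.DataFrame(
        {
            "age": pd.to_numeric(_clean("age", None), errors="raise"),
            "sex": _clean("sex", _SEX_VALUES),
            "phenotype": _clean("phenotype", _PHENOTYPE_VALUES),
            "population": _clean("population", None),
            "ethnicity": _clean("ethnicity", None),
        }
    )
    report = {c: int(table[c].isna().sum()) for c in table.columns}
    logger.info("read_phenotypes: missing counts per column: %s", report)
    return PhenotypeTable(table=table, missing_report=report)


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    out = pheno.table.reset_index().copy()
    out["age"] = out["age"].map(lambda a: "" if pd.isna(a) else f"{a:g}")
    out = out.fillna("")
    out.to_csv(path, sep="\t", index=False)


def assemble_cohort(
    snp_matrix: SnpGenotypeMatrix,
    deletion_calls: pd.Series,
    phenotypes: PhenotypeTable,
) -> Cohort:
    """Inner-join the three components on sample id.

    Samples missing from any component are dropped; per-source drop counts
    are recorded in ``drop_report`` and logged.  An empty intersection is
    an error.
    """
    common = [
        s
        for s in snp_matrix.samples
        if s in deletion_calls.index and s in phenotypes.table.index
    ]
    if not common:
        raise DataError("no sample ids shared by genotypes, deletion calls and phenotypes")
    drop_report = {
        "snp_matrix": snp_matrix.n_samples - len(common),
        "deletion_calls": len(deletion_calls) - len(common),
        "phenotypes": len(phenotypes.table) - len(common),
    }
    if any(drop_report.values()):
        logger.info("assemble_cohort: dropped samples per source: %s", drop_report)
    matrix = SnpGenotypeMatrix(
        dosages=snp_matrix.dosages.loc[common].copy(),
        variants=snp_matrix.variants.copy(),
    )
    pheno = PhenotypeTable(
        table=phenotypes.table.loc[common].copy(),
        missing_report=phenotypes.missing_report,
    )
    return Cohort(
        snp_matrix=matrix,
        deletion_calls=deletion_calls.loc[common].copy(),
        phenotypes=pheno,
        drop_report=drop_report,
    )


def write_vcf(matrix: SnpGenotypeMatrix, path: str) -> None:
    """Write the dosage matrix as an uncompressed VCF 4.2 with GT fields."""
    contigs = list(dict.fromkeys(matrix.variants["chrom"]))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=deltag\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        order = matrix.variants.sort_values(["chrom", "pos"]).index
        dos = matrix.dosages
        for sid in order:
            row = matrix.variants.loc[sid]
            gts = [
                "./." if pd.isna(d) else gt_map[int(d)] for d in dos[sid].to_numpy()
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{sid}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
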