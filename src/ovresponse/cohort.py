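"""Cohort containers and I/O for clinical tables and genotype panels.

The pipeline's unit of observation is an *IVF process* (one controlled
ovarian stimulation followed by oocyte pick-up); a patient may contribute
more than one process.  Clinical covariates live in a pandas DataFrame
indexed by process id; genotypes live in a :class:`GenotypeMatrix` whose
rows are aligned to the same process ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariantDef",
    "GenotypeMatrix",
    "Cohort",
    "MIIGroupPartition",
    "CLINICAL_COLUMNS",
    "MII_BIN_LABELS",
    "read_clinical_table",
    "write_clinical_table",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "bin_mii_counts",
]


class SchemaError(ValueError):
    """A mandatory column is missing or a value cannot be parsed."""


@dataclass(frozen=True)
class VariantDef:
    """One panel variant (bi-allelic SNV identified by its dbSNP rsID)."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"{self.variant_id}: position must be positive")
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are equal")
        if self.alt_frequency is not None and not 0.0 <= self.alt_frequency <= 1.0:
            raise ValueError(f"{self.variant_id}: alt_frequency outside [0, 1]")


class GenotypeMatrix:
    """Processes x variants dosage matrix; NaN marks a missing genotype.

    Dosage is the alternative-allele count in {0, 1, 2}.  All feature
    engineering downstream collapses it to *alt-presence* (dosage > 0),
    i.e. a binary carrier indicator, via :meth:`alt_presence`.
    """

    def __init__(self, process_ids, variants, dosage):
        self.process_ids = list(process_ids)
        self.variants = list(variants)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(self.process_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.process_ids)} processes x {len(self.variants)} variants"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        self.dosage = dosage
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant_id in panel")
        self._index = {vid: j for j, vid in enumerate(ids)}

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def alt_presence(self) -> np.ndarray:
        """Binary carrier matrix (dosage > 0) with missing propagated as NaN."""
        out = (self.dosage > 0).astype(float)
        out[np.isnan(self.dosage)] = np.nan
        return out

    def alt_presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.alt_presence(), index=self.process_ids, columns=self.variant_ids
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.process_ids, columns=self.variant_ids
        )

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return GenotypeMatrix(
            self.process_ids, [self.variants[j] for j in idx], self.dosage[:, idx]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({len(self.process_ids)} processes x "
            f"{len(self.variants)} variants)"
        )


#: clinical covariates, in canonical column order; all but the first four
#: may be missing (empty cell in CSV, NaN in memory).
CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "bmi",
    "amh",
    "fsh",
    "lh",
    "e2",
    "afc_day1",
    "pcos",
    "prev_mii",
    "prev_denuded",
    "stim_days",
    "gonadotropin_dose",
    "mii_count",
    "denuded_count",
]

_MANDATORY = ["process_id", "patient_id", "age", "bmi", "amh", "pcos", "mii_count"]
_NUMERIC = [c for c in CLINICAL_COLUMNS if c not in ("patient_id", "pcos")]


@dataclass
class Cohort:
    """Aligned clinical records, MII outcomes and (optionally) genotypes."""

    clinical: pd.DataFrame  # indexed by process_id
    genotypes: GenotypeMatrix | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.clinical.columns]
        if missing:
            raise SchemaError(f"clinical table lacks column(s): {missing}")
        mii = self.clinical["mii_count"]
        if mii.isna().any() or (mii < 0).any():
            raise ValueError("every process needs a nonnegative mii_count")
        if self.genotypes is not None:
            if list(self.genotypes.process_ids) != list(self.clinical.index):
                raise ValueError("genotype rows are not aligned to clinical rows")

    @property
    def n_processes(self) -> int:
        return len(self.clinical)

    @property
    def n_patients(self) -> int:
        return self.clinical["patient_id"].nunique()

    @property
    def process_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def mii_counts(self) -> pd.Series:
        return self.clinical["mii_count"].astype(int)

    @property
    def patient_ids(self) -> pd.Series:
        return self.clinical["patient_id"]


#: MII-count group edges: [0,2], (2,4], (4,7], (7,11], (11, inf).
#: The lowest bin is closed at 2 so that the five bins are jointly
#: exhaustive over the nonnegative integers.
MII_BIN_EDGES = [-0.5, 2, 4, 7, 11, np.inf]
MII_BIN_LABELS = ["<=2", "(2,4]", "(4,7]", "(7,11]", ">11"]


@dataclass
class MIIGroupPartition:
    """Assignment of every process to one of the five MII-count groups."""

    assignment: pd.Series  # process_id -> label
    labels: list[str] = field(default_factory=lambda: list(MII_BIN_LABELS))

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().reindex(self.labels, fill_value=0)

    def processes_in(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])


def bin_mii_counts(cohort: Cohort) -> MIIGroupPartition:
    """Partition processes into the five MII-count groups.

    Groups are ``<=2``, ``(2,4]``, ``(4,7]``, ``(7,11]``, ``>11``; each
    process falls in exactly one group, so group sizes sum to cohort size.
    """
    counts = cohort.mii_counts
    if (counts < 0).any():
        raise ValueError("negative mii_count")
    cut = pd.cut(counts, bins=MII_BIN_EDGES, labels=MII_BIN_LABELS)
    return MIIGroupPartition(assignment=cut.astype(str).rename("mii_group"))


# ---------------------------------------------------------------------------
# Clinical CSV I/O


def read_clinical_table(
    path, apply_exclusions: bool = True, amh_ceiling: float = 15.0
) -> Cohort:
    """Read a per-process clinical CSV into a :class:`Cohort` (no genotypes).

    The table must carry one row per IVF process with a ``process_id``
    column and the :data:`CLINICAL_COLUMNS`.  With ``apply_exclusions``
    rows whose AMH exceeds ``amh_ceiling`` ng/mL or is missing are dropped
    (the study's exclusion rule for implausible / undetected AMH assays).
    Optional fields stay missing (NaN); nothing is imputed here.
    """
    df = pd.read_csv(path, dtype={"process_id": str, "patient_id": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table lacks mandatory column(s): {missing}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) {list(bad)}: {exc}"
            ) from None
    df["pcos"] = df["pcos"].astype(float).astype(bool)
    df = df.set_index("process_id")

    n_before = len(df)
    if apply_exclusions:
        keep = df["amh"].notna() & (df["amh"] <= amh_ceiling)
        df = df[keep]
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} of {n_before} processes "
            f"(AMH > {amh_ceiling} ng/mL or missing)",
            stacklevel=2,
        )
    return Cohort(clinical=df[CLINICAL_COLUMNS], n_excluded=n_dropped)


def write_clinical_table(cohort: Cohort, path) -> None:
    """Write the clinical table back to CSV (inverse of read, exclusions off)."""
    out = cohort.clinical.copy()
    out["pcos"] = out["pcos"].astype(int)
    out.index.name = "process_id"
    out.to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF I/O

_GT_CODE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def read_genotypes_vcf(path, panel, sample_map=None) -> GenotypeMatrix:
    """Read GT dosages for a variant panel from a VCF 4.2 file.

    ``panel`` is an ordered list of :class:`VariantDef`; variants present
    in the panel but absent from the file come back as all-missing columns
    (with a warning).  ``sample_map`` maps VCF sample names to process ids;
    by default sample names are used directly.  Multi-allelic records are
    rejected.  GT encoding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_map is not None:
        unmatched = [s for s in samples if s not in sample_map]
        if unmatched:
            raise SchemaError(f"sample-ID map misses VCF sample(s): {unmatched}")
        process_ids = [sample_map[s] for s in samples]
    else:
        process_ids = samples

    index = {(v.chrom, v.pos, v.ref, v.alt): j for j, v in enumerate(panel)}
    dosage = np.full((len(samples), len(panel)), np.nan)
    seen = np.zeros(len(panel), dtype=bool)
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise SchemaError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} is not supported"
            )
        key = (rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else None)
        j = index.get(key)
        if j is None:
            continue
        seen[j] = True
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            dosage[i, j] = _GT_CODE.get((min(a, b), max(a, b)), np.nan)
    vcf.close()
    absent = [panel[j].variant_id for j in np.nonzero(~seen)[0]]
    if absent:
        warnings.warn(
            f"{len(absent)} panel variant(s) absent from VCF, set to missing: "
            f"{absent[:5]}{'...' if len(absent) > 5 else ''}",
            stacklevel=2,
        )
    return GenotypeMatrix(process_ids, panel, dosage)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as an (unphased, uncompressed) VCF 4.2 file."""
    order = sorted(
        range(len(genotypes.variants)),
        key=lambda j: (genotypes.variants[j].chrom, genotypes.variants[j].pos),
    )
    back = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({v.chrom for v in genotypes.variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + [str(p) for p in genotypes.process_ids]))
    for j in order:
        v = genotypes.variants[j]
        gts = [back.get(d, "./.") for d in genotypes.dosage[:, j]]
        lines.append(
            "\t".join(
                [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", ".", ".", "GT"]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
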