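"""Readers and writers for mutation tables, clinical tables and gene panels.

Two mutation-table dialects are supported: a 12-column MAF-like TSV and a
minimal VCF with ``AD``-bearing TUMOR/NORMAL sample columns.  Clinical data
travel as CSV/TSV.  All times are months from the start of induction
chemotherapy; ``.`` (or an empty field) marks a missing value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "VariantClass",
    "VariantCall",
    "GenePanel",
    "OutcomeRecord",
    "FormatError",
    "ValidationError",
    "MUTATION_COLUMNS",
    "CLINICAL_COLUMNS",
    "read_mutation_table",
    "write_mutation_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_panel",
    "write_panel",
    "default_panel",
]


class FormatError(ValueError):
    """A table does not conform to the documented dialect."""


class ValidationError(ValueError):
    """Record-level invariant violations, reported per patient."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    ITD = "ITD"
    OTHER = "other"


@dataclass
class VariantCall:
    """One candidate somatic variant with allele depths and annotation flags.

    ``known_somatic_flag`` stands in for COSMIC/ClinVar support,
    ``germline_suspect_flag`` for dbSNP/esp6500 membership, and
    ``control_free_somatic_flag`` for an upstream control-free somatic call
    (made when no matched normal exists).  ``biallelic_annotation`` marks a
    variant explicitly reported as part of a biallelic (double-mutant) pair.
    """

    patient_id: str
    gene: str
    variant_class: VariantClass
    tumor_ref_depth: int
    tumor_alt_depth: int
    protein_change: str | None = None
    normal_ref_depth: int | None = None
    normal_alt_depth: int | None = None
    known_somatic_flag: bool = False
    germline_suspect_flag: bool = False
    control_free_somatic_flag: bool = False
    biallelic_annotation: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not self.gene:
            raise ValidationError("gene must be non-empty")
        self.gene = self.gene.strip().upper()
        if isinstance(self.variant_class, str) and not isinstance(
            self.variant_class, VariantClass
        ):
            self.variant_class = VariantClass(self.variant_class)
        for name in ("tumor_ref_depth", "tumor_alt_depth"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("normal_ref_depth", "normal_alt_depth"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def has_control(self) -> bool:
        return self.normal_ref_depth is not None and self.normal_alt_depth is not None

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref_depth + self.tumor_alt_depth

    @property
    def vaf(self) -> float:
        """Tumor variant-allele fraction, alt / (ref + alt)."""
        if self.tumor_depth == 0:
            raise ValidationError(
                f"{self.patient_id}/{self.gene}: zero tumor depth, VAF undefined"
            )
        return self.tumor_alt_depth / self.tumor_depth


# The nine chromatin-modifier / RNA-splicing ("chromatin-spliceosome") genes
# whose drivers define the corresponding genomic subgroup.
CHROMATIN_SPLICEOSOME_GENES: tuple[str, ...] = (
    "RUNX1",
    "ASXL1",
    "BCOR",
    "STAG2",
    "EZH2",
    "SRSF2",
    "SF3B1",
    "U2AF1",
    "ZRSR2",
)

_DEFAULT_OTHER_DRIVERS: tuple[str, ...] = (
    "NPM1",
    "FLT3",
    "DNMT3A",
    "IDH1",
    "IDH2",
    "NRAS",
    "CEBPA",
    "TET2",
    "TP53",
)


@dataclass(frozen=True)
class GenePanel:
    """The driver-gene panel plus its chromatin/spliceosome subset.

    Gene symbols are matched case-insensitively after trimming.  The default
    panel carries the recurrently mutated genes of a normal-karyotype AML
    targeted-sequencing design; site-specific panels load from a plain-text
    config (one gene per line, ``[drivers]`` / ``[chromatin_spliceosome]``
    section headers).
    """

    driver_genes: frozenset[str]
    chromatin_spliceosome_genes: tuple[str, ...] = CHROMATIN_SPLICEOSOME_GENES

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "driver_genes", frozenset(g.strip().upper() for g in self.driver_genes)
        )
        object.__setattr__(
            self,
            "chromatin_spliceosome_genes",
            tuple(g.strip().upper() for g in self.chromatin_spliceosome_genes),
        )
        missing = set(self.chromatin_spliceosome_genes) - self.driver_genes
        if missing:
            raise ValidationError(
                "chromatin/spliceosome genes missing from driver panel: "
                + ", ".join(sorted(missing))
            )

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.driver_genes

    @property
    def chromatin_spliceosome_set(self) -> frozenset[str]:
        return frozenset(self.chromatin_spliceosome_genes)


def default_panel() -> GenePanel:
    return GenePanel(
        driver_genes=frozenset(_DEFAULT_OTHER_DRIVERS) | set(CHROMATIN_SPLICEOSOME_GENES),
        chromatin_spliceosome_genes=CHROMATIN_SPLICEOSOME_GENES,
    )


@dataclass
class OutcomeRecord:
    """Raw clinical fields for one patient; times in months from induction."""

    patient_id: str
    age: float
    sex: str  # "M" / "F"
    wbc: float  # x10^9/L
    bm_blast_pct: float
    cr_achieved: bool
    last_followup_time: float
    cr_time: float | None = None
    sct_time: float | None = None
    relapse_time: float | None = None
    death_time: float | None = None

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        msgs = []
        if self.sex not in ("M", "F"):
            msgs.append(f"sex must be M or F, got {self.sex!r}")
        times = {
            "cr_time": self.cr_time,
            "sct_time": self.sct_time,
            "relapse_time": self.relapse_time,
            "death_time": self.death_time,
            "last_followup_time": self.last_followup_time,
        }
        for name, t in times.items():
            if t is not None and t < 0:
                msgs.append(f"{name} is negative ({t})")
        if self.relapse_time is not None and not self.cr_achieved:
            msgs.append("relapse_time present but CR was never achieved")
        if self.cr_achieved and self.cr_time is None:
            msgs.append("cr_achieved without cr_time")
        if (
            self.cr_time is not None
            and self.relapse_time is not None
            and self.cr_time > self.relapse_time
        ):
            msgs.append(
                f"cr_time {self.cr_time} exceeds relapse_time {self.relapse_time}"
            )
        present = [t for t in times.values() if t is not None]
        if present and self.last_followup_time < max(present) - 1e-9:
            msgs.append("last_followup_time precedes a recorded event time")
        return msgs


MUTATION_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "gene",
    "variant_class",
    "protein_change",
    "tumor_ref_depth",
    "tumor_alt_depth",
    "normal_ref_depth",
    "normal_alt_depth",
    "known_somatic_flag",
    "germline_suspect_flag",
    "control_free_somatic_flag",
    "biallelic_annotation",
)

CLINICAL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "wbc",
    "bm_blast_pct",
    "cr_achieved",
    "cr_time",
    "sct_time",
    "relapse_time",
    "death_time",
    "last_followup_time",
)

_MISSING = "."


def _fmt(value) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_bool(text: str, column: str, line: int) -> bool:
    if text in ("1", "true", "True", "TRUE"):
        return True
    if text in ("0", "false", "False", "FALSE"):
        return False
    raise FormatError(f"line {line}: column {column!r}: not a boolean: {text!r}")


def _parse_depth(text: str, column: str, line: int) -> int | None:
    if text == _MISSING or text == "":
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(
            f"line {line}: column {column!r}: unparseable depth {text!r}"
        ) from exc


def _read_mutation_tsv(path: Path) -> list[VariantCall]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        warnings.warn(f"{path}: empty mutation table", stacklevel=3)
        return []
    header = lines[0].split("\t")
    missing_cols = [c for c in MUTATION_COLUMNS if c not in header]
    if missing_cols:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing_cols)}"
        )
    idx = {c: header.index(c) for c in MUTATION_COLUMNS}
    out: list[VariantCall] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        get = lambda c: parts[idx[c]]
        t_ref = _parse_depth(get("tumor_ref_depth"), "tumor_ref_depth", lineno)
        t_alt = _parse_depth(get("tumor_alt_depth"), "tumor_alt_depth", lineno)
        if t_ref is None or t_alt is None:
            raise FormatError(
                f"{path}: line {lineno}: tumor depths are mandatory, got missing value"
            )
        pc = get("protein_change")
        out.append(
            VariantCall(
                patient_id=get("patient_id"),
                gene=get("gene"),
                variant_class=VariantClass(get("variant_class")),
                protein_change=None if pc in (_MISSING, "") else pc,
                tumor_ref_depth=t_ref,
                tumor_alt_depth=t_alt,
                normal_ref_depth=_parse_depth(
                    get("normal_ref_depth"), "normal_ref_depth", lineno
                ),
                normal_alt_depth=_parse_depth(
                    get("normal_alt_depth"), "normal_alt_depth", lineno
                ),
                known_somatic_flag=_parse_bool(
                    get("known_somatic_flag"), "known_somatic_flag", lineno
                ),
                germline_suspect_flag=_parse_bool(
                    get("germline_suspect_flag"), "germline_suspect_flag", lineno
                ),
                control_free_somatic_flag=_parse_bool(
                    get("control_free_somatic_flag"), "control_free_somatic_flag", lineno
                ),
                biallelic_annotation=_parse_bool(
                    get("biallelic_annotation"), "biallelic_annotation", lineno
                ),
            )
        )
    return out


_VCF_CLASS_KEY = "VCLASS"


def _read_mutation_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if "TUMOR" not in samples:
        raise FormatError(f"{path}: VCF must carry a TUMOR sample column")
    i_t = samples.index("TUMOR")
    i_n = samples.index("NORMAL") if "NORMAL" in samples else None
    out: list[VariantCall] = []
    for rec in vcf:
        info = dict(rec.INFO)
        gene = info.get("GENE")
        if gene is None:
            raise FormatError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks INFO/GENE")
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record at {rec.CHROM}:{rec.POS} lacks per-sample AD"
            )
        t_ref, t_alt = int(ad[i_t][0]), int(ad[i_t][1])
        n_ref = n_alt = None
        if i_n is not None and ad[i_n][0] >= 0:
            n_ref, n_alt = int(ad[i_n][0]), int(ad[i_n][1])
        out.append(
            VariantCall(
                patient_id=info.get("PATIENT", ""),
                gene=gene,
                variant_class=VariantClass(info.get(_VCF_CLASS_KEY, "other")),
                protein_change=info.get("PCHANGE"),
                tumor_ref_depth=t_ref,
                tumor_alt_depth=t_alt,
                normal_ref_depth=n_ref,
                normal_alt_depth=n_alt,
                known_somatic_flag="KNOWN_SOMATIC" in info,
                germline_suspect_flag="GERMLINE_SUSPECT" in info,
                control_free_somatic_flag="CF_SOMATIC" in info,
                biallelic_annotation="BIALLELIC" in info,
            )
        )
    return out


def read_mutation_table(path: str | Path, format: str = "maf_tsv") -> list[VariantCall]:
    """Read a mutation table; ``format`` is ``maf_tsv`` or ``vcf_like``.

    Output order equals input order.  Rows with unparseable depths raise a
    :class:`FormatError` naming the offending line rather than being dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "maf_tsv":
        return _read_mutation_tsv(path)
    if format == "vcf_like":
        return _read_mutation_vcf(path)
    raise ValueError(f"unknown mutation-table format: {format!r}")


def write_mutation_table(variants: Iterable[VariantCall], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MUTATION_COLUMNS) + "\n")
        for v in variants:
            row = [
                v.patient_id,
                v.gene,
                v.variant_class.value,
                _fmt(v.protein_change),
                str(v.tumor_ref_depth),
                str(v.tumor_alt_depth),
                _fmt(v.normal_ref_depth),
                _fmt(v.normal_alt_depth),
                _fmt(v.known_somatic_flag),
                _fmt(v.germline_suspect_flag),
                _fmt(v.control_free_somatic_flag),
                _fmt(v.biallelic_annotation),
            ]
            fh.write("\t".join(row) + "\n")


def _to_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in (_MISSING, ""):
            return None
    return float(value)


def read_clinical_table(path: str | Path, strict: bool = True) -> list[OutcomeRecord]:
    """Read a clinical CSV/TSV into validated :class:`OutcomeRecord` rows.

    With ``strict`` (default) any invariant violation raises a
    :class:`ValidationError` whose message lists every offending patient_id;
    otherwise violations are emitted as warnings and the records returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing_cols)}"
        )
    records: list[OutcomeRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            rec = OutcomeRecord(
                patient_id=pid,
                age=float(row["age"]),
                sex=str(row["sex"]).strip().upper(),
                wbc=float(row["wbc"]),
                bm_blast_pct=float(row["bm_blast_pct"]),
                cr_achieved=_parse_bool(str(row["cr_achieved"]).strip(), "cr_achieved", i + 2),
                cr_time=_to_float(row["cr_time"]),
                sct_time=_to_float(row["sct_time"]),
                relapse_time=_to_float(row["relapse_time"]),
                death_time=_to_float(row["death_time"]),
                last_followup_time=float(row["last_followup_time"]),
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: patient {pid}: {exc}") from exc
        for msg in rec.validate():
            problems.append(f"{pid}: {msg}")
        records.append(rec)
    if problems:
        report = "; ".join(problems)
        if strict:
            raise ValidationError(f"{path}: invalid clinical records: {report}")
        warnings.warn(f"{path}: invalid clinical records: {report}", stacklevel=2)
    return records


def write_clinical_table(records: Iterable[OutcomeRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(CLINICAL_COLUMNS) + "\n")
        for r in records:
            row = [
                r.patient_id,
                _fmt(r.age),
                r.sex,
                _fmt(r.wbc),
                _fmt(r.bm_blast_pct),
                _fmt(r.cr_achieved),
                _fmt(r.cr_time),
                _fmt(r.sct_time),
                _fmt(r.relapse_time),
                _fmt(r.death_time),
                _fmt(r.last_followup_time),
            ]
            fh.write(sep.join(row) + "\n")


def read_panel(path: str | Path) -> GenePanel:
    """Parse a plain-text panel config (one gene per line, ``[section]`` headers)."""
    drivers: list[str] = []
    chromatin: list[str] = []
    section = "drivers"
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("drivers", "chromatin_spliceosome"):
                raise FormatError(f"{path}: unknown panel section {section!r}")
            continue
        (drivers if section == "drivers" else chromatin).append(line.upper())
    chromatin_t = tuple(chromatin) if chromatin else CHROMATIN_SPLICEOSOME_GENES
    return GenePanel(
        driver_genes=frozenset(drivers) | set(chromatin_t),
        chromatin_spliceosome_genes=chromatin_t,
    )


def write_panel(panel: GenePanel, path: str | Path) -> None:
    chrom = set(panel.chromatin_spliceosome_genes)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("[drivers]\n")
        for g in sorted(panel.driver_genes - chrom):
            fh.write(g + "\n")
        fh.write("[chromatin_spliceosome]\n")
        for g in panel.chromatin_spliceosome_genes:
            fh.write(g + "\n")
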