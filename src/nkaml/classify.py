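"""Eight-way genomic classification of normal-karyotype AML patients.

Class-defining lesions: NPM1 mutation; any driver in the nine
chromatin-modifier/RNA-splicing genes; TP53 mutation; biallelic CEBPA;
IDH2 codon-172 hotspot (only when no other class-defining lesion fires).
Patients matching two or more lesions fall into the multi-class bin;
patients with drivers but no lesion, and patients with no driver at all,
get their own bins.  FLT3-ITD and the other recurrent drivers (DNMT3A,
TET2, NRAS, IDH1, IDH2-R140, ...) are recorded but never class-defining.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .filters import PatientProfile
from .io import GenePanel

__all__ = [
    "GenomicLabel",
    "Lesion",
    "GenomicClass",
    "class_defining_lesions",
    "classify_patient",
    "classify_cohort",
    "CLASS_ORDER",
]


class GenomicLabel(str, Enum):
    NPM1 = "NPM1"
    CHROMATIN_SPLICE = "CHROMATIN_SPLICE"
    TP53 = "TP53"
    BIALLELIC_CEBPA = "BIALLELIC_CEBPA"
    IDH2_R172 = "IDH2_R172"
    DRIVER_NO_CLASS = "DRIVER_NO_CLASS"
    NO_DRIVER = "NO_DRIVER"
    MULTI_CLASS = "MULTI_CLASS"


class Lesion(str, Enum):
    NPM1 = "NPM1"
    CHROMATIN_SPLICE = "CHROMATIN_SPLICE"
    TP53 = "TP53"
    BIALLELIC_CEBPA = "BIALLELIC_CEBPA"
    IDH2_R172 = "IDH2_R172"


# Table-row order used for cohort summaries.
CLASS_ORDER: tuple[GenomicLabel, ...] = (
    GenomicLabel.NPM1,
    GenomicLabel.CHROMATIN_SPLICE,
    GenomicLabel.TP53,
    GenomicLabel.BIALLELIC_CEBPA,
    GenomicLabel.IDH2_R172,
    GenomicLabel.DRIVER_NO_CLASS,
    GenomicLabel.NO_DRIVER,
    GenomicLabel.MULTI_CLASS,
)


@dataclass(frozen=True)
class GenomicClass:
    label: GenomicLabel
    matched_lesions: frozenset[Lesion]

    def __post_init__(self) -> None:
        if self.label is GenomicLabel.MULTI_CLASS:
            assert len(self.matched_lesions) >= 2
        if self.label in (GenomicLabel.DRIVER_NO_CLASS, GenomicLabel.NO_DRIVER):
            assert not self.matched_lesions


def class_defining_lesions(p: PatientProfile, panel: GenePanel) -> frozenset[Lesion]:
    """The set of class-defining lesions a profile carries.

    The IDH2-R172 lesion is subordinate: it fires only when no other lesion
    does, so it can never contribute to a multi-class assignment.
    """
    lesions: set[Lesion] = set()
    if "NPM1" in p.mutated_genes:
        lesions.add(Lesion.NPM1)
    if p.mutated_genes & panel.chromatin_spliceosome_set:
        lesions.add(Lesion.CHROMATIN_SPLICE)
    if "TP53" in p.mutated_genes:
        lesions.add(Lesion.TP53)
    if p.biallelic_cebpa:
        lesions.add(Lesion.BIALLELIC_CEBPA)
    if p.idh2_r172 and not lesions:
        lesions.add(Lesion.IDH2_R172)
    return frozenset(lesions)


def classify_patient(p: PatientProfile, panel: GenePanel) -> GenomicClass:
    lesions = class_defining_lesions(p, panel)
    if len(lesions) >= 2:
        label = GenomicLabel.MULTI_CLASS
    elif len(lesions) == 1:
        label = GenomicLabel(next(iter(lesions)).value)
    elif p.n_driver_mutations >= 1:
        label = GenomicLabel.DRIVER_NO_CLASS
    else:
        label = GenomicLabel.NO_DRIVER
    return GenomicClass(label=label, matched_lesions=lesions)


def classify_cohort(
    profiles: Sequence[PatientProfile], panel: GenePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every profile; return (per-patient table, count summary).

    The summary lists every class in table order with its count and its
    percentage of the cohort to one decimal; counts sum to the cohort size.
    """
    seen: set[str] = set()
    rows = []
    for p in profiles:
        if p.patient_id in seen:
            raise ValueError(f"duplicate patient_id: {p.patient_id}")
        seen.add(p.patient_id)
        gc = classify_patient(p, panel)
        rows.append(
            {
                "patient_id": p.patient_id,
                "label": gc.label.value,
                "matched_lesions": ",".join(sorted(l.value for l in gc.matched_lesions)),
                "n_driver_mutations": p.n_driver_mutations,
            }
        )
    per_patient = pd.DataFrame(
        rows, columns=["patient_id", "label", "matched_lesions", "n_driver_mutations"]
    )
    n = len(per_patient)
    counts = per_patient["label"].value_counts() if n else pd.Series(dtype=int)
    summary = pd.DataFrame(
        {
            "label": [c.value for c in CLASS_ORDER],
            "count": [int(counts.get(c.value, 0)) for c in CLASS_ORDER],
        }
    )
    summary["percent"] = (
        (100.0 * summary["count"] / n).round(1) if n else 0.0
    )
    return per_patient, summary
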