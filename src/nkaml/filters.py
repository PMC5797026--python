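"""Somatic variant retention: Fisher tumor-vs-control test, VAF floor,
database-flag filtering, and per-patient driver-profile construction.

A candidate variant is retained when, in order:

1. its gene is on the driver panel,
2. tumor VAF >= 3% (inclusive floor),
3. it is not flagged as a germline suspect (dbSNP/esp6500 stand-in),
4. there is somatic evidence: with a matched control, two-sided Fisher
   p < 0.001 on the 2x2 ref/alt x tumor/control table; without a control,
   the upstream control-free somatic call must be positive.

The rule order fixes which reason code a failing variant receives.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import GenePanel, VariantCall

__all__ = [
    "FilterReason",
    "FilterDecision",
    "PatientProfile",
    "fisher_two_sided",
    "apply_filter",
    "filter_variants",
    "build_profiles",
    "DEFAULT_VAF_MIN",
    "DEFAULT_P_MAX",
]

DEFAULT_VAF_MIN = 0.03
DEFAULT_P_MAX = 0.001

# Relative guard for probability-mass ties in the two-sided tail: tables whose
# pmf equals the observed one up to floating error are counted in the tail.
_TIE_GUARD = 1e-10


class FilterReason(str, Enum):
    PASS = "pass"
    NOT_IN_PANEL = "not_in_panel"
    BELOW_VAF = "below_vaf"
    GERMLINE_SUSPECT = "germline_suspect"
    FISHER_NS = "fisher_ns"
    CONTROL_FREE_FAIL = "control_free_fail"


@dataclass(frozen=True)
class FilterDecision:
    variant: VariantCall
    vaf: float
    retained: bool
    reason: FilterReason
    fisher_p: float | None = None

    def __post_init__(self) -> None:
        assert self.retained == (self.reason is FilterReason.PASS)


def fisher_two_sided(t_ref: int, t_alt: int, n_ref: int, n_alt: int) -> float:
    """Two-sided Fisher exact p for the 2x2 ref/alt x tumor/control table.

    Probability-mass definition: the p-value sums the hypergeometric
    probabilities of every table (with the observed margins) whose
    probability does not exceed that of the observed table.
    """
    counts = (t_ref, t_alt, n_ref, n_alt)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if all(c == 0 for c in counts):
        raise ValueError("all four counts are zero: table undefined")
    total = sum(counts)
    alt_total = t_alt + n_alt
    tumor_total = t_ref + t_alt
    lo = max(0, tumor_total + alt_total - total)
    hi = min(alt_total, tumor_total)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, alt_total, tumor_total)
    p_obs = pmf[t_alt - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_GUARD)].sum())
    return min(p, 1.0)


def apply_filter(
    v: VariantCall,
    panel: GenePanel,
    vaf_min: float = DEFAULT_VAF_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> FilterDecision:
    """Decide retention of one variant; the first failing rule names the reason."""
    if v.tumor_depth == 0:
        raise ValueError(f"{v.patient_id}/{v.gene}: zero tumor depth")
    vaf = v.vaf
    fisher_p = None
    if v.has_control:
        fisher_p = fisher_two_sided(
            v.tumor_ref_depth, v.tumor_alt_depth, v.normal_ref_depth, v.normal_alt_depth
        )

    def decide(reason: FilterReason) -> FilterDecision:
        return FilterDecision(
            variant=v,
            vaf=vaf,
            retained=reason is FilterReason.PASS,
            reason=reason,
            fisher_p=fisher_p,
        )

    if v.gene not in panel:
        return decide(FilterReason.NOT_IN_PANEL)
    if vaf < vaf_min:  # 3% floor is inclusive
        return decide(FilterReason.BELOW_VAF)
    if v.germline_suspect_flag:
        return decide(FilterReason.GERMLINE_SUSPECT)
    if v.has_control:
        if not fisher_p < p_max:  # p = p_max fails: threshold is strict
            return decide(FilterReason.FISHER_NS)
    elif not v.control_free_somatic_flag:
        return decide(FilterReason.CONTROL_FREE_FAIL)
    return decide(FilterReason.PASS)


def filter_variants(
    variants: Iterable[VariantCall],
    panel: GenePanel,
    vaf_min: float = DEFAULT_VAF_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[FilterDecision]:
    return [apply_filter(v, panel, vaf_min, p_max) for v in variants]


_IDH2_R172_MARK = "R172"


@dataclass
class PatientProfile:
    """A patient's retained driver mutations plus derived lesion flags."""

    patient_id: str
    mutated_genes: frozenset[str]
    n_driver_mutations: int
    biallelic_cebpa: bool = False
    idh2_r172: bool = False
    flt3_itd: bool = False

    def __post_init__(self) -> None:
        if (self.n_driver_mutations == 0) != (not self.mutated_genes):
            raise ValueError(
                f"{self.patient_id}: zero driver mutations iff no mutated genes"
            )


def _is_idh2_r172(v: VariantCall) -> bool:
    pc = (v.protein_change or "").upper().replace("P.", "")
    return v.gene == "IDH2" and pc.startswith(_IDH2_R172_MARK)


def _variant_key(v: VariantCall) -> tuple:
    return (
        v.patient_id,
        v.gene,
        v.variant_class,
        v.protein_change,
        v.tumor_ref_depth,
        v.tumor_alt_depth,
    )


def build_profiles(
    variants: Sequence[VariantCall],
    panel: GenePanel,
    patient_ids: Sequence[str] | None = None,
) -> list[PatientProfile]:
    """Aggregate filter-retained variants into one profile per patient.

    ``patient_ids``, when given, fixes the output roster and order so that
    patients with no retained variant still receive an (empty) profile.
    Duplicate identical variant rows are deduplicated with a warning.
    Derived flags: biallelic CEBPA (two distinct retained CEBPA variants or an
    explicit biallelic annotation), IDH2 codon-172 hotspot, FLT3-ITD.
    """
    by_patient: "OrderedDict[str, list[VariantCall]]" = OrderedDict()
    if patient_ids is not None:
        for pid in patient_ids:
            if pid in by_patient:
                raise ValueError(f"duplicate patient_id in roster: {pid}")
            by_patient[pid] = []
    for v in variants:
        if patient_ids is not None and v.patient_id not in by_patient:
            raise ValueError(f"variant for unknown patient {v.patient_id}")
        by_patient.setdefault(v.patient_id, []).append(v)

    profiles = []
    for pid, vs in by_patient.items():
        seen: set[tuple] = set()
        uniq: list[VariantCall] = []
        for v in vs:
            key = _variant_key(v)
            if key in seen:
                warnings.warn(
                    f"patient {pid}: duplicate variant row for {v.gene} dropped",
                    stacklevel=2,
                )
                continue
            seen.add(key)
            uniq.append(v)
        cebpa = [v for v in uniq if v.gene == "CEBPA"]
        distinct_cebpa = {(v.protein_change, v.variant_class) for v in cebpa}
        profiles.append(
            PatientProfile(
                patient_id=pid,
                mutated_genes=frozenset(v.gene for v in uniq),
                n_driver_mutations=len(uniq),
                biallelic_cebpa=len(distinct_cebpa) >= 2
                or any(v.biallelic_annotation for v in cebpa),
                idh2_r172=any(_is_idh2_r172(v) for v in uniq),
                flt3_itd=any(
                    v.gene == "FLT3" and v.variant_class.value == "ITD" for v in uniq
                ),
            )
        )
    return profiles
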