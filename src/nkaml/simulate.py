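"""Synthetic normal-karyotype AML cohort generator.

Emulates a 393-patient NK-AML cohort: each patient draws a genomic subgroup
from the cohort's subgroup prevalences, receives the class-defining
lesion(s) for that subgroup (so the classifier recovers the planted label
exactly), plus independent non-class-defining co-mutations at their
marginal frequencies, and then clinical outcomes (CR, allogeneic SCT,
relapse, death) calibrated to the subgroup's CR rate, SCT rate, 5-year OS
and 5-year relapse rate.

Hazards are exponential (constant in time), calibrated only at the 5-year
point: the monthly death rate lambda_os is solved so the class-marginal
survival (CR patients are event-free until the CR date, then die at
lambda_os; non-CR patients die at lambda_os from induction) hits S(60) =
the 5-year OS, and for CR patients relapse competes with
death-without-relapse at rates (lambda_1, lambda_os), with lambda_1 solved
from CIF_1(60) = lambda_1/(lambda_1+lambda_os) *
(1 - exp(-(lambda_1+lambda_os)*60)) = target 5-year relapse.  Because the
death hazard is the same before and after relapse, all-cause survival after
CR stays exponential at lambda_os, so both calibration targets hold at
once.  This is a modelling stand-in for the real cohort, not an estimate of
it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import GenomicLabel
from .io import (
    OutcomeRecord,
    VariantCall,
    VariantClass,
    write_clinical_table,
    write_mutation_table,
)

__all__ = [
    "ClassParams",
    "SimConfig",
    "CohortBundle",
    "sample_mutation_profile",
    "sample_outcomes",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ClassParams:
    """Per-subgroup simulation parameters (rates as fractions, times in months)."""

    cr_prob: float
    sct_prob: float
    five_year_os: float
    five_year_relapse: float
    male_frac: float
    age_median: float
    age_range: tuple[float, float]
    wbc_median: float
    wbc_range: tuple[float, float]
    blast_median: float
    blast_range: tuple[float, float]

    def validate(self) -> None:
        for name in ("cr_prob", "sct_prob", "male_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if not 0.0 < self.five_year_os <= 1.0:
            raise ValueError(
                f"five_year_os must lie in (0,1], got {self.five_year_os}"
            )
        if not 0.0 <= self.five_year_relapse < 1.0:
            raise ValueError(
                f"five_year_relapse must lie in [0,1), got {self.five_year_relapse}"
            )
        # competing-risk feasibility: relapse CIF plus death-without-relapse
        # CIF can never exceed one; with the coupled exponential rates this
        # bound is exp(-(l1+l2)*60) away from saturation
        l2 = os_rate(self.five_year_os)
        l1 = relapse_rate(self.five_year_relapse, l2)
        total = 1.0 - math.exp(-(l1 + l2) * 60.0) if (l1 + l2) > 0 else 0.0
        if total > 1.0 + 1e-9:
            raise ValueError("infeasible 5-year relapse / survival combination")


def os_rate(five_year_os: float) -> float:
    """Monthly all-cause death rate hitting S(60) = five_year_os."""
    if not 0.0 < five_year_os <= 1.0:
        raise ValueError("five_year_os must lie in (0, 1]")
    return 0.0 if five_year_os == 1.0 else -math.log(five_year_os) / 60.0


@lru_cache(maxsize=None)
def calibrated_death_rate(
    five_year_os: float,
    cr_prob: float,
    cr_lo: float,
    cr_hi: float,
) -> float:
    """Death rate whose class-marginal survival hits S(60) = five_year_os.

    Patients who reach CR are event-free until the CR date c (uniform on
    [cr_lo, cr_hi]) and die at rate lambda thereafter, so the class marginal
    is S(t) = e^{-lambda t} [cr_prob E(e^{lambda c}) + 1 - cr_prob]; lambda
    is solved so that mixture, not the naive -ln(S5)/60, meets the target.
    """
    if not 0.0 < five_year_os <= 1.0:
        raise ValueError("five_year_os must lie in (0, 1]")
    if five_year_os == 1.0:
        return 0.0

    def mean_exp_c(lam: float) -> float:
        if lam == 0.0 or cr_hi == cr_lo:
            return math.exp(lam * (cr_lo + cr_hi) / 2.0)
        return (math.exp(lam * cr_hi) - math.exp(lam * cr_lo)) / (lam * (cr_hi - cr_lo))

    def f(lam: float) -> float:
        mix = cr_prob * mean_exp_c(lam) + (1.0 - cr_prob)
        return math.exp(-60.0 * lam) * mix - five_year_os

    return float(brentq(f, 0.0, 1.0, xtol=1e-14))


@lru_cache(maxsize=None)
def relapse_rate(five_year_relapse: float, death_rate: float) -> float:
    """Relapse rate solving CIF_1(60) = target against a competing death rate."""
    if not 0.0 <= five_year_relapse < 1.0:
        raise ValueError("five_year_relapse must lie in [0, 1)")
    if five_year_relapse == 0.0:
        return 0.0

    def cif60(l1: float) -> float:
        tot = l1 + death_rate
        return l1 / tot * (1.0 - math.exp(-tot * 60.0))

    hi = 10.0
    if cif60(hi) < five_year_relapse:
        raise ValueError("infeasible five_year_relapse target")
    return float(brentq(lambda l: cif60(l) - five_year_relapse, 1e-12, hi, xtol=1e-14))


# Defaults mirror a published 393-patient NK-AML cohort: subgroup prevalences, per-subgroup CR /
# SCT rates, 5-year OS and relapse, demographics (median + range), and the
# marginal frequencies of the recurrent non-class-defining co-mutations.
_COUNTS: dict[GenomicLabel, int] = {
    GenomicLabel.NPM1: 136,
    GenomicLabel.CHROMATIN_SPLICE: 42,
    GenomicLabel.TP53: 6,
    GenomicLabel.BIALLELIC_CEBPA: 53,
    GenomicLabel.IDH2_R172: 8,
    GenomicLabel.DRIVER_NO_CLASS: 116,
    GenomicLabel.NO_DRIVER: 17,
    GenomicLabel.MULTI_CLASS: 15,
}

_DEFAULT_CLASS_PARAMS: dict[GenomicLabel, ClassParams] = {
    GenomicLabel.NPM1: ClassParams(
        cr_prob=118 / 136, sct_prob=46 / 136, five_year_os=0.493,
        five_year_relapse=0.403, male_frac=58 / 136,
        age_median=54, age_range=(15, 84),
        wbc_median=41.7, wbc_range=(0.9, 384.0),
        blast_median=79, blast_range=(3, 100),
    ),
    GenomicLabel.CHROMATIN_SPLICE: ClassParams(
        cr_prob=26 / 42, sct_prob=6 / 42, five_year_os=0.116,
        five_year_relapse=0.714, male_frac=32 / 42,
        age_median=59, age_range=(19, 76),
        wbc_median=12.6, wbc_range=(0.5, 397.2),
        blast_median=60, blast_range=(10, 100),
    ),
    GenomicLabel.TP53: ClassParams(
        cr_prob=5 / 6, sct_prob=3 / 6, five_year_os=0.500,
        five_year_relapse=0.200, male_frac=3 / 6,
        age_median=39, age_range=(22, 54),
        wbc_median=8.8, wbc_range=(2.0, 120.7),
        blast_median=48, blast_range=(16, 100),
    ),
    GenomicLabel.BIALLELIC_CEBPA: ClassParams(
        cr_prob=50 / 53, sct_prob=30 / 53, five_year_os=0.584,
        five_year_relapse=0.213, male_frac=22 / 53,
        age_median=40, age_range=(15, 72),
        wbc_median=28.5, wbc_range=(4.5, 333.2),
        blast_median=70, blast_range=(16, 100),
    ),
    GenomicLabel.IDH2_R172: ClassParams(
        cr_prob=7 / 8, sct_prob=3 / 8, five_year_os=0.563,
        five_year_relapse=0.214, male_frac=6 / 8,
        age_median=58, age_range=(51, 64),
        wbc_median=1.6, wbc_range=(0.5, 8.6),
        blast_median=72, blast_range=(56, 100),
    ),
    GenomicLabel.DRIVER_NO_CLASS: ClassParams(
        cr_prob=91 / 116, sct_prob=33 / 116, five_year_os=0.243,
        five_year_relapse=0.539, male_frac=62 / 116,
        age_median=50, age_range=(17, 83),
        wbc_median=23.7, wbc_range=(0.5, 279.0),
        blast_median=68, blast_range=(2, 100),
    ),
    GenomicLabel.NO_DRIVER: ClassParams(
        cr_prob=16 / 17, sct_prob=6 / 17, five_year_os=0.294,
        five_year_relapse=0.438, male_frac=8 / 17,
        age_median=41, age_range=(23, 69),
        wbc_median=2.5, wbc_range=(0.3, 121.0),
        blast_median=79, blast_range=(12, 100),
    ),
    GenomicLabel.MULTI_CLASS: ClassParams(
        cr_prob=12 / 15, sct_prob=2 / 15, five_year_os=0.400,
        five_year_relapse=0.333, male_frac=10 / 15,
        age_median=59, age_range=(16, 75),
        wbc_median=13.9, wbc_range=(1.2, 142.0),
        blast_median=69, blast_range=(23, 100),
    ),
}

_DEFAULT_CO_MUTATIONS: dict[str, float] = {
    "FLT3": 0.349,
    "DNMT3A": 0.316,
    "NRAS": 0.183,
    "TET2": 0.102,
}


def _default_class_probs() -> dict[GenomicLabel, float]:
    n = sum(_COUNTS.values())
    return {lab: c / n for lab, c in _COUNTS.items()}


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 393
    seed: int = 0
    class_probs: Mapping[GenomicLabel, float] = field(
        default_factory=_default_class_probs
    )
    per_class: Mapping[GenomicLabel, ClassParams] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PARAMS)
    )
    co_mutation_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CO_MUTATIONS)
    )
    followup_horizon: float = 120.0  # months
    cr_time_range: tuple[float, float] = (0.9, 2.0)
    vaf_range: tuple[float, float] = (0.05, 0.5)
    control_missing_prob: float = 0.3  # variants with no matched normal

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs must sum to 1, got {total}")
        for lab, p in self.class_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class probability out of [0,1] for {lab}")
        for lab, cp in self.per_class.items():
            try:
                cp.validate()
            except ValueError as exc:
                raise ValueError(f"{lab.value}: {exc}") from exc
        for g, f in self.co_mutation_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"co-mutation frequency out of [0,1] for {g}")


_CHROMATIN_GENES = (
    "RUNX1", "ASXL1", "BCOR", "STAG2", "EZH2", "SRSF2", "SF3B1", "U2AF1", "ZRSR2",
)

# lesions eligible for the >=2-subgroup bin (the IDH2-R172 class is defined
# by the absence of any other lesion, so it cannot co-occur)
_MULTI_ELIGIBLE = ("NPM1", "CHROMATIN", "TP53", "CEBPA_BI")


def _draw_depths(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[int, int, int | None, int | None, bool]:
    """Tumor/normal allele depths for a planted somatic variant.

    Deep targeted coverage; alt counts are floored so the variant clears the
    3% VAF filter and, when a clean matched normal exists, the Fisher test.
    """
    from .filters import fisher_two_sided

    depth = int(rng.integers(200, 601))
    vaf = float(rng.uniform(*cfg.vaf_range))
    alt = max(int(rng.binomial(depth, vaf)), math.ceil(0.05 * depth))
    t_ref, t_alt = depth - alt, alt
    if rng.random() < cfg.control_missing_prob:
        return t_ref, t_alt, None, None, True
    # matched normal at the same depth, no alt reads; bump the alt count in
    # the rare draws where the Fisher evidence rule would still not clear
    n_depth = depth
    while fisher_two_sided(depth - alt, alt, n_depth, 0) >= 0.001:
        alt += 1
    return depth - alt, alt, n_depth, 0, False


def _variant(
    pid: str,
    gene: str,
    vclass: VariantClass,
    protein_change: str | None,
    cfg: SimConfig,
    rng: np.random.Generator,
    biallelic: bool = False,
) -> VariantCall:
    t_ref, t_alt, n_ref, n_alt, control_free = _draw_depths(cfg, rng)
    return VariantCall(
        patient_id=pid,
        gene=gene,
        variant_class=vclass,
        protein_change=protein_change,
        tumor_ref_depth=t_ref,
        tumor_alt_depth=t_alt,
        normal_ref_depth=n_ref,
        normal_alt_depth=n_alt,
        known_somatic_flag=True,
        germline_suspect_flag=False,
        control_free_somatic_flag=control_free,
        biallelic_annotation=biallelic,
    )


def _plant_lesion(
    pid: str, lesion: str, cfg: SimConfig, rng: np.random.Generator
) -> list[VariantCall]:
    if lesion == "NPM1":
        return [_variant(pid, "NPM1", VariantClass.FRAMESHIFT, "p.W288fs", cfg, rng)]
    if lesion == "CHROMATIN":
        gene = str(rng.choice(_CHROMATIN_GENES))
        pos = int(rng.integers(20, 700))
        return [_variant(pid, gene, VariantClass.MISSENSE, f"p.E{pos}K", cfg, rng)]
    if lesion == "TP53":
        return [_variant(pid, "TP53", VariantClass.MISSENSE, "p.R273H", cfg, rng)]
    if lesion == "CEBPA_BI":
        return [
            _variant(pid, "CEBPA", VariantClass.FRAMESHIFT, "p.P23fs", cfg, rng),
            _variant(pid, "CEBPA", VariantClass.INFRAME_INDEL, "p.K313dup", cfg, rng),
        ]
    if lesion == "IDH2_R172":
        return [_variant(pid, "IDH2", VariantClass.MISSENSE, "p.R172K", cfg, rng)]
    raise ValueError(f"unknown lesion {lesion!r}")


def _co_mutation(
    pid: str, gene: str, cfg: SimConfig, rng: np.random.Generator
) -> VariantCall:
    if gene == "FLT3":
        if rng.random() < 0.7:
            return _variant(pid, "FLT3", VariantClass.ITD, None, cfg, rng)
        return _variant(pid, "FLT3", VariantClass.MISSENSE, "p.D835Y", cfg, rng)
    changes = {"DNMT3A": "p.R882H", "NRAS": "p.G12D", "TET2": "p.Q1532*"}
    vclass = VariantClass.NONSENSE if gene == "TET2" else VariantClass.MISSENSE
    return _variant(pid, gene, vclass, changes.get(gene), cfg, rng)


def sample_mutation_profile(
    label: GenomicLabel,
    cfg: SimConfig,
    rng: np.random.Generator,
    patient_id: str = "P1",
) -> list[VariantCall]:
    """Plant the class-defining lesion(s) for ``label`` plus co-mutations.

    Co-mutations are independent Bernoulli draws over the configured
    non-class-defining genes, so they can never change the planted class.
    Patients in the no-driver bin receive no variants at all; patients in
    the driver-without-class bin are guaranteed at least one driver.
    """
    if label is GenomicLabel.NO_DRIVER:
        return []
    variants: list[VariantCall] = []
    if label is GenomicLabel.NPM1:
        variants += _plant_lesion(patient_id, "NPM1", cfg, rng)
    elif label is GenomicLabel.CHROMATIN_SPLICE:
        variants += _plant_lesion(patient_id, "CHROMATIN", cfg, rng)
    elif label is GenomicLabel.TP53:
        variants += _plant_lesion(patient_id, "TP53", cfg, rng)
    elif label is GenomicLabel.BIALLELIC_CEBPA:
        variants += _plant_lesion(patient_id, "CEBPA_BI", cfg, rng)
    elif label is GenomicLabel.IDH2_R172:
        variants += _plant_lesion(patient_id, "IDH2_R172", cfg, rng)
    elif label is GenomicLabel.MULTI_CLASS:
        pair = rng.choice(len(_MULTI_ELIGIBLE), size=2, replace=False)
        for i in sorted(pair):
            variants += _plant_lesion(patient_id, _MULTI_ELIGIBLE[i], cfg, rng)

    co_drawn = [
        gene
        for gene, freq in cfg.co_mutation_freqs.items()
        if rng.random() < freq
    ]
    if label is GenomicLabel.DRIVER_NO_CLASS and not co_drawn:
        genes = list(cfg.co_mutation_freqs)
        freqs = np.array([cfg.co_mutation_freqs[g] for g in genes])
        co_drawn = [str(rng.choice(genes, p=freqs / freqs.sum()))]
    for gene in co_drawn:
        variants.append(_co_mutation(patient_id, gene, cfg, rng))
    return variants


def _lognormal(
    median: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> float:
    """Log-normal centred on the median, spread set by the observed range."""
    sigma = math.log(hi / lo) / 6.0 if hi > lo > 0 else 0.0
    value = median * math.exp(sigma * rng.standard_normal())
    return float(min(max(value, lo), hi))


def sample_outcomes(
    label: GenomicLabel,
    cfg: SimConfig,
    rng: np.random.Generator,
    patient_id: str = "P1",
) -> OutcomeRecord:
    """Draw one patient's clinical fields under the subgroup's calibration."""
    p = cfg.per_class[label]
    sex = "M" if rng.random() < p.male_frac else "F"
    age = _lognormal(p.age_median, p.age_range[0], p.age_range[1], rng)
    wbc = _lognormal(p.wbc_median, p.wbc_range[0], p.wbc_range[1], rng)
    blast = _lognormal(p.blast_median, p.blast_range[0], p.blast_range[1], rng)

    lam_os = calibrated_death_rate(
        p.five_year_os, p.cr_prob, cfg.cr_time_range[0], cfg.cr_time_range[1]
    )
    horizon = cfg.followup_horizon
    cr = bool(rng.random() < p.cr_prob)

    def exp_draw(rate: float) -> float:
        return float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf

    relapse: float | None = None
    if cr:
        cr_time = float(rng.uniform(*cfg.cr_time_range))
        lam_rel = relapse_rate(p.five_year_relapse, lam_os)
        r = exp_draw(lam_rel)
        d = exp_draw(lam_os)
        if d <= r:
            death = cr_time + d
        else:
            relapse = cr_time + r
            death = relapse + exp_draw(lam_os)
    else:
        cr_time = None
        death = exp_draw(lam_os)

    death_time = death if death <= horizon else None
    last_fu = death if death <= horizon else horizon
    relapse_time = relapse if relapse is not None and relapse <= last_fu else None

    sct_time: float | None = None
    if cr and rng.random() < p.sct_prob:
        t_event = min(x for x in (relapse, death, horizon) if x is not None)
        window = min(6.0, 0.9 * (t_event - cr_time))
        if window > 0:
            sct_time = cr_time + float(rng.uniform(0.0, window))

    return OutcomeRecord(
        patient_id=patient_id,
        age=round(age, 1),
        sex=sex,
        wbc=round(wbc, 1),
        bm_blast_pct=round(blast, 1),
        cr_achieved=cr,
        cr_time=None if cr_time is None else round(cr_time, 3),
        sct_time=None if sct_time is None else round(sct_time, 3),
        relapse_time=None if relapse_time is None else round(relapse_time, 3),
        death_time=None if death_time is None else round(death_time, 3),
        last_followup_time=round(last_fu, 3),
    )


@dataclass(frozen=True)
class CohortBundle:
    variants: list[VariantCall]
    records: list[OutcomeRecord]
    truth: pd.DataFrame  # patient_id, true_label


def generate_cohort(cfg: SimConfig) -> CohortBundle:
    """Simulate a full cohort (mutations, clinical outcomes, truth labels)."""
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[lab] for lab in labels])
    width = max(4, len(str(max(cfg.n_patients, 1))))
    variants: list[VariantCall] = []
    records: list[OutcomeRecord] = []
    truth_rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:0{width}d}"
        label = labels[int(rng.choice(len(labels), p=probs))]
        variants.extend(sample_mutation_profile(label, cfg, rng, patient_id=pid))
        records.append(sample_outcomes(label, cfg, rng, patient_id=pid))
        truth_rows.append({"patient_id": pid, "true_label": label.value})
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "true_label"])
    return CohortBundle(variants=variants, records=records, truth=truth)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write mutations.tsv, clinical.csv and truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.tsv",
    }
    write_mutation_table(bundle.variants, paths["mutations"])
    write_clinical_table(bundle.records, paths["clinical"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
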