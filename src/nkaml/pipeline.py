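"""End-to-end orchestration: filter -> classify -> stats -> survival.

``run_pipeline`` turns a mutation table plus a clinical table into a
single cohort-characteristics report: per subgroup the patient count and share, CR rate with its
subgroup-versus-rest odds ratio, allogeneic SCT rate and odds ratio, and
the 5-year OS, EFS and relapse-incidence estimates with Wald intervals,
plus cohort-level log-rank / Gray's / time-dependent Cox results.
Percentages print to one decimal and odds ratios to three.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import CLASS_ORDER, classify_cohort
from .cox import cox_time_dependent, sct_start_stop
from .filters import (
    DEFAULT_P_MAX,
    DEFAULT_VAF_MIN,
    build_profiles,
    filter_variants,
)
from .io import (
    GenePanel,
    OutcomeRecord,
    default_panel,
    read_clinical_table,
    read_mutation_table,
    read_panel,
)
from .stats import TwoByTwo, odds_ratio, proportion_with_ci
from .survival import (
    EndpointSet,
    aalen_johansen,
    cif_point,
    derive_endpoints,
    grays_test,
    kaplan_meier,
    logrank,
    survival_point,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending records."""


@dataclass(frozen=True)
class RunConfig:
    mutation_table: Path
    clinical_table: Path
    outdir: Path
    panel_path: Path | None = None
    mutation_format: str = "maf_tsv"
    vaf_min: float = DEFAULT_VAF_MIN
    p_max: float = DEFAULT_P_MAX
    report_format: str = "csv"  # csv | markdown
    horizon_months: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_min < 1.0:
            raise ValueError("vaf_min must lie in (0, 1)")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")
        if self.report_format not in ("csv", "markdown"):
            raise ValueError("report_format must be csv or markdown")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _fmt_pct(x: float) -> float:
    return round(x, 1)


def _subgroup_rows(
    labels: pd.DataFrame,
    records: Sequence[OutcomeRecord],
    endpoints: Sequence[EndpointSet],
    horizon: float,
) -> pd.DataFrame:
    by_id = {r.patient_id: r for r in records}
    ep_by_id = {e.patient_id: e for e in endpoints}
    n_total = len(labels)
    rows = []
    for cls in CLASS_ORDER:
        ids = labels.loc[labels["label"] == cls.value, "patient_id"]
        group = [by_id[i] for i in ids]
        rest = [r for r in records if r.patient_id not in set(ids)]
        n_g = len(group)
        row: dict = {"label": cls.value, "n": n_g}
        row["percent"] = _fmt_pct(100.0 * n_g / n_total) if n_total else 0.0
        if n_g == 0:
            rows.append(row)
            continue
        # CR and SCT rates with subgroup-vs-rest odds ratios
        for name, flag in (
            ("cr", lambda r: r.cr_achieved),
            ("sct", lambda r: r.sct_time is not None),
        ):
            k_g = sum(flag(r) for r in group)
            k_r = sum(flag(r) for r in rest)
            prop = proportion_with_ci(k_g, n_g)
            row[f"{name}_n"] = k_g
            row[f"{name}_pct"] = _fmt_pct(prop.point)
            row[f"{name}_ci"] = f"{prop.ci_low:.1f}-{prop.ci_high:.1f}"
            if rest:
                orr = odds_ratio(TwoByTwo(k_g, n_g - k_g, k_r, len(rest) - k_r))
                row[f"{name}_or"] = round(orr.point, 3)
                row[f"{name}_or_ci"] = f"{orr.ci_low:.3f}-{orr.ci_high:.3f}"
                row[f"{name}_or_p"] = orr.p_value
        eps = [ep_by_id[i] for i in ids]
        km_os = kaplan_meier([e.os_time for e in eps], [e.os_event for e in eps])
        km_efs = kaplan_meier([e.efs_time for e in eps], [e.efs_event for e in eps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pt_os = survival_point(km_os, horizon)
            pt_efs = survival_point(km_efs, horizon)
        row["os_5y_pct"] = _fmt_pct(100 * pt_os.estimate)
        row["os_5y_ci"] = f"{100 * pt_os.ci_low:.1f}-{100 * pt_os.ci_high:.1f}"
        row["efs_5y_pct"] = _fmt_pct(100 * pt_efs.estimate)
        row["efs_5y_ci"] = f"{100 * pt_efs.ci_low:.1f}-{100 * pt_efs.ci_high:.1f}"
        cr_eps = [e for e in eps if e.relapse_time is not None]
        if cr_eps:
            cif = aalen_johansen(
                [e.relapse_time for e in cr_eps],
                [e.relapse_event_code for e in cr_eps],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pt_rel = cif_point(cif, horizon)
            row["relapse_5y_pct"] = _fmt_pct(100 * pt_rel.estimate)
            row["relapse_5y_ci"] = (
                f"{100 * pt_rel.ci_low:.1f}-{100 * pt_rel.ci_high:.1f}"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _group_tests(
    labels: pd.DataFrame, endpoints: Sequence[EndpointSet]
) -> dict:
    ep_by_id = {e.patient_id: e for e in endpoints}
    out: dict = {}
    os_groups, rel_groups = [], []
    for cls in CLASS_ORDER:
        ids = labels.loc[labels["label"] == cls.value, "patient_id"]
        eps = [ep_by_id[i] for i in ids]
        if eps:
            os_groups.append(
                ([e.os_time for e in eps], [e.os_event for e in eps])
            )
        cr_eps = [e for e in eps if e.relapse_time is not None]
        if cr_eps:
            rel_groups.append(
                (
                    [e.relapse_time for e in cr_eps],
                    [e.relapse_event_code for e in cr_eps],
                )
            )
    if len(os_groups) >= 2:
        lr = logrank(os_groups)
        out["logrank_os"] = {"statistic": lr.statistic, "p": lr.p_value, "df": lr.df}
    if len(rel_groups) >= 2:
        gr = grays_test(rel_groups)
        out["grays_relapse"] = {
            "statistic": gr.statistic,
            "p": gr.p_value,
            "df": gr.df,
        }
    sct_df = sct_start_stop(list(endpoints))
    if sct_df["event"].any() and sct_df["sct"].any():
        cox = cox_time_dependent(sct_df, ["sct"])
        out["cox_sct_os"] = {
            "log_hr": float(cox.coef[0]),
            "hr": float(np.exp(cox.coef[0])),
            "se": float(cox.se[0]),
            "p": float(cox.p[0]),
            "converged": cox.converged,
        }
    return out


def _write_report(report: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "csv":
        report.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(report.to_markdown(index=False))
            fh.write("\n")


@_stage("pipeline")
def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a bundle of output paths and results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = read_panel(cfg.panel_path) if cfg.panel_path else default_panel()

    try:
        variants = read_mutation_table(cfg.mutation_table, format=cfg.mutation_format)
        records = read_clinical_table(cfg.clinical_table)
    except Exception as exc:
        raise PipelineError(f"stage 'read' failed: {exc}") from exc

    try:
        decisions = filter_variants(variants, panel, cfg.vaf_min, cfg.p_max)
    except Exception as exc:
        raise PipelineError(f"stage 'filter' failed: {exc}") from exc
    retained = [d.variant for d in decisions if d.retained]

    try:
        profiles = build_profiles(
            retained, panel, patient_ids=[r.patient_id for r in records]
        )
        labels, summary = classify_cohort(profiles, panel)
    except Exception as exc:
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc

    try:
        endpoints = [derive_endpoints(r) for r in records]
    except Exception as exc:
        raise PipelineError(f"stage 'endpoints' failed: {exc}") from exc

    try:
        report = _subgroup_rows(labels, records, endpoints, cfg.horizon_months)
        tests = _group_tests(labels, endpoints)
    except Exception as exc:
        raise PipelineError(f"stage 'stats/survival' failed: {exc}") from exc

    dec_df = pd.DataFrame(
        {
            "patient_id": [d.variant.patient_id for d in decisions],
            "gene": [d.variant.gene for d in decisions],
            "vaf": [round(d.vaf, 4) for d in decisions],
            "fisher_p": [d.fisher_p for d in decisions],
            "retained": [int(d.retained) for d in decisions],
            "reason": [d.reason.value for d in decisions],
        }
    )
    ext = "md" if cfg.report_format == "markdown" else "csv"
    paths = {
        "decisions": outdir / "filter_decisions.tsv",
        "labels": outdir / "labels.tsv",
        "summary": outdir / "class_summary.csv",
        "report": outdir / f"subgroup_report.{ext}",
        "tests": outdir / "group_tests.json",
        "log": outdir / "run_log.json",
    }
    dec_df.to_csv(paths["decisions"], sep="\t", index=False)
    labels.to_csv(paths["labels"], sep="\t", index=False)
    summary.to_csv(paths["summary"], index=False)
    _write_report(report, paths["report"], cfg.report_format)
    with open(paths["tests"], "w", encoding="utf-8") as fh:
        json.dump(tests, fh, indent=2, sort_keys=True)
    log = {
        "nkaml_version": __version__,
        "n_patients": len(records),
        "n_variants_in": len(variants),
        "n_variants_retained": len(retained),
        "vaf_min": cfg.vaf_min,
        "p_max": cfg.p_max,
        "horizon_months": cfg.horizon_months,
        "panel_size": len(panel.driver_genes),
    }
    with open(paths["log"], "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {
        "paths": paths,
        "labels": labels,
        "summary": summary,
        "report": report,
        "tests": tests,
        "log": log,
    }
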