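"""Endpoint derivation and survival estimation for the cohort analysis.

Everything here is written against the counting-process formulation:

* Kaplan-Meier product-limit estimator with Greenwood variance (ties are
  handled by processing deaths before censorings at equal times).
* k-sample log-rank test.
* Aalen-Johansen cumulative incidence for competing risks (relapse vs
  death-without-relapse), with a delta-method variance from the i.i.d.
  representation of the estimator.
* Gray's k-sample test of subdistribution hazards.  The score compares
  cause-specific event counts against expectations on the subdistribution
  risk set R_j(t) = Y_j(t) (1 - F1_j(t-)) / S_j(t-); the variance follows
  the martingale representation of the score, including the correction for
  the estimated per-group CIF and survivor function entering R_j.

Endpoints: OS runs from induction start to death; EFS to death, relapse or
CR non-achievement (whichever first); the relapse clock restarts at CR with
death-without-relapse as the competing event.  Allogeneic SCT never censors
anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .io import OutcomeRecord, ValidationError

__all__ = [
    "EndpointSet",
    "SurvivalCurve",
    "SurvivalPoint",
    "CIFCurve",
    "TestResult",
    "derive_endpoints",
    "kaplan_meier",
    "survival_at",
    "survival_point",
    "logrank",
    "aalen_johansen",
    "cif_at",
    "grays_test",
    "DEFAULT_NONCR_EFS_TIME",
]

# EFS event time for patients who never achieve CR: the induction-failure
# assessment, defaulting to one month after induction start when the clinical
# table carries no assessment date.
DEFAULT_NONCR_EFS_TIME = 1.0

CENSORED, RELAPSE, DEATH_WITHOUT_RELAPSE = 0, 1, 2


@dataclass(frozen=True)
class EndpointSet:
    """Derived OS / EFS / relapse endpoints for one patient."""

    patient_id: str
    os_time: float
    os_event: bool
    efs_time: float
    efs_event: bool
    relapse_entry: float | None = None  # CR date (months from induction)
    relapse_time: float | None = None  # months since CR
    relapse_event_code: int | None = None  # 0 censored, 1 relapse, 2 death w/o relapse
    sct_time: float | None = None

    def __post_init__(self) -> None:
        assert self.os_time >= 0 and self.efs_time >= 0
        assert (self.relapse_time is None) == (self.relapse_entry is None)
        if self.relapse_time is not None:
            assert self.relapse_time >= 0
            assert self.relapse_event_code in (CENSORED, RELAPSE, DEATH_WITHOUT_RELAPSE)


def derive_endpoints(
    r: OutcomeRecord, noncr_efs_time: float = DEFAULT_NONCR_EFS_TIME
) -> EndpointSet:
    """Turn raw clinical fields into OS, EFS and competing-risk relapse endpoints."""
    problems = r.validate()
    if problems:
        raise ValidationError(f"{r.patient_id}: " + "; ".join(problems))

    dead = r.death_time is not None
    os_time = r.death_time if dead else r.last_followup_time

    if r.cr_achieved:
        event_times = [t for t in (r.relapse_time, r.death_time) if t is not None]
        if event_times:
            efs_time, efs_event = min(event_times), True
        else:
            efs_time, efs_event = r.last_followup_time, False
        cr = r.cr_time
        if r.relapse_time is not None:
            rel_time, code = r.relapse_time - cr, RELAPSE
        elif dead:
            rel_time, code = r.death_time - cr, DEATH_WITHOUT_RELAPSE
        else:
            rel_time, code = r.last_followup_time - cr, CENSORED
        return EndpointSet(
            patient_id=r.patient_id,
            os_time=os_time,
            os_event=dead,
            efs_time=efs_time,
            efs_event=efs_event,
            relapse_entry=cr,
            relapse_time=rel_time,
            relapse_event_code=code,
            sct_time=r.sct_time,
        )

    # CR never achieved: EFS event is the non-achievement itself, clocked at
    # the induction-failure assessment (capped by death when that came first).
    efs_time = min(noncr_efs_time, r.death_time) if dead else noncr_efs_time
    return EndpointSet(
        patient_id=r.patient_id,
        os_time=os_time,
        os_event=dead,
        efs_time=efs_time,
        efs_event=True,
        sct_time=r.sct_time,
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous product-limit step function with Greenwood SEs."""

    times: np.ndarray  # distinct event times, ascending
    estimates: np.ndarray  # S(t) just after each event time
    greenwood_se: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n: int
    max_time: float  # largest observed time, censored or not

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.times) > 0)
        assert np.all((self.estimates >= -1e-12) & (self.estimates <= 1 + 1e-12))
        assert np.all(np.diff(self.estimates) <= 1e-12)


def _check_times(times: np.ndarray) -> None:
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times < 0):
        raise ValueError("negative time")
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite time")


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit estimate of the survivor function.

    ``events`` is True for a death, False for censoring.  At tied times
    deaths are processed before censorings, which the risk-set construction
    (everyone with time >= t is at risk at t) realises automatically.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _check_times(t)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size
    if event_times.size == 0:
        return SurvivalCurve(
            times=np.empty(0),
            estimates=np.empty(0),
            greenwood_se=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            events=np.empty(0, dtype=int),
            n=n,
            max_time=float(t[-1]),
        )
    # at risk just before each event time; deaths at each event time
    at_risk = n - np.searchsorted(t, event_times, side="left")
    deaths = np.array([int(np.sum((t == et) & e)) for et in event_times])
    frac = 1.0 - deaths / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = deaths / (at_risk * (at_risk - deaths))
    gw_terms[~np.isfinite(gw_terms)] = 0.0  # S=0 step: variance term degenerate
    se = surv * np.sqrt(np.cumsum(gw_terms))
    return SurvivalCurve(
        times=event_times,
        estimates=surv,
        greenwood_se=se,
        at_risk=at_risk,
        events=deaths,
        n=n,
        max_time=float(t[-1]),
    )


def survival_at(curve: SurvivalCurve, t: float = 60.0) -> float:
    """Right-continuous evaluation of the step function at ``t`` (months)."""
    if t > curve.max_time:
        warnings.warn(
            f"t={t} beyond last observed time {curve.max_time}; "
            "returning last value (extrapolation)",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t, side="right")
    return 1.0 if idx == 0 else float(curve.estimates[idx - 1])


@dataclass(frozen=True)
class SurvivalPoint:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


def survival_point(
    curve: SurvivalCurve, t: float = 60.0, level: float = 0.95, clamp: bool = True
) -> SurvivalPoint:
    """S(t) with a plain-scale Greenwood Wald interval (clamped to [0, 1])."""
    est = survival_at(curve, t)
    idx = np.searchsorted(curve.times, t, side="right")
    se = 0.0 if idx == 0 else float(curve.greenwood_se[idx - 1])
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    lo, hi = est - z * se, est + z * se
    if clamp:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return SurvivalPoint(estimate=est, se=se, ci_low=lo, ci_high=hi)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[bool]]]) -> TestResult:
    """k-sample log-rank test over the pooled event times."""
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ts, es, gs = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {g} has zero subjects")
        _check_times(t)
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.size, g))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    event_times = np.unique(t[e])
    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        Y = float(at_risk.sum())
        d = float(((t == et) & e).sum())
        Yj = np.array([float((at_risk & (g == j)).sum()) for j in range(k)])
        dj = np.array([float(((t == et) & e & (g == j)).sum()) for j in range(k)])
        obs += dj
        exp += d * Yj / Y
        if Y > 1:
            frac = Yj / Y
            cov += (
                d * (Y - d) / (Y - 1) * (np.diag(frac) - np.outer(frac, frac))
            )
    z = (obs - exp)[: k - 1]
    V = cov[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(V) @ z) if z.size else 0.0
    return TestResult(
        statistic=stat, p_value=float(sps.chi2.sf(stat, df=k - 1)), df=k - 1
    )


@dataclass(frozen=True)
class CIFCurve:
    """Aalen-Johansen cumulative incidence per cause, with variances."""

    times: np.ndarray  # distinct times with any-cause events
    cif: dict  # cause -> non-decreasing array
    variance: dict  # cause -> array
    km_allcause: np.ndarray  # all-cause KM at the same times
    at_risk: np.ndarray
    n: int
    max_time: float

    def __post_init__(self) -> None:
        for arr in self.cif.values():
            assert np.all(np.diff(arr) >= -1e-12)


def aalen_johansen(
    times: Sequence[float],
    codes: Sequence[int],
    entry: Sequence[float] | None = None,
    causes: tuple[int, ...] = (RELAPSE, DEATH_WITHOUT_RELAPSE),
) -> CIFCurve:
    """Aalen-Johansen cumulative incidence functions under competing risks.

    ``codes``: 0 = censored, otherwise the cause id.  ``entry`` allows
    left-truncated (delayed-entry) risk sets.  CIF_k(t) sums
    S(s-) d_k(s) / Y(s) over event times s <= t; the variance is the
    delta-method estimate from the estimator's i.i.d. representation.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    _check_times(t)
    known = set(causes) | {CENSORED}
    if not set(np.unique(c)) <= known:
        raise ValueError(f"unknown event code(s): {sorted(set(c) - known)}")
    if entry is None:
        ent = np.zeros_like(t)
    else:
        ent = np.asarray(entry, dtype=float)
        if np.any(ent > t):
            raise ValueError("entry time after exit time")
    event_times = np.unique(t[c != CENSORED])
    n = t.size
    T = event_times.size
    Y = np.array([float(np.sum((ent < et) & (t >= et))) for et in event_times])
    d_all = np.array([float(np.sum((t == et) & (c != CENSORED))) for et in event_times])
    # left limit of all-cause KM at each event time
    frac = np.where(Y > 0, 1.0 - d_all / np.maximum(Y, 1.0), 1.0)
    km = np.cumprod(frac)
    km_left = np.concatenate(([1.0], km[:-1]))
    cif: dict[int, np.ndarray] = {}
    variance: dict[int, np.ndarray] = {}
    d_by_cause = {
        cause: np.array([float(np.sum((t == et) & (c == cause))) for et in event_times])
        for cause in causes
    }
    for cause in causes:
        d_k = d_by_cause[cause]
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(Y > 0, km_left * d_k / np.maximum(Y, 1.0), 0.0)
        F = np.cumsum(inc)
        # variance via the i.i.d. representation: integrand S(s-) - (F(t)-F(s))
        # against cause-k event martingales, -(F(t)-F(s)) against the others
        var = np.empty(T)
        d_other = d_all - d_k
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_Y2 = np.where(Y > 0, 1.0 / np.maximum(Y, 1.0) ** 2, 0.0)
        for i in range(T):
            lag = F[i] - F[: i + 1]
            term_k = (km_left[: i + 1] - lag) ** 2 * d_k[: i + 1] * inv_Y2[: i + 1]
            term_o = lag**2 * d_other[: i + 1] * inv_Y2[: i + 1]
            var[i] = term_k.sum() + term_o.sum()
        cif[cause] = F
        variance[cause] = var
    return CIFCurve(
        times=event_times,
        cif=cif,
        variance=variance,
        km_allcause=km,
        at_risk=Y,
        n=n,
        max_time=float(t.max()),
    )


def cif_at(curve: CIFCurve, t: float = 60.0, cause: int = RELAPSE) -> float:
    """Right-continuous evaluation of CIF_cause at ``t``."""
    if t > curve.max_time:
        warnings.warn(
            f"t={t} beyond last observed time {curve.max_time}; "
            "returning last value (extrapolation)",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.times, t, side="right")
    return 0.0 if idx == 0 else float(curve.cif[cause][idx - 1])


def cif_point(
    curve: CIFCurve, t: float = 60.0, cause: int = RELAPSE, level: float = 0.95
) -> SurvivalPoint:
    """CIF_cause(t) with a plain-scale Wald interval clamped to [0, 1]."""
    est = cif_at(curve, t, cause)
    idx = np.searchsorted(curve.times, t, side="right")
    se = 0.0 if idx == 0 else float(np.sqrt(curve.variance[cause][idx - 1]))
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return SurvivalPoint(
        estimate=est,
        se=se,
        ci_low=max(0.0, est - z * se),
        ci_high=min(1.0, est + z * se),
    )


def _group_left_limits(
    t: np.ndarray, c: np.ndarray, eval_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left limits of (S, F1, F2) for one group's own data at ``eval_times``."""
    own_times = np.unique(t[c != CENSORED])
    if own_times.size == 0:
        ones = np.ones(eval_times.size)
        zeros = np.zeros(eval_times.size)
        return ones, zeros, zeros
    Y = np.array([float(np.sum(t >= et)) for et in own_times])
    d_all = np.array([float(np.sum((t == et) & (c != CENSORED))) for et in own_times])
    d1 = np.array([float(np.sum((t == et) & (c == RELAPSE))) for et in own_times])
    d2 = d_all - d1
    km = np.cumprod(1.0 - d_all / Y)
    km_left = np.concatenate(([1.0], km[:-1]))
    F1 = np.cumsum(km_left * d1 / Y)
    F2 = np.cumsum(km_left * d2 / Y)
    idx = np.searchsorted(own_times, eval_times, side="left")  # strictly before
    S_out = np.where(idx == 0, 1.0, km[np.maximum(idx - 1, 0)])
    F1_out = np.where(idx == 0, 0.0, F1[np.maximum(idx - 1, 0)])
    F2_out = np.where(idx == 0, 0.0, F2[np.maximum(idx - 1, 0)])
    return S_out, F1_out, F2_out


def grays_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
    cause: int = RELAPSE,
    rho: float = 0.0,
) -> TestResult:
    """Gray's k-sample test of equality of subdistribution hazards.

    ``groups`` is a sequence of (times, codes) with codes 0 = censored,
    otherwise cause ids; the test targets ``cause``.  The statistic is the
    quadratic form of the weighted score over the subdistribution risk sets,
    with weight (1 - F1_pooled(t-))^rho; its variance includes the correction
    terms arising because each group's CIF and survivor function are
    estimated.  Returns a chi-square test with k-1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ts, cs = [], []
    for gi, (t, c) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        _check_times(t)
        # relabel: target cause -> 1, any other event -> 2
        c2 = np.where(c == CENSORED, 0, np.where(c == cause, 1, 2))
        ts.append(t)
        cs.append(c2)

    all_t = np.concatenate(ts)
    all_c = np.concatenate(cs)
    if not np.any(all_c == 1):
        warnings.warn("no events of the tested cause in any group", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, df=k - 1)
    ev = np.unique(all_t[all_c != 0])  # any-cause pooled event times
    T = ev.size

    Y = np.zeros((k, T))
    d1 = np.zeros((k, T))
    d2 = np.zeros((k, T))
    S_left = np.zeros((k, T))
    F1_left = np.zeros((k, T))
    F2_left = np.zeros((k, T))
    for j in range(k):
        t, c = ts[j], cs[j]
        Y[j] = [float(np.sum(t >= et)) for et in ev]
        d1[j] = [float(np.sum((t == et) & (c == 1))) for et in ev]
        d2[j] = [float(np.sum((t == et) & (c == 2))) for et in ev]
        S_left[j], F1_left[j], F2_left[j] = _group_left_limits(t, c, ev)

    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where((Y > 0) & (S_left > 0), Y * (1.0 - F1_left) / S_left, 0.0)
    R_tot = R.sum(axis=0)
    ok = R_tot > 0
    p_share = np.where(ok, R / np.where(ok, R_tot, 1.0), 0.0)  # (k, T)
    d1_tot = d1.sum(axis=0)

    if rho != 0.0:
        _, F1_pool, _ = _group_left_limits(all_t, all_c, ev)
        K = (1.0 - F1_pool) ** rho
    else:
        K = np.ones(T)

    score = (K * (d1 - p_share * d1_tot)).sum(axis=1)  # length k

    # dGamma: pooled subdistribution-hazard increments
    dG = np.where(ok, d1_tot / np.where(ok, R_tot, 1.0), 0.0)

    # B[j, l, s] = -sum_{t>s} K(t) (delta_jl - p_j(t)) (Y_l(t)/S_l(t-)) dG(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        YS = np.where(S_left > 0, Y / np.where(S_left > 0, S_left, 1.0), 0.0)
    c_l = K * YS * dG  # (k, T)

    def revcum_excl(x: np.ndarray) -> np.ndarray:
        # out[..., s] = sum_{t > s} x[..., t]
        rc = np.cumsum(x[..., ::-1], axis=-1)[..., ::-1]
        out = np.zeros_like(x)
        out[..., :-1] = rc[..., 1:]
        return out

    C = revcum_excl(c_l)  # (k=l, T): sum_{t>s} c_l
    D = revcum_excl(p_share[:, None, :] * c_l[None, :, :])  # (j, l, T)
    B = -(np.eye(k)[:, :, None] * C[None, :, :] - D)  # (j, l, T)

    with np.errstate(divide="ignore", invalid="ignore"):
        invY = np.where(Y > 0, 1.0 / np.where(Y > 0, Y, 1.0), 0.0)
    a = K[None, None, :] * (np.eye(k)[:, :, None] - p_share[:, None, :]) + B * (
        F2_left * invY
    )[None, :, :]
    b = B * ((1.0 - F1_left) * invY)[None, :, :]
    # V[j, m] = sum_l sum_s a_jl a_ml d1_l + b_jl b_ml d2_l
    V = np.einsum("jls,mls,ls->jm", a, a, d1) + np.einsum("jls,mls,ls->jm", b, b, d2)

    z = score[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(Vsub) @ z)
    return TestResult(
        statistic=stat, p_value=float(sps.chi2.sf(stat, df=k - 1)), df=k - 1
    )
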