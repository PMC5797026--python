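"""Cox proportional-hazards regression on start-stop (counting-process) data.

Built for the cohort's one genuinely time-varying covariate — allogeneic
SCT, which switches from 0 to 1 at transplant — but accepts any covariate
matrix.  Ties are handled with the Breslow approximation; the partial
likelihood is maximised by damped Newton iterations to a gradient tolerance
of 1e-8.  Monotone likelihood (perfect separation) is detected by runaway
coefficients and reported via a flag on the bounded estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .survival import EndpointSet

__all__ = ["CoxResult", "cox_time_dependent", "sct_start_stop"]

_GRAD_TOL = 1e-8
_MAX_ITER = 100
_BETA_BOUND = 20.0


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[str, ...]
    coef: np.ndarray  # log hazard ratios
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    monotone_flagged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": np.exp(self.coef),
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=list(self.covariates),
        )


def _partial_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    event_times: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow log partial likelihood with gradient and Hessian."""
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((beta.size, beta.size))
    for et in event_times:
        at_risk = (start < et) & (stop >= et)
        dead = at_risk & event & (stop == et)
        d = int(dead.sum())
        if d == 0:
            continue
        wr = w[at_risk]
        Xr = X[at_risk]
        s0 = wr.sum()
        s1 = wr @ Xr
        s2 = (Xr * wr[:, None]).T @ Xr
        xbar = s1 / s0
        ll += eta[dead].sum() - d * np.log(s0)
        grad += X[dead].sum(axis=0) - d * xbar
        hess -= d * (s2 / s0 - np.outer(xbar, xbar))
    return ll, grad, hess


def cox_time_dependent(
    data: pd.DataFrame,
    covariates: Sequence[str],
    start: str = "start",
    stop: str = "stop",
    event: str = "event",
) -> CoxResult:
    """Fit a Cox model on start-stop rows (risk interval ``(start, stop]``).

    ``data`` holds one row per risk interval; a subject changing covariate
    values contributes several contiguous intervals, with ``event`` true only
    on the interval where the failure occurs.
    """
    covariates = tuple(covariates)
    X = data[list(covariates)].to_numpy(dtype=float)
    t0 = data[start].to_numpy(dtype=float)
    t1 = data[stop].to_numpy(dtype=float)
    ev = data[event].to_numpy(dtype=bool)
    if np.any(t1 <= t0):
        raise ValueError("every interval needs stop > start")
    event_times = np.unique(t1[ev])
    if event_times.size == 0:
        raise ValueError("no events in the data")

    beta = np.zeros(X.shape[1])
    monotone = False
    converged = False
    ll, grad, hess = _partial_loglik(beta, X, t0, t1, ev, event_times)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving on the log-likelihood
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = _partial_loglik(
                cand, X, t0, t1, ev, event_times
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > _BETA_BOUND:
            monotone = True
            beta = np.clip(beta, -_BETA_BOUND, _BETA_BOUND)
            ll, grad, hess = _partial_loglik(beta, X, t0, t1, ev, event_times)
            warnings.warn(
                "monotone partial likelihood (possible perfect separation); "
                "coefficient bounded",
                stacklevel=2,
            )
            break
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break

    cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * sps.norm.sf(np.abs(zval))
    return CoxResult(
        covariates=covariates,
        coef=beta,
        se=se,
        z=zval,
        p=pval,
        loglik=ll,
        n_iter=it,
        converged=converged,
        monotone_flagged=monotone,
    )


def sct_start_stop(
    endpoints: Sequence[EndpointSet],
    extra_covariates: pd.DataFrame | None = None,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Expand per-patient endpoints into start-stop rows with a time-varying
    SCT indicator (0 before transplant, 1 from transplant onward).

    ``endpoint`` selects ``os`` or ``efs``; ``extra_covariates`` (indexed by
    patient_id) are carried onto every interval of the patient.  Zero-length
    follow-up is nudged by half a day so every interval is valid.
    """
    if endpoint not in ("os", "efs"):
        raise ValueError("endpoint must be 'os' or 'efs'")
    rows = []
    for ep in endpoints:
        time = ep.os_time if endpoint == "os" else ep.efs_time
        ev = ep.os_event if endpoint == "os" else ep.efs_event
        if time <= 0:
            time = 1.0 / 60.0
        sct = ep.sct_time
        if sct is not None and 0 < sct < time:
            rows.append((ep.patient_id, 0.0, sct, False, 0.0))
            rows.append((ep.patient_id, sct, time, ev, 1.0))
        else:
            rows.append((ep.patient_id, 0.0, time, ev, 0.0))
    df = pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event", "sct"])
    if extra_covariates is not None:
        df = df.join(extra_covariates, on="patient_id", how="left")
        if df[extra_covariates.columns].isna().any().any():
            raise ValueError("extra_covariates missing for some patients")
    return df
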