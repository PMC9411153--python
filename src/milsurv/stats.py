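"""Evaluation statistics: concordance index, Kaplan–Meier, Cox PH, and the
three-stage statistical protocol applied to model risk predictions.

The concordance index follows

    c_hat = (C + R/2) / (C + D + R)

over *permissible* pairs under right-censoring (Harrell's convention): a
pair counts only when the shorter observed time belongs to an observed
event, so the true risk ordering is known. On fully-observed data every
time-ordered pair is permissible and the statistic reduces exactly to the
count-based definition above. Setting ``restrict_permissible=False``
recovers the naive all-time-ordered-pairs variant.

The Cox fitter maximizes the same partial likelihood the training loss
minimizes (shared code path with :mod:`milsurv.objectives`), by Newton–
Raphson with Breslow tie handling; confidence intervals and p-values are
Wald-based. Kaplan–Meier estimation delegates to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.special import logsumexp
from scipy.stats import norm

from .cohort import SurvivalLabel
from .objectives import _risk_matrix, _unpack, npll_loss

__all__ = [
    "ConcordanceResult",
    "KMCurve",
    "CoxFitResult",
    "concordance_index",
    "dichotomize_by_median",
    "kaplan_meier",
    "cox_fit",
    "staged_analysis",
    "StagedReport",
]


@dataclass(frozen=True)
class ConcordanceResult:
    c_hat: float
    concordant: int
    discordant: int
    tied_risk: int
    n_permissible: int


def concordance_index(risks, labels, restrict_permissible: bool = True) -> ConcordanceResult:
    """Concordance of predicted risks with observed survival.

    A pair (shorter time i, longer time j) is concordant when o_i > o_j,
    discordant when o_i < o_j, and an equal-risk pair when o_i = o_j
    (counted with half weight). Tied observation times are never
    permissible. Raises when no permissible pair exists.
    """
    o = np.asarray(risks, dtype=float)
    t, d = _unpack(labels)
    if o.shape[0] != t.shape[0] or o.shape[0] < 2:
        raise ValueError("need matching risks/labels for at least two patients")
    earlier = t[:, None] < t[None, :]  # i strictly before j
    if restrict_permissible:
        permissible = earlier & (d[:, None] == 1)
    else:
        permissible = earlier
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs (all tied times or no events)")
    higher = o[:, None] > o[None, :]
    tied = o[:, None] == o[None, :]
    C = int((permissible & higher).sum())
    R = int((permissible & tied).sum())
    D = n_perm - C - R
    return ConcordanceResult(
        c_hat=(C + R / 2.0) / n_perm,
        concordant=C,
        discordant=D,
        tied_risk=R,
        n_permissible=n_perm,
    )


def dichotomize_by_median(predictions) -> tuple[np.ndarray, float]:
    """High/low risk split at the median of the supplied predictions.

    high iff risk > cutoff, low iff risk <= cutoff (so with all values
    equal, every patient is low). Returns (is_high boolean array, cutoff).
    """
    o = np.asarray(predictions, dtype=float)
    if o.size < 2:
        raise ValueError("need at least two predictions")
    cutoff = float(np.median(o))
    return o > cutoff, cutoff


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve with its risk table."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(labels, groups: Sequence | None = None) -> dict:
    """Kaplan–Meier curve per group (single group 'all' when None)."""
    t, d = _unpack(labels)
    g = np.asarray(["all"] * t.size) if groups is None else np.asarray(groups)
    out: dict = {}
    for name in pd.unique(g):
        sel = g == name
        if sel.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], event_observed=d[sel])
        table = kmf.event_table.iloc[1:] if 0.0 not in t[sel] else kmf.event_table
        times = table.index.to_numpy(dtype=float)
        surv = np.array([float(kmf.predict(x)) for x in times])
        out[name] = KMCurve(
            times=times,
            survival=surv,
            at_risk=table["at_risk"].to_numpy(dtype=int),
            events=table["observed"].to_numpy(dtype=int),
        )
    return out


@dataclass(frozen=True)
class CoxFitResult:
    """One fitted Cox PH model (one row per covariate)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool
    log_likelihood: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "coef": self.coef,
                "HR": self.hr,
                "CI_low": self.ci_low,
                "CI_high": self.ci_high,
                "p": self.p,
            }
        )


def _cox_grad_hess(X: np.ndarray, beta: np.ndarray, t: np.ndarray, d: np.ndarray):
    """Gradient and Hessian of the negative partial log-likelihood in beta."""
    o = X @ beta
    ev = np.flatnonzero(d == 1)
    mask = _risk_matrix(t)[ev]
    logits = np.where(mask, o[None, :], -np.inf)
    P = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))  # (events, n)
    xbar = P @ X  # (events, p)
    grad = xbar.sum(axis=0) - X[ev].sum(axis=0)
    hess = np.einsum("ej,jk,jl->kl", P, X, X) - xbar.T @ xbar
    return grad, hess


def cox_fit(
    covariates,
    labels,
    mode: str = "multivariate",
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Cox proportional-hazards fit by Newton–Raphson (Breslow ties).

    ``mode='multivariate'`` fits all columns jointly and returns one
    CoxFitResult; ``mode='univariate'`` fits each column separately and
    returns a list. Wald 95% CI = exp(coef ± 1.96 SE). Non-convergence or
    complete separation is flagged, never raised.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t, d = _unpack(labels)
    if d.sum() < 1:
        raise ValueError("Cox fit needs at least one event")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    if mode == "univariate":
        return [
            cox_fit(X[:, k], labels, mode="multivariate", names=[names[k]],
                    max_iter=max_iter, tol=tol)
            for k in range(X.shape[1])
        ]
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")

    p = X.shape[1]
    beta = np.zeros(p)
    nll = npll_loss(X @ beta, (t, d))
    converged = False
    for _ in range(max_iter):
        grad, hess = _cox_grad_hess(X, beta, t, d)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break  # singular information (e.g. constant covariate)
        # backtracking line search on the negative partial log-likelihood
        alpha = 1.0
        for _ in range(30):
            new_beta = beta - alpha * step
            new_nll = npll_loss(X @ new_beta, (t, d))
            if new_nll <= nll + 1e-12:
                break
            alpha /= 2.0
        if not np.isfinite(new_nll):
            break
        beta, delta, nll = new_beta, nll - new_nll, new_nll
        if abs(delta) < tol:
            converged = True
            break
    if np.any(np.abs(beta) > 50):
        converged = False  # effectively complete separation
    _, hess = _cox_grad_hess(X, beta, t, d)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            converged = False
    with np.errstate(invalid="ignore", over="ignore"):
        z = beta / se
        hr, ci_low, ci_high = np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return CoxFitResult(
        names=tuple(names),
        coef=beta,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=2 * norm.sf(np.abs(z)),
        n=X.shape[0],
        n_events=int(d.sum()),
        converged=converged,
        log_likelihood=-nll,
    )


# --- three-stage protocol ---------------------------------------------------

@dataclass
class StagedReport:
    table: pd.DataFrame  # stage,parameter,cutoff,n_high,n_low,HR,CI_low,CI_high,p
    km: dict  # (stage, group) -> KMCurve
    cutoffs: dict  # stage -> median cutoff


STAGES = {1: ("test",), 2: ("test", "val"), 3: ("train", "val", "test")}


def staged_analysis(
    risks: Mapping[str, float],
    labels: Mapping[str, SurvivalLabel],
    roles: Mapping[str, str],
    clinical_covariates: pd.DataFrame | None = None,
) -> StagedReport:
    """Three-stage Cox/KM analysis of model predictions.

    Stage 1 uses the test split only, Stage 2 test + validation, Stage 3
    the whole cohort; each stage recomputes the median cutoff from the
    patients it includes, dichotomizes, fits a univariate Cox model on the
    high/low indicator and — when ``clinical_covariates`` (a patient-indexed
    frame of pre-dichotomized 0/1 indicators) is given — a multivariate
    model alongside them. Stages with fewer than two events are skipped
    with a warning.
    """
    rows = []
    km: dict = {}
    cutoffs: dict = {}
    for stage, wanted in STAGES.items():
        ids = [pid for pid in risks if roles.get(pid) in wanted]
        if len(ids) < 2:
            warnings.warn(f"stage {stage}: fewer than two patients, skipped", stacklevel=2)
            continue
        o = np.array([risks[pid] for pid in ids])
        labs = [labels[pid] for pid in ids]
        t, d = _unpack(labs)
        if d.sum() < 2:
            warnings.warn(f"stage {stage}: fewer than two events, skipped", stacklevel=2)
            continue
        is_high, cutoff = dichotomize_by_median(o)
        cutoffs[stage] = cutoff
        groups = np.where(is_high, "high", "low")
        for name, curve in kaplan_meier((t, d), groups).items():
            km[(stage, name)] = curve
        indicator = is_high.astype(float)
        if indicator.std() == 0:
            warnings.warn(f"stage {stage}: constant risk group indicator, degenerate fit", stacklevel=2)
            rows.append(
                dict(stage=stage, parameter="MIL", cutoff=cutoff,
                     n_high=int(is_high.sum()), n_low=int((~is_high).sum()),
                     HR=np.nan, CI_low=np.nan, CI_high=np.nan, p=np.nan, analysis="univariate")
            )
            continue
        uni = cox_fit(indicator, (t, d), names=["MIL"])
        rows.append(
            dict(stage=stage, parameter="MIL", cutoff=cutoff,
                 n_high=int(is_high.sum()), n_low=int((~is_high).sum()),
                 HR=uni.hr[0], CI_low=uni.ci_low[0], CI_high=uni.ci_high[0], p=uni.p[0],
                 analysis="univariate")
        )
        if clinical_covariates is not None:
            cov = clinical_covariates.loc[ids]
            Xm = np.column_stack([indicator, cov.to_numpy(dtype=float)])
            names = ["MIL"] + list(cov.columns)
            multi = cox_fit(Xm, (t, d), names=names)
            for k, name in enumerate(names):
                rows.append(
                    dict(stage=stage, parameter=name, cutoff=cutoff if name == "MIL" else np.nan,
                         n_high=int(Xm[:, k].sum()), n_low=int((1 - Xm[:, k]).sum()),
                         HR=multi.hr[k], CI_low=multi.ci_low[k], CI_high=multi.ci_high[k],
                         p=multi.p[k], analysis="multivariate")
                )
    table = pd.DataFrame(
        rows,
        columns=["stage", "parameter", "cutoff", "n_high", "n_low",
                 "HR", "CI_low", "CI_high", "p", "analysis"],
    )
    return StagedReport(table=table, km=km, cutoffs=cutoffs)
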