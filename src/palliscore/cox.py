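"""Cox proportional-hazards regression and stepwise factor selection.

The partial likelihood uses the Breslow tie convention (tied deaths share a
single risk set) and is maximized by Newton's method with step halving.
Standard errors come from the observed information at the maximum.

Factor selection mirrors a two-stage clinical workflow:

1. :func:`univariate_screen` — a log-rank test per factor (pooled over all
   levels when a factor has more than two), carrying forward factors with
   p below a threshold (default 0.1, strict ``<``).
2. :func:`backward_eliminate` — starting from the carried-forward set,
   repeatedly drop the factor whose likelihood-ratio removal test has the
   largest p-value at or above the removal threshold (default 0.10),
   refitting after each drop, until every remaining factor has removal
   p below the threshold. Multi-level factors (e.g. the 3-level performance
   status grouping) enter and leave as a block of indicator columns.

Complete-case analysis throughout: a record missing any factor in the model
is excluded from that model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, FactorSpec, get_factor
from .survival import logrank_test

__all__ = [
    "CoxFit",
    "ScreenResult",
    "DesignMatrix",
    "build_design",
    "cox_fit",
    "univariate_screen",
    "backward_eliminate",
]

logger = logging.getLogger("palliscore")

_MAX_ITER = 50
_GRAD_TOL = 1e-9
_DIVERGENCE_BETA = 15.0  # |beta| beyond this flags a monotone likelihood


@dataclass
class DesignMatrix:
    """Numeric encoding of a cohort for Cox regression.

    One indicator column per non-reference factor level; ``terms`` maps each
    factor name to the indices of its columns so multi-level factors can be
    tested and removed jointly. Complete-case: only records non-missing on
    every factor are included.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    ids: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class CoxFit:
    """A fitted Cox model.

    ``beta`` are log hazard ratios per indicator column, ``se`` model-based
    standard errors from the observed information, ``wald_p`` two-sided Wald
    p-values. ``loglik`` is the maximized Breslow partial log-likelihood and
    ``loglik_null`` its value at beta = 0. ``retained`` is filled by
    :func:`backward_eliminate` with the surviving factor names.
    """

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_used: int
    n_events: int
    terms: dict[str, list[int]] = field(default_factory=dict)
    retained: list[str] | None = None

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hazard_ratios,
                "wald_p": self.wald_p,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards (Breslow ties), n={self.n_used}, "
            f"events={self.n_events}",
            f"partial log-likelihood: {self.loglik:.6f} (null {self.loglik_null:.6f})",
            f"converged: {self.converged}",
        ]
        if self.retained is not None:
            lines.append(f"retained factors: {', '.join(self.retained) or '(none)'}")
        lines.append(self.to_frame().to_string(index=False))
        return "\n".join(lines)


@dataclass
class ScreenResult:
    """Univariate log-rank screen across candidate factors."""

    p_values: dict[str, float]
    carried_forward: list[str]
    excluded: dict[str, str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f,
                "logrank_p": p,
                "carried_forward": f in self.carried_forward,
            }
            for f, p in self.p_values.items()
        ]
        return pd.DataFrame(rows, columns=["factor", "logrank_p", "carried_forward"])


def _resolve_factors(factors: Sequence[str | FactorSpec]) -> list[FactorSpec]:
    return [f if isinstance(f, FactorSpec) else get_factor(f) for f in factors]


def build_design(cohort: Cohort, factors: Sequence[str | FactorSpec]) -> DesignMatrix:
    """Indicator-encode ``factors`` on the complete-case subset of ``cohort``."""
    specs = _resolve_factors(factors)
    rows, times, events, ids = [], [], [], []
    for rec in cohort:
        levels = [spec.level_of(rec) for spec in specs]
        if any(lvl is None for lvl in levels):
            continue
        rows.append(levels)
        times.append(rec.time_months)
        events.append(rec.event)
        ids.append(rec.id)

    columns: list[str] = []
    terms: dict[str, list[int]] = {}
    for spec in specs:
        terms[spec.name] = []
        for lvl in spec.levels[1:]:
            terms[spec.name].append(len(columns))
            columns.append(f"{spec.name}={lvl}")

    X = np.zeros((len(rows), len(columns)))
    for i, levels in enumerate(rows):
        for spec, lvl in zip(specs, levels):
            if lvl != spec.levels[0]:
                j = terms[spec.name][spec.levels[1:].index(lvl)]
                X[i, j] = 1.0
    return DesignMatrix(
        X=X,
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=bool),
        columns=columns,
        terms=terms,
        ids=ids,
    )


def _breslow_ll_grad_hess(
    beta: np.ndarray, Xs: np.ndarray, risk_idx: np.ndarray, event_rows: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood with gradient and Hessian.

    ``Xs`` is sorted by ascending time; ``risk_idx[i]`` is the first sorted
    row belonging to the risk set of event row i (ties share a risk set);
    ``event_rows`` indexes the death rows in sorted order.
    """
    eta = Xs @ beta
    eta_max = eta.max() if eta.size else 0.0
    w = np.exp(eta - eta_max)  # stabilized; constants cancel in all terms below
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    xw = w[:, None] * Xs
    S2 = np.cumsum(np.einsum("ni,nj->nij", xw, Xs)[::-1], axis=0)[::-1]

    S0e = S0[risk_idx]
    ll = float(np.sum(eta[event_rows] - eta_max) - np.sum(np.log(S0e)))
    xbar = S1[risk_idx] / S0e[:, None]
    grad = Xs[event_rows].sum(axis=0) - xbar.sum(axis=0)
    hess = -(
        S2[risk_idx] / S0e[:, None, None]
        - np.einsum("mi,mj->mij", xbar, xbar)
    ).sum(axis=0)
    return ll, grad, hess


def _prepare_sorted(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    event_rows = np.nonzero(es)[0]
    risk_idx = np.searchsorted(ts, ts[event_rows], side="left")
    return Xs, event_rows, risk_idx


def _newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    Xs, event_rows, risk_idx = _prepare_sorted(X, time, event)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _breslow_ll_grad_hess(beta, Xs, risk_idx, event_rows)
    ll_null = ll
    converged = False
    for _ in range(_MAX_ITER):
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving if the likelihood does not improve
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _breslow_ll_grad_hess(
                cand, Xs, risk_idx, event_rows
            )
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > _DIVERGENCE_BETA:
            break
    else:
        converged = np.max(np.abs(grad)) < _GRAD_TOL
    if np.max(np.abs(beta)) > _DIVERGENCE_BETA:
        converged = False
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, ll, ll_null, converged


def cox_fit(cohort: Cohort, covariates: Sequence[str | FactorSpec]) -> CoxFit:
    """Fit a Cox model with the given factors as indicator covariates.

    Uses complete-case records. A factor that is constant on the analysis
    set raises a ``ValueError`` naming it. A monotone likelihood (e.g.
    perfect separation) is returned with ``converged=False`` and a diverging
    coefficient rather than raising.
    """
    design = build_design(cohort, covariates)
    if design.n == 0:
        raise ValueError("no complete-case records for the requested covariates")
    if not np.any(design.event):
        raise ValueError("no events among complete-case records; Cox fit undefined")
    for name, cols in design.terms.items():
        for j in cols:
            col = design.X[:, j]
            if np.all(col == col[0]):
                raise ValueError(
                    f"covariate {design.columns[j]!r} (factor {name!r}) is constant "
                    "on the analysis set"
                )
    beta, se, ll, ll_null, converged = _newton_cox(design.X, design.time, design.event)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(zscores))
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood / perfect "
            "separation); coefficients are unreliable",
            stacklevel=2,
        )
    return CoxFit(
        covariates=design.columns,
        beta=beta,
        se=se,
        wald_p=wald_p,
        loglik=ll,
        loglik_null=ll_null,
        converged=converged,
        n_used=design.n,
        n_events=int(design.event.sum()),
        terms=design.terms,
    )


def univariate_screen(
    cohort: Cohort,
    factors: Sequence[str | FactorSpec],
    threshold: float = 0.1,
) -> ScreenResult:
    """Log-rank screen: one pooled test per factor on its non-missing records.

    Factors with fewer than two non-empty levels, or whose records carry no
    events, are excluded with a logged warning rather than tested. Factors
    with p strictly below ``threshold`` are carried forward.
    """
    specs = _resolve_factors(factors)
    p_values: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for spec in specs:
        groups: dict[str, tuple[list[float], list[bool]]] = {}
        for rec in cohort:
            lvl = spec.level_of(rec)
            if lvl is None:
                continue
            groups.setdefault(lvl, ([], []))
            groups[lvl][0].append(rec.time_months)
            groups[lvl][1].append(rec.event)
        nonempty = {lvl: g for lvl, g in groups.items() if len(g[0]) > 0}
        if len(nonempty) < 2:
            reason = f"only {len(nonempty)} non-empty level(s)"
            logger.warning("screen: excluding factor %r (%s)", spec.name, reason)
            excluded[spec.name] = reason
            continue
        if not any(any(e) for _, e in nonempty.values()):
            reason = "no events among non-missing records"
            logger.warning("screen: excluding factor %r (%s)", spec.name, reason)
            excluded[spec.name] = reason
            continue
        p_values[spec.name] = logrank_test(nonempty).p_value
    carried = [f for f, p in p_values.items() if p < threshold]
    return ScreenResult(
        p_values=p_values, carried_forward=carried, excluded=excluded, threshold=threshold
    )


def backward_eliminate(
    cohort: Cohort,
    start_covariates: Sequence[str | FactorSpec],
    removal_p: float = 0.10,
) -> CoxFit:
    """Backward elimination by likelihood-ratio removal tests.

    At each round the model is refit without each remaining factor in turn;
    the factor with the largest removal p-value is dropped if that p-value
    is at or above ``removal_p`` (multi-level factors are dropped as a
    block, with df equal to their number of indicator columns). Iteration
    stops when every remaining factor has removal p < ``removal_p``. An
    empty final set is allowed and returned with a warning (the null model).

    The analysis set is fixed up front to the records complete on every
    starting factor (listwise deletion), so the likelihood-ratio tests
    compare nested models on identical data throughout the elimination.
    """
    specs = _resolve_factors(start_covariates)
    cohort = cohort.subset(
        lambda r: all(s.level_of(r) is not None for s in specs),
        provenance="complete-case",
    )
    current = list(specs)
    fit = cox_fit(cohort, current)
    while current:
        removal: list[tuple[float, FactorSpec]] = []
        for spec in current:
            reduced = [s for s in current if s is not spec]
            if reduced:
                red_ll = cox_fit(cohort, reduced).loglik
            else:
                red_ll = fit.loglik_null
            lr = max(0.0, 2.0 * (fit.loglik - red_ll))
            df = len(fit.terms[spec.name])
            removal.append((float(stats.chi2.sf(lr, df)), spec))
        worst_p, worst = max(removal, key=lambda t: t[0])
        if worst_p < removal_p:
            break
        logger.info(
            "backward elimination: removing %r (removal p=%.4g >= %.3g)",
            worst.name,
            worst_p,
            removal_p,
        )
        current = [s for s in current if s is not worst]
        if current:
            fit = cox_fit(cohort, current)
    if not current:
        warnings.warn(
            "backward elimination removed every covariate; returning the null model",
            stacklevel=2,
        )
        fit = CoxFit(
            covariates=[],
            beta=np.zeros(0),
            se=np.zeros(0),
            wald_p=np.zeros(0),
            loglik=fit.loglik_null,
            loglik_null=fit.loglik_null,
            converged=True,
            n_used=fit.n_used,
            n_events=fit.n_events,
            terms={},
        )
    fit.retained = [s.name for s in current]
    return fit
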