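"""Right-censored survival machinery: Kaplan-Meier curves, actuarial death
rates at fixed horizons, median survival, and k-group log-rank tests.

Conventions
-----------
* At a time carrying both deaths and censorings, deaths are processed first:
  individuals censored at t are still at risk at t.
* The survival function is right-continuous: S(t) is the value just after
  the events at t, so a death at exactly the horizon counts as dead.
* The "actuarial death rate" at horizon t is 100 * (1 - S(t)) with S the
  Kaplan-Meier estimate (not a life-table interval estimator).
* Log-rank p-values come from the asymptotic chi-square reference
  distribution with df = k - 1; the k-group statistic uses the
  hypergeometric variance of observed-minus-expected deaths.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "ExtrapolationWarning",
    "km_estimate",
    "death_rate_at",
    "median_survival",
    "logrank_test",
    "pairwise_logrank",
]


class ExtrapolationWarning(UserWarning):
    """A quantity was requested beyond the observed follow-up."""


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the distinct death times; ``survival[i]`` is S just after
    ``times[i]``; ``at_risk[i]`` the number at risk just before ``times[i]``;
    ``deaths[i]`` the deaths at ``times[i]``. ``greenwood_se`` is the
    Greenwood standard error of S at each time. ``max_followup`` is the
    largest observed time (death or censoring); estimates beyond it are
    extrapolations.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    greenwood_se: np.ndarray
    n0: int
    max_followup: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.deaths > self.at_risk):
            raise ValueError("deaths cannot exceed the number at risk")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """S(t), right-continuous; 1 before the first death time."""
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per distinct death time."""
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )

    def plot(self, ax=None, label: str | None = None):
        """Step plot of the estimate (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate(([0.0], self.times, [self.max_followup]))
        s = np.concatenate(([1.0], self.survival, [self.survival[-1] if len(self.survival) else 1.0]))
        ax.step(t, s, where="post", label=label)
        ax.set_xlabel("months from start of reirradiation")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


@dataclass
class LogRankResult:
    """k-group log-rank test: chi-square statistic, df = k - 1, p-value."""

    chi_square: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length 1-d sequences")
    if t.size == 0:
        raise ValueError("empty input: the survival curve is undefined")
    if np.any(t < 0):
        raise ValueError(f"negative survival time at index {int(np.argmin(t))}")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Deaths are processed before censorings at tied times. The Greenwood
    variance of S at each death time is included as a standard error.
    """
    t, e = _validate_times_events(times, events)
    n0 = t.size
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]

    death_times = np.unique(ts[es])
    # at risk just before each death time: everyone with observed time >= t
    at_risk = ts.size - np.searchsorted(ts, death_times, side="left")
    deaths = np.array(
        [np.count_nonzero(es & (ts == dt)) for dt in death_times], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - deaths / at_risk
    survival = np.cumprod(frac)
    # Greenwood: var S(t) = S(t)^2 * sum d / (n (n - d)); the final factor is
    # 0/0 when everyone dies, which we map to SE 0 (S is exactly 0 there).
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = deaths / (at_risk * (at_risk - deaths)).astype(float)
    terms = np.where(np.isfinite(terms), terms, 0.0)
    greenwood_se = survival * np.sqrt(np.cumsum(terms))
    return SurvivalCurve(
        times=death_times,
        survival=survival,
        at_risk=at_risk,
        deaths=deaths,
        greenwood_se=greenwood_se,
        n0=n0,
        max_followup=float(ts[-1]),
    )


def death_rate_at(curve: SurvivalCurve, horizon: float) -> float:
    """Actuarial death rate 100 * (1 - S(horizon)), in percent.

    S is right-continuous, so deaths at exactly the horizon count. A horizon
    beyond the observed follow-up (with patients still at risk at the end)
    returns the last available estimate and emits an
    :class:`ExtrapolationWarning`.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    if horizon > curve.max_followup and curve.survival_at(curve.max_followup) > 0:
        warnings.warn(
            f"death rate at {horizon} months extrapolates beyond the observed "
            f"follow-up of {curve.max_followup} months; returning the last estimate",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(100.0 * (1.0 - curve.survival_at(horizon)))


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None when the median is not reached."""
    idx = np.nonzero(curve.survival <= 0.5 + 1e-12)[0]
    if idx.size == 0:
        return None
    return float(curve.times[idx[0]])


def _logrank_arrays(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    labels = tuple(groups.keys())
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    ts, es, gs = [], [], []
    for g, (t_g, e_g) in enumerate(groups.values()):
        t, e = _validate_times_events(t_g, e_g)
        ts.append(t)
        es.append(e)
        gs.append(np.full(t.size, g, dtype=int))
    return np.concatenate(ts), np.concatenate(es), np.concatenate(gs), labels


def logrank_test(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]]
) -> LogRankResult:
    """Pooled k-group log-rank test.

    At each distinct death time the observed deaths per group are compared
    with their expectation under the multivariate hypergeometric law given
    the margins; the chi-square statistic is z' V^+ z over the first k-1
    groups (generalized inverse for safety with degenerate strata), with
    df = k - 1 and an upper-tail chi-square p-value.
    """
    t, e, g, labels = _logrank_arrays(groups)
    k = len(labels)
    if not np.any(e):
        raise ValueError("log-rank statistic undefined: no events in any group")

    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = t.size

    death_times = np.unique(t[e])
    # at-risk per group just before each death time
    start = np.searchsorted(t, death_times, side="left")
    # cumulative count of group members with time < tau, per group
    onehot = np.zeros((n + 1, k), dtype=float)
    np.add.at(onehot, np.arange(1, n + 1), np.eye(k)[g])
    cum = np.cumsum(onehot, axis=0)  # cum[i, j] = members of group j among first i sorted
    n_at_risk = cum[-1] - cum[start]  # (m, k)
    n_total = n_at_risk.sum(axis=1)

    d_obs = np.zeros((death_times.size, k))
    dead = e
    ti = np.searchsorted(death_times, t[dead])
    np.add.at(d_obs, (ti, g[dead]), 1.0)
    d_total = d_obs.sum(axis=1)

    p_g = n_at_risk / n_total[:, None]
    expected = d_total[:, None] * p_g
    z = (d_obs - expected).sum(axis=0)[: k - 1]

    # hypergeometric covariance, summed over death times
    with np.errstate(divide="ignore", invalid="ignore"):
        c = d_total * (n_total - d_total) / (n_total - 1.0)
    c = np.where(np.isfinite(c), c, 0.0)  # strata with a single subject contribute nothing
    V = np.einsum("m,mi,mj->ij", c, p_g, p_g) * -1.0
    V[np.diag_indices(k)] += np.einsum("m,mi->i", c, p_g)
    Vsub = V[: k - 1, : k - 1]

    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi_square=chi2, df=df, p_value=p, groups=labels)


def pairwise_logrank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    correction: str | None = None,
) -> dict[tuple[str, str], LogRankResult]:
    """Two-group log-rank test for every unordered pair of groups.

    No multiplicity correction by default; ``correction`` may be
    ``"bonferroni"`` or ``"holm"``, which adjusts the p-values in place
    (capped at 1).
    """
    labels = list(groups.keys())
    if len(labels) < 2:
        raise ValueError("pairwise log-rank needs at least two groups")
    results: dict[tuple[str, str], LogRankResult] = {}
    for a, b in itertools.combinations(labels, 2):
        results[(a, b)] = logrank_test({a: groups[a], b: groups[b]})
    if correction is None:
        return results
    m = len(results)
    if correction == "bonferroni":
        for key, r in results.items():
            results[key] = LogRankResult(r.chi_square, r.df, min(1.0, r.p_value * m), r.groups)
    elif correction == "holm":
        items = sorted(results.items(), key=lambda kv: kv[1].p_value)
        running = 0.0
        for rank, (key, r) in enumerate(items):
            adj = min(1.0, (m - rank) * r.p_value)
            running = max(running, adj)
            results[key] = LogRankResult(r.chi_square, r.df, running, r.groups)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return results
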