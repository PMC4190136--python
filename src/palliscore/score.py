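"""Actuarial death-rate point scores and risk-group stratification.

The score construction: for each prognostic factor level, take the
Kaplan-Meier (actuarial) death rate at a fixed horizon, expressed in
percent, and divide by 10. Two horizon variants are kept side by side:

* **v1** (1-month horizon): points are kept at half-point resolution —
  rate/10 is floored to the nearest multiple of 0.5.
* **v2** (2-month horizon): points are whole numbers — rate/10 is rounded
  to the nearest integer, halves up.

These rounding rules are a reconstruction: they are the simplest rules
consistent with every published point value, but the original report states
only "death rate divided by 10".

A patient's total score is the sum of the four component points (Karnofsky
performance status dichotomized at <=60, known liver metastases, pleural
effusion, steroid use at the start of radiotherapy); patients missing any
component are *unassignable*, never imputed. Totals map onto four ordered
risk groups at fixed, configurable cutpoints. The three-variable SPS
(survival prediction score) comparator counts adverse features among
nonbreast primary, metastases other than bone, and KPS <= 60.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import Cohort, FactorSpec, PatientRecord, get_factor
from .survival import (
    SurvivalCurve,
    death_rate_at,
    km_estimate,
    logrank_test,
    median_survival,
    pairwise_logrank,
)

__all__ = [
    "VARIANTS",
    "SCORE_FACTORS",
    "DEVELOPMENT_COHORT_RATES",
    "DEFAULT_CUTPOINTS",
    "DEFAULT_BOUNDS",
    "PointTable",
    "ScoreResult",
    "SPSResult",
    "StratificationReport",
    "assign_points",
    "derive_point_table",
    "reference_point_table",
    "total_score",
    "assign_risk_group",
    "apply_table",
    "sps_assign",
    "sps_from_record",
    "evaluate_stratification",
    "read_point_table",
    "write_point_table",
]

#: Score variants: label -> horizon in months.
VARIANTS = {"v1": 1.0, "v2": 2.0}

#: The four component factors of the score, in reporting order.
SCORE_FACTORS = ("kps_le60", "liver_mets", "pleural_effusion", "steroids")

#: Actuarial death rates (percent) of the original development cohort at the
#: two horizons, per factor level — usable as inputs to rebuild the published
#: point tables without patient-level data.
DEVELOPMENT_COHORT_RATES: dict[str, dict[tuple[str, str], float]] = {
    "v1": {
        ("kps_le60", "70-100"): 2.0,
        ("kps_le60", "<=60"): 15.0,
        ("liver_mets", "no"): 4.0,
        ("liver_mets", "yes"): 11.0,
        ("pleural_effusion", "no"): 4.0,
        ("pleural_effusion", "yes"): 33.0,
        ("steroids", "no"): 3.0,
        ("steroids", "yes"): 11.0,
    },
    "v2": {
        ("kps_le60", "70-100"): 7.0,
        ("kps_le60", "<=60"): 39.0,
        ("liver_mets", "no"): 8.0,
        ("liver_mets", "yes"): 49.0,
        ("pleural_effusion", "no"): 14.0,
        ("pleural_effusion", "yes"): 50.0,
        ("steroids", "no"): 10.0,
        ("steroids", "yes"): 28.0,
    },
}

#: Risk-group upper cutpoints (totals <= c1 -> group 1, <= c2 -> 2, <= c3 -> 3,
#: above -> 4), per variant.
DEFAULT_CUTPOINTS: dict[str, tuple[float, float, float]] = {
    "v1": (0.0, 1.5, 3.0),
    "v2": (5.0, 8.0, 11.0),
}

#: Attainable total-score range per variant under the published tables.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {"v1": (0.0, 6.5), "v2": (4.0, 17.0)}

_EPS = 1e-9  # guards rounding against float noise from long KM products


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")


def assign_points(death_rate_percent: float, variant: str) -> float:
    """Convert an actuarial death rate (percent) into score points.

    ``rate / 10``, then rounded by the variant rule: v1 floors to the
    nearest multiple of 0.5 (so 15 -> 1.5, 11 -> 1.0, 4 -> 0); v2 rounds to
    the nearest integer, halves up (so 39 -> 4, 49 -> 5, 50 -> 5).
    """
    _check_variant(variant)
    if not (0.0 <= death_rate_percent <= 100.0):
        raise ValueError(f"death rate must be in [0, 100], got {death_rate_percent}")
    raw = death_rate_percent / 10.0
    if variant == "v1":
        return math.floor(raw * 2.0 + _EPS) / 2.0
    return float(math.floor(raw + 0.5 + _EPS))


@dataclass(frozen=True)
class PointEntry:
    rate_percent: float
    points: float


@dataclass
class PointTable:
    """Per-factor, per-level point values for one score variant.

    ``entries`` maps ``(factor, level)`` to the observed death rate and the
    rounded points. ``factors`` preserves reporting order.
    """

    variant: str
    horizon: float
    entries: dict[tuple[str, str], PointEntry]
    factors: tuple[str, ...] = SCORE_FACTORS

    def __post_init__(self) -> None:
        _check_variant(self.variant)
        for (factor, level), entry in self.entries.items():
            pts = entry.points
            if pts < 0:
                raise ValueError(f"negative points for ({factor}, {level})")
            if self.variant == "v2" and pts != int(pts):
                raise ValueError(f"v2 points must be integers, got {pts} for ({factor}, {level})")
            if self.variant == "v1" and (pts * 2.0) != int(pts * 2.0):
                raise ValueError(
                    f"v1 points must be multiples of 0.5, got {pts} for ({factor}, {level})"
                )
        for factor in self.factors:
            levels = self.factor_levels(factor)
            if not levels:
                raise ValueError(f"point table has no entries for factor {factor!r}")

    @classmethod
    def from_rates(
        cls,
        rates: Mapping[tuple[str, str], float],
        variant: str,
        horizon: float | None = None,
    ) -> "PointTable":
        """Build a table by applying the variant rounding rule to raw rates."""
        _check_variant(variant)
        entries = {
            key: PointEntry(rate_percent=float(r), points=assign_points(r, variant))
            for key, r in rates.items()
        }
        factors = tuple(dict.fromkeys(f for f, _ in rates))
        return cls(
            variant=variant,
            horizon=VARIANTS[variant] if horizon is None else horizon,
            entries=entries,
            factors=factors,
        )

    def factor_levels(self, factor: str) -> list[str]:
        return [lvl for (f, lvl) in self.entries if f == factor]

    def points_for(self, factor: str, level: str) -> float:
        return self.entries[(factor, level)].points

    @property
    def min_total(self) -> float:
        return sum(
            min(self.entries[(f, lvl)].points for lvl in self.factor_levels(f))
            for f in self.factors
        )

    @property
    def max_total(self) -> float:
        return sum(
            max(self.entries[(f, lvl)].points for lvl in self.factor_levels(f))
            for f in self.factors
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f,
                "level": lvl,
                "rate_percent": self.entries[(f, lvl)].rate_percent,
                "points": self.entries[(f, lvl)].points,
                "variant": self.variant,
                "horizon_months": self.horizon,
            }
            for f in self.factors
            for lvl in self.factor_levels(f)
        ]
        return pd.DataFrame(rows)


def reference_point_table(variant: str) -> PointTable:
    """The published point table, rebuilt from the development-cohort rates."""
    _check_variant(variant)
    return PointTable.from_rates(DEVELOPMENT_COHORT_RATES[variant], variant)


def derive_point_table(
    cohort: Cohort,
    factors: Sequence[str | FactorSpec],
    horizon: float,
    variant: str,
) -> PointTable:
    """Derive a point table from a cohort.

    Per factor level: Kaplan-Meier estimate on the subcohort non-missing
    for that factor at that level, actuarial death rate at ``horizon``,
    then the variant rounding. An empty level raises a ``ValueError``
    naming the factor and level.
    """
    _check_variant(variant)
    specs = [f if isinstance(f, FactorSpec) else get_factor(f) for f in factors]
    entries: dict[tuple[str, str], PointEntry] = {}
    for spec in specs:
        for level in spec.levels:
            sub = [r for r in cohort if spec.level_of(r) == level]
            if not sub:
                raise ValueError(
                    f"cannot derive points: no records at level {level!r} of "
                    f"factor {spec.name!r}"
                )
            curve = km_estimate([r.time_months for r in sub], [r.event for r in sub])
            rate = death_rate_at(curve, horizon)
            entries[(spec.name, level)] = PointEntry(
                rate_percent=rate, points=assign_points(rate, variant)
            )
    return PointTable(
        variant=variant,
        horizon=horizon,
        entries=entries,
        factors=tuple(s.name for s in specs),
    )


@dataclass
class ScoreResult:
    """One patient's component points, total, and risk group.

    ``assignable`` is False (and ``total``/``group`` None) when any
    component factor is missing on the patient.
    """

    patient_id: str
    variant: str
    components: dict[str, float | None]
    total: float | None
    group: int | None = None

    @property
    def assignable(self) -> bool:
        return self.total is not None


def total_score(patient: PatientRecord, table: PointTable) -> ScoreResult:
    """Sum the component points of ``patient`` under ``table``."""
    components: dict[str, float | None] = {}
    assignable = True
    for fname in table.factors:
        spec = get_factor(fname)
        level = spec.level_of(patient)
        if level is None:
            components[fname] = None
            assignable = False
        else:
            components[fname] = table.points_for(fname, level)
    total = sum(components.values()) if assignable else None  # type: ignore[arg-type]
    return ScoreResult(
        patient_id=patient.id, variant=table.variant, components=components, total=total
    )


def assign_risk_group(
    total: float,
    variant: str,
    cutpoints: tuple[float, float, float] | None = None,
    bounds: tuple[float, float] | None = None,
) -> int:
    """Map a total score onto risk group 1 (favorable) .. 4 (unfavorable).

    ``cutpoints`` are the upper boundaries of groups 1-3 (defaults: v1
    0 / 1.5 / 3 points, v2 5 / 8 / 11 points). A total outside the
    attainable ``bounds`` (defaults per published table) raises.
    """
    _check_variant(variant)
    c1, c2, c3 = cutpoints if cutpoints is not None else DEFAULT_CUTPOINTS[variant]
    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS[variant]
    if not (lo - _EPS <= total <= hi + _EPS):
        raise ValueError(
            f"total {total} outside the attainable range [{lo}, {hi}] for {variant}"
        )
    if total <= c1 + _EPS:
        return 1
    if total <= c2 + _EPS:
        return 2
    if total <= c3 + _EPS:
        return 3
    return 4


def apply_table(
    cohort: Cohort,
    table: PointTable,
    cutpoints: tuple[float, float, float] | None = None,
) -> list[ScoreResult]:
    """Score every patient and attach risk groups (None when unassignable)."""
    bounds = (table.min_total, table.max_total)
    results = []
    for rec in cohort:
        res = total_score(rec, table)
        if res.assignable:
            res.group = assign_risk_group(res.total, table.variant, cutpoints, bounds)
        results.append(res)
    return results


@dataclass(frozen=True)
class SPSResult:
    """Survival prediction score: count of adverse features and prognosis group."""

    adverse_count: int | None
    group: str  # "good" | "intermediate" | "poor" | "unassignable"


def sps_assign(
    nonbreast_primary: bool | None,
    mets_other_than_bone: bool | None,
    kps_le_60: bool | None,
) -> SPSResult:
    """Three-variable SPS: poor when all three adverse features are present,
    intermediate when two, good when zero or one; unassignable on missing
    input."""
    flags = (nonbreast_primary, mets_other_than_bone, kps_le_60)
    if any(f is None for f in flags):
        return SPSResult(adverse_count=None, group="unassignable")
    count = sum(bool(f) for f in flags)
    group = "poor" if count == 3 else "intermediate" if count == 2 else "good"
    return SPSResult(adverse_count=count, group=group)


def sps_from_record(patient: PatientRecord) -> SPSResult:
    """Derive the three SPS inputs from a patient record."""
    nonbreast = None if patient.primary_site is None else patient.primary_site != "breast"
    mets_other = None if patient.bone_mets_only is None else not patient.bone_mets_only
    kps_le60 = None if patient.kps is None else patient.kps <= 60
    return sps_assign(nonbreast, mets_other, kps_le60)


# ---------------------------------------------------------------------------
# Stratification report
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    label: str
    n: int
    median_months: float | None
    death_rate_1mo: float
    death_rate_2mo: float
    curve: SurvivalCurve


@dataclass
class StratificationReport:
    """Per-risk-group survival summary with uncorrected pairwise log-rank."""

    groups: list[GroupSummary]
    pairwise_p: dict[tuple[str, str], float]
    overall_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": g.label,
                    "n": g.n,
                    "median_months": g.median_months,
                    "death_rate_1mo_percent": g.death_rate_1mo,
                    "death_rate_2mo_percent": g.death_rate_2mo,
                }
                for g in self.groups
            ]
        )

    def to_text(self) -> str:
        lines = ["Risk-group stratification", "-" * 60]
        for g in self.groups:
            med = "not reached" if g.median_months is None else f"{g.median_months:.1f} mo"
            lines.append(
                f"group {g.label}: n={g.n}, median {med}, "
                f"death rate 1 mo {g.death_rate_1mo:.1f}%, 2 mo {g.death_rate_2mo:.1f}%"
            )
        lines.append(f"overall log-rank p = {self.overall_p:.4g}")
        lines.append("pairwise log-rank (uncorrected):")
        for (a, b), p in sorted(self.pairwise_p.items()):
            lines.append(f"  {a} vs {b}: p = {p:.4g}")
        return "\n".join(lines)


def evaluate_stratification(
    cohort: Cohort, results: Sequence[ScoreResult] | Mapping[str, str]
) -> StratificationReport:
    """Summarize survival by risk group.

    ``results`` is either the :func:`apply_table` output (risk groups 1-4;
    unassignable patients are dropped) or a mapping ``patient id -> group
    label`` (e.g. SPS groups). Requires at least two non-empty groups.
    """
    by_id = {p.id: p for p in cohort}
    assignment: dict[str, str] = {}
    if isinstance(results, Mapping):
        assignment = {pid: str(g) for pid, g in results.items()}
    else:
        for res in results:
            if res.group is not None:
                assignment[res.patient_id] = str(res.group)

    groups: dict[str, tuple[list[float], list[bool]]] = {}
    for pid, label in assignment.items():
        rec = by_id.get(pid)
        if rec is None:
            raise ValueError(f"score result for unknown patient id {pid!r}")
        groups.setdefault(label, ([], []))
        groups[label][0].append(rec.time_months)
        groups[label][1].append(rec.event)
    groups = {k: v for k, v in sorted(groups.items()) if len(v[0]) > 0}
    if len(groups) < 2:
        raise ValueError(
            f"stratification needs at least two non-empty groups, got {len(groups)}"
        )

    summaries = []
    for label, (times, events) in groups.items():
        curve = km_estimate(times, events)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # short-follow-up groups extrapolate benignly
            r1 = death_rate_at(curve, 1.0)
            r2 = death_rate_at(curve, 2.0)
        summaries.append(
            GroupSummary(
                label=label,
                n=len(times),
                median_months=median_survival(curve),
                death_rate_1mo=r1,
                death_rate_2mo=r2,
                curve=curve,
            )
        )
    overall = logrank_test(groups).p_value
    pairwise = {
        pair: res.p_value for pair, res in pairwise_logrank(groups, correction=None).items()
    }
    return StratificationReport(groups=summaries, pairwise_p=pairwise, overall_p=overall)


# ---------------------------------------------------------------------------
# Point-table serialization
# ---------------------------------------------------------------------------

def write_point_table(table: PointTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_point_table(path: str | Path) -> PointTable:
    df = pd.read_csv(path)
    required = {"factor", "level", "rate_percent", "points", "variant", "horizon_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"point-table CSV missing columns: {sorted(missing)}")
    variants = df["variant"].unique()
    if len(variants) != 1:
        raise ValueError("point-table CSV must contain exactly one variant")
    entries = {
        (str(r.factor), str(r.level)): PointEntry(
            rate_percent=float(r.rate_percent), points=float(r.points)
        )
        for r in df.itertuples()
    }
    return PointTable(
        variant=str(variants[0]),
        horizon=float(df["horizon_months"].iloc[0]),
        entries=entries,
        factors=tuple(dict.fromkeys(df["factor"].astype(str))),
    )
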