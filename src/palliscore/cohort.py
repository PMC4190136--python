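"""Patient-level cohort container and lossless CSV round-tripping.

The unit of analysis is one palliative reirradiation course, not one person:
a patient who was reirradiated twice contributes two records. Survival time
is measured in months from the start of the reirradiation course; records of
patients lost to follow-up carry ``event=False`` and the time of last
documented contact.

Missing covariate values are first-class (``None``), never imputed here:
downstream stages decide per analysis whether a record is usable
(complete-case modelling, "unassignable" score results).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "FactorSpec",
    "SchemaError",
    "CohortValidationError",
    "KPS_LEVELS",
    "PRIMARY_SITES",
    "DEFAULT_COLUMNS",
    "MISSING_SENTINEL",
    "get_factor",
    "read_cohort",
    "write_cohort",
    "cohort_to_dataframe",
]

#: Admissible Karnofsky performance status values (10..100 in steps of 10).
KPS_LEVELS = tuple(range(10, 101, 10))

#: Controlled vocabulary for the primary tumor site.
PRIMARY_SITES = (
    "prostate",
    "breast",
    "nsclc",
    "colorectal",
    "bladder",
    "kidney",
    "melanoma",
    "other",
)

#: Canonical CSV column order (extra covariates are appended alphabetically).
DEFAULT_COLUMNS = (
    "id",
    "time_months",
    "event",
    "kps",
    "steroids",
    "liver_mets",
    "pleural_effusion",
    "primary_site",
    "bone_mets_only",
)

#: Default missing-value sentinel; the empty string is always treated as missing.
MISSING_SENTINEL = "NA"

_TRUE_TOKENS = frozenset({"yes", "true", "1"})
_FALSE_TOKENS = frozenset({"no", "false", "0"})


class SchemaError(ValueError):
    """A mandatory column is absent or the column mapping is malformed."""


class CohortValidationError(ValueError):
    """A cell failed validation; the message names the row and column."""


@dataclass
class PatientRecord:
    """One reirradiation course with its prognostic covariates.

    ``time_months`` is the observed follow-up (death or censoring) in months
    from the start of reirradiation; ``event`` is True when death was
    observed. All covariates other than ``event`` may be missing (``None``).
    ``extra_covariates`` holds further named categorical values (e.g.
    ``opioids``, ``brain_mets``) as strings.
    """

    id: str
    time_months: float
    event: bool
    kps: int | None = None
    steroids: bool | None = None
    liver_mets: bool | None = None
    pleural_effusion: bool | None = None
    primary_site: str | None = None
    bone_mets_only: bool | None = None
    extra_covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.event, bool):
            raise CohortValidationError(
                f"record {self.id!r}: event must be boolean, got {self.event!r}"
            )
        self.time_months = float(self.time_months)
        if self.time_months < 0:
            raise CohortValidationError(
                f"record {self.id!r}: time_months must be >= 0, got {self.time_months}"
            )
        if self.kps is not None:
            self.kps = int(self.kps)
            if self.kps not in KPS_LEVELS:
                raise CohortValidationError(
                    f"record {self.id!r}: kps must be one of {KPS_LEVELS}, got {self.kps}"
                )
        if self.primary_site is not None and self.primary_site not in PRIMARY_SITES:
            raise CohortValidationError(
                f"record {self.id!r}: primary_site must be one of {PRIMARY_SITES}, "
                f"got {self.primary_site!r}"
            )


@dataclass
class Cohort:
    """An ordered collection of reirradiation courses with unique ids."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.patients[i]

    def subset(self, predicate: Callable[[PatientRecord], bool], provenance: str = "") -> "Cohort":
        return Cohort(
            [p for p in self.patients if predicate(p)],
            provenance=provenance or f"{self.provenance}|subset",
        )


# ---------------------------------------------------------------------------
# Prognostic factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpec:
    """A named grouping of patients into categorical levels.

    ``levels`` is ordered with the reference (favorable) level first;
    ``extract`` maps a record to its level label, or None when missing.
    """

    name: str
    levels: tuple[str, ...]
    extract: Callable[[PatientRecord], str | None]

    def level_of(self, record: PatientRecord) -> str | None:
        lvl = self.extract(record)
        if lvl is not None and lvl not in self.levels:
            raise CohortValidationError(
                f"factor {self.name!r}: record {record.id!r} yields level {lvl!r}, "
                f"allowed {self.levels}"
            )
        return lvl


def _bool_level(value: bool | None) -> str | None:
    if value is None:
        return None
    return "yes" if value else "no"


def _kps_group3(r: PatientRecord) -> str | None:
    if r.kps is None:
        return None
    if r.kps >= 90:
        return "90-100"
    if r.kps >= 70:
        return "70-80"
    return "<=60"


def _kps_group2(r: PatientRecord) -> str | None:
    if r.kps is None:
        return None
    return "70-100" if r.kps >= 70 else "<=60"


#: Built-in factors. ``kps_group`` is the 3-level split used for univariate
#: screening and multivariate selection; ``kps_le60`` the 2-level split used
#: by the point score.
BUILTIN_FACTORS: dict[str, FactorSpec] = {
    "kps_group": FactorSpec("kps_group", ("90-100", "70-80", "<=60"), _kps_group3),
    "kps_le60": FactorSpec("kps_le60", ("70-100", "<=60"), _kps_group2),
    "steroids": FactorSpec("steroids", ("no", "yes"), lambda r: _bool_level(r.steroids)),
    "liver_mets": FactorSpec("liver_mets", ("no", "yes"), lambda r: _bool_level(r.liver_mets)),
    "pleural_effusion": FactorSpec(
        "pleural_effusion", ("no", "yes"), lambda r: _bool_level(r.pleural_effusion)
    ),
    "bone_mets_only": FactorSpec(
        "bone_mets_only", ("yes", "no"), lambda r: _bool_level(r.bone_mets_only)
    ),
    "primary_site": FactorSpec("primary_site", PRIMARY_SITES, lambda r: r.primary_site),
}


def _extra_factor(name: str) -> FactorSpec:
    def extract(r: PatientRecord, _name: str = name) -> str | None:
        raw = r.extra_covariates.get(_name)
        if raw is None or raw == "":
            return None
        token = str(raw).strip().lower()
        if token in _TRUE_TOKENS:
            return "yes"
        if token in _FALSE_TOKENS:
            return "no"
        return token

    return FactorSpec(name, ("no", "yes"), extract)


def get_factor(name: str) -> FactorSpec:
    """Resolve a factor by name: built-in first, else a yes/no factor read
    from ``extra_covariates[name]``."""
    try:
        return BUILTIN_FACTORS[name]
    except KeyError:
        return _extra_factor(name)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_bool(token: str, row: int, column: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise CohortValidationError(
        f"row {row}, column {column!r}: cannot parse boolean from {token!r} "
        f"(accepted: yes/no/true/false/1/0)"
    )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    missing_sentinel: str = MISSING_SENTINEL,
    provenance: str | None = None,
) -> Cohort:
    """Read a cohort from a UTF-8 CSV file with a header row.

    Parameters
    ----------
    path
        CSV file location.
    schema
        Optional mapping ``PatientRecord field -> CSV column name``; fields
        not mentioned use their own name as the column. ``time_months`` and
        ``event`` are mandatory; all other known columns are optional.
        Columns not mapped to any field become ``extra_covariates``.
    missing_sentinel
        Cell value treated as missing (besides the empty string).

    Raises
    ------
    SchemaError
        when a mandatory column is absent.
    CohortValidationError
        when a cell fails validation; the message names row and column.
    """
    path = Path(path)
    field_to_col = {f: f for f in DEFAULT_COLUMNS}
    if schema:
        field_to_col.update(schema)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, header row required")
        for mandatory in ("time_months", "event"):
            if field_to_col[mandatory] not in header:
                raise SchemaError(
                    f"{path}: mandatory column {field_to_col[mandatory]!r} "
                    f"(field {mandatory!r}) not found in header {header}"
                )
        known_cols = {c for c in field_to_col.values() if c in header}
        extra_cols = [c for c in header if c not in known_cols]

        def cell(row: dict, fieldname: str) -> str | None:
            col = field_to_col[fieldname]
            raw = row.get(col)
            if raw is None:
                return None
            raw = raw.strip()
            if raw == "" or raw == missing_sentinel:
                return None
            return raw

        patients: list[PatientRecord] = []
        for idx, row in enumerate(reader):
            rownum = idx + 2  # 1-based, counting the header
            raw_time = cell(row, "time_months")
            raw_event = cell(row, "event")
            if raw_time is None:
                raise CohortValidationError(
                    f"row {rownum}, column {field_to_col['time_months']!r}: "
                    "survival time is mandatory"
                )
            if raw_event is None:
                raise CohortValidationError(
                    f"row {rownum}, column {field_to_col['event']!r}: event is mandatory"
                )
            try:
                time_months = float(raw_time)
            except ValueError:
                raise CohortValidationError(
                    f"row {rownum}, column {field_to_col['time_months']!r}: "
                    f"cannot parse number from {raw_time!r}"
                ) from None
            if time_months < 0:
                raise CohortValidationError(
                    f"row {rownum}, column {field_to_col['time_months']!r}: "
                    f"negative survival time {time_months}"
                )
            event = _parse_bool(raw_event, rownum, field_to_col["event"])

            raw_kps = cell(row, "kps")
            kps: int | None = None
            if raw_kps is not None:
                try:
                    kps = int(float(raw_kps))
                except ValueError:
                    raise CohortValidationError(
                        f"row {rownum}, column {field_to_col['kps']!r}: "
                        f"cannot parse integer from {raw_kps!r}"
                    ) from None
                if kps not in KPS_LEVELS:
                    raise CohortValidationError(
                        f"row {rownum}, column {field_to_col['kps']!r}: "
                        f"kps {kps} not in allowed levels {KPS_LEVELS}"
                    )

            def opt_bool(fieldname: str) -> bool | None:
                raw = cell(row, fieldname)
                if raw is None:
                    return None
                return _parse_bool(raw, rownum, field_to_col[fieldname])

            raw_site = cell(row, "primary_site")
            if raw_site is not None and raw_site not in PRIMARY_SITES:
                raise CohortValidationError(
                    f"row {rownum}, column {field_to_col['primary_site']!r}: "
                    f"unknown level {raw_site!r}, allowed {PRIMARY_SITES}"
                )

            raw_id = cell(row, "id")
            extras = {}
            for c in extra_cols:
                raw = row.get(c)
                if raw is None:
                    continue
                raw = raw.strip()
                if raw != "" and raw != missing_sentinel:
                    extras[c] = raw

            patients.append(
                PatientRecord(
                    id=raw_id if raw_id is not None else f"row{rownum}",
                    time_months=time_months,
                    event=event,
                    kps=kps,
                    steroids=opt_bool("steroids"),
                    liver_mets=opt_bool("liver_mets"),
                    pleural_effusion=opt_bool("pleural_effusion"),
                    primary_site=raw_site,
                    bone_mets_only=opt_bool("bone_mets_only"),
                    extra_covariates=extras,
                )
            )
    return Cohort(patients, provenance=provenance if provenance is not None else str(path))


def _format_value(value, missing_sentinel: str) -> str:
    if value is None:
        return missing_sentinel
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    missing_sentinel: str = MISSING_SENTINEL,
) -> Path:
    """Write a cohort as CSV with a stable column order.

    Known fields come first in :data:`DEFAULT_COLUMNS` order, then the union
    of extra-covariate names sorted alphabetically. Missing values are
    written as ``missing_sentinel``. Returns the path written.
    """
    path = Path(path)
    extra_names = sorted({k for p in cohort for k in p.extra_covariates})
    columns = list(DEFAULT_COLUMNS) + extra_names
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for p in cohort:
            row = [
                p.id,
                repr(p.time_months),
                "true" if p.event else "false",
                _format_value(p.kps, missing_sentinel),
                _format_value(p.steroids, missing_sentinel),
                _format_value(p.liver_mets, missing_sentinel),
                _format_value(p.pleural_effusion, missing_sentinel),
                _format_value(p.primary_site, missing_sentinel),
                _format_value(p.bone_mets_only, missing_sentinel),
            ]
            row += [p.extra_covariates.get(name, missing_sentinel) for name in extra_names]
            writer.writerow(row)
    return path


def cohort_to_dataframe(cohort: Cohort) -> pd.DataFrame:
    """Tidy view of the cohort for modelling/reporting (one row per course)."""
    extra_names = sorted({k for p in cohort for k in p.extra_covariates})
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "time_months": p.time_months,
            "event": p.event,
            "kps": p.kps,
            "steroids": p.steroids,
            "liver_mets": p.liver_mets,
            "pleural_effusion": p.pleural_effusion,
            "primary_site": p.primary_site,
            "bone_mets_only": p.bone_mets_only,
        }
        for name in extra_names:
            row[name] = p.extra_covariates.get(name)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS) + extra_names)
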