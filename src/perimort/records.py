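"""Pregnancy-record ingestion, eligibility filtering, and interval restructuring.

A cohort of pregnancies of at least seven months' gestation is followed from
late gestation through the ninth day of life and restructured onto ten
analysis intervals::

    j=1   STB    stillbirth (fetal death at >=7 months' gestation)
    j=2   D0-1   death on day 0 or 1 of life (pooled: day-0 vs day-1
                 recording is inconsistent across surveys)
    j=3..10      single days 2..9

Everything still alive at the start of day 10 is censored there, as are
ongoing pregnancies (censored in the stillbirth interval).  Because censoring
occurs only at interval boundaries, the at-risk accounting is the exact flow
``n[j+1] = n[j] - d[j] - c[j]``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTERVAL_LABELS",
    "N_INTERVALS",
    "OUTCOMES",
    "PregnancyRecord",
    "EligibilityRules",
    "IntervalCountTable",
    "RecordValidationError",
    "SchemaError",
    "read_pregnancy_table",
    "records_to_frame",
    "frame_to_records",
    "apply_eligibility",
    "build_interval_counts",
]

def json_default(obj):
    """``json.dumps`` fallback for numpy scalars and arrays."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"Object of type {type(obj).__name__} is not JSON serializable")


#: Ordered labels of the ten analysis intervals.
INTERVAL_LABELS = ("STB", "D0-1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9")
N_INTERVALS = 10

OUTCOMES = ("stillbirth", "livebirth", "ongoing")

#: Columns the delimited-text reader requires.
REQUIRED_COLUMNS = (
    "survey_id",
    "record_id",
    "gestation_months",
    "conception_offset_months",
    "outcome",
)
#: Optional columns (defaults applied / allowed missing per-row).
OPTIONAL_COLUMNS = (
    "child_alive",
    "age_at_death_days",
    "current_age_months",
    "weight",
)


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be parsed."""


class RecordValidationError(ValueError):
    """One or more rows violate a record invariant.

    The message lists every offending row number (1-based, excluding the
    header) together with its record_id and the reason.
    """

    def __init__(self, problems: Sequence[tuple[int, str, str]]):
        self.problems = list(problems)
        lines = [f"row {r}: record_id={rid!r}: {why}" for r, rid, why in self.problems]
        super().__init__("invalid pregnancy records:\n" + "\n".join(lines))


@dataclass
class PregnancyRecord:
    """A single pregnancy of >=7 months' gestation.

    ``age_at_death_days`` must be present if and only if the pregnancy ended
    in a livebirth and the child has died; ``current_age_months`` describes
    surviving children and ongoing pregnancies.
    """

    survey_id: str
    record_id: str
    gestation_months: int
    conception_offset_months: int
    outcome: str
    child_alive: bool | None = None
    age_at_death_days: int | None = None
    current_age_months: int | None = None
    sampling_weight: float = 1.0
    covariates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.gestation_months < 0:
            raise ValueError("gestation_months must be >= 0")
        if self.sampling_weight <= 0:
            raise ValueError("sampling_weight must be > 0")
        dead_livebirth = self.outcome == "livebirth" and self.child_alive is False
        if dead_livebirth and self.age_at_death_days is None:
            raise ValueError("dead livebirth lacks age_at_death_days")
        if not dead_livebirth and self.age_at_death_days is not None:
            raise ValueError("age_at_death_days present on a non-dead-livebirth record")
        if self.age_at_death_days is not None and self.age_at_death_days < 0:
            raise ValueError("age_at_death_days must be >= 0")
        if self.outcome == "livebirth" and self.child_alive is None:
            raise ValueError("livebirth lacks child_alive")


@dataclass
class EligibilityRules:
    """Cohort eligibility and censoring rules.

    Pregnancies terminated before ``min_gestation_months`` are excluded
    (the survey proxy for the 28-week stillbirth definition), as are
    pregnancies conceived outside ``conception_window_months`` before the
    interview.  With ``interview_month_rule`` on, livebirths in the month of
    the interview are assumed to have survived past day 9.  Follow-up is
    censored at the start of ``censor_day``.
    """

    min_gestation_months: int = 7
    conception_window_months: tuple[int, int] = (7, 66)
    interview_month_rule: bool = True
    censor_day: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.conception_window_months
        if lo > hi:
            raise ValueError("conception window lower bound exceeds upper bound")
        if lo < self.min_gestation_months:
            raise ValueError(
                "conception window lower bound must be >= min_gestation_months"
            )


@dataclass
class IntervalCountTable:
    """Weighted death/censoring/at-risk counts on the ten analysis intervals.

    Index 0 is the stillbirth interval, index 1 pools days 0-1, and indices
    2..9 are single days 2..9 (so ``deaths[k]`` is the day-k death count for
    k >= 2).  ``entrants`` is derived from the exact flow identity.
    """

    deaths: np.ndarray
    censored: np.ndarray
    total_pregnancies: float
    survey_id: str = ""
    d01_weight: float = 1.0
    entrants: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.censored = np.asarray(self.censored, dtype=float)
        if self.deaths.shape != (N_INTERVALS,) or self.censored.shape != (N_INTERVALS,):
            raise ValueError(f"deaths and censored must have length {N_INTERVALS}")
        n = np.empty(N_INTERVALS, dtype=float)
        n[0] = float(self.total_pregnancies)
        for j in range(N_INTERVALS - 1):
            n[j + 1] = n[j] - self.deaths[j] - self.censored[j]
        self.entrants = n
        self.validate()

    def validate(self) -> None:
        if np.any(self.deaths < 0) or np.any(self.censored < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.entrants < -1e-9):
            raise ValueError("negative at-risk count: flow accounting violated")
        if np.any(self.deaths - self.entrants > 1e-9):
            raise ValueError("deaths exceed entrants in some interval")
        if self.d01_weight < 1:
            raise ValueError("d01_weight must be >= 1")

    # -- convenience views used by the quality metrics -------------------
    @property
    def stillbirths(self) -> float:
        return float(self.deaths[0])

    @property
    def d01(self) -> float:
        """Deaths on days 0-1."""
        return float(self.deaths[1])

    @property
    def d26(self) -> float:
        """Deaths on days 2-6."""
        return float(self.deaths[2:7].sum())

    @property
    def first_week_deaths(self) -> float:
        """Early neonatal deaths (days 0-6)."""
        return float(self.deaths[1:7].sum())

    def day_deaths(self, day: int) -> float:
        """Death count on a single day of life, 2 <= day <= 9."""
        if not 2 <= day <= 9:
            raise ValueError("single-day counts exist only for days 2..9")
        return float(self.deaths[day])

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": list(INTERVAL_LABELS),
                "deaths": self.deaths,
                "entrants": self.entrants,
                "censored": self.censored,
            }
        )

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    def to_dict(self) -> dict:
        return {
            "survey_id": self.survey_id,
            "total_pregnancies": self.total_pregnancies,
            "d01_weight": self.d01_weight,
            "intervals": list(INTERVAL_LABELS),
            "deaths": self.deaths.tolist(),
            "entrants": self.entrants.tolist(),
            "censored": self.censored.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=json_default, **kwargs)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "IntervalCountTable":
        return cls(
            deaths=np.asarray(payload["deaths"], dtype=float),
            censored=np.asarray(payload["censored"], dtype=float),
            total_pregnancies=float(payload["total_pregnancies"]),
            survey_id=payload.get("survey_id", ""),
            d01_weight=float(payload.get("d01_weight", 1.0)),
        )

    @classmethod
    def from_json(cls, text: str) -> "IntervalCountTable":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# reading and validation


def _coerce_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str, str]]]:
    """Coerce column dtypes; return (frame, row-level problems)."""
    problems: list[tuple[int, str, str]] = []
    df = df.copy()
    df["survey_id"] = df["survey_id"].astype(str)
    df["record_id"] = df["record_id"].astype(str)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce").fillna(1.0)
    for col in ("child_alive", "age_at_death_days", "current_age_months"):
        if col not in df.columns:
            df[col] = pd.NA

    for col in ("gestation_months", "conception_offset_months", "age_at_death_days",
                "current_age_months"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append((i + 1, df.at[i, "record_id"], f"non-numeric {col}"))
        df[col] = coerced.astype("Float64")

    alive = df["child_alive"]
    if alive.dtype == object:
        mapping = {"true": True, "false": False, "1": True, "0": False,
                   "yes": True, "no": False, "": pd.NA}
        alive = alive.map(
            lambda v: mapping.get(str(v).strip().lower(), pd.NA) if pd.notna(v) else pd.NA
        )
    df["child_alive"] = alive.astype("boolean")
    df["outcome"] = df["outcome"].astype(str).str.strip().str.lower()
    return df, problems


def _validate_rows(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    problems: list[tuple[int, str, str]] = []
    for i in df.index:
        rid = df.at[i, "record_id"]
        row = i + 1
        outcome = df.at[i, "outcome"]
        if outcome not in OUTCOMES:
            problems.append((row, rid, f"unknown outcome {outcome!r}"))
            continue
        gest = df.at[i, "gestation_months"]
        if pd.notna(gest) and gest < 0:
            problems.append((row, rid, "negative gestation_months"))
        if pd.isna(gest):
            problems.append((row, rid, "missing gestation_months"))
        if df.at[i, "weight"] <= 0:
            problems.append((row, rid, "non-positive weight"))
        aad = df.at[i, "age_at_death_days"]
        alive = df.at[i, "child_alive"]
        if pd.notna(aad) and aad < 0:
            problems.append((row, rid, "negative age_at_death_days"))
        dead_lb = outcome == "livebirth" and pd.notna(alive) and not bool(alive)
        if outcome == "livebirth" and pd.isna(alive):
            problems.append((row, rid, "livebirth lacks child_alive"))
        elif dead_lb and pd.isna(aad):
            problems.append((row, rid, "dead livebirth lacks age_at_death_days"))
        elif not dead_lb and pd.notna(aad):
            problems.append(
                (row, rid, "age_at_death_days present on a non-dead-livebirth record")
            )
        cam = df.at[i, "current_age_months"]
        if pd.notna(cam) and cam < 0:
            problems.append((row, rid, "negative current_age_months"))
    return problems


def read_pregnancy_table(source, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited pregnancy table into a validated DataFrame.

    Parameters
    ----------
    source
        Path, file object, or string buffer. UTF-8, header row mandatory.
    delimiter
        Field delimiter; ``None`` auto-detects comma vs tab.

    Returns
    -------
    DataFrame with one row per pregnancy, input order preserved, weight
    defaulted to 1 where the column is absent.

    Raises
    ------
    SchemaError
        when a mandatory column is missing.
    RecordValidationError
        listing every row that fails type coercion or a record invariant.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        if delimiter is None:
            df = pd.read_csv(source, sep=None, engine="python", skipinitialspace=True)
        else:
            df = pd.read_csv(source, sep=delimiter, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # pragma: no cover - defensive
        raise SchemaError(f"cannot parse input: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.reset_index(drop=True)
    df, problems = _coerce_frame(df)
    problems += _validate_rows(df)
    if problems:
        raise RecordValidationError(sorted(set(problems)))
    return df


def records_to_frame(records: Iterable[PregnancyRecord]) -> pd.DataFrame:
    """Build a schema DataFrame from PregnancyRecord objects (each validated)."""
    rows = []
    for rec in records:
        rec.validate()
        rows.append(
            {
                "survey_id": rec.survey_id,
                "record_id": rec.record_id,
                "gestation_months": rec.gestation_months,
                "conception_offset_months": rec.conception_offset_months,
                "outcome": rec.outcome,
                "child_alive": rec.child_alive,
                "age_at_death_days": rec.age_at_death_days,
                "current_age_months": rec.current_age_months,
                "weight": rec.sampling_weight,
                **rec.covariates,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("gestation_months", "conception_offset_months",
                "age_at_death_days", "current_age_months"):
        df[col] = df[col].astype("Float64")
    df["child_alive"] = df["child_alive"].astype("boolean")
    return df


def frame_to_records(df: pd.DataFrame) -> list[PregnancyRecord]:
    """Convert a schema DataFrame to a list of PregnancyRecord objects."""
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    out = []
    for _, r in df.iterrows():
        out.append(
            PregnancyRecord(
                survey_id=str(r["survey_id"]),
                record_id=str(r["record_id"]),
                gestation_months=int(r["gestation_months"]),
                conception_offset_months=int(r["conception_offset_months"]),
                outcome=r["outcome"],
                child_alive=None if pd.isna(r["child_alive"]) else bool(r["child_alive"]),
                age_at_death_days=None
                if pd.isna(r["age_at_death_days"])
                else int(r["age_at_death_days"]),
                current_age_months=None
                if pd.isna(r["current_age_months"])
                else int(r["current_age_months"]),
                sampling_weight=float(r.get("weight", 1.0)),
                covariates={c: r[c] for c in extra},
            )
        )
    return out


# ---------------------------------------------------------------------------
# eligibility


def apply_eligibility(
    df: pd.DataFrame, rules: EligibilityRules | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply eligibility rules; return (retained frame, exclusion tally).

    Exclusion reasons partition the removed rows: ``gestation<min`` for
    pregnancies terminated before the minimum gestation, ``outside_window``
    for conceptions outside the allowed offset window.  Ongoing pregnancies
    of eligible gestation are retained (they are censored downstream).
    Re-applying the same rules to the retained frame excludes nothing.
    """
    rules = rules or EligibilityRules()
    lo, hi = rules.conception_window_months
    gest = df["gestation_months"].astype(float)
    short = gest < rules.min_gestation_months
    offset = df["conception_offset_months"].astype(float)
    outside = (~short) & ((offset < lo) | (offset > hi))
    keep = ~(short | outside)
    tally = {
        f"gestation<{rules.min_gestation_months}": int(short.sum()),
        "outside_window": int(outside.sum()),
    }
    return df.loc[keep].reset_index(drop=True), tally


# ---------------------------------------------------------------------------
# interval restructuring


def build_interval_counts(
    df: pd.DataFrame,
    use_weights: bool = False,
    rules: EligibilityRules | None = None,
    survey_id: str | None = None,
) -> IntervalCountTable:
    """Tabulate eligibility-filtered records onto the ten analysis intervals.

    Stillbirths die in interval 1; neonatal deaths on days 0-1 in interval 2;
    a death on day k (2 <= k <= 9) in interval k+1.  Survivors past day 9
    and deaths at >=10 days are censored at day 10; ongoing pregnancies are
    censored in the stillbirth interval.  With ``use_weights`` the counts are
    sampling-weight sums, otherwise unit counts.
    """
    rules = rules or EligibilityRules()
    if use_weights and "weight" in df.columns:
        w = df["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(df))
    deaths = np.zeros(N_INTERVALS)
    censored = np.zeros(N_INTERVALS)

    outcome = df["outcome"].to_numpy()
    alive = df["child_alive"].to_numpy(dtype=object)
    aad = df["age_at_death_days"].to_numpy(dtype=object)

    sb = outcome == "stillbirth"
    ongoing = outcome == "ongoing"
    lb = outcome == "livebirth"
    deaths[0] = w[sb].sum()
    censored[0] = w[ongoing].sum()

    lb_idx = np.flatnonzero(lb)
    for i in lb_idx:
        if alive[i] is True or alive[i] is np.True_:
            censored[9] += w[i]  # survived the analysis window
            continue
        if aad[i] is None or (isinstance(aad[i], float) and math.isnan(aad[i])) or pd.isna(aad[i]):
            raise ValueError(
                f"record_id={df.at[i, 'record_id']!r}: dead child without age_at_death_days"
            )
        day = int(aad[i])
        if day <= 1:
            deaths[1] += w[i]
        elif day < rules.censor_day:
            deaths[day] += w[i]
        else:
            censored[9] += w[i]  # survived the analysis window, died later
    return IntervalCountTable(
        deaths=deaths,
        censored=censored,
        total_pregnancies=float(w.sum()),
        survey_id=survey_id if survey_id is not None else _single_survey_id(df),
    )


def _single_survey_id(df: pd.DataFrame) -> str:
    ids = df["survey_id"].unique() if "survey_id" in df.columns else []
    return str(ids[0]) if len(ids) == 1 else ""
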