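"""Synthetic survey-like pregnancy cohorts with known truth and injected errors.

The generator emulates the structure of a household-survey reproductive
calendar linked to a birth history: one row per pregnancy of at least seven
months' gestation, with outcome, conception offset from the interview, age at
death in days for neonatal deaths, and current age for survivors.  True
mortality is controlled by a stillbirth risk and nine neonatal interval
hazards (pooled days 0-1, then single days 2-9), so the ground-truth rates
are known analytically from the parameters rather than from any one sample.

Reporting errors mirror the taxonomy seen in real surveys: omission of
stillbirths or very early neonatal deaths, transference between the two in
either direction, and heaping of the reported age at death onto day 7.
Per record the omit/relabel decision is a single mutually exclusive draw.

:func:`calibrated_cohort_params` builds a cohort whose *expected* death-count
ratios equal the reference constants (STB/D0-1 = 1.89, D0-1/D2-6 = 2.4),
the regime in which the adjustment models are correctly specified, and
:func:`recovery_experiment` measures how well each model recovers the true
rates from corrupted samples.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gm import AdjustmentConfig, adjust_survey
from .lifetable import MortalityRates
from .records import EligibilityRules, apply_eligibility, build_interval_counts

__all__ = [
    "TrueCohortParams",
    "ReportingErrorParams",
    "RecoveryResult",
    "calibrated_cohort_params",
    "error_preset",
    "true_rates",
    "expected_interval_deaths",
    "simulate_cohort",
    "inject_reporting_errors",
    "recovery_experiment",
]

#: Days whose reported age can be heaped onto day 7.
HEAP_SOURCE_DAYS = (5, 6, 8, 9)


@dataclass
class TrueCohortParams:
    """True data-generating parameters of a synthetic pregnancy cohort.

    ``daily_hazards`` holds nine conditional death probabilities matching
    the neonatal analysis intervals: pooled days 0-1, then single days 2-9.
    Conception offsets are drawn uniformly on ``conception_offset_range``
    (9..66 months by default so every completed pregnancy has nonnegative
    child age); ongoing pregnancies of 7-9 months replace a configurable
    fraction of the cohort and are censored in the stillbirth interval.
    Sampling weights are degenerate at 1 unless ``weight_lognormal_sigma``
    is positive.
    """

    n_pregnancies: int
    stillbirth_risk: float
    daily_hazards: tuple[float, ...]
    ongoing_fraction: float = 0.03
    conception_offset_range: tuple[int, int] = (9, 66)
    weight_lognormal_sigma: float = 0.0
    survey_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.daily_hazards = tuple(float(h) for h in self.daily_hazards)
        if len(self.daily_hazards) != 9:
            raise ValueError("daily_hazards must hold 9 values (D0-1, days 2..9)")
        probs = (self.stillbirth_risk, self.ongoing_fraction, *self.daily_hazards)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_pregnancies < 1:
            raise ValueError("n_pregnancies must be positive")


@dataclass
class ReportingErrorParams:
    """Reporting-error probabilities applied record by record.

    Omission and transference are mutually exclusive per record (one draw
    over keep / omit / relabel).  ``p_heap`` maps a source day in
    {5, 6, 8, 9} to the probability its death is recorded on day 7.
    """

    p_sb_omit: float = 0.0
    p_sb_to_d0: float = 0.0
    p_d0_to_sb: float = 0.0
    p_d01_omit: float = 0.0
    p_heap: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_sb_omit, self.p_sb_to_d0, self.p_d0_to_sb, self.p_d01_omit,
                 *self.p_heap.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_sb_omit + self.p_sb_to_d0 > 1.0:
            raise ValueError("stillbirth omit+relabel probabilities exceed 1")
        if self.p_d01_omit + self.p_d0_to_sb > 1.0:
            raise ValueError("D0-1 omit+relabel probabilities exceed 1")
        if any(d not in HEAP_SOURCE_DAYS for d in self.p_heap):
            raise ValueError(f"heaping source days must be in {HEAP_SOURCE_DAYS}")


def true_rates(params: TrueCohortParams) -> MortalityRates:
    """Analytic true rates implied by the parameters (the estimand)."""
    h = np.asarray(params.daily_hazards)
    q_en = 1.0 - (1.0 - h[0]) * np.prod(1.0 - h[1:6])
    sbr = 1000.0 * params.stillbirth_risk
    enmr = 1000.0 * q_en
    pmr = 1000.0 * (1.0 - (1.0 - params.stillbirth_risk) * (1.0 - q_en))
    return MortalityRates(sbr=sbr, enmr=enmr, pmr=pmr, model="observed")


def expected_interval_deaths(params: TrueCohortParams) -> np.ndarray:
    """Expected deaths per completed pregnancy on the ten analysis intervals."""
    out = np.zeros(10)
    out[0] = params.stillbirth_risk
    surv = 1.0 - params.stillbirth_risk
    for j, hz in enumerate(params.daily_hazards, start=1):
        out[j] = surv * hz
        surv *= 1.0 - hz
    return out


def calibrated_cohort_params(
    n_pregnancies: int,
    sbr_per_1000: float = 22.0,
    target_sb_d01: float = 1.89,
    target_d01_d26: float = 2.4,
    daily_decline: float = 0.65,
    ongoing_fraction: float = 0.03,
    survey_id: str = "synthetic",
) -> TrueCohortParams:
    """Cohort whose expected death-count ratios hit the reference constants.

    The day 2-9 hazards decline geometrically (``h_day_k = c * decline**(k-2)``);
    the D0-1 hazard and the scale ``c`` are solved so that the expected
    STB/D0-1 and D0-1/D2-6 ratios equal the targets exactly.
    """
    p_sb = sbr_per_1000 / 1000.0
    h01 = p_sb / (target_sb_d01 * (1.0 - p_sb))
    d2_expected = (1.0 - p_sb) * h01
    d26_target = d2_expected / target_d01_d26
    rho = daily_decline

    def gap(c: float) -> float:
        hz = c * rho ** np.arange(0, 5)  # days 2..6
        d26 = (1.0 - p_sb) * (1.0 - h01) * (1.0 - np.prod(1.0 - hz))
        return d26 - d26_target

    c = brentq(gap, 1e-12, 0.5, xtol=1e-15)
    hazards = (h01, *(c * rho ** k for k in range(8)))  # days 2..9
    return TrueCohortParams(
        n_pregnancies=n_pregnancies,
        stillbirth_risk=p_sb,
        daily_hazards=hazards,
        ongoing_fraction=ongoing_fraction,
        survey_id=survey_id,
    )


def error_preset(name: str, seed: int = 0) -> ReportingErrorParams:
    """Named reporting-error scenarios keyed to the plausibility archetypes.

    ``none``        error-free reporting;
    ``plausible``   mild heaping only — observed ratios stay in plausible bands;
    ``probable``    moderate stillbirth omission and heaping;
    ``improbable``  severe stillbirth omission and heaping;
    ``typical``     the corrupted-world regime most surveys show: stillbirth
                    omission and transference, strong D0-1 under-reporting,
                    and day-7 heaping near the corpus median.
    """
    heap = dict.fromkeys(HEAP_SOURCE_DAYS, 0.0)
    presets = {
        "none": dict(),
        "plausible": dict(p_heap=dict.fromkeys(HEAP_SOURCE_DAYS, 0.1)),
        "probable": dict(
            p_sb_omit=0.35, p_d01_omit=0.1, p_heap=dict.fromkeys(HEAP_SOURCE_DAYS, 0.3)
        ),
        "improbable": dict(
            p_sb_omit=0.6, p_heap=dict.fromkeys(HEAP_SOURCE_DAYS, 0.6)
        ),
        "typical": dict(
            p_sb_omit=0.35,
            p_sb_to_d0=0.05,
            p_d0_to_sb=0.03,
            p_d01_omit=0.40,
            p_heap=dict.fromkeys(HEAP_SOURCE_DAYS, 0.3),
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = {"p_heap": dict(heap), **presets[name]}
    return ReportingErrorParams(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# simulation


def simulate_cohort(
    params: TrueCohortParams, seed: int
) -> tuple[pd.DataFrame, MortalityRates]:
    """Draw one cohort; return (records frame, analytic true rates).

    Reproducible: a fixed seed yields an identical frame.  The truth is
    computed from the parameters, not from the sample.
    """
    rng = np.random.default_rng(seed)
    n = params.n_pregnancies
    lo, hi = params.conception_offset_range

    ongoing = rng.random(n) < params.ongoing_fraction
    sb = (~ongoing) & (rng.random(n) < params.stillbirth_risk)
    lb = ~ongoing & ~sb

    gestation = np.full(n, 9, dtype=int)
    gestation[ongoing] = rng.integers(7, 10, size=int(ongoing.sum()))
    gestation[sb] = rng.integers(7, 10, size=int(sb.sum()))

    offset = rng.integers(lo, hi + 1, size=n)
    offset[ongoing] = gestation[ongoing]
    # completed pregnancies need offset >= gestation for nonnegative child age
    offset = np.maximum(offset, gestation)

    # neonatal deaths: pass livebirths through the nine interval hazards
    stage = np.full(n, -1, dtype=int)
    alive = lb.copy()
    for s, hz in enumerate(params.daily_hazards):
        u = rng.random(n)
        dies = alive & (u < hz)
        stage[dies] = s
        alive &= ~dies

    age_days = np.full(n, -1, dtype=int)
    d01 = stage == 0
    age_days[d01] = rng.integers(0, 2, size=int(d01.sum()))
    later = stage >= 1
    age_days[later] = stage[later] + 1

    weight = np.ones(n)
    if params.weight_lognormal_sigma > 0:
        weight = rng.lognormal(0.0, params.weight_lognormal_sigma, size=n)

    outcome = np.where(ongoing, "ongoing", np.where(sb, "stillbirth", "livebirth"))
    # child_alive: livebirth rows only; True iff never died
    child_alive = pd.array(
        [(stage[i] < 0) if lb[i] else None for i in range(n)], dtype="boolean"
    )
    df = pd.DataFrame(
        {
            "survey_id": params.survey_id,
            "record_id": [f"{params.survey_id}-{i:07d}" for i in range(n)],
            "gestation_months": gestation,
            "conception_offset_months": offset,
            "outcome": outcome,
            "child_alive": child_alive,
            "age_at_death_days": pd.array(
                [int(age_days[i]) if age_days[i] >= 0 else None for i in range(n)],
                dtype="Float64",
            ),
            "current_age_months": pd.array(
                [
                    int(offset[i] - gestation[i]) if (lb[i] and stage[i] < 0) else None
                    for i in range(n)
                ],
                dtype="Float64",
            ),
            "weight": weight,
        }
    )
    df["gestation_months"] = df["gestation_months"].astype("Float64")
    df["conception_offset_months"] = df["conception_offset_months"].astype("Float64")
    return df, true_rates(params)


def inject_reporting_errors(
    df: pd.DataFrame, errors: ReportingErrorParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a cohort with omission, transference, and heaping.

    Returns the corrupted frame and a truth ledger (one row per affected
    record: action taken, true and recorded outcome/age).  Records absent
    from the ledger are unchanged; the output size equals the input size
    minus the omitted rows.
    """
    rng = np.random.default_rng(errors.seed)
    out = df.copy().reset_index(drop=True)
    ledger_rows: list[dict] = []

    # true (pre-corruption) state, frozen before any mutation
    true_outcome = out["outcome"].to_numpy().copy()
    true_aad = out["age_at_death_days"].to_numpy(dtype=object).copy()
    alive = out["child_alive"].to_numpy(dtype=object)
    rid = out["record_id"].to_numpy()

    def _log(i: int, action: str, rec_outcome, rec_age) -> None:
        ta = true_aad[i]
        ledger_rows.append(
            {
                "record_id": rid[i],
                "action": action,
                "true_outcome": true_outcome[i],
                "true_age_at_death_days": None if pd.isna(ta) else int(ta),
                "recorded_outcome": rec_outcome,
                "recorded_age_at_death_days": rec_age,
            }
        )

    drop: set[int] = set()

    sb_idx = np.flatnonzero(true_outcome == "stillbirth")
    u = rng.random(sb_idx.size)
    for i, ui in zip(sb_idx, u):
        if ui < errors.p_sb_omit:
            drop.add(i)
            _log(i, "omitted", None, None)
        elif ui < errors.p_sb_omit + errors.p_sb_to_d0:
            out.at[i, "outcome"] = "livebirth"
            out.at[i, "child_alive"] = False
            out.at[i, "age_at_death_days"] = 0
            _log(i, "relabelled_sb_to_d0", "livebirth", 0)

    d01_idx = [
        i
        for i in range(len(out))
        if true_outcome[i] == "livebirth"
        and not pd.isna(alive[i])
        and not bool(alive[i])
        and not pd.isna(true_aad[i])
        and int(true_aad[i]) <= 1
    ]
    u = rng.random(len(d01_idx))
    for i, ui in zip(d01_idx, u):
        if ui < errors.p_d01_omit:
            drop.add(i)
            _log(i, "omitted", None, None)
        elif ui < errors.p_d01_omit + errors.p_d0_to_sb:
            out.at[i, "outcome"] = "stillbirth"
            out.at[i, "child_alive"] = None
            out.at[i, "age_at_death_days"] = None
            _log(i, "relabelled_d0_to_sb", "stillbirth", None)

    heap_idx = [
        i
        for i in range(len(out))
        if i not in drop
        and true_outcome[i] == "livebirth"
        and not pd.isna(true_aad[i])
        and int(true_aad[i]) in errors.p_heap
    ]
    u = rng.random(len(heap_idx))
    for i, ui in zip(heap_idx, u):
        day = int(true_aad[i])
        if ui < errors.p_heap.get(day, 0.0):
            out.at[i, "age_at_death_days"] = 7
            _log(i, "heaped_to_day7", "livebirth", 7)

    corrupted = out.drop(index=sorted(drop)).reset_index(drop=True)
    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "record_id",
            "action",
            "true_outcome",
            "true_age_at_death_days",
            "recorded_outcome",
            "recorded_age_at_death_days",
        ],
    )
    return corrupted, ledger


# ---------------------------------------------------------------------------
# recovery experiment


@dataclass
class RecoveryResult:
    """Bias/RMSE of the four models against the analytic truth."""

    summary: pd.DataFrame
    frac_model4_better_pmr: float
    truth: MortalityRates
    n_reps: int
    n_failed: int
    per_rep: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.to_dict(),
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "frac_model4_better_pmr": self.frac_model4_better_pmr,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
        }


def recovery_experiment(
    cohort: TrueCohortParams,
    errors: ReportingErrorParams,
    n_reps: int,
    seed: int,
    config: AdjustmentConfig | None = None,
    keep_reps: bool = False,
) -> RecoveryResult:
    """Simulate -> corrupt -> adjust, ``n_reps`` times; score each model.

    Per replicate the cohort is drawn, corrupted, passed through eligibility
    filtering and interval tabulation, and the four models are fitted; each
    model's rates are compared with the analytic truth.  The summary holds
    mean bias and RMSE per model and rate plus the fraction of replicates in
    which model 4's absolute perinatal-rate error beats model 1's.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or AdjustmentConfig()
    truth = true_rates(cohort)
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    err_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rows: list[dict] = []
    n_failed = 0
    for r in range(n_reps):
        try:
            df, _ = simulate_cohort(cohort, seed=int(sim_seeds[r]))
            err = dataclasses.replace(errors, seed=int(err_seeds[r]))
            corrupted, _ledger_df = inject_reporting_errors(df, err)
            retained, _tally = apply_eligibility(corrupted, EligibilityRules())
            table = build_interval_counts(retained, use_weights=config.use_weights)
            est = adjust_survey(table, config=config)
            for m, res in est.models.items():
                if res.error is not None:
                    raise RuntimeError(f"model {m}: {res.error}")
                rows.append(
                    {
                        "rep": r,
                        "model": m,
                        "sbr": res.rates.sbr,
                        "enmr": res.rates.enmr,
                        "pmr": res.rates.pmr,
                    }
                )
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            n_failed += 1
            rows = [row for row in rows if row["rep"] != r]
            warnings.warn(f"replicate {r} failed and was excluded: {exc}", stacklevel=2)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise RuntimeError("all replicates failed")
    for name in ("sbr", "enmr", "pmr"):
        per_rep[f"err_{name}"] = per_rep[name] - getattr(truth, name)
    summary = (
        per_rep.groupby("model")
        .agg(
            **{
                f"{stat}_{name}": (f"err_{name}", fn)
                for name in ("sbr", "enmr", "pmr")
                for stat, fn in (("bias", "mean"), ("rmse", lambda s: float(np.sqrt(np.mean(s**2)))))
            }
        )
        .sort_index()
    )
    wide = per_rep.pivot(index="rep", columns="model", values="err_pmr")
    frac = float((wide[4].abs() < wide[1].abs()).mean()) if {1, 4} <= set(wide.columns) else float("nan")
    return RecoveryResult(
        summary=summary,
        frac_model4_better_pmr=frac,
        truth=truth,
        n_reps=n_reps,
        n_failed=n_failed,
        per_rep=per_rep if keep_reps else None,
    )
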