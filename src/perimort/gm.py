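"""Modified Gompertz-Makeham adjustment of stillbirth and neonatal risks.

The observed life table (model 1) is distorted by three reporting problems:
stillbirth omission/transference, under-reporting of deaths on days 0-1, and
heaping of the reported age at death on day 7.  The adjustment keeps the
interval-censored binomial likelihood with a complementary log-log link but
replaces the saturated linear predictor with

* ``gamma_1`` for the stillbirth interval,
* ``gamma_2`` for the pooled days 0-1,
* ``log h_j`` with a Makeham-plus-Gompertz daily hazard
  ``h_j = gamma_0 + exp(alpha + beta * x_j)`` for days 2-9
  (``x_j`` the day midpoint 2.5 .. 9.5).

The three-parameter smooth hazard for days 2-9 cannot reproduce a spike at
day 7, so fitting it redistributes heaped deaths over neighbouring days.

Two data-driven corrections are layered on top:

* **D0-1 weighting** (models 3 and 4): when the observed D0-1/D2-6 ratio
  falls below the reference value 2.4, deaths on days 0-1 are inflated by
  ``2.4 / observed ratio`` so the weighted ratio equals the reference.
* **Stillbirth constraint** (models 2 and 4): when the observed STB/D0-1
  ratio falls below the reference value 1.89, the observed stillbirth count
  is treated as unreliable; the stillbirth coefficient is imputed from the
  neonatal data through the exact hazard-scale constraint
  ``gamma_1 = gamma_2 + log(1.89)``, and the stillbirth interval is dropped
  from the likelihood.  (A joint refit that retains the under-reported
  stillbirth count would let the omitted deaths drag the constrained
  estimate far below the reference ratio's implication; see
  ``docs/methods.md`` for the rationale.)

Model 4 weights first, re-evaluates the stillbirth ratio on the weighted
table, and then applies the constraint if it still triggers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .records import INTERVAL_LABELS, N_INTERVALS, IntervalCountTable, json_default
from .quality import (
    CONSTRAINT_CONSTANT,
    WEIGHT_CONSTANT,
    QualityMetrics,
    ReferenceBands,
    default_bands,
    quality_report,
)
from .lifetable import (
    LifeTable,
    MortalityRates,
    PiecewiseExponentialModel,
    binomial_loglik,
    cloglog,
    inv_cloglog,
    rates_from_lifetable,
)

__all__ = [
    "DAY_MIDPOINTS",
    "GMParameters",
    "AdjustmentConfig",
    "ModelResult",
    "AdjustedEstimates",
    "apply_d01_weighting",
    "GompertzMakehamModel",
    "fit_gm",
    "adjust_survey",
    "SurveyAdjuster",
]

#: Midpoints of the single-day intervals (days 2..9).
DAY_MIDPOINTS = np.arange(2.5, 10.0, 1.0)

RATE_NAMES = ("sbr", "enmr", "pmr")


@dataclass
class GMParameters:
    """Fitted coefficients of the modified Gompertz-Makeham model.

    ``gamma1``/``gamma2`` are the cloglog coefficients of the stillbirth and
    days-0-1 intervals; days 2-9 share the smooth hazard
    ``gamma0 + exp(alpha + beta * x)``.  When ``constraint_active``,
    ``gamma1 - gamma2 == log(constraint_constant)`` exactly by construction.
    """

    gamma1: float
    gamma2: float
    gamma0: float
    alpha: float
    beta: float
    constraint_active: bool
    d01_weight: float
    loglik: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AdjustmentConfig:
    """Tuning knobs of the adjustment procedure.

    ``constraint_constant`` and ``weight_constant`` are fixed reference
    values of the method (corpus medians), not re-estimated from the input.
    """

    constraint_constant: float = CONSTRAINT_CONSTANT
    weight_constant: float = WEIGHT_CONSTANT
    models: tuple[int, ...] = (1, 2, 3, 4)
    tol: float = 1e-8
    max_iter: int = 500
    restarts: int = 3
    weighting_balance: str = "reduce-entrants"
    use_weights: bool = False

    def __post_init__(self) -> None:
        if any(m not in (1, 2, 3, 4) for m in self.models):
            raise ValueError("models must be a subset of {1,2,3,4}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.weighting_balance not in ("reduce-entrants", "inflate-cohort"):
            raise ValueError("weighting_balance must be reduce-entrants or inflate-cohort")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "AdjustmentConfig":
        payload = dict(payload)
        if "models" in payload:
            payload["models"] = tuple(int(m) for m in payload["models"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# D0-1 weighting


def apply_d01_weighting(
    table: IntervalCountTable,
    weight_constant: float = WEIGHT_CONSTANT,
    balance: str = "reduce-entrants",
) -> tuple[IntervalCountTable, float]:
    """Inflate D0-1 deaths so that the D0-1/D2-6 ratio meets the reference.

    With observed ratio ``r = d01 / d26`` below ``weight_constant``, D0-1
    deaths are multiplied by ``weight_constant / r``; tables at or above the
    reference are returned unchanged with weight 1.  ``balance`` decides how
    flow conservation is restored: ``reduce-entrants`` (default) lets the
    extra deaths deplete later at-risk counts; ``inflate-cohort`` adds the
    extra deaths as additional pregnancies so later entrants are untouched.

    A zero D0-1 count cannot be rescaled (the ratio degenerates to 0); the
    table is returned unchanged with weight 1.

    Raises
    ------
    ValueError
        when there are no deaths on days 2-6 (the ratio is undefined) or the
        inflated deaths exceed the at-risk count.
    """
    d26 = table.d26
    if d26 == 0:
        raise ValueError("weighting undefined: no deaths on days 2-6")
    d01 = table.d01
    if d01 == 0:
        return table, 1.0
    r = d01 / d26
    if r >= weight_constant:
        return table, 1.0
    w = weight_constant / r
    deaths = table.deaths.copy()
    censored = table.censored.copy()
    deaths[1] = d01 * w
    total = table.total_pregnancies
    extra = deaths[1] - d01
    if balance == "inflate-cohort":
        total = total + extra
    else:
        # later entrants shrink; absorb the shortfall in the day-10 censoring
        n = np.empty(N_INTERVALS)
        n[0] = total
        for j in range(N_INTERVALS - 1):
            n[j + 1] = n[j] - deaths[j] - censored[j]
        new_c10 = n[9] - deaths[9]
        if new_c10 < 0 or np.any(n[1:] < deaths[1:]):
            raise ValueError("weighting would exhaust the cohort")
        censored[9] = new_c10
    if deaths[1] > (total - deaths[0] - censored[0]) + 1e-9:
        raise ValueError("weighted D0-1 deaths exceed livebirths at risk")
    out = IntervalCountTable(
        deaths=deaths,
        censored=censored,
        total_pregnancies=total,
        survey_id=table.survey_id,
        d01_weight=w,
    )
    return out, float(w)


# ---------------------------------------------------------------------------
# Gompertz-Makeham fitting


def _smooth_nll(theta: np.ndarray, d: np.ndarray, n: np.ndarray) -> float:
    g0, a, b = theta
    h = g0 + np.exp(a + b * DAY_MIDPOINTS)
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log(-np.expm1(-h))
    term = np.where(d > 0, d * np.where(np.isfinite(logq), logq, -1e12), 0.0)
    return float(-(term - (n - d) * h).sum())


def _fit_smooth_hazard(
    d: np.ndarray, n: np.ndarray, tol: float, max_iter: int, restarts: int
) -> tuple[float, float, float, bool]:
    """Maximum-likelihood (gamma0, alpha, beta) for the days 2-9 hazard."""
    if d.sum() == 0:
        return 0.0, -np.inf, 0.0, True
    with np.errstate(divide="ignore", invalid="ignore"):
        crude = np.where(n > 0, d / np.maximum(n, 1e-12), 0.0)
    level = max(float(crude[n > 0].mean()), 1e-8)
    starts = [
        (level / 2.0, math.log(level / 2.0), -0.3),
        (1e-8, math.log(level), -0.3),
        (0.9 * level, math.log(level) - 2.0, 0.0),
    ]
    # deterministic extra starts if more restarts requested
    for k in range(3, restarts):
        starts.append((level / (k + 1), math.log(level) - k, -0.1 * k))
    bounds = [(0.0, 1.0), (-30.0, 2.0), (-5.0, 5.0)]
    best = None
    trace = []
    for s in starts[: max(restarts, 3)]:
        res = minimize(
            _smooth_nll,
            x0=np.asarray(s),
            args=(d, n),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "maxiter": max_iter},
        )
        trace.append((s, res.fun, res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):  # pragma: no cover - defensive
        raise RuntimeError(f"Gompertz-Makeham hazard fit failed; trace: {trace}")
    if not any(ok for _, _, ok in trace):
        raise RuntimeError(
            f"Gompertz-Makeham hazard fit did not converge from any start; trace: {trace}"
        )
    g0, a, b = best.x
    return float(g0), float(a), float(b), bool(best.success)


class GompertzMakehamModel(BaseEstimator):
    """Constrained modified Gompertz-Makeham mortality model (models 2-4).

    scikit-learn style estimator over an
    :class:`~perimort.records.IntervalCountTable` (or a pregnancy-record
    DataFrame, tabulated unweighted first).

    Parameters
    ----------
    constraint : {"auto", True, False}, default "auto"
        Apply the stillbirth hazard constraint
        ``gamma1 = gamma2 + log(constraint_constant)``.  Under ``"auto"``
        (and also ``True``, which merely requests it) the constraint is
        applied only when the observed STB/D0-1 ratio is below
        ``constraint_constant``; otherwise it is skipped and flagged.
    weighting : {"auto", True, False}, default False
        Apply the D0-1 weighting before fitting when the observed
        D0-1/D2-6 ratio is below ``weight_constant``.
    constraint_constant, weight_constant : float
        Fixed reference ratios (defaults 1.89 and 2.4).
    tol, max_iter, restarts
        Optimizer controls for the smooth-hazard likelihood maximization.
    weighting_balance : str
        Flow-conservation mode passed to :func:`apply_d01_weighting`.

    Attributes
    ----------
    params_ : GMParameters
    life_table_ : LifeTable
    rates_ : MortalityRates
    loglik_ : float
        Binomial log-likelihood of the fitted risks on the table the model
        was fitted to (the weighted table for models 3-4).
    loglik_input_ : float
        Same fitted risks evaluated on the unweighted input table; this is
        the quantity to compare across constrained/unconstrained fits.
    fitted_heaping_index_ : float or None
        Heaping index recomputed from the fitted expected deaths on days 5-9.
    d01_weight_ : float
    constraint_active_ : bool
    flags_ : list of str
    """

    def __init__(
        self,
        constraint: bool | str = "auto",
        weighting: bool | str = False,
        constraint_constant: float = CONSTRAINT_CONSTANT,
        weight_constant: float = WEIGHT_CONSTANT,
        tol: float = 1e-8,
        max_iter: int = 500,
        restarts: int = 3,
        weighting_balance: str = "reduce-entrants",
        source: str | None = None,
    ):
        self.constraint = constraint
        self.weighting = weighting
        self.constraint_constant = constraint_constant
        self.weight_constant = weight_constant
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.weighting_balance = weighting_balance
        self.source = source

    def fit(self, X, y=None):
        from .lifetable import _as_table

        raw = _as_table(X)
        if raw.entrants[0] <= 0:
            raise ValueError("empty cohort: no pregnancies at risk")
        self.input_table_ = raw
        self.flags_ = []

        # --- optional D0-1 weighting -----------------------------------
        w = 1.0
        table = raw
        if self.weighting in (True, "auto"):
            if raw.d26 == 0:
                raise ValueError("weighting undefined: no deaths on days 2-6")
            if raw.d01 == 0:
                self.flags_.append("weighting degenerate: zero D0-1 deaths")
            else:
                table, w = apply_d01_weighting(
                    raw, self.weight_constant, balance=self.weighting_balance
                )
                if w == 1.0:
                    self.flags_.append("weighting not triggered: ratio >= reference")
        self.table_ = table
        self.d01_weight_ = w

        # --- stillbirth constraint (re-evaluated on the weighted table) --
        d, n = table.deaths, table.entrants
        ratio = d[0] / d[1] if d[1] > 0 else None
        requested = self.constraint in (True, "auto")
        active = requested and ratio is not None and ratio < self.constraint_constant
        if requested and not active:
            self.flags_.append(
                "constraint skipped: STB/D0-1 ratio "
                + ("undefined" if ratio is None else f"{ratio:.4g} >= reference")
            )
        self.constraint_active_ = active

        # --- gamma_2 and gamma_1 ----------------------------------------
        # The likelihood separates over intervals, so the free cloglog
        # coefficients have closed-form binomial MLEs.
        q2 = d[1] / n[1] if n[1] > 0 else 0.0
        gamma2 = cloglog(q2) if q2 > 0 else -np.inf
        if active:
            # stillbirth count deemed unreliable; impute via the reference
            # hazard ratio (interval 1 excluded from the likelihood)
            gamma1 = gamma2 + math.log(self.constraint_constant)
        else:
            q1 = d[0] / n[0]
            gamma1 = cloglog(q1) if q1 > 0 else -np.inf
        if not np.isfinite(gamma2):
            self.flags_.append("zero D0-1 deaths: gamma2 sentinel -inf")

        # --- smooth hazard for days 2-9 ---------------------------------
        g0, a, b, smooth_ok = _fit_smooth_hazard(
            d[2:], n[2:], self.tol, self.max_iter, self.restarts
        )
        self.converged_ = smooth_ok

        q = np.empty(N_INTERVALS)
        q[0] = inv_cloglog(gamma1) if np.isfinite(gamma1) else 0.0
        q[1] = inv_cloglog(gamma2) if np.isfinite(gamma2) else 0.0
        h = g0 + (np.exp(a + b * DAY_MIDPOINTS) if np.isfinite(a) else 0.0)
        q[2:] = -np.expm1(-h)

        if self.source:
            label = self.source
        elif self.weighting in (True, "auto"):
            label = "model4" if self.constraint in (True, "auto") else "model3"
        else:
            label = "model2"
        self.life_table_ = LifeTable(q=np.clip(q, 0.0, 1.0), entrants=n.copy(),
                                     source=label)
        self.rates_ = rates_from_lifetable(self.life_table_, model=label)
        self.loglik_ = binomial_loglik(d, n, q)
        self.loglik_input_ = binomial_loglik(raw.deaths, raw.entrants, q)
        exp_deaths = n[5:] * q[5:]
        tot = exp_deaths.sum()
        self.fitted_heaping_index_ = float(5.0 * exp_deaths[2] / tot) if tot > 0 else None
        self.params_ = GMParameters(
            gamma1=float(gamma1),
            gamma2=float(gamma2),
            gamma0=g0,
            alpha=a,
            beta=b,
            constraint_active=active,
            d01_weight=w,
            loglik=self.loglik_,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted per-interval conditional risks q_j."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "life_table_")
        return self.life_table_.q.copy()


def fit_gm(
    table: IntervalCountTable,
    config: AdjustmentConfig | None = None,
    quality: QualityMetrics | None = None,
    constraint: bool | str = "auto",
    weighting: bool | str = False,
) -> tuple[GMParameters, LifeTable]:
    """Functional wrapper over :class:`GompertzMakehamModel`.

    ``quality`` may carry precomputed triggers; if given, a requested
    constraint/weighting is demoted when its trigger did not fire.
    """
    config = config or AdjustmentConfig()
    if quality is not None:
        if constraint in (True, "auto") and not quality.trigger_sb_constraint:
            constraint = False
        if weighting in (True, "auto") and not quality.trigger_d01_weight:
            weighting = False
    est = GompertzMakehamModel(
        constraint=constraint,
        weighting=weighting,
        constraint_constant=config.constraint_constant,
        weight_constant=config.weight_constant,
        tol=config.tol,
        max_iter=config.max_iter,
        restarts=config.restarts,
        weighting_balance=config.weighting_balance,
    ).fit(table)
    return est.params_, est.life_table_


# ---------------------------------------------------------------------------
# the four-model adjustment


@dataclass
class ModelResult:
    """Rates and diagnostics for one of the four models."""

    model: int
    rates: MortalityRates
    relative_diff: dict[str, float | None] = field(default_factory=dict)
    params: GMParameters | None = None
    life_table: LifeTable | None = None
    loglik: float | None = None
    converged: bool | None = None
    fitted_heaping_index: float | None = None
    flags: list[str] = field(default_factory=list)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "rates": self.rates.to_dict() if self.rates else None,
            "relative_diff": self.relative_diff,
            "params": self.params.to_dict() if self.params else None,
            "life_table": self.life_table.to_dict() if self.life_table else None,
            "loglik": self.loglik,
            "converged": self.converged,
            "fitted_heaping_index": self.fitted_heaping_index,
            "flags": self.flags,
            "error": self.error,
        }


@dataclass
class AdjustedEstimates:
    """Per-survey output: quality report plus observed and adjusted rates."""

    survey_id: str
    quality: QualityMetrics
    models: dict[int, ModelResult]
    table: IntervalCountTable | None = None

    def rates(self, model: int) -> MortalityRates:
        return self.models[model].rates

    def to_dict(self) -> dict:
        return {
            "survey_id": self.survey_id,
            "quality": self.quality.to_dict(),
            "models": {str(k): v.to_dict() for k, v in self.models.items()},
            "table": self.table.to_dict() if self.table is not None else None,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=json_default, **kw)


def _relative_diffs(rates: MortalityRates, base: MortalityRates) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for name in RATE_NAMES:
        b = getattr(base, name)
        out[name] = 100.0 * (getattr(rates, name) - b) / b if b > 0 else None
    return out


def adjust_survey(
    X,
    bands: ReferenceBands | None = None,
    config: AdjustmentConfig | None = None,
) -> AdjustedEstimates:
    """Run the quality report and models 1-4 on one survey.

    Model 1 is the saturated piece-wise exponential (observed) fit; model 2
    adds the stillbirth constraint; model 3 the D0-1 weighting; model 4 both
    (weighting first, constraint trigger re-evaluated on the weighted
    table).  A failure in one model is recorded in its ``error`` field and
    leaves the other models intact.
    """
    from .lifetable import _as_table

    config = config or AdjustmentConfig()
    bands = bands or default_bands()
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        from .records import build_interval_counts

        table = build_interval_counts(X, use_weights=config.use_weights)
    else:
        table = X
    qm = quality_report(table, bands, config.constraint_constant, config.weight_constant)

    specs = {
        1: dict(),
        2: dict(constraint="auto", weighting=False),
        3: dict(constraint=False, weighting="auto"),
        4: dict(constraint="auto", weighting="auto"),
    }
    results: dict[int, ModelResult] = {}
    for m in config.models:
        try:
            if m == 1:
                est = PiecewiseExponentialModel().fit(table)
                results[m] = ModelResult(
                    model=1,
                    rates=est.rates_,
                    life_table=est.life_table_,
                    loglik=est.loglik_,
                    converged=est.converged_,
                    flags=[f"zero-death intervals: {est.zero_death_intervals_}"]
                    if est.zero_death_intervals_
                    else [],
                )
            else:
                est = GompertzMakehamModel(
                    constraint_constant=config.constraint_constant,
                    weight_constant=config.weight_constant,
                    tol=config.tol,
                    max_iter=config.max_iter,
                    restarts=config.restarts,
                    weighting_balance=config.weighting_balance,
                    source=f"model{m}",
                    **specs[m],
                ).fit(table)
                results[m] = ModelResult(
                    model=m,
                    rates=est.rates_,
                    params=est.params_,
                    life_table=est.life_table_,
                    loglik=est.loglik_input_,
                    converged=est.converged_,
                    fitted_heaping_index=est.fitted_heaping_index_,
                    flags=list(est.flags_),
                )
        except Exception as exc:  # noqa: BLE001 - per-model isolation
            results[m] = ModelResult(model=m, rates=None, error=str(exc))

    if 1 in results and results[1].error is None:
        base = results[1].rates
        for m, res in results.items():
            if res.error is None:
                res.relative_diff = (
                    {name: 0.0 for name in RATE_NAMES}
                    if m == 1
                    else _relative_diffs(res.rates, base)
                )
    return AdjustedEstimates(
        survey_id=table.survey_id, quality=qm, models=results, table=table
    )


class SurveyAdjuster(BaseEstimator):
    """Estimator facade over :func:`adjust_survey` (models 1-4 in one fit).

    Attributes after ``fit``: ``estimates_`` (:class:`AdjustedEstimates`),
    ``quality_``, and ``rates_`` (dict model -> :class:`MortalityRates`).
    """

    def __init__(
        self,
        constraint_constant: float = CONSTRAINT_CONSTANT,
        weight_constant: float = WEIGHT_CONSTANT,
        models: tuple[int, ...] = (1, 2, 3, 4),
        tol: float = 1e-8,
        max_iter: int = 500,
        restarts: int = 3,
        use_weights: bool = False,
    ):
        self.constraint_constant = constraint_constant
        self.weight_constant = weight_constant
        self.models = models
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.use_weights = use_weights

    def fit(self, X, y=None):
        config = AdjustmentConfig(
            constraint_constant=self.constraint_constant,
            weight_constant=self.weight_constant,
            models=tuple(self.models),
            tol=self.tol,
            max_iter=self.max_iter,
            restarts=self.restarts,
            use_weights=self.use_weights,
        )
        self.estimates_ = adjust_survey(X, config=config)
        self.quality_ = self.estimates_.quality
        self.rates_ = {
            m: r.rates for m, r in self.estimates_.models.items() if r.error is None
        }
        return self
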