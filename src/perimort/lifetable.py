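"""Real-cohort interval-censored life tables and the piece-wise exponential fit.

The observed analysis follows the cohort from seven months' gestation through
day 9 of life on ten intervals.  Because censoring happens only at interval
boundaries, the conditional risk in interval j is the simple binomial ratio
``q_j = d_j / n_j`` and the cumulative survival is the product
``S_j = prod_{i<=j} (1 - q_i)``.

The same quantity can be estimated by a piece-wise exponential model with a
complementary log-log link, ``cloglog(q_j) = log(-log(1-q_j)) = gamma_j``,
one coefficient per interval.  That saturated fit is exactly equivalent to
the life table; it is exposed both for the equivalence check and as the
"model 1" baseline that the Gompertz-Makeham adjustments are compared with.

Rates
-----
* stillbirth rate (SBR): ``1000 * q_1`` per 1000 births;
* early neonatal mortality rate (ENMR): cumulative death probability over
  days 0-6 among livebirths, per 1000 livebirths (days 7-9 are carried only
  to measure heaping and never enter the rate);
* perinatal mortality rate (PMR): ``1000 * (1 - (1-q_1) * (1-ENMR/1000))``
  per 1000 births.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .records import INTERVAL_LABELS, N_INTERVALS, IntervalCountTable

__all__ = [
    "LifeTable",
    "MortalityRates",
    "compute_life_table",
    "fit_piecewise_exponential",
    "rates_from_lifetable",
    "binomial_loglik",
    "cloglog",
    "inv_cloglog",
    "PiecewiseExponentialModel",
]

#: Enumeration of life-table provenance labels.
SOURCES = ("observed", "model1", "model2", "model3", "model4")


def cloglog(q: np.ndarray | float) -> np.ndarray | float:
    """Complementary log-log transform log(-log(1-q)); -inf at q=0."""
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(-np.log1p(-q))
    return out if out.ndim else float(out)


def inv_cloglog(g: np.ndarray | float) -> np.ndarray | float:
    """Inverse transform 1 - exp(-exp(g)); 0 at g=-inf."""
    g = np.asarray(g, dtype=float)
    out = -np.expm1(-np.exp(g))
    return out if out.ndim else float(out)


def binomial_loglik(deaths: np.ndarray, entrants: np.ndarray, q: np.ndarray) -> float:
    """Grouped binomial log-likelihood (without the combinatorial constant).

    Non-deaths in an interval — survivors and boundary-censored records
    alike — contribute ``log(1-q)``.  Intervals with no entrants contribute
    nothing; a zero fitted risk with observed deaths yields ``-inf``.
    """
    d = np.asarray(deaths, dtype=float)
    n = np.asarray(entrants, dtype=float)
    q = np.asarray(q, dtype=float)
    ll = 0.0
    with np.errstate(divide="ignore"):
        for dj, nj, qj in zip(d, n, q):
            if nj <= 0:
                continue
            if dj > 0:
                ll += dj * math.log(qj) if qj > 0 else -math.inf
            if nj - dj > 0:
                ll += (nj - dj) * math.log1p(-qj)
    return ll


@dataclass
class LifeTable:
    """Per-interval conditional risks with the derived survival quantities."""

    q: np.ndarray
    entrants: np.ndarray
    source: str = "observed"
    labels: tuple[str, ...] = INTERVAL_LABELS
    survival: np.ndarray = field(init=False)
    cum_death: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.entrants = np.asarray(self.entrants, dtype=float)
        if self.q.shape != (N_INTERVALS,):
            raise ValueError(f"expected {N_INTERVALS} interval risks")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("interval risks must lie in [0, 1]")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        self.survival = np.cumprod(1.0 - self.q)
        self.cum_death = 1.0 - self.survival

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "intervals": list(self.labels),
            "q": self.q.tolist(),
            "entrants": self.entrants.tolist(),
            "survival": self.survival.tolist(),
            "cum_death": self.cum_death.tolist(),
        }


@dataclass
class MortalityRates:
    """Stillbirth / early neonatal / perinatal rates per 1000, one model."""

    sbr: float
    enmr: float
    pmr: float
    model: str = "observed"

    def __post_init__(self) -> None:
        for r in (self.sbr, self.enmr, self.pmr):
            if not 0.0 <= r <= 1000.0:
                raise ValueError("rates must lie in [0, 1000]")
        if self.pmr < self.sbr - 1e-9:
            raise ValueError("perinatal rate cannot be below the stillbirth rate")

    def to_dict(self) -> dict:
        return {"model": self.model, "sbr": self.sbr, "enmr": self.enmr, "pmr": self.pmr}


def compute_life_table(
    table: IntervalCountTable,
    actuarial_censoring: bool = False,
    source: str = "observed",
) -> LifeTable:
    """Observed real-cohort life table.

    ``q_j = d_j / n_j`` by default; with ``actuarial_censoring`` the
    denominator is ``n_j - c_j/2`` (the classic half-interval correction,
    relevant only if censoring can occur inside an interval).
    """
    if table.entrants[0] <= 0:
        raise ValueError("empty cohort: no pregnancies at risk")
    denom = table.entrants - (table.censored / 2.0 if actuarial_censoring else 0.0)
    q = np.zeros(N_INTERVALS)
    for j in range(N_INTERVALS):
        if denom[j] <= 0:
            if table.deaths[j] > 0:
                raise ValueError(f"interval {INTERVAL_LABELS[j]}: deaths with no one at risk")
            q[j] = 0.0
        else:
            q[j] = table.deaths[j] / denom[j]
    return LifeTable(q=q, entrants=table.entrants.copy(), source=source)


def fit_piecewise_exponential(
    table: IntervalCountTable, source: str = "model1"
) -> tuple[np.ndarray, LifeTable, dict]:
    """Saturated piece-wise exponential fit via a cloglog-link binomial GLM.

    One coefficient per interval; intervals with zero deaths get the
    ``gamma = -inf`` sentinel (fitted risk exactly 0) and are flagged rather
    than penalized, preserving exact life-table equivalence.

    Returns ``(gamma, fitted life table, diagnostics)`` where diagnostics
    holds ``loglik``, ``converged``, and ``zero_death_intervals``.
    """
    d, n = table.deaths, table.entrants
    if n[0] <= 0:
        raise ValueError("empty cohort: no pregnancies at risk")
    est = np.flatnonzero((d > 0) & (n > 0))
    gamma = np.full(N_INTERVALS, -np.inf)
    converged = True
    if est.size:
        endog = np.column_stack([d[est], n[est] - d[est]])
        exog = np.eye(est.size)
        model = sm.GLM(
            endog, exog, family=sm.families.Binomial(link=sm.families.links.CLogLog())
        )
        with warnings.catch_warnings():
            # the saturated model predicts each interval exactly; statsmodels
            # flags that as perfect separation, which is the intended outcome
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-12)
        converged = bool(res.converged)
        if not converged:  # pragma: no cover - saturated IRLS converges
            raise RuntimeError(
                f"piece-wise exponential fit did not converge: {res.mle_retvals}"
            )
        gamma[est] = res.params
    q = inv_cloglog(gamma)
    q = np.where(np.isneginf(gamma), 0.0, q)
    lt = LifeTable(q=np.clip(q, 0.0, 1.0), entrants=n.copy(), source=source)
    diagnostics = {
        "loglik": binomial_loglik(d, n, lt.q),
        "converged": converged,
        "zero_death_intervals": [INTERVAL_LABELS[j] for j in range(N_INTERVALS)
                                 if d[j] == 0],
    }
    return gamma, lt, diagnostics


def rates_from_lifetable(lt: LifeTable, model: str | None = None) -> MortalityRates:
    """Mortality rates per 1000 from a life table.

    ENMR covers days 0-6 only (intervals 2..7); days 7-9 are excluded from
    the rate and used only for the heaping assessment.
    """
    q1 = lt.q[0]
    q_en = 1.0 - np.prod(1.0 - lt.q[1:7])
    sbr = 1000.0 * q1
    enmr = 1000.0 * q_en
    pmr = 1000.0 * (1.0 - (1.0 - q1) * (1.0 - q_en))
    return MortalityRates(sbr=sbr, enmr=enmr, pmr=pmr, model=model or lt.source)


class PiecewiseExponentialModel(BaseEstimator):
    """Saturated piece-wise exponential mortality model (the observed baseline).

    scikit-learn style estimator: ``fit(X)`` accepts an
    :class:`~perimort.records.IntervalCountTable` or a pregnancy-record
    DataFrame (which is tabulated first).

    Parameters
    ----------
    actuarial_censoring : bool, default False
        Use the half-interval at-risk correction in the observed life table
        cross-check.

    Attributes
    ----------
    gamma_ : ndarray of shape (10,)
        Cloglog coefficients; ``-inf`` sentinel marks zero-death intervals.
    life_table_ : LifeTable
    rates_ : MortalityRates
    loglik_ : float
    zero_death_intervals_ : list of str
    """

    def __init__(self, actuarial_censoring: bool = False):
        self.actuarial_censoring = actuarial_censoring

    def fit(self, X, y=None):
        table = _as_table(X)
        self.table_ = table
        self.gamma_, self.life_table_, diag = fit_piecewise_exponential(table)
        self.loglik_ = diag["loglik"]
        self.converged_ = diag["converged"]
        self.zero_death_intervals_ = diag["zero_death_intervals"]
        self.rates_ = rates_from_lifetable(self.life_table_, model="model1")
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted per-interval conditional risks q_j."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "life_table_")
        return self.life_table_.q.copy()


def _as_table(X) -> IntervalCountTable:
    if isinstance(X, IntervalCountTable):
        return X
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        from .records import build_interval_counts

        return build_interval_counts(X)
    raise TypeError("X must be an IntervalCountTable or a pregnancy-record DataFrame")
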