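"""Survey data-quality indicators for perinatal mortality and their bands.

Four indicators are computed from the interval death counts:

* **heaping index at day 7** — five times the deaths reported on day 7
  divided by the sum of deaths on days 5-9; 1.0 means no heaping.
* **STB/D0-1** — stillbirths to deaths on days 0-1; low values signal
  stillbirth under-reporting or transference to very early neonatal deaths.
* **STB/first-week** — stillbirths to deaths on days 0-6.
* **D0-1/D2-6** — very early to later first-week neonatal deaths; low
  values signal under-reporting of deaths in the first two days.

Each indicator is compared against fixed reference bands (plausible /
probable / improbable) derived from vital registration, surveillance and
prospective pregnancy-outcome studies.  Two of the reference constants also
drive the model-based adjustment: STB/D0-1 below 1.89 triggers the
stillbirth constraint and D0-1/D2-6 below 2.4 triggers the D0-1 weighting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import IntervalCountTable, json_default

__all__ = [
    "CONSTRAINT_CONSTANT",
    "WEIGHT_CONSTANT",
    "QualityMetrics",
    "ReferenceBands",
    "default_bands",
    "heaping_index",
    "ratio_metrics",
    "classify",
    "quality_report",
]

#: Reference ratio of stillbirths to deaths on days 0-1 (corpus median).
CONSTRAINT_CONSTANT = 1.89
#: Reference ratio of deaths on days 0-1 to deaths on days 2-6.
WEIGHT_CONSTANT = 2.4

_METRICS = ("heaping", "sb_d01", "sb_week", "d01_d26")

_INF = math.inf


@dataclass
class ReferenceBands:
    """Plausibility bands per metric: ordered (lo, hi, label) triples.

    Intervals are lower-inclusive, upper-exclusive, contiguous, and cover
    [0, inf).  The D0-1/D2-6 metric has a one-sided rule only: values below
    the plausible threshold are labelled ``under-reported``.
    """

    bands: dict[str, list[tuple[float, float, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric, segs in self.bands.items():
            lo0 = segs[0][0]
            if lo0 != 0:
                raise ValueError(f"{metric}: bands must start at 0")
            for (a, b, _), (c, _d, _l) in zip(segs, segs[1:]):
                if not (a < b and b == c):
                    raise ValueError(f"{metric}: bands must be contiguous and increasing")
            if segs[-1][1] != _INF:
                raise ValueError(f"{metric}: bands must cover [0, inf)")

    def classify(self, metric: str, value: float | None) -> str:
        if metric not in self.bands:
            raise KeyError(f"unknown metric {metric!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "unclassifiable"
        if value < 0:
            raise ValueError("metric values are nonnegative")
        for lo, hi, label in self.bands[metric]:
            if lo <= value < hi:
                return label
        raise AssertionError("bands do not cover value")  # pragma: no cover

    def to_dict(self) -> dict:
        return {
            m: [[lo, "inf" if hi == _INF else hi, lab] for lo, hi, lab in segs]
            for m, segs in self.bands.items()
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=json_default, **kw)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReferenceBands":
        bands = {
            m: [(float(lo), _INF if hi in ("inf", None) else float(hi), str(lab))
                for lo, hi, lab in segs]
            for m, segs in payload.items()
        }
        return cls(bands=bands)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceBands":
        return cls.from_dict(json.loads(text))


def default_bands() -> ReferenceBands:
    """The default reference bands for the four indicators."""
    return ReferenceBands(
        bands={
            "heaping": [
                (0.0, 0.6, "improbable"),
                (0.6, 0.8, "probable"),
                (0.8, 1.3, "plausible"),
                (1.3, 1.5, "probable"),
                (1.5, _INF, "improbable"),
            ],
            "sb_d01": [
                (0.0, 1.0, "improbable"),
                (1.0, 1.7, "probable"),
                (1.7, 3.0, "plausible"),
                (3.0, 4.0, "probable"),
                (4.0, _INF, "improbable"),
            ],
            "sb_week": [
                (0.0, 0.5, "improbable"),
                (0.5, 1.0, "probable"),
                (1.0, 1.9, "plausible"),
                (1.9, 2.4, "probable"),
                (2.4, _INF, "improbable"),
            ],
            "d01_d26": [
                (0.0, 2.4, "under-reported"),
                (2.4, _INF, "plausible"),
            ],
        }
    )


@dataclass
class QualityMetrics:
    """The four indicator values, their component counts, bands, and triggers.

    A metric is ``None`` exactly when its denominator is zero; such metrics
    classify as ``unclassifiable`` and never fire an adjustment trigger.
    """

    heaping_index_day7: float | None
    ratio_sb_d01: float | None
    ratio_sb_week: float | None
    ratio_d01_d26: float | None
    counts: dict[str, float] = field(default_factory=dict)
    bands: dict[str, str] = field(default_factory=dict)
    trigger_sb_constraint: bool = False
    trigger_d01_weight: bool = False
    flags: list[str] = field(default_factory=list)

    def value(self, metric: str) -> float | None:
        return {
            "heaping": self.heaping_index_day7,
            "sb_d01": self.ratio_sb_d01,
            "sb_week": self.ratio_sb_week,
            "d01_d26": self.ratio_d01_d26,
        }[metric]

    def to_dict(self) -> dict:
        return {
            "heaping_index_day7": self.heaping_index_day7,
            "ratio_sb_d01": self.ratio_sb_d01,
            "ratio_sb_week": self.ratio_sb_week,
            "ratio_d01_d26": self.ratio_d01_d26,
            "counts": self.counts,
            "bands": self.bands,
            "trigger_sb_constraint": self.trigger_sb_constraint,
            "trigger_d01_weight": self.trigger_d01_weight,
            "flags": self.flags,
        }


def heaping_index(d5: float, d6: float, d7: float, d8: float, d9: float) -> float | None:
    """Age heaping index at day 7: ``5*d7 / (d5+d6+d7+d8+d9)``.

    Returns ``None`` when no deaths were reported on days 5-9.
    """
    counts = np.asarray([d5, d6, d7, d8, d9], dtype=float)
    if np.any(counts < 0):
        raise ValueError("death counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        return None
    return float(5.0 * d7 / total)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else float(num / den)


def ratio_metrics(table: IntervalCountTable) -> QualityMetrics:
    """Compute the four quality indicators from an interval count table."""
    d = table.deaths
    counts = {
        "stillbirths": table.stillbirths,
        "d01": table.d01,
        "d26": table.d26,
        "first_week": table.first_week_deaths,
        **{f"day{k}": table.day_deaths(k) for k in range(5, 10)},
    }
    qm = QualityMetrics(
        heaping_index_day7=heaping_index(d[5], d[6], d[7], d[8], d[9]),
        ratio_sb_d01=_ratio(table.stillbirths, table.d01),
        ratio_sb_week=_ratio(table.stillbirths, table.first_week_deaths),
        ratio_d01_d26=_ratio(table.d01, table.d26),
        counts=counts,
    )
    for metric in _METRICS:
        if qm.value(metric) is None:
            qm.flags.append(f"{metric}: undefined (zero denominator)")
    return qm


def classify(metric_name: str, value: float | None,
             bands: ReferenceBands | None = None) -> str:
    """Band label for one metric value (``unclassifiable`` if undefined)."""
    bands = bands or default_bands()
    return bands.classify(metric_name, value)


def quality_report(
    table: IntervalCountTable,
    bands: ReferenceBands | None = None,
    constraint_constant: float = CONSTRAINT_CONSTANT,
    weight_constant: float = WEIGHT_CONSTANT,
) -> QualityMetrics:
    """Full quality assessment: metric values, band labels, adjustment triggers.

    The stillbirth constraint fires when STB/D0-1 is strictly below
    ``constraint_constant``; the D0-1 weighting fires when D0-1/D2-6 is
    strictly below ``weight_constant``.  Undefined metrics never trigger.
    """
    bands = bands or default_bands()
    qm = ratio_metrics(table)
    for metric in _METRICS:
        qm.bands[metric] = bands.classify(metric, qm.value(metric))
    qm.trigger_sb_constraint = (
        qm.ratio_sb_d01 is not None and qm.ratio_sb_d01 < constraint_constant
    )
    qm.trigger_d01_weight = (
        qm.ratio_d01_d26 is not None and qm.ratio_d01_d26 < weight_constant
    )
    return qm
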