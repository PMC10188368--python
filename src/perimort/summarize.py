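"""Multi-survey summaries of quality metrics and observed/adjusted rates.

Aggregates the per-survey JSON outputs of the adjustment pipeline into the
summary statistics a corpus analysis reports: median / IQR / range of each
quality indicator, counts of surveys per plausibility band, pairwise metric
correlations, per-model rate summaries, and the median of the per-survey
relative differences from model 1 (a median of per-survey values, *not* a
difference of medians).

Quantiles use the median-unbiased definition (numpy ``method=
"median_unbiased"``), fixed here so summaries are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .records import json_default

__all__ = ["MultiSurveySummary", "summarize", "load_survey_outputs"]

_QUANTILE_METHOD = "median_unbiased"
_METRIC_KEYS = {
    "heaping": "heaping_index_day7",
    "sb_d01": "ratio_sb_d01",
    "sb_week": "ratio_sb_week",
    "d01_d26": "ratio_d01_d26",
}
_RATES = ("sbr", "enmr", "pmr")


def _five_numbers(values: np.ndarray) -> dict[str, float]:
    q = np.quantile(values, [0.25, 0.5, 0.75], method=_QUANTILE_METHOD)
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "q1": float(q[0]),
        "median": float(q[1]),
        "q3": float(q[2]),
        "max": float(values.max()),
    }


@dataclass
class MultiSurveySummary:
    """Corpus-level summary across per-survey adjustment outputs."""

    n_surveys: int
    metrics: dict[str, dict] = field(default_factory=dict)
    band_counts: dict[str, dict[str, dict]] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    rates: dict[str, dict[str, dict]] = field(default_factory=dict)
    relative_diffs: dict[str, dict[str, dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_surveys": self.n_surveys,
            "metrics": self.metrics,
            "band_counts": self.band_counts,
            "correlations": self.correlations,
            "rates": self.rates,
            "relative_diffs": self.relative_diffs,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=json_default, **kw)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T


def load_survey_outputs(directory: str | Path) -> list[dict]:
    """Read every ``*.json`` per-survey adjustment output in a directory."""
    paths = sorted(Path(directory).glob("*.json"))
    if not paths:
        raise FileNotFoundError(f"no per-survey JSON outputs in {directory}")
    return [json.loads(p.read_text()) for p in paths]


def summarize(outputs: Iterable[Mapping]) -> MultiSurveySummary:
    """Aggregate per-survey adjustment outputs (parsed JSON dicts).

    Band counts cover classifiable surveys only and therefore sum to the
    number of surveys with a defined metric value.  Relative differences are
    summarized by the median of the per-survey values.
    """
    outputs = list(outputs)
    if not outputs:
        raise ValueError("no survey outputs to summarize")

    summary = MultiSurveySummary(n_surveys=len(outputs))

    metric_values: dict[str, list[float]] = {m: [] for m in _METRIC_KEYS}
    for m, key in _METRIC_KEYS.items():
        bands: dict[str, int] = {}
        for out in outputs:
            q = out["quality"]
            v = q.get(key)
            band = q.get("bands", {}).get(m, "unclassifiable")
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                metric_values[m].append(float(v))
                bands[band] = bands.get(band, 0) + 1
        vals = np.asarray(metric_values[m], dtype=float)
        if vals.size:
            summary.metrics[m] = _five_numbers(vals)
        n_classifiable = sum(bands.values())
        summary.band_counts[m] = {
            band: {"count": c, "percent": 100.0 * c / n_classifiable}
            for band, c in sorted(bands.items())
        }

    pairs = [("heaping", "sb_d01"), ("heaping", "d01_d26"), ("sb_d01", "d01_d26"),
             ("sb_d01", "sb_week")]
    for a, b in pairs:
        xs, ys = [], []
        for out in outputs:
            q = out["quality"]
            va, vb = q.get(_METRIC_KEYS[a]), q.get(_METRIC_KEYS[b])
            if va is not None and vb is not None:
                xs.append(va)
                ys.append(vb)
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            r, _p = stats.pearsonr(xs, ys)
            summary.correlations[f"{a}~{b}"] = float(r)

    for model in ("1", "2", "3", "4"):
        rate_block: dict[str, dict] = {}
        diff_block: dict[str, dict] = {}
        for rate in _RATES:
            vals, diffs = [], []
            for out in outputs:
                res = out.get("models", {}).get(model)
                if not res or res.get("error"):
                    continue
                vals.append(res["rates"][rate])
                d = res.get("relative_diff", {}).get(rate)
                if d is not None:
                    diffs.append(d)
            if vals:
                rate_block[rate] = _five_numbers(np.asarray(vals, dtype=float))
            if diffs:
                diff_block[rate] = _five_numbers(np.asarray(diffs, dtype=float))
        if rate_block:
            summary.rates[f"model{model}"] = rate_block
        if diff_block:
            summary.relative_diffs[f"model{model}"] = diff_block
    return summary
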