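"""Binary-classification evaluation: seven metrics and percentile CIs.

Metrics: accuracy, sensitivity, specificity, F-score (harmonic mean of PPV
and sensitivity), PPV, NPV and the Brier score.  Ratios with a zero
denominator are reported as NaN (a flagged missing value), never as 0.
Confidence intervals over repeated runs are the empirical 2.5% and 97.5%
percentiles with linear interpolation between order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

RATIO_METRICS = ("accuracy", "sensitivity", "specificity", "f_score", "ppv", "npv")
ALL_METRICS = RATIO_METRICS + ("brier",)


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    ppv: float
    npv: float
    brier: float = math.nan

    @property
    def undefined(self) -> tuple[str, ...]:
        """Names of metrics that could not be computed (zero denominator)."""
        return tuple(
            f.name for f in fields(self) if math.isnan(getattr(self, f.name))
        )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _validate_vectors(y_true, y_prob) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.float64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise MetricsError(
            f"length mismatch: {y_true.shape} labels vs {y_prob.shape} probabilities"
        )
    if y_true.size == 0:
        raise MetricsError("empty input")
    if np.any((y_prob < 0) | (y_prob > 1)) or not np.all(np.isfinite(y_prob)):
        raise MetricsError("probabilities must lie in [0, 1]")
    if not np.all((y_true == 0) | (y_true == 1)):
        raise MetricsError("labels must be 0/1")
    return y_true, y_prob


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities at ``prob >= threshold`` and tally the calls."""
    y_true, y_prob = _validate_vectors(y_true, y_prob)
    calls = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        tn=int(np.sum(~calls & ~pos)),
        fp=int(np.sum(calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six ratio metrics from a confusion table (Brier left NaN)."""
    if c.total == 0:
        raise MetricsError("cannot evaluate an empty confusion table")
    sens = _ratio(c.tp, c.tp + c.fn)
    ppv = _ratio(c.tp, c.tp + c.fp)
    if math.isnan(sens) or math.isnan(ppv) or (ppv + sens) == 0:
        f_score = math.nan
    else:
        f_score = 2 * ppv * sens / (ppv + sens)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f_score=f_score,
        ppv=ppv,
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def brier(y_true, y_prob) -> float:
    """Mean squared difference between probabilities and 0/1 labels."""
    y_true, y_prob = _validate_vectors(y_true, y_prob)
    return float(np.mean((y_prob - y_true) ** 2))


def evaluate(y_true, y_prob, threshold: float = 0.5) -> MetricsReport:
    """All seven metrics for one set of probabilistic predictions."""
    report = compute_metrics(confusion(y_true, y_prob, threshold))
    return MetricsReport(**{**report.as_dict(), "brier": brier(y_true, y_prob)})


def percentile_ci(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise MetricsError("need at least 2 values for a percentile CI")
    ci_low, ci_high = np.percentile(values, [lo, hi], method="linear")
    return float(ci_low), float(ci_high)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and 95% percentile CI per metric over repeated runs.

    NaN (undefined) per-run values are dropped per metric before
    aggregation; a metric undefined in every run stays NaN.
    """
    out: dict[str, dict[str, float]] = {}
    for name in ALL_METRICS:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[name] = {"mean": math.nan, "ci_low": math.nan, "ci_high": math.nan}
        elif vals.size == 1:
            v = float(vals[0])
            out[name] = {"mean": v, "ci_low": v, "ci_high": v}
        else:
            lo, hi = percentile_ci(vals)
            out[name] = {"mean": float(vals.mean()), "ci_low": lo, "ci_high": hi}
    return out


def format_aggregate(agg: dict[str, dict[str, float]]) -> str:
    """Render aggregated metrics as ``mean [low-high]`` lines."""
    lines = []
    for name in ALL_METRICS:
        a = agg[name]
        lines.append(
            f"{name}\t{a['mean']:.4f} [{a['ci_low']:.4f}-{a['ci_high']:.4f}]"
        )
    return "\n".join(lines)
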