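"""Confusion-matrix construction and the derived rates for the two-stage
classification scheme, plus reaction-time growth rates and volatility.

Stage-1 rates treat level 3 as positive. Note the convention for the
negative class: a level-1/2 row counts toward stage-1 specificity (and
accuracy) only if it is correct at the full three-class level, while the
stage-1 false-positive rate counts rows wrongly predicted as level 3 among
all actual level-1/2 rows. Stage-2 rates restrict numerators to actual
level-1/2 rows with denominators the full actual per-level totals, level 2
positive. These conventions reproduce the published worked example exactly.

Rates with a zero denominator are reported as None, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageMetrics",
    "ConfusionReport",
    "GrowthReport",
    "confusion_matrix",
    "stage_metrics",
    "growth_rates",
    "rt_volatility",
]

LEVELS = (1, 2, 3)


@dataclass
class StageMetrics:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    fp_rate: float | None
    fn_rate: float | None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
        }


@dataclass
class ConfusionReport:
    matrix: np.ndarray
    stage1: StageMetrics
    stage2: StageMetrics

    def as_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "stage1": self.stage1.as_dict(),
            "stage2": self.stage2.as_dict(),
        }


def confusion_matrix(actual: Sequence[int], predicted: Sequence[int]) -> np.ndarray:
    """3x3 count matrix, rows = actual level, columns = predicted level."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.size == 0:
        raise ValueError("empty label vectors")
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if not (np.all(np.isin(a, LEVELS)) and np.all(np.isin(p, LEVELS))):
        raise ValueError("labels must lie in {1, 2, 3}")
    m = np.zeros((3, 3), dtype=int)
    for ai, pi in zip(a, p):
        m[ai - 1, pi - 1] += 1
    return m


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def stage_metrics(matrix: np.ndarray) -> ConfusionReport:
    """Derive both stages' six rates from a 3x3 actual-by-predicted matrix."""
    m = np.asarray(matrix)
    if m.shape != (3, 3) or np.any(m < 0):
        raise ValueError("matrix must be 3x3 with nonnegative counts")
    m = m.astype(float)

    total = m.sum()
    n3 = m[2].sum()
    n_neg = m[0].sum() + m[1].sum()
    stage1 = StageMetrics(
        sensitivity=_ratio(m[2, 2], n3),
        specificity=_ratio(m[0, 0] + m[1, 1], n_neg),
        accuracy=_ratio(m[2, 2] + m[0, 0] + m[1, 1], total),
        precision=_ratio(m[2, 2], m[:, 2].sum()),
        fp_rate=_ratio(m[0, 2] + m[1, 2], n_neg),
        fn_rate=_ratio(m[2, 0] + m[2, 1], n3),
    )

    n1, n2 = m[0].sum(), m[1].sum()
    stage2 = StageMetrics(
        sensitivity=_ratio(m[1, 1], n2),
        specificity=_ratio(m[0, 0], n1),
        accuracy=_ratio(m[0, 0] + m[1, 1], n1 + n2),
        precision=_ratio(m[1, 1], m[0, 1] + m[1, 1]),
        fp_rate=_ratio(m[0, 1], n1),
        fn_rate=_ratio(m[1, 0], n2),
    )
    return ConfusionReport(matrix=np.asarray(matrix, dtype=int), stage1=stage1, stage2=stage2)


@dataclass
class GrowthReport:
    """Per-group level means with pairwise growth rates (percent)."""

    means: dict[str, tuple[float, float, float]]
    rates: dict[str, dict[str, float]] = field(default_factory=dict)
    average_rates: dict[str, float] = field(default_factory=dict)
    between_group_rates: dict[str, float] | None = None

    def as_dict(self) -> dict:
        return {
            "means": {k: list(v) for k, v in self.means.items()},
            "rates": self.rates,
            "average_rates": self.average_rates,
            "between_group_rates": self.between_group_rates,
        }


def _pair_rates(means: Sequence[float]) -> dict[str, float]:
    m1, m2, m3 = means
    return {
        "L1_to_L2": (m2 - m1) / m1 * 100.0,
        "L1_to_L3": (m3 - m1) / m1 * 100.0,
        "L2_to_L3": (m3 - m2) / m2 * 100.0,
    }


def growth_rates(
    means_by_level: Mapping[str, Sequence[float]] | Sequence[float],
) -> GrowthReport:
    """Relative reaction-time increases between levels, in percent.

    Accepts either one triple of per-level means or a mapping of group name
    (gender / age band) to its triple. ``average_rates`` averages each
    pairwise rate across groups; with exactly two groups the per-level
    between-group rate (low group as baseline) is also reported.
    """
    if not isinstance(means_by_level, Mapping):
        means_by_level = {"all": tuple(means_by_level)}
    means: dict[str, tuple[float, float, float]] = {}
    for group, triple in means_by_level.items():
        triple = tuple(float(v) for v in triple)
        if len(triple) != 3:
            raise ValueError(f"group {group!r} needs exactly three level means")
        if any(v <= 0 for v in triple):
            raise ValueError(f"group {group!r} has a nonpositive mean")
        means[group] = triple

    rates = {g: _pair_rates(m) for g, m in means.items()}
    keys = next(iter(rates.values())).keys()
    average = {k: float(np.mean([r[k] for r in rates.values()])) for k in keys}

    between = None
    if len(means) == 2:
        (ga, ma), (gb, mb) = means.items()
        between = {
            f"L{i + 1}": (hi - lo) / lo * 100.0
            for i, (lo, hi) in enumerate(
                (min(a, b), max(a, b)) for a, b in zip(ma, mb)
            )
        }
    return GrowthReport(
        means=means, rates=rates, average_rates=average, between_group_rates=between
    )


def rt_volatility(
    rt: Sequence[float], window: int, stat: str = "var"
) -> np.ndarray:
    """Rolling dispersion of a reaction-time series.

    ``stat`` selects population variance (default) or standard deviation.
    Returns one value per complete window (length n - window + 1).
    """
    x = np.asarray(rt, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if x.size < window:
        raise ValueError("series shorter than one window")
    if stat not in ("var", "sd"):
        raise ValueError("stat must be 'var' or 'sd'")
    rolled = pd.Series(x).rolling(window).var(ddof=0).to_numpy()[window - 1 :]
    return np.sqrt(rolled) if stat == "sd" else rolled
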