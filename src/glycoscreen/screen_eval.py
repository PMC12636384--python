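"""Score transform, cutoff classification and prevalence-adjusted screening
metrics, plus stagewise ROC and two-stage cancer-type classification.

The screening score is -log10(1 - p), capped at 10: a monotone transform of
the classifier probability that spreads out values near 1 for histogramming
and cutoff selection without changing ROC behaviour.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ROCResult, roc_auc
from .exceptions import ConfigurationError, UndefinedMetricError

logger = logging.getLogger(__name__)

SCORE_CAP = 10.0
DEFAULT_CUTOFF = 5.0


def neg_log_score(p, cap: float = SCORE_CAP):
    """-log10(1 - p) capped at ``cap``; p must lie in [0, 1].

    Strictly increasing below the cap; p = 1 maps to the cap. Accepts
    scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ConfigurationError("predicted values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        score = np.minimum(cap, -np.log10(1.0 - arr))
    if np.ndim(p) == 0:
        return float(score)
    return score


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("confusion counts must be >= 0")

    @property
    def positives_row(self) -> int:
        return self.tp + self.fp

    @property
    def negatives_row(self) -> int:
        return self.fn + self.tn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[int], cutoff: float = DEFAULT_CUTOFF
) -> ConfusionTable:
    """Tally the 2x2 table; a score >= cutoff is called positive."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if set(np.unique(y)) - {0, 1}:
        raise ConfigurationError("labels must be binary 0/1")
    pos = s >= cutoff
    return ConfusionTable(
        tp=int((pos & (y == 1)).sum()),
        fp=int((pos & (y == 0)).sum()),
        fn=int((~pos & (y == 1)).sum()),
        tn=int((~pos & (y == 0)).sum()),
    )


def sens_spec(conf: ConfusionTable) -> tuple[float, float]:
    """(sensitivity %, specificity %), unrounded."""
    if conf.n_cases == 0 or conf.n_controls == 0:
        raise UndefinedMetricError("sensitivity/specificity need both true classes")
    return (100.0 * conf.tp / conf.n_cases, 100.0 * conf.tn / conf.n_controls)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ScreeningMetrics:
    sensitivity: float  # proportion in [0, 1]
    specificity: float
    prevalence_per_100k: int
    population: int
    adjusted: ConfusionTable
    ppv_pct: float
    npv_pct: float


def prevalence_adjust(
    conf: ConfusionTable, prevalence_per_100k: int, population: int = 100_000
) -> ScreeningMetrics:
    """Project observed sensitivity/specificity onto a screening population.

    Expected case counts are rounded half-up to integers and complements
    obtained by subtraction, so the adjusted table sums to the population
    exactly.
    """
    if prevalence_per_100k <= 0:
        raise ConfigurationError("prevalence must be > 0")
    if prevalence_per_100k >= population:
        raise ConfigurationError("prevalence must be below the population size")
    sens_pct, spec_pct = sens_spec(conf)
    sens = sens_pct / 100.0
    spec = spec_pct / 100.0
    n_cases = prevalence_per_100k
    n_controls = population - prevalence_per_100k
    tp = _round_half_up(n_cases * sens)
    fn = n_cases - tp
    fp = _round_half_up(n_controls * (1.0 - spec))
    tn = n_controls - fp
    adj = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    ppv = 100.0 * adj.tp / adj.positives_row if adj.positives_row else float("nan")
    npv = 100.0 * adj.tn / adj.negatives_row if adj.negatives_row else float("nan")
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        prevalence_per_100k=prevalence_per_100k,
        population=population,
        adjusted=adj,
        ppv_pct=ppv,
        npv_pct=npv,
    )


def screening_report(
    conf: ConfusionTable, prevalence_per_100k: int, population: int = 100_000
) -> Dict:
    """Rounded, display-ready report: observed block, adjusted block, metrics.

    Sensitivity, specificity and PPV are reported to one decimal, NPV to two
    (it sits very close to 100 %).
    """
    sens_pct, spec_pct = sens_spec(conf)
    m = prevalence_adjust(conf, prevalence_per_100k, population)
    return {
        "observed": {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn},
        "sensitivity_pct": round(sens_pct, 1),
        "specificity_pct": round(spec_pct, 1),
        "prevalence_per_100k": prevalence_per_100k,
        "adjusted": {
            "tp": m.adjusted.tp,
            "fp": m.adjusted.fp,
            "fn": m.adjusted.fn,
            "tn": m.adjusted.tn,
        },
        "ppv_pct": round(m.ppv_pct, 1),
        "npv_pct": round(m.npv_pct, 2),
    }


def select_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    target_specificity_pct: float = 99.9,
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Smallest cutoff on a grid achieving the target specificity."""
    if grid is None:
        grid = np.arange(0.0, SCORE_CAP + 0.25, 0.25)
    for c in grid:
        conf = confusion_at_cutoff(scores, labels, cutoff=float(c))
        if conf.n_controls and 100.0 * conf.tn / conf.n_controls >= target_specificity_pct:
            return float(c)
    return float(grid[-1])


def stagewise_auc(
    scores: Sequence[float],
    stages: Sequence[str],
    healthy_scores: Sequence[float],
) -> Dict[str, ROCResult]:
    """One ROC per stage: that stage's cancer scores vs the healthy pool."""
    scores = np.asarray(scores, float)
    stages = np.asarray(stages, str)
    healthy = np.asarray(healthy_scores, float)
    if len(healthy) == 0:
        raise UndefinedMetricError("healthy pool is empty")
    out: Dict[str, ROCResult] = {}
    for stage in ("I", "II", "III", "IV"):
        s_stage = scores[stages == stage]
        if len(s_stage) == 0:
            logger.info("stage %s empty; skipped", stage)
            continue
        pool = np.r_[s_stage, healthy]
        y = np.r_[np.ones(len(s_stage), int), np.zeros(len(healthy), int)]
        out[stage] = roc_auc(pool, y)
    return out


@dataclass
class TypeClassification:
    """Per-type outcome of the two-stage (detect, then type) classifier."""

    table: pd.DataFrame  # index: type; n_entered, n_predicted, n_correct, accuracy_pct
    mode: str  # "recall" or "precision"


def two_stage_classify(
    scores: Sequence[float],
    predicted_types: Sequence[str],
    true_groups: Sequence[str],
    cancer_types: Sequence[str] = ("CRC", "GC", "EC"),
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "recall",
) -> TypeClassification:
    """Stage 1 thresholds the screening score; stage 2 types the positives.

    ``predicted_types`` are the stage-2 type calls (from a model trained on
    cancer-only training samples). Per-type accuracy is, in "recall" mode,
    correct calls of a type divided by true members of that type entering
    stage 2; in "precision" mode, divided by the number of calls of that type.
    """
    if mode not in ("recall", "precision"):
        raise ConfigurationError("mode must be 'recall' or 'precision'")
    s = np.asarray(scores, float)
    pred = np.asarray(predicted_types, str)
    true = np.asarray(true_groups, str)
    entered = s >= cutoff
    if not entered.any():
        logger.warning("no stage-1 positives at cutoff %.2f", cutoff)
        return TypeClassification(
            table=pd.DataFrame(
                columns=["n_entered", "n_predicted", "n_correct", "accuracy_pct"]
            ),
            mode=mode,
        )
    pred_e = pred[entered]
    true_e = true[entered]
    rows = {}
    for t in cancer_types:
        n_entered = int((true_e == t).sum())
        n_predicted = int((pred_e == t).sum())
        n_correct = int(((true_e == t) & (pred_e == t)).sum())
        denom = n_entered if mode == "recall" else n_predicted
        acc = 100.0 * n_correct / denom if denom else float("nan")
        rows[t] = {
            "n_entered": n_entered,
            "n_predicted": n_predicted,
            "n_correct": n_correct,
            "accuracy_pct": acc,
        }
    return TypeClassification(table=pd.DataFrame(rows).T, mode=mode)
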