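"""Rater evaluation: one-vs-rest diagnostic metrics and ICC calibration.

Stage answers (1, 2, 3/4) are scored as three separate binary tests, one per
stage, so that true/false positive/negative counts can be tallied.  Per-stage
metrics follow the study conventions:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* precision   = TP / (TP + FP)
* "recall"    = (TP + TN) / total — the rate of success over positive and
  negative answers jointly (conventionally called accuracy; exposed here as
  ``accuracy_recall`` to avoid collision with recall-as-sensitivity)
* F1          = harmonic mean of sensitivity and precision

with every 0/0 ratio defined as 0.  Aggregates are macro (unweighted mean),
weighted (support-proportion weighted mean) and micro (metrics recomputed on
counts pooled across stages).  Rater self-consistency is calibrated with the
two-way random-effects, absolute-agreement, single-rater intraclass
correlation coefficient, ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from perioloss.staging import STAGES

_METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy_recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary diagnostic counts for one stage treated as its own test."""

    stage: int
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class StageMetrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy_recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class MetricsTable:
    """Per-stage metrics plus macro/weighted/micro aggregates and supports."""

    per_stage: dict[int, StageMetrics]
    counts: dict[int, ConfusionCounts]
    macro: StageMetrics
    weighted: StageMetrics
    micro: StageMetrics
    supports: dict[int, int]

    @property
    def n_items(self) -> int:
        return sum(self.supports.values())

    def to_frame(self) -> pd.DataFrame:
        rows = {f"stage_{s}": m.as_dict() for s, m in self.per_stage.items()}
        rows["macro"] = self.macro.as_dict()
        rows["weighted"] = self.weighted.as_dict()
        rows["micro"] = self.micro.as_dict()
        frame = pd.DataFrame(rows).T
        frame["support"] = [self.supports.get(s, self.n_items) for s in STAGES] + [
            self.n_items
        ] * 3
        return frame


def _check_stage(stage: int) -> int:
    if stage not in STAGES:
        raise ValueError(f"unknown stage token {stage!r}; expected one of {STAGES}")
    return stage


def binarize_per_stage(truth: int, answer: int) -> dict[int, str]:
    """Score one item against each stage as a separate binary test."""
    _check_stage(truth)
    _check_stage(answer)
    out = {}
    for s in STAGES:
        if truth == s:
            out[s] = "TP" if answer == s else "FN"
        else:
            out[s] = "FP" if answer == s else "TN"
    return out


def _ratio(num: float, den: float) -> float:
    """Safe ratio with the study's 0/0 := 0 convention."""
    return num / den if den > 0 else 0.0


def metrics_from_counts(counts: ConfusionCounts) -> StageMetrics:
    """Compute the five per-stage metrics from binary diagnostic counts."""
    if counts.total <= 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    prec = _ratio(counts.TP, counts.TP + counts.FP)
    acc = _ratio(counts.TP + counts.TN, counts.total)
    f1 = f1_score(sens, prec)
    return StageMetrics(sens, spec, prec, acc, f1)


def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision (0 when both vanish)."""
    return _ratio(2.0 * sensitivity * precision, sensitivity + precision)


def macro_average(per_stage: dict[int, StageMetrics]) -> StageMetrics:
    """Unweighted mean of each metric over the stages."""
    return StageMetrics(
        *(float(np.mean([getattr(per_stage[s], m) for s in STAGES])) for m in _METRIC_NAMES)
    )


def average_metrics(
    per_stage: dict[int, StageMetrics],
    supports: dict[int, int],
    pooled: dict[int, ConfusionCounts],
) -> dict[str, StageMetrics]:
    """Macro, weighted and micro aggregates of per-stage metrics.

    Macro is the unweighted per-metric mean; weighted uses support
    proportions as weights; micro recomputes the metrics on the diagnostic
    counts summed across the three stage tests.
    """
    for s in STAGES:
        if s not in per_stage or s not in supports or s not in pooled:
            raise ValueError(f"stage {s} missing from inputs")
    total = sum(supports.values())
    if total <= 0:
        raise ValueError("zero total support")
    weights = {s: supports[s] / total for s in STAGES}
    weighted = StageMetrics(
        *(
            float(sum(weights[s] * getattr(per_stage[s], m) for s in STAGES))
            for m in _METRIC_NAMES
        )
    )
    summed = ConfusionCounts(
        stage=-1,
        TP=sum(pooled[s].TP for s in STAGES),
        TN=sum(pooled[s].TN for s in STAGES),
        FP=sum(pooled[s].FP for s in STAGES),
        FN=sum(pooled[s].FN for s in STAGES),
    )
    return {
        "macro": macro_average(per_stage),
        "weighted": weighted,
        "micro": metrics_from_counts(summed),
    }


def icc_absolute_agreement(ratings_a, ratings_b) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings_a`` and ``ratings_b`` are paired measurements of the same items
    (e.g. the same radiographs labeled twice, one month apart).  Computed from
    the two-way ANOVA mean squares; raises when the between-subject variance
    is zero, where the coefficient is undefined.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D sequences")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired ratings")
    x = np.stack([a, b], axis=1)  # subjects x raters
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr < 1e-12:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def _as_sheet(sheet) -> pd.DataFrame:
    frame = pd.DataFrame(sheet) if not isinstance(sheet, pd.DataFrame) else sheet.copy()
    if "item_id" not in frame.columns and "molar_id" in frame.columns:
        frame = frame.rename(columns={"molar_id": "item_id"})
    required = {"item_id", "side", "stage"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"answer sheet missing columns {sorted(missing)}")
    frame["stage"] = frame["stage"].map(lambda s: _check_stage(int(s)))
    return frame.set_index(["item_id", "side"])


def evaluate_rater(answers, truth) -> MetricsTable:
    """Score one rater's answer sheet against a ground-truth sheet.

    Both sheets carry one row per scored item (item id + anatomical side)
    with a stage answer.  Items missing from either sheet are dropped with a
    warning; an empty intersection is an error.
    """
    ans = _as_sheet(answers)
    tru = _as_sheet(truth)
    common = ans.index.intersection(tru.index)
    dropped = len(ans.index.symmetric_difference(tru.index))
    if dropped:
        warnings.warn(f"{dropped} items present in only one sheet were dropped", stacklevel=2)
    if len(common) == 0:
        raise ValueError("answer and truth sheets share no items")

    tallies = {s: {"TP": 0, "TN": 0, "FP": 0, "FN": 0} for s in STAGES}
    supports = {s: 0 for s in STAGES}
    for item in common:
        t = int(tru.loc[item, "stage"])
        a = int(ans.loc[item, "stage"])
        supports[t] += 1
        for s, outcome in binarize_per_stage(t, a).items():
            tallies[s][outcome] += 1
    counts = {s: ConfusionCounts(stage=s, **tallies[s]) for s in STAGES}
    per_stage = {s: metrics_from_counts(counts[s]) for s in STAGES}
    agg = average_metrics(per_stage, supports, counts)
    return MetricsTable(
        per_stage=per_stage,
        counts=counts,
        macro=agg["macro"],
        weighted=agg["weighted"],
        micro=agg["micro"],
        supports=supports,
    )


def round_report(value: float, decimals: int = 3) -> float:
    """Half-up rounding used for report display."""
    q = 10.0 ** decimals
    return float(np.floor(value * q + 0.5) / q)
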