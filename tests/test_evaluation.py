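"""One-vs-rest diagnostic metrics, aggregates and ICC calibration."""

import numpy as np
import pandas as pd
import pytest

from perioloss.evaluation import (
    ConfusionCounts,
    StageMetrics,
    average_metrics,
    binarize_per_stage,
    evaluate_rater,
    f1_score,
    icc_absolute_agreement,
    macro_average,
    metrics_from_counts,
    round_report,
)
from perioloss.staging import STAGES


@pytest.mark.parametrize(
    "truth, answer, expected",
    [
        (1, 1, {1: "TP", 2: "TN", 34: "TN"}),
        (2, 1, {1: "FP", 2: "FN", 34: "TN"}),
        (34, 34, {1: "TN", 2: "TN", 34: "TP"}),
        (1, 34, {1: "FN", 2: "TN", 34: "FP"}),
    ],
)
def test_binarization_table(truth, answer, expected):
    assert binarize_per_stage(truth, answer) == expected


def test_binarization_rejects_unknown_stage():
    with pytest.raises(ValueError):
        binarize_per_stage(3, 1)


def test_f1_reproduces_reported_stage1_value():
    assert round_report(f1_score(0.500, 0.261)) == 0.343


def test_zero_over_zero_convention():
    m = metrics_from_counts(ConfusionCounts(stage=2, TP=0, TN=30, FP=0, FN=10))
    assert m.precision == 0.0 and m.f1 == 0.0


def test_perfect_classifier_metrics():
    m = metrics_from_counts(ConfusionCounts(stage=1, TP=10, TN=30, FP=0, FN=0))
    assert m == StageMetrics(1.0, 1.0, 1.0, 1.0, 1.0)


def _random_sheets(rng, n=60):
    items = [(f"q{i:02d}", side) for i in range(n // 2) for side in ("mesial", "distal")]
    frame = lambda stages: pd.DataFrame(
        [{"item_id": i, "side": s, "stage": st} for (i, s), st in zip(items, stages)]
    )
    stages = np.array(STAGES)
    return (
        frame(rng.choice(stages, size=n, p=[0.5, 0.35, 0.15])),
        frame(rng.choice(stages, size=n, p=[0.57, 0.36, 0.07])),
    )


def test_counts_agree_with_brute_force_recount():
    """evaluate_rater's pooled counts match a direct per-item recount."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        answers, truth = _random_sheets(rng)
        table = evaluate_rater(answers, truth)
        for s in STAGES:
            tp = sum(
                (t == s) and (a == s)
                for t, a in zip(truth["stage"], answers["stage"])
            )
            fn = sum((t == s) and (a != s) for t, a in zip(truth["stage"], answers["stage"]))
            fp = sum((t != s) and (a == s) for t, a in zip(truth["stage"], answers["stage"]))
            c = table.counts[s]
            assert (c.TP, c.FN, c.FP) == (tp, fn, fp)
            assert c.total == len(truth)
        # pooled TP+FN across stages equals the number of items
        assert sum(table.counts[s].TP + table.counts[s].FN for s in STAGES) == len(truth)


def test_micro_sensitivity_is_multiclass_accuracy():
    rng = np.random.default_rng(7)
    answers, truth = _random_sheets(rng, n=80)
    table = evaluate_rater(answers, truth)
    acc = float(np.mean(answers["stage"].to_numpy() == truth["stage"].to_numpy()))
    assert table.micro.sensitivity == pytest.approx(acc)


def test_macro_is_unweighted_mean():
    per_stage = {
        1: StageMetrics(0.500, 0.393, 0.261, 0.425, f1_score(0.500, 0.261)),
        2: StageMetrics(0.400, 0.569, 0.176, 0.538, f1_score(0.400, 0.176)),
        34: StageMetrics(0.000, 1.000, 0.000, 0.963, 0.0),
    }
    macro = macro_average(per_stage)
    assert round_report(macro.sensitivity) == 0.300
    assert round_report(macro.precision) == 0.146
    assert round_report(macro.f1) == 0.196


def test_weighted_degenerates_to_single_stage():
    per_stage = {
        1: StageMetrics(0.6, 0.7, 0.8, 0.9, 0.5),
        2: StageMetrics(0.0, 0.0, 0.0, 0.0, 0.0),
        34: StageMetrics(1.0, 1.0, 1.0, 1.0, 1.0),
    }
    supports = {1: 50, 2: 0, 34: 0}
    pooled = {s: ConfusionCounts(stage=s, TP=1, TN=1, FP=1, FN=1) for s in STAGES}
    agg = average_metrics(per_stage, supports, pooled)
    assert agg["weighted"] == per_stage[1]


def test_average_metrics_rejects_zero_support():
    per_stage = {s: StageMetrics(0, 0, 0, 0, 0) for s in STAGES}
    pooled = {s: ConfusionCounts(stage=s, TP=1, TN=1, FP=1, FN=1) for s in STAGES}
    with pytest.raises(ValueError):
        average_metrics(per_stage, {s: 0 for s in STAGES}, pooled)


def test_evaluate_rater_perfect_and_supports():
    rng = np.random.default_rng(3)
    stages = [1] * 48 + [2] * 30 + [34] * 6
    rng.shuffle(stages)
    sheet = pd.DataFrame(
        [{"item_id": f"q{i}", "side": "mesial", "stage": s} for i, s in enumerate(stages)]
    )
    table = evaluate_rater(sheet, sheet)
    assert all(table.per_stage[s].sensitivity == 1.0 for s in STAGES)
    n = table.n_items
    assert (table.supports[1] / n, table.supports[2] / n, table.supports[34] / n) == (
        pytest.approx(0.5714, abs=1e-4),
        pytest.approx(0.3571, abs=1e-4),
        pytest.approx(0.0714, abs=1e-4),
    )


def test_always_stage1_rater_has_blind_severe_stage():
    truth = pd.DataFrame(
        [{"item_id": f"q{i}", "side": "m", "stage": s}
         for i, s in enumerate([1] * 10 + [2] * 6 + [34] * 4)]
    )
    answers = truth.assign(stage=1)
    table = evaluate_rater(answers, truth)
    assert table.per_stage[34].sensitivity == 0.0
    assert table.per_stage[34].specificity == 1.0


def test_evaluate_rater_drops_unmatched_items():
    truth = pd.DataFrame(
        [{"item_id": f"q{i}", "side": "m", "stage": 1} for i in range(5)]
    )
    answers = pd.DataFrame(
        [{"item_id": f"q{i}", "side": "m", "stage": 1} for i in range(3, 8)]
    )
    with pytest.warns(UserWarning):
        table = evaluate_rater(answers, truth)
    assert table.n_items == 2
    with pytest.raises(ValueError):
        evaluate_rater(answers.assign(item_id="zz"), truth)


# --- intraclass correlation -------------------------------------------------


def test_icc_perfect_agreement():
    x = np.array([1.0, 2.0, 3.0, 7.0, 4.5])
    assert icc_absolute_agreement(x, x) == pytest.approx(1.0)


def test_icc_recovers_variance_ratio():
    """Subject variance 9x error variance -> ICC near 0.9 for every seed."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        subject = rng.normal(0.0, 3.0, 200)
        a = subject + rng.normal(0.0, 1.0, 200)
        b = subject + rng.normal(0.0, 1.0, 200)
        assert icc_absolute_agreement(a, b) == pytest.approx(0.9, abs=0.05)


def test_icc_null_simulation():
    rng = np.random.default_rng(12)
    a, b = rng.normal(size=500), rng.normal(size=500)
    assert abs(icc_absolute_agreement(a, b)) < 0.1


def test_icc_matches_pingouin_icc2():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    subject = rng.normal(0.0, 2.0, 60)
    a = subject + rng.normal(0.0, 1.0, 60) + 0.5  # systematic rater offset
    b = subject + rng.normal(0.0, 1.0, 60)
    ours = icc_absolute_agreement(a, b)
    data = pd.DataFrame(
        {
            "targets": np.tile(np.arange(60), 2),
            "raters": np.repeat(["a", "b"], 60),
            "ratings": np.concatenate([a, b]),
        }
    )
    ref = pingouin.intraclass_corr(data, "targets", "raters", "ratings")
    icc2 = float(ref.set_index("Type").loc["ICC(A,1)", "ICC"])
    assert ours == pytest.approx(icc2, abs=1e-9)


def test_icc_undefined_without_subject_variance():
    with pytest.raises(ValueError):
        icc_absolute_agreement([2.0, 2.0, 2.0, 2.0], [2.0, 2.0, 2.0, 2.0])
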