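"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from icbt_dynamics.evaluation import (
    auroc,
    bootstrap_ci,
    confusion_metrics,
    km_time_to_improvement,
    sensitivity_at_specificity,
    stratified_evaluation,
    sustained_improvement_time,
)

from conftest import make_record


def frame(labels, predicted, scores=None, client_ids=None, t=1):
    n = len(labels)
    return pd.DataFrame(
        {
            "client_id": client_ids or [f"c{i}" for i in range(n)],
            "t": t,
            "score": scores if scores is not None else [float(p) for p in predicted],
            "predicted": predicted,
            "label": labels,
        }
    )


# ---------------------------------------------------------------------------
# confusion metrics


def test_confusion_metrics_hand_counted():
    df = frame([1, 1, 0, 0], [1, 0, 0, 0])
    assert confusion_metrics(df) == (0.75, 0.5, 1.0)


def test_perfect_predictions():
    df = frame([1, 0, 1], [1, 0, 1])
    assert confusion_metrics(df) == (1.0, 1.0, 1.0)


def test_all_negative_predictions():
    df = frame([1, 0, 1], [0, 0, 0])
    acc, sens, spec = confusion_metrics(df)
    assert (sens, spec) == (0.0, 1.0)


def test_missing_class_marked_not_applicable():
    df = frame([0, 0], [1, 0])
    _, sens, _ = confusion_metrics(df)
    assert np.isnan(sens)


# ---------------------------------------------------------------------------
# AUROC vs pairwise oracle


def _auroc_oracle(y, s):
    pos = [si for yi, si in zip(y, s) if yi]
    neg = [si for yi, si in zip(y, s) if not yi]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_separated_and_tied():
    assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
    assert auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5


def test_auroc_equals_pairwise_oracle_on_random_sets():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(6, 51))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.random(n), 2)  # rounding forces ties
        assert auroc(y, s) == pytest.approx(_auroc_oracle(y, s), abs=1e-12)


# ---------------------------------------------------------------------------
# sensitivity at fixed specificity vs threshold-sweep oracle


def _sens_at_spec_oracle(y, s, target):
    """Exhaustive sweep over distinct score thresholds."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(s, dtype=float)
    best = None
    for thr in np.unique(s):
        pred = s >= thr
        spec = np.mean(~pred[~y])
        sens = np.mean(pred[y])
        if spec >= target and (best is None or (spec, -sens) < (best[0], -best[1])):
            best = (spec, sens)
    return best  # None when unattainable


def test_sensitivity_at_specificity_separable():
    ops = sensitivity_at_specificity([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert all(op.sensitivity == 1.0 and op.attainable for op in ops.values())


def test_sensitivity_at_specificity_matches_sweep_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(10, 51))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        s = np.round(rng.random(n), 1)
        for target in (0.0, 0.5, 0.9, 0.95, 0.97):
            expected = _sens_at_spec_oracle(y, s, target)
            op = sensitivity_at_specificity(y, s, [target])[target]
            if expected is None:
                assert not op.attainable
            else:
                assert op.attainable
                assert op.sensitivity == pytest.approx(expected[1], abs=1e-12)


def test_monotone_in_target_and_all_positive_limit():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=40)
    s = np.round(rng.random(40), 2)
    targets = (0.0, 0.5, 0.9, 0.95, 0.97)
    ops = sensitivity_at_specificity(y, s, targets)
    sens = [ops[t].sensitivity for t in targets if ops[t].attainable]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert ops[0.0].sensitivity == 1.0  # all-positive threshold


def test_tied_scores_flagged_unattainable():
    ops = sensitivity_at_specificity([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], [0.9])
    assert not ops[0.9].attainable


# ---------------------------------------------------------------------------
# stratified evaluation


def test_single_stratum_reduces_to_confusion_metrics():
    df = frame([1, 1, 0, 0], [1, 0, 0, 0], scores=[0.9, 0.3, 0.4, 0.1])
    report = stratified_evaluation(df)
    cell = report.cell("all")
    assert (cell["accuracy"], cell["sensitivity"], cell["specificity"]) == (0.75, 0.5, 1.0)


def test_pooled_accuracy_is_count_weighted_mean():
    df1 = frame([1, 1, 0], [1, 0, 0], t=1)
    df2 = frame([1, 0], [1, 0], client_ids=["d0", "d1"], t=2)
    df = pd.concat([df1, df2], ignore_index=True)
    report = stratified_evaluation(df)
    a1 = report.cell(1)["accuracy"]
    a2 = report.cell(2)["accuracy"]
    pooled = report.cell("all")["accuracy"]
    assert pooled == pytest.approx((3 * a1 + 2 * a2) / 5)


def test_min_t_filter_drops_early_predictions():
    df1 = frame([1, 0], [1, 0], t=1)
    df2 = frame([1, 0], [0, 0], client_ids=["d0", "d1"], t=3)
    report = stratified_evaluation(pd.concat([df1, df2], ignore_index=True), min_t=3)
    assert report.cell("all")["n"] == 2


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_collapses_for_zero_variance_metric():
    df = frame([1, 1, 0, 0] * 50, [1, 1, 0, 0] * 50)
    lo, hi = bootstrap_ci(lambda d: confusion_metrics(d)[0], df, n_boot=200, seed=0)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_is_seed_deterministic():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 100)
    p = rng.integers(0, 2, 100)
    df = frame(y, p)
    a = bootstrap_ci(lambda d: confusion_metrics(d)[0], df, n_boot=200, seed=11)
    b = bootstrap_ci(lambda d: confusion_metrics(d)[0], df, n_boot=200, seed=11)
    assert a == b


def test_bootstrap_width_shrinks_with_sample_size():
    rng = np.random.default_rng(8)

    def make(n):
        y = rng.integers(0, 2, n)
        p = np.where(rng.random(n) < 0.8, y, 1 - y)
        return frame(y, p, client_ids=[f"c{i}" for i in range(n)])

    widths = {}
    for n in (200, 800):
        lo, hi = bootstrap_ci(lambda d: confusion_metrics(d)[0], make(n), n_boot=300, seed=2)
        widths[n] = hi - lo
    ratio = widths[200] / widths[800]
    assert 1.4 < ratio < 2.9  # ~2 expected from 1/sqrt(n)


# ---------------------------------------------------------------------------
# Kaplan-Meier time to sustained improvement


def test_survival_one_when_nobody_improves():
    cohort = [make_record(f"c{i}", [20, 19, 18]) for i in range(10)]
    curves = km_time_to_improvement(cohort, by_band=False)
    assert np.allclose(curves["overall"].survival, 1.0)


def test_survival_drops_to_zero_when_everyone_improves_at_two():
    cohort = [make_record(f"c{i}", [20, 12, 11]) for i in range(10)]
    curves = km_time_to_improvement(cohort, by_band=False)
    curve = curves["overall"]
    assert curve.survival[curve.times == 2][0] == 0.0


def test_survival_matches_hand_computed_product_limit_table():
    """Six clients, one improvement-free censored early, one censored late:
    S(2) = 2/3, S(3) = 4/9, S(4) = 2/9 by hand."""
    cohort = [
        make_record("a", [20, 12]),  # event at 2
        make_record("b", [20, 16, 12]),  # event at 3
        make_record("c", [20, 18]),  # censored at 2
        make_record("d", [20, 13, 12, 12]),  # event at 2, sustained
        make_record("e", [20, 18, 17, 16]),  # censored at 4
        make_record("f", [20, 17, 16, 12]),  # event at 4
    ]
    assert sustained_improvement_time(cohort[3]) == (2, True)
    assert sustained_improvement_time(cohort[2]) == (2, False)
    curves = km_time_to_improvement(cohort, by_band=False)
    curve = curves["overall"]
    expected = {2: 2 / 3, 3: 4 / 9, 4: 2 / 9}
    for t, s in expected.items():
        assert curve.survival[curve.times == t][0] == pytest.approx(s)
    assert np.all(np.diff(curve.survival) <= 1e-12)


def test_non_sustained_improvement_is_not_an_event():
    # improves at 2 but relapses at 3
    record = make_record("relapse", [20, 12, 19])
    assert sustained_improvement_time(record) == (3, False)
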