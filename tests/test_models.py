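"""Models: splitting, LSTM gradients and training, benchmarks, EMA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icbt_dynamics.labeling import label_cohort
from icbt_dynamics.models import (
    EmaClassifier,
    RnnConfig,
    RecurrentClassifier,
    SplitSpec,
    ema_classify,
    ema_forecast,
    split_data,
    train_rnn,
    train_static_classifier,
)
from icbt_dynamics.models.recurrent import _pad
from icbt_dynamics.models.split import StratificationError
from icbt_dynamics.records import ClientRecord, ReviewObservation

from conftest import make_record


# ---------------------------------------------------------------------------
# splitting


def test_stratified_split_sizes_and_prevalence(default_cohort, default_labels):
    train, val, test = split_data(default_cohort, default_labels, "phq9", SplitSpec(seed=4))
    n = len(default_cohort)
    assert (len(train), len(val), len(test)) == (round(0.7 * n), round(0.2 * n), round(0.1 * n))
    overall = np.mean([default_labels[r.client_id].ri_phq for r in default_cohort])
    for part in (train, val, test):
        prev = np.mean([default_labels[r.client_id].ri_phq for r in part])
        assert abs(prev - overall) < 0.02
    ids = [r.client_id for part in (train, val, test) for r in part]
    assert sorted(ids) == sorted(r.client_id for r in default_cohort)


def test_split_is_seed_deterministic(default_cohort, default_labels):
    a = split_data(default_cohort, default_labels, "gad7", SplitSpec(seed=9))
    b = split_data(default_cohort, default_labels, "gad7", SplitSpec(seed=9))
    assert [[r.client_id for r in part] for part in a] == [
        [r.client_id for r in part] for part in b
    ]


def test_single_class_split_rejected():
    records = [make_record(f"c{i}", [10, 10]) for i in range(20)]
    labels = label_cohort(records)
    with pytest.raises(StratificationError):
        split_data(records, labels, "phq9", SplitSpec(seed=0))


# ---------------------------------------------------------------------------
# LSTM mechanics


def test_lstm_backprop_matches_finite_differences():
    cfg = RnnConfig(hidden_dim=7, projection_dim=5, dropout=0.0, seed=3)
    model = RecurrentClassifier(cfg, "Q", "phq9", input_dim=2)
    rng = np.random.default_rng(0)
    seqs = [rng.normal(size=(t, 2)) for t in (1, 3, 4, 2)]
    x, lengths = _pad(seqs)
    y = np.array([0, 1, 1, 0])
    _, cache = model._forward(x, lengths)
    grads = model._backward(cache, y)

    def loss():
        probs, _ = model._forward(x, lengths)
        return model._loss(probs, y)

    eps = 1e-5
    for key in model.params:
        flat = model.params[key].ravel()
        analytic = grads[key].ravel()
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            denom = max(1e-6, abs(numeric) + abs(analytic[i]))
            assert abs(numeric - analytic[i]) / denom < 1e-3, key


def test_lstm_memorizes_tiny_cohort(separable_cohort, separable_labels):
    """Capacity sanity check: near-perfect training accuracy on 20 clients."""
    small = separable_cohort[:20]
    labels = {r.client_id: separable_labels[r.client_id] for r in small}
    assert len({labels[r.client_id].ri_phq for r in small}) == 2
    model = train_rnn(
        (small, labels),
        (small, labels),
        "Q",
        "phq9",
        RnnConfig(seed=0, max_epochs=150, patience=150, dropout=0.0),
        n_interaction_types=40,
    )
    correct = 0
    total = 0
    for r in small:
        for t in range(1, len(r) + 1):
            if t < 2:
                continue
            pred = model.predict_at_time(r, t) >= 0.5
            correct += pred == labels[r.client_id].ri_phq
            total += 1
    assert correct / total >= 0.95


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train_rnn(([], {}), ([], {}), "Q", "phq9", RnnConfig(seed=0))


def test_prediction_beyond_last_measurement_rejected(default_cohort):
    record = default_cohort[0]
    cfg = RnnConfig(hidden_dim=4, projection_dim=3, seed=0)
    model = RecurrentClassifier(cfg, "Q", "phq9", input_dim=1)
    with pytest.raises(ValueError):
        model.predict_at_time(record, len(record) + 1)


def test_prediction_is_probability_and_deterministic(default_cohort):
    cfg = RnnConfig(hidden_dim=6, projection_dim=4, seed=1)
    model = RecurrentClassifier(cfg, "Q", "phq9", input_dim=1)
    for r in default_cohort[:200]:
        p1 = model.predict_at_time(r, 2)
        p2 = model.predict_at_time(r, 2)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0


# ---------------------------------------------------------------------------
# no-leakage audit


def _altered_after(record, t):
    """Copy of the record with every review after t replaced by extremes."""
    new_obs = []
    for o in record.observations:
        if o.review_index <= t:
            new_obs.append(o)
        else:
            new_obs.append(
                ReviewObservation(
                    review_index=o.review_index,
                    phq_items=(3,) * 9,
                    gad_items=(3,) * 7,
                    week=o.week,
                    interaction_counts={0: 999},
                )
            )
    return ClientRecord(record.client_id, tuple(new_obs), record.censored)


def test_predictions_ignore_future_reviews(separable_cohort, separable_labels):
    """Prefix predictions are bit-identical under arbitrary later changes."""
    train = separable_cohort[:300]
    labels = separable_labels
    models = [
        train_rnn(
            (train, labels), (train, labels), "Q", "phq9",
            RnnConfig(seed=0, max_epochs=3), n_interaction_types=40,
        ),
        train_static_classifier("logistic_regression", (train, labels), "phq9", seed=0),
        train_static_classifier(
            "random_forest", (train, labels), "phq9", seed=0, hyperparams={"n_estimators": 20}
        ),
        train_static_classifier(
            "gradient_boosting", (train, labels), "phq9", seed=0, hyperparams={"n_estimators": 20}
        ),
        EmaClassifier("phq9"),
    ]
    probe = [r for r in separable_cohort if len(r) >= 4][:20]
    for model in models:
        for record in probe:
            t = 3
            altered = _altered_after(record, t)
            assert model.predict_at_time(record, t) == model.predict_at_time(altered, t)


# ---------------------------------------------------------------------------
# static classifiers


def test_static_classifier_learns_separable_prefixes(separable_cohort, separable_labels):
    model = train_static_classifier(
        "logistic_regression", (separable_cohort[:500], separable_labels), "phq9", seed=0
    )
    correct = total = 0
    for r in separable_cohort[500:700]:
        for t in range(2, len(r) + 1):
            pred = model.predict_at_time(r, t) >= 0.5
            correct += pred == separable_labels[r.client_id].ri_phq
            total += 1
    assert correct / total >= 0.95


def test_unknown_static_kind_rejected(separable_cohort, separable_labels):
    with pytest.raises(ValueError):
        train_static_classifier("svm", (separable_cohort[:10], separable_labels), "phq9")


def test_static_prediction_requires_length_16(separable_cohort, separable_labels):
    model = train_static_classifier(
        "logistic_regression", (separable_cohort[:50], separable_labels), "phq9", seed=0
    )
    with pytest.raises(ValueError):
        model.predict_proba_vector(np.zeros(15))


# ---------------------------------------------------------------------------
# EMA


@pytest.mark.parametrize(
    "scores, alpha, expected",
    [
        ([10, 10, 10], 0.3, 10.0),  # fixed point
        ([20, 15, 9], 1.0, 9.0),  # no smoothing
        ([10, 6], 0.5, 8.0),  # one smoothing step
    ],
)
def test_ema_forecast_recurrence(scores, alpha, expected):
    assert ema_forecast(scores, alpha) == pytest.approx(expected)


def test_ema_invalid_alpha_rejected():
    for alpha in (0.0, 1.5, -0.2):
        with pytest.raises(ValueError):
            ema_forecast([10.0], alpha)


@given(
    scores=st.lists(st.floats(0, 27), min_size=1, max_size=8),
    alpha=st.floats(0.05, 1.0),
)
@settings(max_examples=200, deadline=None)
def test_ema_matches_closed_form(scores, alpha):
    t = len(scores)
    closed = alpha * sum(
        (1 - alpha) ** k * scores[t - 1 - k] for k in range(t - 1)
    ) + (1 - alpha) ** (t - 1) * scores[0]
    assert abs(ema_forecast(scores, alpha) - closed) < 1e-12


def test_ema_classify_flat_trajectory_negative():
    record = make_record("flat", [15, 15, 15], gad_totals=[10, 10, 10])
    assert ema_classify(record, 3, alpha=0.5) == (False, False)


def test_ema_classify_alpha_one_uses_last_score():
    record = make_record("down", [20, 18, 16, 13], gad_totals=[10, 10, 10, 10])
    ri_phq, _ = ema_classify(record, 4, alpha=1.0)
    assert ri_phq  # forecast 13, decrease 7 >= 6


def test_ema_rounding_below_threshold_stays_negative():
    # alpha=0.9 on [20, 14]: forecast 14.6 -> rounds to 15 -> decrease 5 < 6
    record = make_record("near", [20, 14], gad_totals=[10, 10])
    ri_phq, _ = ema_classify(record, 2, alpha=0.9)
    assert not ri_phq
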