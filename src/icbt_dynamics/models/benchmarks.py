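"""Static benchmark classifiers and the exponential-moving-average baseline.

The static models (logistic regression, random forest, gradient boosting)
consume length-16 benchmark vectors — 8 zero-filled total-score slots plus 8
availability indicators — with one training example per observed prefix, so
a single model serves every prediction time.

The EMA baseline is a naive trend follower: it forecasts the next clinical
measurement by exponential smoothing of the scores so far and converts the
implied change from baseline into a hard outcome label via the
reliable-improvement criterion.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from icbt_dynamics.features import BENCHMARK_LENGTH, Instrument, build_benchmark_vector
from icbt_dynamics.labeling import OutcomeLabel, label_reliable_improvement
from icbt_dynamics.records import ClientRecord, GAD_RANGE, MAX_REVIEWS, PHQ_RANGE

StaticKind = Literal["logistic_regression", "random_forest", "gradient_boosting"]

DEFAULT_EMA_ALPHA = 0.6


class StaticClassifier:
    """Handle around a fitted scikit-learn estimator on benchmark vectors."""

    def __init__(self, kind: StaticKind, estimator, target_instrument: Instrument):
        self.kind = kind
        self.estimator = estimator
        self.target_instrument = target_instrument

    def predict_proba_vector(self, vec: np.ndarray) -> float:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (BENCHMARK_LENGTH,):
            raise ValueError(f"benchmark vector must have length {BENCHMARK_LENGTH}, got {vec.shape}")
        return float(self.estimator.predict_proba(vec[None, :])[0, 1])

    def predict_at_time(self, record: ClientRecord, t: int) -> float:
        last = record.observations[-1].review_index
        if t > last:
            raise ValueError(f"t={t} beyond client {record.client_id}'s last measurement ({last})")
        return self.predict_proba_vector(
            build_benchmark_vector(record, t, self.target_instrument)
        )


def train_static_classifier(
    kind: StaticKind,
    train: tuple[Sequence[ClientRecord], Mapping[str, OutcomeLabel]],
    target_instrument: Instrument,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> StaticClassifier:
    """Fit one static model on benchmark vectors at every observed prefix."""
    records, labels = train
    if len(records) == 0:
        raise ValueError("empty training set")
    hyperparams = dict(hyperparams or {})
    if kind == "logistic_regression":
        hyperparams.setdefault("max_iter", 2000)
        est = LogisticRegression(random_state=seed, **hyperparams)
    elif kind == "random_forest":
        hyperparams.setdefault("n_estimators", 200)
        est = RandomForestClassifier(random_state=seed, **hyperparams)
    elif kind == "gradient_boosting":
        est = GradientBoostingClassifier(random_state=seed, **hyperparams)
    else:
        raise ValueError(f"unknown static classifier kind {kind!r}")

    X, y = [], []
    for r in records:
        lab = labels[r.client_id]
        target = int(lab.ri_phq if target_instrument == "phq9" else lab.ri_gad)
        for o in r.observations:
            if o.review_index <= MAX_REVIEWS:
                X.append(build_benchmark_vector(r, o.review_index, target_instrument))
                y.append(target)
    est.fit(np.asarray(X), np.asarray(y))
    return StaticClassifier(kind=kind, estimator=est, target_instrument=target_instrument)


# ---------------------------------------------------------------------------
# exponential moving average


def ema_forecast(scores: Sequence[float], alpha: float) -> float:
    """One-step forecast by exponential smoothing.

    ``s_1 = x_1; s_k = alpha * x_k + (1 - alpha) * s_{k-1}``; the forecast of
    the next measurement is the final smoothed value.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if len(scores) == 0:
        raise ValueError("at least one score is required")
    s = float(scores[0])
    for x in scores[1:]:
        s = alpha * float(x) + (1 - alpha) * s
    return s


def ema_classify(
    record: ClientRecord, t: int, alpha: float = DEFAULT_EMA_ALPHA
) -> tuple[bool, bool]:
    """Hard RI labels from EMA forecasts of both instruments at time ``t``.

    The one-step forecast stands in for the end-of-treatment score: it is
    rounded to the nearest integer, clipped to the instrument range, and run
    through the reliable-improvement criterion against the baselines.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    last = record.observations[-1].review_index
    if t > last:
        raise ValueError(f"t={t} beyond client {record.client_id}'s last measurement ({last})")
    prefix = [o for o in record.observations if o.review_index <= t]
    phq_forecast = ema_forecast([o.phq_total for o in prefix], alpha)
    gad_forecast = ema_forecast([o.gad_total for o in prefix], alpha)
    final_phq = int(np.clip(np.rint(phq_forecast), *PHQ_RANGE))
    final_gad = int(np.clip(np.rint(gad_forecast), *GAD_RANGE))
    baseline = record.observations[0]
    return label_reliable_improvement(
        baseline.phq_total, final_phq, baseline.gad_total, final_gad
    )


class EmaClassifier:
    """EMA baseline with the same prediction interface as the learned models.

    The "probability" it reports is the hard label (0.0 or 1.0) for the
    target instrument; it has no learned parameters.
    """

    def __init__(self, target_instrument: Instrument, alpha: float = DEFAULT_EMA_ALPHA):
        if not 0 < alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
        self.target_instrument = target_instrument
        self.alpha = alpha

    def predict_at_time(self, record: ClientRecord, t: int) -> float:
        ri_phq, ri_gad = ema_classify(record, t, self.alpha)
        return float(ri_phq if self.target_instrument == "phq9" else ri_gad)
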