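"""Feature construction for sequence models and static classifiers.

Four per-review featurizations feed the sequence models:

* ``Q``  — the target instrument's total score (dimension 1; optionally both
  totals, dimension 2),
* ``Qc`` — the individual item scores (9 for PHQ-9, 7 for GAD-7),
* ``I``  — counts of each interaction type (default taxonomy 1133),
* ``I+Q`` — interaction counts concatenated with the total score.

Static classifiers instead consume fixed-length *benchmark vectors*: 8
zero-filled total-score slots (one per review period, 0 where not observed,
avoiding imputation bias) followed by 8 availability indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from icbt_dynamics.records import ClientRecord, GAD_ITEMS, MAX_REVIEWS, PHQ_ITEMS

FeatureSet = Literal["Q", "Qc", "I", "I+Q"]
Instrument = Literal["phq9", "gad7"]

BENCHMARK_LENGTH = 2 * MAX_REVIEWS


@dataclass(frozen=True)
class FeatureSequence:
    """Model-ready per-review vectors for one client (constant dimension)."""

    client_id: str
    feature_set: FeatureSet
    vectors: np.ndarray  # shape (n_reviews, dim)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def feature_dimension(
    feature_set: FeatureSet,
    target_instrument: Instrument,
    n_interaction_types: int,
    include_both_totals: bool = False,
) -> int:
    n_totals = 2 if include_both_totals else 1
    if feature_set == "Q":
        return n_totals
    if feature_set == "Qc":
        return PHQ_ITEMS if target_instrument == "phq9" else GAD_ITEMS
    if feature_set == "I":
        return n_interaction_types
    if feature_set == "I+Q":
        return n_interaction_types + n_totals
    raise ValueError(f"unknown feature set {feature_set!r}")


def build_sequence_features(
    record: ClientRecord,
    feature_set: FeatureSet,
    target_instrument: Instrument,
    n_interaction_types: int = 1133,
    include_both_totals: bool = False,
) -> FeatureSequence:
    """Per-review feature vectors for one client.

    Interaction counts are the events within each review period (not
    cumulative).  Observations past review 8 are not used.
    """
    if feature_set not in ("Q", "Qc", "I", "I+Q"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    obs = [o for o in record.observations if o.review_index <= MAX_REVIEWS]
    dim = feature_dimension(feature_set, target_instrument, n_interaction_types, include_both_totals)
    out = np.zeros((len(obs), dim), dtype=float)
    for i, o in enumerate(obs):
        if feature_set == "Q":
            out[i] = _totals(o, target_instrument, include_both_totals)
        elif feature_set == "Qc":
            out[i] = o.phq_items if target_instrument == "phq9" else o.gad_items
        elif feature_set == "I":
            _fill_interactions(out[i], o.interaction_counts, n_interaction_types)
        else:  # I+Q
            _fill_interactions(out[i, :n_interaction_types], o.interaction_counts, n_interaction_types)
            out[i, n_interaction_types:] = _totals(o, target_instrument, include_both_totals)
    return FeatureSequence(client_id=record.client_id, feature_set=feature_set, vectors=out)


def _totals(o, target_instrument: Instrument, include_both: bool) -> list[int]:
    if include_both:
        return [o.phq_total, o.gad_total]
    return [o.phq_total if target_instrument == "phq9" else o.gad_total]


def _fill_interactions(row: np.ndarray, counts, n_types: int) -> None:
    for k, v in counts.items():
        if k < n_types:
            row[k] = v


def build_benchmark_vector(
    record: ClientRecord,
    t: int,
    target_instrument: Instrument,
) -> np.ndarray:
    """Length-16 static feature vector for a prediction at review ``t``.

    Slots 0..7 hold the target instrument's totals at reviews 1..t where
    observed (0 elsewhere); slots 8..15 are availability indicators.
    """
    if not 1 <= t <= MAX_REVIEWS:
        raise ValueError(f"prediction time t={t} outside [1, {MAX_REVIEWS}]")
    vec = np.zeros(BENCHMARK_LENGTH, dtype=float)
    for o in record.observations:
        if o.review_index <= t:
            total = o.phq_total if target_instrument == "phq9" else o.gad_total
            vec[o.review_index - 1] = total
            vec[MAX_REVIEWS + o.review_index - 1] = 1.0
    return vec


def truncate_to_prefix(features: FeatureSequence, t: int) -> FeatureSequence:
    """First ``t`` review vectors; predictions are defined only up to the
    last available measurement, so ``t`` beyond the sequence is an error."""
    if not 1 <= t <= len(features):
        raise ValueError(
            f"prefix length {t} outside [1, {len(features)}] for client {features.client_id}"
        )
    return FeatureSequence(
        client_id=features.client_id,
        feature_set=features.feature_set,
        vectors=features.vectors[:t].copy(),
    )
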