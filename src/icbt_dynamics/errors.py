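"""Error analysis of dynamic predictions at a fixed review period.

Partitions predictions at a chosen prediction time (default t = 3) into
true/false positives/negatives, summarizes the full symptom trajectories of
each group, and quantifies how strongly the true final changes cluster near
the reliable-improvement threshold (-6 for PHQ-9, -4 for GAD-7) — the
signature pattern of prediction errors in this task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from icbt_dynamics.labeling import GAD_RI_DECREASE, Instrument, OutcomeLabel, PHQ_RI_DECREASE
from icbt_dynamics.records import ClientRecord

ERROR_KINDS = ("true_positive", "false_positive", "true_negative", "false_negative")

#: Change from baseline at which the RI criterion activates.
RI_THRESHOLD_CHANGE = {"phq9": -PHQ_RI_DECREASE, "gad7": -GAD_RI_DECREASE}


@dataclass(frozen=True)
class ErrorMember:
    client_id: str
    t: int
    trajectory: tuple[int, ...]  # full observed total-score sequence
    final_change: int  # final minus baseline


@dataclass(frozen=True)
class ErrorSet:
    kind: str
    t: int
    members: tuple[ErrorMember, ...]

    def __len__(self) -> int:
        return len(self.members)


def classify_errors(
    predictions: pd.DataFrame,
    records: Mapping[str, ClientRecord] | Sequence[ClientRecord],
    labels: Mapping[str, OutcomeLabel],
    t: int = 3,
    instrument: Instrument = "phq9",
) -> dict[str, ErrorSet]:
    """Exhaustive partition of the predictions at time ``t`` into the four
    confusion cells, carrying each client's full trajectory and final change."""
    if not isinstance(records, Mapping):
        records = {r.client_id: r for r in records}
    at_t = predictions[predictions["t"] == t]
    buckets: dict[str, list[ErrorMember]] = {k: [] for k in ERROR_KINDS}
    for row in at_t.itertuples(index=False):
        record = records[row.client_id]
        lab = labels[row.client_id]
        totals = record.phq_totals if instrument == "phq9" else record.gad_totals
        final = lab.final_phq if instrument == "phq9" else lab.final_gad
        baseline = lab.baseline_phq if instrument == "phq9" else lab.baseline_gad
        member = ErrorMember(
            client_id=row.client_id,
            t=t,
            trajectory=tuple(totals),
            final_change=final - baseline,
        )
        if row.predicted and row.label:
            kind = "true_positive"
        elif row.predicted and not row.label:
            kind = "false_positive"
        elif not row.predicted and not row.label:
            kind = "true_negative"
        else:
            kind = "false_negative"
        buckets[kind].append(member)
    return {k: ErrorSet(kind=k, t=t, members=tuple(v)) for k, v in buckets.items()}


def trajectory_summary(error_set: ErrorSet) -> tuple[np.ndarray, np.ndarray]:
    """(mean trajectory, final-change distribution) for one error set.

    The mean at each review index averages only the clients observed there
    (dropout makes trajectories ragged).  Returns NaN-free arrays; an empty
    set raises, callers treat that as not-applicable.
    """
    if len(error_set) == 0:
        raise ValueError(f"error set {error_set.kind!r} at t={error_set.t} is empty")
    max_len = max(len(m.trajectory) for m in error_set.members)
    sums = np.zeros(max_len)
    counts = np.zeros(max_len)
    for m in error_set.members:
        arr = np.asarray(m.trajectory, dtype=float)
        sums[: len(arr)] += arr
        counts[: len(arr)] += 1
    mean_trajectory = sums / counts
    deltas = np.array([m.final_change for m in error_set.members])
    return mean_trajectory, deltas


def threshold_proximity(
    error_set: ErrorSet, instrument: Instrument, window: int = 2
) -> float:
    """Fraction of members whose true final change lies within ``window``
    points of the RI threshold change for ``instrument``."""
    if window < 0:
        raise ValueError("window must be non-negative")
    if len(error_set) == 0:
        raise ValueError(f"error set {error_set.kind!r} is empty")
    threshold = RI_THRESHOLD_CHANGE[instrument]
    deltas = np.array([m.final_change for m in error_set.members])
    return float(np.mean(np.abs(deltas - threshold) <= window))
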