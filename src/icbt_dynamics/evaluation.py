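"""Dynamic evaluation surface: accuracy/AUROC/operating points by review
period and baseline severity, cluster-bootstrap intervals, and
time-to-improvement survival curves.

Predictions are evaluated at every review period up to each client's last
available measurement; "all t" figures pool prediction time points (each
client contributes one evaluated prediction per observed review).
Sensitivity at a fixed specificity reports the true-positive rate at the
score threshold attaining the smallest specificity at or above the target —
the operating point used when false positives must be capped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.metrics import roc_auc_score, roc_curve

from icbt_dynamics.labeling import (
    Instrument,
    OutcomeLabel,
    assign_severity_band,
    label_reliable_improvement,
)
from icbt_dynamics.records import ClientRecord, MAX_REVIEWS

SPEC_TARGETS = (0.90, 0.95, 0.97)

#: Columns of a prediction table.
PREDICTION_COLUMNS = ("client_id", "t", "score", "predicted", "label")


def predict_cohort(
    model,
    records: Sequence[ClientRecord],
    labels: Mapping[str, OutcomeLabel],
    instrument: Instrument,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every client at every observed review period.

    Returns a prediction table with one row per (client, t); ``t`` never
    exceeds the client's last available measurement.
    """
    rows = []
    for r in records:
        lab = labels[r.client_id]
        y = bool(lab.ri_phq if instrument == "phq9" else lab.ri_gad)
        for o in r.observations:
            if o.review_index > MAX_REVIEWS:
                continue
            score = model.predict_at_time(r, o.review_index)
            rows.append((r.client_id, o.review_index, score, score >= threshold, y))
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def confusion_metrics(predictions: pd.DataFrame) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) over (label, predicted) pairs.

    A rate whose denominator is empty (no positives / no negatives) is
    returned as NaN — not applicable rather than zero.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    y = predictions["label"].to_numpy(dtype=bool)
    p = predictions["predicted"].to_numpy(dtype=bool)
    accuracy = float(np.mean(y == p))
    sensitivity = float(np.mean(p[y])) if y.any() else float("nan")
    specificity = float(np.mean(~p[~y])) if (~y).any() else float("nan")
    return accuracy, sensitivity, specificity


def auroc(labels: Iterable[bool], scores: Iterable[float]) -> float:
    """Probability a random positive outscores a random negative, ties
    counted half.  NaN when only one class is present."""
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class OperatingPoint:
    target_specificity: float
    sensitivity: float
    specificity: float
    threshold: float
    attainable: bool


def sensitivity_at_specificity(
    labels: Iterable[bool],
    scores: Iterable[float],
    spec_targets: Sequence[float] = SPEC_TARGETS,
) -> dict[float, OperatingPoint]:
    """Sensitivity at the smallest attainable specificity >= each target.

    Operating points are the distinct score thresholds of the classifier
    (predict positive iff score >= threshold); the degenerate all-negative
    point is not an operating point.  When ties collapse specificity below
    a target, the most specific attainable point is reported and flagged.
    """
    y = np.asarray(list(labels), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    # drop the synthetic all-negative endpoint added by roc_curve
    real = np.isfinite(thr)
    fpr, tpr, thr = fpr[real], tpr[real], thr[real]
    spec = 1.0 - fpr

    out: dict[float, OperatingPoint] = {}
    for target in spec_targets:
        ok = spec >= target
        if ok.any():
            cand = np.flatnonzero(ok)
            # smallest specificity >= target; at ties take the higher
            # sensitivity (the upper ROC envelope)
            order = np.lexsort((-tpr[cand], spec[cand]))
            best = cand[order[0]]
            out[target] = OperatingPoint(
                target_specificity=target,
                sensitivity=float(tpr[best]),
                specificity=float(spec[best]),
                threshold=float(thr[best]),
                attainable=True,
            )
        else:
            best = int(np.argmax(spec))
            out[target] = OperatingPoint(
                target_specificity=target,
                sensitivity=float(tpr[best]),
                specificity=float(spec[best]),
                threshold=float(thr[best]),
                attainable=False,
            )
    return out


# ---------------------------------------------------------------------------
# stratified reporting


@dataclass
class EvaluationReport:
    """Metrics per (review period, severity band) cell plus marginals.

    ``cells`` rows carry: stratum identifiers (``t`` as int or "all",
    ``band`` name or "overall"), n, accuracy, sensitivity, specificity,
    auroc, and sensitivity at each fixed-specificity target.
    """

    cells: pd.DataFrame
    instrument: Instrument
    spec_targets: tuple[float, ...] = SPEC_TARGETS
    intervals: pd.DataFrame | None = None

    def cell(self, t, band="overall") -> pd.Series:
        m = (self.cells["t"].astype(str) == str(t)) & (self.cells["band"] == band)
        sub = self.cells[m]
        if len(sub) == 0:
            raise KeyError(f"no cell for t={t}, band={band}")
        return sub.iloc[0]

    def to_json_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "spec_targets": list(self.spec_targets),
            "cells": self.cells.to_dict(orient="records"),
            "intervals": (
                self.intervals.to_dict(orient="records") if self.intervals is not None else None
            ),
        }


def _cell_metrics(sub: pd.DataFrame, spec_targets) -> dict:
    accuracy, sens, spec = confusion_metrics(sub)
    row = {
        "n": len(sub),
        "accuracy": accuracy,
        "sensitivity": sens,
        "specificity": spec,
        "auroc": auroc(sub["label"], sub["score"]),
    }
    if len(sub["label"].unique()) == 2:
        ops = sensitivity_at_specificity(sub["label"], sub["score"], spec_targets)
        for tgt, op in ops.items():
            row[f"sens_at_spec_{int(round(tgt * 100))}"] = (
                op.sensitivity if op.attainable else float("nan")
            )
    else:
        for tgt in spec_targets:
            row[f"sens_at_spec_{int(round(tgt * 100))}"] = float("nan")
    return row


def stratified_evaluation(
    predictions: pd.DataFrame,
    baselines: Mapping[str, int] | None = None,
    instrument: Instrument = "phq9",
    spec_targets: Sequence[float] = SPEC_TARGETS,
    min_t: int | None = None,
) -> EvaluationReport:
    """Metrics per (t, band) cell, per-t marginals, and pooled "all t" rows.

    ``baselines`` maps client_id to the baseline total used for severity
    banding; without it only the time stratification is produced.  ``min_t``
    restricts the pooled rows to predictions at or after that review.
    """
    df = predictions.copy()
    if min_t is not None:
        df = df[df["t"] >= min_t]
    if len(df) == 0:
        raise ValueError("no predictions to evaluate")
    if baselines is not None:
        df["band"] = df["client_id"].map(
            lambda cid: assign_severity_band(baselines[cid], instrument).band
        )
        band_values = ["overall"] + sorted(df["band"].unique())
    else:
        df["band"] = "overall"
        band_values = ["overall"]

    rows = []
    t_values: list = ["all"] + sorted(df["t"].unique())
    for t in t_values:
        sub_t = df if t == "all" else df[df["t"] == t]
        for band in band_values:
            sub = sub_t if band == "overall" else sub_t[sub_t["band"] == band]
            if len(sub) == 0:
                continue
            rows.append({"t": t, "band": band, **_cell_metrics(sub, tuple(spec_targets))})
    return EvaluationReport(
        cells=pd.DataFrame(rows), instrument=instrument, spec_targets=tuple(spec_targets)
    )


def bootstrap_ci(
    metric: Callable[[pd.DataFrame], float],
    predictions: pd.DataFrame,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile interval from a cluster bootstrap over clients.

    Whole clients are resampled with replacement so repeated predictions of
    one client stay together; resamples where the metric is undefined are
    skipped.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    groups = {cid: g for cid, g in predictions.groupby("client_id")}
    ids = np.array(list(groups.keys()))
    values = []
    for _ in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        df = pd.concat([groups[cid] for cid in sample], ignore_index=True)
        v = metric(df)
        if np.isfinite(v):
            values.append(v)
    if not values:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# time-to-improvement survival


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate that sustained RI has not yet occurred."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    band: str = "overall"


def sustained_improvement_time(record: ClientRecord) -> tuple[int, bool]:
    """First review at which RI (vs baseline) holds and keeps holding.

    Returns ``(time, event)``: the review index of the first observation
    opening an unbroken run of RI through the last observed review, or the
    last observed review with ``event=False`` (censored) if none exists.
    RI here is the joint criterion for either instrument's improvement
    evaluated on the scores at that review.
    """
    base = record.observations[0]
    status = []
    for o in record.observations[1:]:
        ri_phq, ri_gad = label_reliable_improvement(
            base.phq_total, o.phq_total, base.gad_total, o.gad_total
        )
        status.append((o.review_index, ri_phq or ri_gad))
    for i, (idx, ok) in enumerate(status):
        if ok and all(later for _, later in status[i:]):
            return idx, True
    return record.observations[-1].review_index, False


def km_time_to_improvement(
    cohort: Sequence[ClientRecord],
    instrument: Instrument = "phq9",
    by_band: bool = True,
) -> dict[str, SurvivalCurve]:
    """Kaplan–Meier curves of time to sustained reliable improvement,
    optionally per baseline-severity band of ``instrument``."""
    rows = []
    for r in cohort:
        baseline = (
            r.observations[0].phq_total if instrument == "phq9" else r.observations[0].gad_total
        )
        band = assign_severity_band(baseline, instrument).band if by_band else "overall"
        time, event = sustained_improvement_time(r)
        rows.append((band, time, event))
    df = pd.DataFrame(rows, columns=["band", "time", "event"])

    curves: dict[str, SurvivalCurve] = {}
    for band, sub in df.groupby("band"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array(
            [int((sub["time"] >= t).sum()) for t in times], dtype=int
        )
        curves[str(band)] = SurvivalCurve(times=times, survival=surv, at_risk=at_risk, band=str(band))
    return curves
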