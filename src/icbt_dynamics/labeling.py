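"""Reliable-improvement outcome labels, LOCF final scores, severity bands.

The outcome of interest is *reliable improvement* (RI), a reliable-change
criterion used across IAPT services: a symptom decrease large enough to
exceed measurement error, with no disqualifying deterioration on the
companion instrument.  Concretely:

* RI in depression: PHQ-9 decreases by >= 6 points and GAD-7 does not
  increase by >= 4 points between baseline and the end of the programme.
* RI in anxiety: GAD-7 decreases by >= 4 points and PHQ-9 does not increase
  by >= 6 points.

The end-of-programme score is the last available measurement at or before
review 8 (last observation carried forward), so clients who stop early are
labeled from their final completed measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

from icbt_dynamics.records import (
    ClientRecord,
    GAD_RANGE,
    MAX_REVIEWS,
    MIN_REVIEWS,
    PHQ_RANGE,
)

logger = logging.getLogger(__name__)

#: Minimum decrease that counts as reliable improvement.
PHQ_RI_DECREASE = 6
GAD_RI_DECREASE = 4
#: Increase on the companion measure that disqualifies the label.
PHQ_DISQUALIFYING_INCREASE = 6
GAD_DISQUALIFYING_INCREASE = 4

Instrument = Literal["phq9", "gad7"]

#: Default mild/moderate/severe boundaries.  Only the mild band upper edge
#: (PHQ-9 <= 8, GAD-7 <= 6) is fixed by the subgroup analysis this package
#: reproduces; the moderate/severe split follows conventional instrument
#: banding and can be overridden.
DEFAULT_BANDS: dict[Instrument, dict[str, tuple[int, int]]] = {
    "phq9": {"mild": (0, 8), "moderate": (9, 16), "severe": (17, 27)},
    "gad7": {"mild": (0, 6), "moderate": (7, 14), "severe": (15, 21)},
}


@dataclass(frozen=True)
class SeverityBand:
    instrument: Instrument
    band: Literal["mild", "moderate", "severe"]
    lower: int
    upper: int


@dataclass(frozen=True)
class OutcomeLabel:
    """Binary RI labels together with the scores they were derived from."""

    ri_phq: bool
    ri_gad: bool
    baseline_phq: int
    baseline_gad: int
    final_phq: int
    final_gad: int
    last_observed_index: int


def _check_range(value: int, lo: int, hi: int, what: str) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{what} score {value} outside [{lo}, {hi}]")


def locf_final_scores(record: ClientRecord) -> tuple[int, int, int]:
    """Final PHQ-9 and GAD-7 totals under last-observation-carried-forward.

    Returns ``(final_phq, final_gad, last_observed_index)`` taken from the
    last observation at or before review ``MAX_REVIEWS`` (8); observations
    past review 8 are outside the supported programme and ignored.
    """
    eligible = [o for o in record.observations if o.review_index <= MAX_REVIEWS]
    if len(eligible) < MIN_REVIEWS:
        raise ValueError(
            f"client {record.client_id}: fewer than {MIN_REVIEWS} observations "
            f"within the first {MAX_REVIEWS} reviews"
        )
    last = eligible[-1]
    return last.phq_total, last.gad_total, last.review_index


def label_reliable_improvement(
    baseline_phq: int,
    final_phq: int,
    baseline_gad: int,
    final_gad: int,
) -> tuple[bool, bool]:
    """Apply the reliable-improvement criterion to baseline/final totals.

    An increase of exactly the disqualifying threshold (4 GAD-7 points for
    the depression label, 6 PHQ-9 points for the anxiety label) already
    disqualifies: "no increase >= k" is read literally.
    """
    _check_range(baseline_phq, *PHQ_RANGE, what="baseline PHQ-9")
    _check_range(final_phq, *PHQ_RANGE, what="final PHQ-9")
    _check_range(baseline_gad, *GAD_RANGE, what="baseline GAD-7")
    _check_range(final_gad, *GAD_RANGE, what="final GAD-7")

    ri_phq = (baseline_phq - final_phq >= PHQ_RI_DECREASE) and (
        final_gad - baseline_gad < GAD_DISQUALIFYING_INCREASE
    )
    ri_gad = (baseline_gad - final_gad >= GAD_RI_DECREASE) and (
        final_phq - baseline_phq < PHQ_DISQUALIFYING_INCREASE
    )
    return ri_phq, ri_gad


def assign_severity_band(
    baseline: int,
    instrument: Instrument,
    bands: dict[Instrument, dict[str, tuple[int, int]]] | None = None,
) -> SeverityBand:
    """Map a baseline total to its mild/moderate/severe band."""
    table = (bands or DEFAULT_BANDS)[instrument]
    lo, hi = PHQ_RANGE if instrument == "phq9" else GAD_RANGE
    _check_range(baseline, lo, hi, what=f"baseline {instrument}")
    for name, (lower, upper) in table.items():
        if lower <= baseline <= upper:
            return SeverityBand(instrument=instrument, band=name, lower=lower, upper=upper)  # type: ignore[arg-type]
    raise ValueError(f"bands for {instrument} do not cover score {baseline}")


def label_record(record: ClientRecord) -> OutcomeLabel:
    """Label one client from their first and LOCF-final measures."""
    final_phq, final_gad, last_idx = locf_final_scores(record)
    first = record.observations[0]
    ri_phq, ri_gad = label_reliable_improvement(
        first.phq_total, final_phq, first.gad_total, final_gad
    )
    return OutcomeLabel(
        ri_phq=ri_phq,
        ri_gad=ri_gad,
        baseline_phq=first.phq_total,
        baseline_gad=first.gad_total,
        final_phq=final_phq,
        final_gad=final_gad,
        last_observed_index=last_idx,
    )


def label_cohort(cohort: Iterable[ClientRecord]) -> dict[str, OutcomeLabel]:
    """Label every client; logs the resulting prevalence summary."""
    labels: dict[str, OutcomeLabel] = {}
    for record in cohort:
        try:
            labels[record.client_id] = label_record(record)
        except ValueError as exc:
            raise ValueError(f"client {record.client_id}: {exc}") from exc
    if labels:
        n = len(labels)
        prev_phq = sum(l.ri_phq for l in labels.values()) / n
        prev_gad = sum(l.ri_gad for l in labels.values()) / n
        logger.info(
            "labeled %d clients: RI prevalence PHQ-9 %.3f, GAD-7 %.3f",
            n, prev_phq, prev_gad,
        )
    return labels
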