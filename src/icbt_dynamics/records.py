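"""Core record types: one client's review-period observations.

A *review period* is the unit of prediction time: it starts when the client
completes an assigned PHQ-9/GAD-7 pair and ends when the supporter reviews
their work (on average 1.8 weeks later).  Treatment is capped at eight review
periods for labeling and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

PHQ_ITEMS = 9
GAD_ITEMS = 7
ITEM_CAP = 3
PHQ_RANGE = (0, 27)
GAD_RANGE = (0, 21)
#: Review periods considered for outcome labeling and evaluation.
MAX_REVIEWS = 8
#: Inclusion criterion: at least two completed measure sets.
MIN_REVIEWS = 2


@dataclass(frozen=True)
class ReviewObservation:
    """Item-level clinical scores plus interaction counts for one review.

    ``interaction_counts`` is sparse: a mapping from interaction-type id to a
    positive count; absent ids are zero.
    """

    review_index: int
    phq_items: tuple[int, ...]
    gad_items: tuple[int, ...]
    week: float = 0.0
    interaction_counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.review_index < 1:
            raise ValueError(f"review_index must be >= 1, got {self.review_index}")
        if len(self.phq_items) != PHQ_ITEMS:
            raise ValueError(f"expected {PHQ_ITEMS} PHQ-9 items, got {len(self.phq_items)}")
        if len(self.gad_items) != GAD_ITEMS:
            raise ValueError(f"expected {GAD_ITEMS} GAD-7 items, got {len(self.gad_items)}")
        for name, items in (("PHQ-9", self.phq_items), ("GAD-7", self.gad_items)):
            for v in items:
                if not 0 <= v <= ITEM_CAP:
                    raise ValueError(f"{name} item score {v} outside [0, {ITEM_CAP}]")
        for k, v in self.interaction_counts.items():
            if v < 0:
                raise ValueError(f"negative interaction count for type {k}")

    @property
    def phq_total(self) -> int:
        return sum(self.phq_items)

    @property
    def gad_total(self) -> int:
        return sum(self.gad_items)


@dataclass(frozen=True)
class ClientRecord:
    """Ordered, variable-length sequence of review observations.

    ``censored`` marks clients whose sequence was truncated by dropout before
    the eighth review.
    """

    client_id: str
    observations: tuple[ReviewObservation, ...]
    censored: bool = False

    def __post_init__(self) -> None:
        if len(self.observations) < MIN_REVIEWS:
            raise ValueError(
                f"client {self.client_id}: at least {MIN_REVIEWS} completed "
                f"measure sets are required, got {len(self.observations)}"
            )
        idx = [o.review_index for o in self.observations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"client {self.client_id}: review_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def phq_totals(self) -> list[int]:
        return [o.phq_total for o in self.observations]

    @property
    def gad_totals(self) -> list[int]:
        return [o.gad_total for o in self.observations]


Cohort = Sequence[ClientRecord]
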