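"""Stratified 70:20:10 train/validation/test splitting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from icbt_dynamics.labeling import OutcomeLabel
from icbt_dynamics.records import ClientRecord


class StratificationError(ValueError):
    """Raised when a split cannot be stratified (a class is absent)."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    validation_fraction: float = 0.20
    test_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_fraction, self.validation_fraction, self.test_fraction) <= 0:
            raise ValueError("split fractions must be positive")


def split_data(
    cohort: Sequence[ClientRecord],
    labels: Mapping[str, OutcomeLabel],
    instrument: str,
    spec: SplitSpec | None = None,
) -> tuple[list[ClientRecord], list[ClientRecord], list[ClientRecord]]:
    """Partition clients 70:20:10, stratified by the instrument's RI label.

    Deterministic given ``spec.seed``; raises ``StratificationError`` when
    either class is missing.
    """
    spec = spec or SplitSpec()
    missing = [r.client_id for r in cohort if r.client_id not in labels]
    if missing:
        raise ValueError(f"labels missing for clients: {missing[:5]}...")
    y = np.array(
        [
            (labels[r.client_id].ri_phq if instrument == "phq9" else labels[r.client_id].ri_gad)
            for r in cohort
        ],
        dtype=int,
    )
    if len(np.unique(y)) < 2:
        raise StratificationError("both outcome classes are required for a stratified split")

    idx = np.arange(len(cohort))
    train_idx, rest_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=y,
        random_state=spec.seed,
    )
    rel_val = spec.validation_fraction / (spec.validation_fraction + spec.test_fraction)
    val_idx, test_idx = train_test_split(
        rest_idx,
        train_size=rel_val,
        stratify=y[rest_idx],
        random_state=spec.seed + 1,
    )
    pick = lambda ids: [cohort[i] for i in sorted(ids)]
    return pick(train_idx), pick(val_idx), pick(test_idx)
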