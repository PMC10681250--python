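"""Shared fixtures: small synthetic cohorts and hand-built records."""

from __future__ import annotations

import numpy as np
import pytest

from icbt_dynamics.cohort import default_generator_config, sample_cohort
from icbt_dynamics.labeling import label_cohort
from icbt_dynamics.records import ClientRecord, ReviewObservation


def make_observation(review_index, phq_total=10, gad_total=8, week=None, interactions=None):
    """Observation with items split deterministically to match the totals."""

    def split(total, n_items):
        base, rem = divmod(total, n_items)
        return tuple(base + (1 if i < rem else 0) for i in range(n_items))

    return ReviewObservation(
        review_index=review_index,
        phq_items=split(phq_total, 9),
        gad_items=split(gad_total, 7),
        week=week if week is not None else 1.8 * (review_index - 1),
        interaction_counts=interactions or {},
    )


def make_record(client_id, phq_totals, gad_totals=None, censored=False):
    gad_totals = gad_totals or [8] * len(phq_totals)
    obs = tuple(
        make_observation(i + 1, phq_total=p, gad_total=g)
        for i, (p, g) in enumerate(zip(phq_totals, gad_totals))
    )
    return ClientRecord(client_id=client_id, observations=obs, censored=censored)


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default-condition cohort shared across read-only tests."""
    cfg = default_generator_config(n_clients=600, seed=101, n_interaction_types=40)
    return sample_cohort(cfg)


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    return label_cohort(default_cohort)


@pytest.fixture(scope="session")
def separable_cohort():
    """Noiseless sudden-gain improvers vs non-responders, no dropout: the
    outcome is exactly determined by the visible early score change."""
    cfg = default_generator_config(
        n_clients=800,
        seed=202,
        n_interaction_types=40,
        archetype_weights={
            "steady_improver": 0.0,
            "sudden_gain_improver": 0.5,
            "late_improver": 0.0,
            "non_responder": 0.5,
            "deteriorator": 0.0,
        },
        noise_sd=0.0,
        noise_corr=0.0,
        dropout_hazard=0.0,
    )
    return sample_cohort(cfg)


@pytest.fixture(scope="session")
def separable_labels(separable_cohort):
    return label_cohort(separable_cohort)
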