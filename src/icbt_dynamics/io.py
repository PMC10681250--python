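"""CSV / YAML serialization of cohorts, labels, and configs.

Cohorts are stored as two long-format tables: ``observations.csv`` with one
row per (client, review) holding item scores and totals, and
``interactions.csv`` with sparse (client, review, interaction_type, count)
triples.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from icbt_dynamics.labeling import OutcomeLabel, assign_severity_band
from icbt_dynamics.records import ClientRecord, GAD_ITEMS, PHQ_ITEMS, ReviewObservation

OBS_FILE = "observations.csv"
INTERACTIONS_FILE = "interactions.csv"
LABELS_FILE = "labels.csv"

_PHQ_COLS = [f"phq_item_{i}" for i in range(1, PHQ_ITEMS + 1)]
_GAD_COLS = [f"gad_item_{i}" for i in range(1, GAD_ITEMS + 1)]


def cohort_to_frames(cohort: Sequence[ClientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    obs_rows, int_rows = [], []
    for r in cohort:
        for o in r.observations:
            obs_rows.append(
                {
                    "client_id": r.client_id,
                    "review_index": o.review_index,
                    "week": round(o.week, 4),
                    **dict(zip(_PHQ_COLS, o.phq_items)),
                    **dict(zip(_GAD_COLS, o.gad_items)),
                    "phq_total": o.phq_total,
                    "gad_total": o.gad_total,
                    "censored": int(r.censored),
                }
            )
            for k in sorted(o.interaction_counts):
                int_rows.append(
                    {
                        "client_id": r.client_id,
                        "review_index": o.review_index,
                        "interaction_type_id": k,
                        "count": o.interaction_counts[k],
                    }
                )
    obs = pd.DataFrame(obs_rows)
    interactions = pd.DataFrame(
        int_rows, columns=["client_id", "review_index", "interaction_type_id", "count"]
    )
    return obs, interactions


def write_cohort(cohort: Sequence[ClientRecord], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs, interactions = cohort_to_frames(cohort)
    obs.to_csv(out / OBS_FILE, index=False)
    interactions.to_csv(out / INTERACTIONS_FILE, index=False)


def read_cohort(in_dir: str | Path) -> list[ClientRecord]:
    in_dir = Path(in_dir)
    obs = pd.read_csv(in_dir / OBS_FILE)
    ipath = in_dir / INTERACTIONS_FILE
    interactions = pd.read_csv(ipath) if ipath.exists() else None
    sparse: dict[tuple, dict[int, int]] = {}
    if interactions is not None:
        for row in interactions.itertuples(index=False):
            sparse.setdefault((row.client_id, row.review_index), {})[
                int(row.interaction_type_id)
            ] = int(row.count)

    records = []
    for cid, grp in obs.groupby("client_id", sort=True):
        grp = grp.sort_values("review_index")
        observations = tuple(
            ReviewObservation(
                review_index=int(row.review_index),
                phq_items=tuple(int(getattr(row, c)) for c in _PHQ_COLS),
                gad_items=tuple(int(getattr(row, c)) for c in _GAD_COLS),
                week=float(row.week),
                interaction_counts=sparse.get((cid, int(row.review_index)), {}),
            )
            for row in grp.itertuples(index=False)
        )
        records.append(
            ClientRecord(
                client_id=str(cid),
                observations=observations,
                censored=bool(grp["censored"].iloc[0]),
            )
        )
    return records


def labels_to_frame(labels: Mapping[str, OutcomeLabel]) -> pd.DataFrame:
    rows = []
    for cid in sorted(labels):
        lab = labels[cid]
        rows.append(
            {
                "client_id": cid,
                "ri_phq": int(lab.ri_phq),
                "ri_gad": int(lab.ri_gad),
                "baseline_phq": lab.baseline_phq,
                "baseline_gad": lab.baseline_gad,
                "final_phq": lab.final_phq,
                "final_gad": lab.final_gad,
                "last_observed_index": lab.last_observed_index,
                "phq_band": assign_severity_band(lab.baseline_phq, "phq9").band,
                "gad_band": assign_severity_band(lab.baseline_gad, "gad7").band,
            }
        )
    return pd.DataFrame(rows)


def write_labels(labels: Mapping[str, OutcomeLabel], path: str | Path) -> None:
    labels_to_frame(labels).to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, OutcomeLabel]:
    df = pd.read_csv(path)
    return {
        str(row.client_id): OutcomeLabel(
            ri_phq=bool(row.ri_phq),
            ri_gad=bool(row.ri_gad),
            baseline_phq=int(row.baseline_phq),
            baseline_gad=int(row.baseline_gad),
            final_phq=int(row.final_phq),
            final_gad=int(row.final_gad),
            last_observed_index=int(row.last_observed_index),
        )
        for row in df.itertuples(index=False)
    }


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
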