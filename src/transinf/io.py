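"""Dataset readers/writers and validation.

Cohorts are serialised as a single long CSV, one row per trial, with a
``participant`` column followed by the trial schema::

    participant, trial, block, item_hi, item_lo, first_position,
    feedback_scheduled, outcome_winner, truthful, choice, correct

``outcome_winner`` and ``truthful`` are empty on no-feedback trials.
Generating-model provenance of synthetic cohorts (model name, parameter
draws, subgroup) travels in a JSON sidecar next to the CSV, restored on
read when present.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import ChoiceDataset

__all__ = ["write_cohort", "read_choice_datasets", "SchemaError"]

REQUIRED_COLUMNS = [
    "participant",
    "trial",
    "block",
    "item_hi",
    "item_lo",
    "first_position",
    "feedback_scheduled",
    "outcome_winner",
    "truthful",
    "choice",
    "correct",
]


class SchemaError(ValueError):
    """A dataset file violates the documented schema."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_cohort(cohort: Sequence[ChoiceDataset], path) -> Path:
    """Write a cohort as one long CSV (plus a provenance sidecar)."""
    path = Path(path)
    frames = []
    meta = {}
    for ds in cohort:
        df = ds.trials.copy()
        df.insert(0, "participant", ds.participant)
        frames.append(df[REQUIRED_COLUMNS])
        meta[ds.participant] = {
            "design": ds.design_name,
            "model": ds.model_name,
            "params": ds.params,
            "subgroup": ds.subgroup,
        }
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=REQUIRED_COLUMNS).to_csv(path, index=False)
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _validate(df: pd.DataFrame, origin: str):
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{origin}: missing columns {missing}")
    pair_ok = (df["choice"] == df["item_hi"]) | (df["choice"] == df["item_lo"])
    if not pair_ok.all():
        row = int(df.index[~pair_ok][0])
        raise SchemaError(
            f"{origin}: column 'choice' not in presented pair at row {row}"
        )
    corr_ok = df["correct"].astype(bool) == (df["choice"] == df["item_hi"])
    if not corr_ok.all():
        row = int(df.index[~corr_ok][0])
        raise SchemaError(
            f"{origin}: column 'correct' inconsistent with true ranks at row {row}"
        )
    fb = df["feedback_scheduled"].astype(bool)
    has_winner = df["outcome_winner"].notna()
    if not (fb == has_winner).all():
        row = int(df.index[fb != has_winner][0])
        raise SchemaError(
            f"{origin}: column 'outcome_winner' must be present exactly on "
            f"feedback trials (row {row})"
        )
    scheduled = df[fb]
    bad = scheduled[
        (scheduled["outcome_winner"] != scheduled["item_hi"])
        & (scheduled["outcome_winner"] != scheduled["item_lo"])
    ]
    if len(bad):
        raise SchemaError(
            f"{origin}: column 'outcome_winner' outside pair at row {int(bad.index[0])}"
        )


def read_choice_datasets(path) -> list:
    """Read a long cohort CSV back into :class:`ChoiceDataset` objects.

    Validates the schema (named column and row on violation); an empty
    file yields an empty cohort with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty cohort file", stacklevel=2)
        return []
    _validate(df, str(path))
    df["outcome_winner"] = df["outcome_winner"].astype("Int64")
    df["truthful"] = df["truthful"].astype("boolean")
    df["feedback_scheduled"] = df["feedback_scheduled"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    out = []
    for pid, sub in df.groupby("participant", sort=False):
        info = meta.get(str(pid), {})
        out.append(
            ChoiceDataset(
                participant=str(pid),
                design_name=info.get("design", "unknown"),
                trials=sub.drop(columns=["participant"]).reset_index(drop=True),
                model_name=info.get("model"),
                params=info.get("params"),
                subgroup=info.get("subgroup"),
            )
        )
    return out
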