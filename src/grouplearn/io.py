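"""Trial-table CSV I/O and configuration loading.

CSV dialect: UTF-8, comma-separated, header row.  One row per trial with
columns ``participant_id, block, global_trial_index, agent_id, condition,
presentation_index, predicted_vase, actual_choice, missed``.  Vase indices
are 0-3 (row-major over color x shape, phenotype A first); a missed trial
has an empty ``predicted_vase`` and ``missed=1``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, DesignConfig
from .simulate import TRIAL_COLUMNS, LearnerParams


class SchemaError(ValueError):
    """A trial CSV violates the schema."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table; lossless inverse of :func:`read_trials`."""
    out = trials.copy()
    out["missed"] = out["missed"].astype(int)
    out["predicted_vase"] = out["predicted_vase"].astype("Int64")
    out[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV into the canonical in-memory table."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": "Int64",
            "block": "Int64",
            "global_trial_index": "Int64",
            "agent_id": str,
            "condition": str,
            "presentation_index": "Int64",
            "predicted_vase": "Int64",
            "actual_choice": "Int64",
            "missed": "Int64",
        },
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS]

    def _bad_rows(mask) -> list[int]:
        return (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # 1-based + header

    for col in ("participant_id", "block", "global_trial_index",
                "presentation_index", "actual_choice", "missed"):
        if df[col].isna().any():
            raise SchemaError(f"empty {col} in rows {_bad_rows(df[col].isna())[:10]}")
    bad = ~df["block"].isin([1, 2])
    if bad.any():
        raise SchemaError(f"block outside {{1,2}} in rows {_bad_rows(bad)[:10]}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise SchemaError(f"unknown condition in rows {_bad_rows(bad)[:10]}")
    for col in ("predicted_vase", "actual_choice"):
        bad = df[col].notna() & ~df[col].isin([0, 1, 2, 3])
        if bad.any():
            raise SchemaError(
                f"{col} outside 0-3 in rows {_bad_rows(bad)[:10]}"
            )
    bad = ~df["missed"].isin([0, 1])
    if bad.any():
        raise SchemaError(f"missed must be 0/1, rows {_bad_rows(bad)[:10]}")
    bad = df["missed"].eq(0) & df["predicted_vase"].isna()
    if bad.any():
        raise SchemaError(
            f"non-missed rows without a prediction: {_bad_rows(bad)[:10]}"
        )
    out = df.copy()
    out["missed"] = out["missed"].astype(bool)
    for col in ("participant_id", "block", "global_trial_index",
                "presentation_index", "actual_choice"):
        out[col] = out[col].astype(int)
    out.loc[out["missed"], "predicted_vase"] = pd.NA
    return out


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    design: DesignConfig = DesignConfig()
    learner: LearnerParams = LearnerParams()
    n_participants: int = 26
    seed: int = 0
    block2_agent_set: str = "new_only"
    assimilation_pairwise: bool = False
    pseudocount: float = 1.0
    output_dir: str = "grouplearn_out"
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.block2_agent_set not in ("new_only", "all"):
            raise ValueError(f"block2_agent_set={self.block2_agent_set!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = dataclasses.asdict(self.design)
        d["learner"] = dataclasses.asdict(self.learner)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignConfig(**d["design"])
        if "learner" in d:
            d["learner"] = LearnerParams(**d["learner"])
        try:
            return cls(**d)
        except TypeError as err:
            raise ValueError(f"invalid config: {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON, a YAML subset) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
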