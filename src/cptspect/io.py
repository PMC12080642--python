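"""Delimited-text readers/writers for the tables exchanged between stages.

All interchange is plain TSV so any stage can be run standalone on external
data that follows the same schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "trial_index",
    "onset_time_s",
    "stimulus",
    "is_target",
    "rt_ms",
]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"participant_id": str, "group": str, "sex": str, "stimulus": str},
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns: {missing}")
    df["trial_index"] = df["trial_index"].astype(np.int64)
    df["is_target"] = df["is_target"].astype(bool)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
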