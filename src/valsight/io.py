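"""Trial-table and configuration I/O, plus deterministic seed derivation.

Event tables travel as TSV with BIDS-events-style column naming, matrices
as CSV, reports as JSON, and configuration as YAML — one format per role.
Seeds are never global state: every stage derives its own seed from the
pipeline seed and the stage name.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_TRIAL_COLUMNS = [
    "subject_id", "phase", "pair", "optimal_side", "choice", "reward",
    "onset_s", "feedback_onset_s", "trial_sign",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = zlib.crc32(f"{stage}".encode())
    return int((int(global_seed) * 1_000_003 + h) % (2**31 - 1))


def write_trials(records: pd.DataFrame, path) -> None:
    """Write a trial table as TSV (NA cells left empty)."""
    records.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial TSV.

    Unknown columns are preserved. Transfer rows must carry NA rewards
    (no feedback is delivered in transfer); violations raise. An empty
    file yields a typed empty table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REQUIRED_TRIAL_COLUMNS)
    if df.empty and not list(df.columns):
        df = pd.DataFrame(columns=REQUIRED_TRIAL_COLUMNS)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path.name} is missing required "
                         f"column(s): {', '.join(missing)}")
    df["choice"] = df["choice"].astype("string")
    df["reward"] = pd.to_numeric(df["reward"], errors="coerce")
    bad = (df["phase"] == "transfer") & df["reward"].notna()
    if bad.any():
        raise ValueError(f"{int(bad.sum())} transfer row(s) carry non-NA "
                         "reward; transfer trials deliver no feedback")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
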