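"""Reader/writer for the canonical tidy per-trial table.

One row per participant x trial with columns::

    participant_id, trial, x1..x4, p1..p4, choice, outcome, valence, arousal

Outcomes are integers in SEK, probabilities floats summing to 1 per row,
``choice`` is 1 for accept / 0 for reject, ``outcome`` the realized feedback
(0 when rejected), and ``valence`` / ``arousal`` the raw rating values as
collected (standardization happens downstream).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TRIAL_COLUMNS", "write_trials", "read_trials", "validate_trials"]

TRIAL_COLUMNS = (
    ["participant_id", "trial"]
    + [f"x{i}" for i in range(1, 5)]
    + [f"p{i}" for i in range(1, 5)]
    + ["choice", "outcome", "valence", "arousal"]
)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    probs = df[[f"p{i}" for i in range(1, 5)]].to_numpy(float)
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities must sum to 1 in every row")
    if not df["choice"].isin([0, 1]).all():
        raise ValueError("choice must be 0 or 1")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    validate_trials(df)
    # %.17g guarantees float64 round-trips through the CSV
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS, float_format="%.17g")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "trial": int, "choice": int},
        float_precision="round_trip",
    )
    return validate_trials(df)
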