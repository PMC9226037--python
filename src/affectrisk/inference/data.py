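"""Model-ready data containers built from the tidy per-trial table.

Both containers assume a balanced design (every participant has the same
number of trials, as in the task where each participant sees 50 gambles) and
validate it.  Ratings are standardized within participant on construction;
trial-lagged regressors (previous valence/arousal/outcome/PE) use 0 for the
first trial, which is the individual's mean state on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..gambles import transform_uncertainty

__all__ = ["AffectData", "ChoiceData", "session_arrays"]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if np.ptp(x) == 0 or sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def session_arrays(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Stack one column set per participant into (N, T) / (N, T, 4) arrays."""
    pids = df["participant_id"].unique()
    counts = df.groupby("participant_id", sort=False).size()
    if counts.min() == 0:
        raise ValueError("participant with zero trials")
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: participants differ in trial count")
    t = int(counts.iloc[0])
    if t < 2:
        raise ValueError("sessions must have at least 2 trials")
    n = len(pids)
    df = df.sort_values(["participant_id", "trial"], kind="stable")

    x = df[[f"x{i}" for i in range(1, 5)]].to_numpy(float).reshape(n, t, 4)
    p = df[[f"p{i}" for i in range(1, 5)]].to_numpy(float).reshape(n, t, 4)
    choice = df["choice"].to_numpy(int).reshape(n, t)
    outcome = df["outcome"].to_numpy(float).reshape(n, t)
    valence = df["valence"].to_numpy(float).reshape(n, t)
    arousal = df["arousal"].to_numpy(float).reshape(n, t)

    ev = (x * p).sum(axis=2)
    u_raw = (((x - ev[:, :, None]) ** 2) * p).sum(axis=2)
    u_trans = np.vstack([transform_uncertainty(u_raw[i]) for i in range(n)])
    pe = np.where(choice == 1, outcome - ev, 0.0)
    val_z = np.vstack([_zscore(valence[i]) for i in range(n)])
    aro_z = np.vstack([_zscore(arousal[i]) for i in range(n)])

    return {
        "participants": pids,
        "x": x,
        "p": p,
        "choice": choice,
        "outcome": outcome,
        "ev": ev,
        "u_trans": u_trans,
        "pe": pe,
        "abs_pe": np.abs(pe),
        "valence_z": val_z,
        "arousal_z": aro_z,
    }


def _lag(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[:, 1:] = x[:, :-1]
    return out


@dataclass
class AffectData:
    """Per-trial predictors and standardized ratings for one affect dimension."""

    participants: np.ndarray
    ratings: np.ndarray  # (N, T) standardized
    predictors: dict[str, np.ndarray]  # each (N, T)

    @classmethod
    def from_trials(cls, df: pd.DataFrame, dimension: str = "valence") -> "AffectData":
        if dimension not in ("valence", "arousal"):
            raise ValueError("dimension must be 'valence' or 'arousal'")
        arr = session_arrays(df)
        return cls(
            participants=arr["participants"],
            ratings=arr[f"{dimension}_z"],
            predictors={
                "ev": arr["ev"],
                "outcome": arr["outcome"],
                "u_trans": arr["u_trans"],
                "pe": arr["pe"],
                "abs_pe": arr["abs_pe"],
            },
        )

    @property
    def n_participants(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_trials(self) -> int:
        return self.ratings.shape[1]


@dataclass
class ChoiceData:
    """Gambles, choices and lagged affect/control regressors for the choice models."""

    participants: np.ndarray
    x: np.ndarray  # (N, T, 4)
    p: np.ndarray
    choice: np.ndarray  # (N, T) in {0, 1}
    valence_prev: np.ndarray  # (N, T), standardized rating of trial t-1, 0 at t=0
    arousal_prev: np.ndarray
    outcome_prev: np.ndarray
    pe_prev: np.ndarray
    log_abs_x: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.x == 0):
            raise ValueError("gamble outcomes must be nonzero")
        if self.log_abs_x is None:
            self.log_abs_x = np.log(np.abs(self.x))

    @classmethod
    def from_trials(cls, df: pd.DataFrame) -> "ChoiceData":
        arr = session_arrays(df)
        return cls(
            participants=arr["participants"],
            x=arr["x"],
            p=arr["p"],
            choice=arr["choice"],
            valence_prev=_lag(arr["valence_z"]),
            arousal_prev=_lag(arr["arousal_z"]),
            outcome_prev=_lag(arr["outcome"]),
            pe_prev=_lag(arr["pe"]),
        )

    @property
    def n_participants(self) -> int:
        return self.choice.shape[0]

    @property
    def n_trials(self) -> int:
        return self.choice.shape[1]
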