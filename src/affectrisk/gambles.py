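"""Constrained four-outcome gamble generation and per-trial decision variables.

A gamble is four distinct, nonzero monetary outcomes (multiples of 5 SEK,
capped at |x| <= 75) with probabilities on the simplex, rejection-sampled so
that the expected value never exceeds +-25 SEK.  Drawn this way the expected
values form an approximately normal distribution with mean 0 and standard
deviation close to 10 SEK, which is the calibration target for the
probability-simplex concentration (see :class:`GambleConfig`).

The decision variables derived from a gamble and the participant's choice are

* ``EV``      — probability-weighted mean outcome,
* ``U``       — outcome variance around EV (square-root transformed and
  mean-centered within a session before entering the affect model),
* ``PE``      — realized outcome minus EV for accepted gambles, exactly 0 for
  rejected ones (the feedback screen shows "0 SEK").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gamble",
    "GambleConfig",
    "DecisionVariables",
    "round_to_nearest_5",
    "draw_gamble",
    "generate_session",
    "compute_ev",
    "compute_uncertainty",
    "transform_uncertainty",
    "compute_pe",
    "decision_variables",
]


class GambleGenerationError(RuntimeError):
    """Rejection sampling failed to produce a valid gamble within the attempt cap."""


@dataclass(frozen=True)
class GambleConfig:
    """Constraints and distributional choices for gamble generation.

    ``prob_concentration`` is the symmetric Dirichlet concentration for the
    outcome probabilities.  The default 2.5 is calibrated so that the emergent
    EV distribution has a standard deviation of ~10 SEK (a flat simplex gives
    ~11 SEK).
    """

    outcome_mean: float = 0.0
    outcome_sd: float = 18.0
    outcome_cap: float = 75.0
    ev_cap: float = 25.0
    grid: int = 5
    n_outcomes: int = 4
    prob_concentration: float = 2.5
    max_attempts: int = 10_000


@dataclass(frozen=True)
class Gamble:
    """Four outcome/probability pairs.

    Outcomes are integer multiples of 5 SEK, all distinct and nonzero;
    probabilities sum to one.
    """

    outcomes: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.outcomes) != len(self.probabilities):
            raise ValueError("outcomes and probabilities must have equal length")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if any(p <= 0 or p > 1 for p in self.probabilities):
            raise ValueError("probabilities must lie in (0, 1]")

    @property
    def ev(self) -> float:
        return compute_ev(self)

    @property
    def uncertainty(self) -> float:
        return compute_uncertainty(self)


@dataclass(frozen=True)
class DecisionVariables:
    """Per-trial derived quantities feeding the affect model."""

    ev: float
    u_raw: float
    u_trans: float
    pe: float
    abs_pe: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.abs_pe):
            object.__setattr__(self, "abs_pe", abs(self.pe))


def round_to_nearest_5(x: float, grid: int = 5) -> int:
    """Round ``x`` to the nearest multiple of ``grid`` SEK, ties away from zero.

    Examples: 13.4 -> 15, -7.9 -> -10, 12.5 -> 15, -12.5 -> -15.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.copysign(math.floor(abs(x) / grid + 0.5), x)) * grid


def _candidate(rng: np.random.Generator, config: GambleConfig) -> Gamble | None:
    raw = rng.normal(config.outcome_mean, config.outcome_sd, config.n_outcomes)
    outcomes = tuple(round_to_nearest_5(v, config.grid) for v in raw)
    if 0 in outcomes or len(set(outcomes)) < config.n_outcomes:
        return None
    if max(abs(o) for o in outcomes) > config.outcome_cap:
        return None
    probs = rng.dirichlet([config.prob_concentration] * config.n_outcomes)
    if np.any(probs <= 0):  # degenerate simplex draw; redraw
        return None
    # renormalise exactly so the invariant holds to 1e-9 after float noise
    probs = probs / probs.sum()
    g = Gamble(outcomes, tuple(probs))
    if abs(g.ev) > config.ev_cap:
        return None
    return g


def draw_gamble(rng: np.random.Generator, config: GambleConfig | None = None) -> Gamble:
    """Rejection-sample one gamble satisfying the full constraint set."""
    config = config or GambleConfig()
    for _ in range(config.max_attempts):
        g = _candidate(rng, config)
        if g is not None:
            return g
    raise GambleGenerationError(
        f"no valid gamble after {config.max_attempts} attempts; check config"
    )


def generate_session(
    rng: np.random.Generator, n_trials: int = 50, config: GambleConfig | None = None
) -> list[Gamble]:
    """Independent gambles for one participant session (paper-scale default 50)."""
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    config = config or GambleConfig()
    return [draw_gamble(rng, config) for _ in range(n_trials)]


def compute_ev(gamble: Gamble) -> float:
    """Probability-weighted mean outcome, sum_i x_i * p_i."""
    return float(np.dot(gamble.outcomes, gamble.probabilities))


def compute_uncertainty(gamble: Gamble) -> float:
    """Outcome variance around EV, sum_i (x_i - EV)^2 * p_i (>= 0)."""
    x = np.asarray(gamble.outcomes, dtype=float)
    p = np.asarray(gamble.probabilities, dtype=float)
    ev = float(np.dot(x, p))
    return float(np.dot((x - ev) ** 2, p))


def transform_uncertainty(u_raw: np.ndarray) -> np.ndarray:
    """Square-root transform, then mean-center within the session.

    Centering is within-participant (one session at a time), matching the
    per-individual standardization of the affect ratings.
    """
    u = np.asarray(u_raw, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("expected a session of at least 2 trials")
    if np.any(u < 0):
        raise ValueError("raw uncertainty must be nonnegative")
    s = np.sqrt(u)
    return s - s.mean()


def compute_pe(ev: float, accepted: bool, outcome: float, gamble: Gamble | None = None) -> float:
    """Prediction error: outcome - EV when accepted, exactly 0 when rejected.

    If the gamble is supplied, an accepted outcome must be one of its four
    outcomes (consistency check against the feedback screen).
    """
    if not accepted:
        return 0.0
    if gamble is not None and outcome not in gamble.outcomes:
        raise ValueError(f"accepted outcome {outcome} not among gamble outcomes {gamble.outcomes}")
    return float(outcome) - float(ev)


def decision_variables(
    session: list[Gamble], accepted: np.ndarray, outcomes: np.ndarray
) -> list[DecisionVariables]:
    """Full per-trial decision-variable table for one session."""
    if not (len(session) == len(accepted) == len(outcomes)):
        raise ValueError("session, choices and outcomes must align")
    evs = np.array([compute_ev(g) for g in session])
    u_raw = np.array([compute_uncertainty(g) for g in session])
    u_trans = transform_uncertainty(u_raw)
    out = []
    for g, ev, ur, ut, acc, x in zip(session, evs, u_raw, u_trans, accepted, outcomes):
        pe = compute_pe(ev, bool(acc), float(x), g)
        out.append(DecisionVariables(ev=float(ev), u_raw=float(ur), u_trans=float(ut), pe=pe))
    return out
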