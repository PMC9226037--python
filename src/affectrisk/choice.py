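"""Prospect-theory valuation and choice, with trial-by-trial affective modulation.

The base model values each outcome with the two-parameter power utility

    u(x) = x^rho            if x > 0
    u(x) = -lam * (-x)^rho  if x < 0

(lam: loss aversion, rho: curvature), aggregates to the gamble's subjective
value V = sum_i u(x_i) * p_i, and accepts with probability
logistic(c * V), where c in [0, 20] is the choice-consistency
(inverse-temperature) parameter; c = 0 is fully random choice.

Trial-by-trial modulation shifts each parameter around the individual mean by
the valence and arousal reported at the end of the previous trial,
e.g.  lam_t = lam + beta_V * valence_{t-1} + beta_A * arousal_{t-1},
with optional previous-outcome / previous-PE control regressors.  The shifted
parameters are clipped back to their admissible ranges (lam_t >= 0,
rho_t >= 0, c_t in [0, 20]); the first trial has no prior rating and uses
zero regressors, i.e. the individual means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affect import AffectModelSpec, AffectParams, integrate_affect
from .gambles import Gamble, compute_ev, compute_uncertainty, transform_uncertainty

__all__ = [
    "ChoiceParams",
    "AffectRegressionWeights",
    "TrialChoiceParams",
    "GambleValue",
    "utility",
    "gamble_value",
    "p_accept",
    "modulate_params",
    "loglik_choice",
    "simulate_choices",
    "SimulatedSession",
]

C_MAX = 20.0


@dataclass(frozen=True)
class ChoiceParams:
    """Individual-mean loss aversion, curvature, and choice consistency."""

    lam: float
    rho: float
    c: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.rho < 0:
            raise ValueError("lam and rho must be nonnegative")
        if not 0.0 <= self.c <= C_MAX:
            raise ValueError(f"c must lie in [0, {C_MAX}]")


@dataclass(frozen=True)
class AffectRegressionWeights:
    """Per-individual regression weights shifting (lam, rho, c) trial by trial.

    ``beta_v_*`` / ``beta_a_*`` multiply the previous trial's valence and
    arousal ratings; ``beta_out_*`` / ``beta_pe_*`` are the control-model
    regressors on the previous outcome and prediction error.  All default to
    zero, which reduces the modulated model to the base model exactly.
    """

    beta_v_lam: float = 0.0
    beta_v_rho: float = 0.0
    beta_v_c: float = 0.0
    beta_a_lam: float = 0.0
    beta_a_rho: float = 0.0
    beta_a_c: float = 0.0
    beta_out_lam: float = 0.0
    beta_out_rho: float = 0.0
    beta_out_c: float = 0.0
    beta_pe_lam: float = 0.0
    beta_pe_rho: float = 0.0
    beta_pe_c: float = 0.0


@dataclass(frozen=True)
class TrialChoiceParams:
    """Affect-modulated parameters for one trial, clipped to admissible ranges."""

    lam: float
    rho: float
    c: float


@dataclass(frozen=True)
class GambleValue:
    utilities: tuple[float, ...]
    v: float


def utility(x: float, lam: float, rho: float) -> float:
    """Prospect-theory utility of a single nonzero monetary outcome."""
    if x == 0:
        raise ValueError("outcomes are never 0 by construction; got x = 0")
    if x > 0:
        return float(x**rho)
    return float(-lam * (-x) ** rho)


def gamble_value(gamble: Gamble, lam: float, rho: float) -> GambleValue:
    """Subjective gamble value: probability-weighted sum of outcome utilities."""
    utils = tuple(utility(x, lam, rho) for x in gamble.outcomes)
    return GambleValue(utilities=utils, v=float(np.dot(utils, gamble.probabilities)))


def p_accept(v: float, c: float) -> float:
    """Acceptance probability logistic(c * v); c = 0 gives 0.5 for any value."""
    if not 0.0 <= c <= C_MAX:
        raise ValueError(f"c must lie in [0, {C_MAX}]")
    return float(1.0 / (1.0 + np.exp(-np.clip(c * v, -700, 700))))


def modulate_params(
    base: ChoiceParams,
    weights: AffectRegressionWeights,
    valence_prev: float = 0.0,
    arousal_prev: float = 0.0,
    outcome_prev: float = 0.0,
    pe_prev: float = 0.0,
) -> TrialChoiceParams:
    """Shift (lam, rho, c) by the previous trial's affect (and control) regressors."""
    lam = (
        base.lam
        + weights.beta_v_lam * valence_prev
        + weights.beta_a_lam * arousal_prev
        + weights.beta_out_lam * outcome_prev
        + weights.beta_pe_lam * pe_prev
    )
    rho = (
        base.rho
        + weights.beta_v_rho * valence_prev
        + weights.beta_a_rho * arousal_prev
        + weights.beta_out_rho * outcome_prev
        + weights.beta_pe_rho * pe_prev
    )
    c = (
        base.c
        + weights.beta_v_c * valence_prev
        + weights.beta_a_c * arousal_prev
        + weights.beta_out_c * outcome_prev
        + weights.beta_pe_c * pe_prev
    )
    return TrialChoiceParams(lam=max(lam, 0.0), rho=max(rho, 0.0), c=float(np.clip(c, 0.0, C_MAX)))


def loglik_choice(
    trial_params: list[TrialChoiceParams], session: list[Gamble], choices: np.ndarray
) -> float:
    """Bernoulli log-likelihood of accept/reject choices under per-trial parameters."""
    if not (len(trial_params) == len(session) == len(choices)):
        raise ValueError("trial parameters, session and choices must align")
    ll = 0.0
    for tp, g, ch in zip(trial_params, session, choices):
        z = tp.c * gamble_value(g, tp.lam, tp.rho).v
        # log sigmoid(z) = -log(1 + e^-z); numerically safe via logaddexp
        ll += -np.logaddexp(0.0, -z) if ch else -np.logaddexp(0.0, z)
    return float(ll)


@dataclass(frozen=True)
class SimulatedSession:
    """One simulated participant-session from the closed generative loop."""

    choices: np.ndarray  # 1 = accept
    outcomes: np.ndarray  # realized outcome, 0 when rejected
    valence: np.ndarray  # raw emitted ratings (model scale)
    arousal: np.ndarray
    ev: np.ndarray
    u_trans: np.ndarray
    pe: np.ndarray
    trial_params: list[TrialChoiceParams]


def simulate_choices(
    rng: np.random.Generator,
    base: ChoiceParams,
    weights: AffectRegressionWeights,
    session: list[Gamble],
    valence_params: AffectParams,
    arousal_params: AffectParams,
    affect_spec: AffectModelSpec | None = None,
) -> SimulatedSession:
    """Simulate the full task loop for one participant.

    Per trial: modulate (lam, rho, c) by the previous trial's emitted ratings,
    draw accept/reject, realize the outcome (from the gamble's own distribution
    if accepted, 0 otherwise), update the affect traces, emit noisy valence and
    arousal ratings that feed the next trial.

    During generation the modulating ratings are the raw emitted ones; the
    analysis pipeline standardizes ratings within participant afterwards.
    """
    spec = affect_spec or AffectModelSpec()
    n = len(session)
    evs = np.array([compute_ev(g) for g in session])
    u_raw = np.array([compute_uncertainty(g) for g in session])
    u_trans = transform_uncertainty(u_raw) if n >= 2 else np.zeros(n)

    choices = np.zeros(n, dtype=int)
    outcomes = np.zeros(n)
    pe = np.zeros(n)
    valence = np.zeros(n)
    arousal = np.zeros(n)
    trial_params: list[TrialChoiceParams] = []

    for t, g in enumerate(session):
        v_prev = valence[t - 1] if t > 0 else 0.0
        a_prev = arousal[t - 1] if t > 0 else 0.0
        out_prev = outcomes[t - 1] if t > 0 else 0.0
        pe_prev = pe[t - 1] if t > 0 else 0.0
        tp = modulate_params(base, weights, v_prev, a_prev, out_prev, pe_prev)
        trial_params.append(tp)

        p = p_accept(gamble_value(g, tp.lam, tp.rho).v, tp.c)
        accept = rng.random() < p
        choices[t] = int(accept)
        if accept:
            idx = rng.choice(len(g.outcomes), p=np.asarray(g.probabilities))
            outcomes[t] = g.outcomes[idx]
            pe[t] = outcomes[t] - evs[t]
        # rejected: outcome shown is 0 SEK and PE is defined as 0

        dv_so_far = {
            "ev": evs[: t + 1],
            "outcome": outcomes[: t + 1],
            "u_trans": u_trans[: t + 1],
            "pe": pe[: t + 1],
            "abs_pe": np.abs(pe[: t + 1]),
        }
        ae_v = integrate_affect(valence_params, dv_so_far, spec).predicted[-1]
        ae_a = integrate_affect(arousal_params, dv_so_far, spec).predicted[-1]
        valence[t] = ae_v + rng.normal(0.0, valence_params.sigma)
        arousal[t] = ae_a + rng.normal(0.0, arousal_params.sigma)

    return SimulatedSession(
        choices=choices,
        outcomes=outcomes,
        valence=valence,
        arousal=arousal,
        ev=evs,
        u_trans=u_trans,
        pe=pe,
        trial_params=trial_params,
    )
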