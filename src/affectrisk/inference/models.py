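"""Hierarchical model definitions for the affect and choice models.

A :class:`HierarchicalModel` couples a list of individual-level parameters
(each with a link to its natural scale) to a vectorized per-participant
log-likelihood.  The hierarchy itself — normal population distributions on
the unconstrained scale with standard-normal hyperpriors on the group means
and half-normal(1) hyperpriors on the group scales — lives in the sampler and
is shared by every model.

Choice-model variants:

* ``base``            — lam, rho, c only (no affect input)
* ``full``            — valence and arousal modulate all three parameters
* ``adjusted``        — arousal modulators only (valence removed)
* ``control_outcome`` — adjusted plus previous-outcome regressors
* ``control_pe``      — adjusted plus previous-PE regressors

With every modulation weight at zero the full model's likelihood reduces to
the base model's exactly (the nesting used by the WAIC comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..affect import AffectModelSpec
from . import links
from .data import AffectData, ChoiceData

__all__ = [
    "ParamSpec",
    "HierarchicalModel",
    "build_choice_model",
    "build_affect_model",
    "CHOICE_VARIANTS",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

CHOICE_VARIANTS = ("base", "full", "adjusted", "control_outcome", "control_pe")


@dataclass(frozen=True)
class ParamSpec:
    name: str
    link: str  # see links.LINKS


@dataclass
class HierarchicalModel:
    """Parameter layout plus vectorized likelihood for one model."""

    name: str
    params: list[ParamSpec]
    # theta_nat: dict param name -> (N,) natural values; returns (N,) loglik
    participant_loglik: Callable[[dict, object], np.ndarray]
    # WAIC grain: (N,) for choice (participant level), (N*T,) for affect (trial level)
    pointwise_loglik: Callable[[dict, object], np.ndarray] = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pointwise_loglik is None:
            self.pointwise_loglik = self.participant_loglik

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def natural(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Map an (N, K) unconstrained matrix to named natural-scale columns."""
        return {
            spec.name: links.forward(theta[:, k], spec.link)
            for k, spec in enumerate(self.params)
        }


# --------------------------------------------------------------------------
# choice models
# --------------------------------------------------------------------------

_MOD_REGRESSORS = {
    "v": "valence_prev",
    "a": "arousal_prev",
    "out": "outcome_prev",
    "pe": "pe_prev",
}


def _choice_beta_tags(variant: str) -> list[str]:
    if variant == "base":
        return []
    if variant == "full":
        return ["v", "a"]
    if variant == "adjusted":
        return ["a"]
    if variant == "control_outcome":
        return ["a", "out"]
    if variant == "control_pe":
        return ["a", "pe"]
    raise ValueError(f"unknown choice variant {variant!r}; expected one of {CHOICE_VARIANTS}")


def build_choice_model(variant: str = "base") -> HierarchicalModel:
    """Prospect-theory choice model with optional trial-by-trial modulation."""
    tags = _choice_beta_tags(variant)
    params = [ParamSpec("lam", "log"), ParamSpec("rho", "log"), ParamSpec("c", "unit20")]
    for tag in tags:
        for target in ("lam", "rho", "c"):
            params.append(ParamSpec(f"beta_{tag}_{target}", "identity"))

    def participant_loglik(nat: dict, data: ChoiceData) -> np.ndarray:
        lam_t = np.repeat(nat["lam"][:, None], data.n_trials, axis=1)
        rho_t = np.repeat(nat["rho"][:, None], data.n_trials, axis=1)
        c_t = np.repeat(nat["c"][:, None], data.n_trials, axis=1)
        for tag in tags:
            reg = getattr(data, _MOD_REGRESSORS[tag])
            lam_t = lam_t + nat[f"beta_{tag}_lam"][:, None] * reg
            rho_t = rho_t + nat[f"beta_{tag}_rho"][:, None] * reg
            c_t = c_t + nat[f"beta_{tag}_c"][:, None] * reg
        if tags:
            lam_t = np.maximum(lam_t, 0.0)
            rho_t = np.maximum(rho_t, 0.0)
            c_t = np.clip(c_t, 0.0, 20.0)
        # |x|^rho via exp(rho * log|x|); outcomes are nonzero by construction.
        # The exponent is capped so that absurd proposed rho values yield a
        # finite (terrible) likelihood instead of inf - inf = nan.
        mag = np.exp(np.minimum(rho_t[:, :, None] * data.log_abs_x, 80.0))
        util = np.where(data.x > 0, mag, -lam_t[:, :, None] * mag)
        v = (util * data.p).sum(axis=2)
        z = c_t * v
        ll_t = np.where(data.choice == 1, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
        return ll_t.sum(axis=1)

    return HierarchicalModel(
        name=f"choice_{variant}",
        params=params,
        participant_loglik=participant_loglik,
        meta={"variant": variant, "kind": "choice"},
    )


# --------------------------------------------------------------------------
# affect models
# --------------------------------------------------------------------------

_AFFECT_WEIGHT_OF = {"ev": "w_ev", "outcome": "w_ev", "u_trans": "w_u", "pe": "w_pe", "abs_pe": "w_abs_pe"}


def build_affect_model(spec: AffectModelSpec | None = None) -> HierarchicalModel:
    """Temporal affect-integration model (any predictor variant)."""
    spec = spec or AffectModelSpec()
    predictors = spec.predictors()
    params = [ParamSpec("w0", "identity")]
    params += [ParamSpec(_AFFECT_WEIGHT_OF[p], "identity") for p in predictors]
    params += [ParamSpec("gamma", "unit"), ParamSpec("sigma", "log")]

    def _predicted(nat: dict, data: AffectData) -> np.ndarray:
        n, t = data.ratings.shape
        gamma = nat["gamma"]
        ae = np.repeat(nat["w0"][:, None], t, axis=1)
        for pred in predictors:
            w = nat[_AFFECT_WEIGHT_OF[pred]]
            series = data.predictors[pred]
            s = np.zeros(n)
            trace = np.empty((n, t))
            for j in range(t):
                s = gamma * s + series[:, j]
                trace[:, j] = s
            ae += w[:, None] * trace
        return ae

    def trial_loglik(nat: dict, data: AffectData) -> np.ndarray:
        resid = data.ratings - _predicted(nat, data)
        sigma = nat["sigma"][:, None]
        return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (resid / sigma) ** 2

    def participant_loglik(nat: dict, data: AffectData) -> np.ndarray:
        return trial_loglik(nat, data).sum(axis=1)

    return HierarchicalModel(
        name=f"affect_{'outcome' if spec.use_outcome else 'ev'}",
        params=params,
        participant_loglik=participant_loglik,
        pointwise_loglik=lambda nat, data: trial_loglik(nat, data).ravel(),
        meta={"spec": spec, "kind": "affect", "predictors": predictors},
    )
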