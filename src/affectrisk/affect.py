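"""Temporal affect-integration model.

Momentary affective experience (valence or arousal, on the within-participant
standardized rating scale) is modelled as a weighted sum of exponentially
decaying traces of the decision variables encountered so far:

    AE_t = w0 + sum_k w_k * sum_{j<=t} gamma^(t-j) * X_{k,j}

with predictors X in {EV, U (centered sqrt), PE, |PE|} and an individual
forgetting factor gamma in [0, 1]:  gamma = 0 means only the current trial
matters, gamma = 1 weighs every past trial evenly.  Observed ratings are the
predicted trace plus Gaussian noise with an individual scale.

The double sum is evaluated with the O(T) recursion S_t = gamma*S_{t-1} + X_t
(S_0 = 0); the literal O(T^2) form is kept in the test suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffectParams",
    "AffectModelSpec",
    "AffectTrace",
    "decay_sum",
    "integrate_affect",
    "simulate_ratings",
    "loglik_affect",
    "build_affect_variant",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class AffectParams:
    """Weights, forgetting factor and rating-noise scale for one individual."""

    w0: float = 0.0
    w_ev: float = 0.0
    w_u: float = 0.0
    w_pe: float = 0.0
    w_abs_pe: float = 0.0
    gamma: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class AffectModelSpec:
    """Predictor-selection flags for the model variants.

    The full variant uses expectation-based predictors (EV, PE, |PE|) plus the
    uncertainty term; the outcome variant replaces EV and PE with the realized
    outcome, testing whether affect tracks expectations or raw outcomes.
    ``pe_parametrization`` switches between the signed-plus-magnitude default
    ("signed_abs"), signed-only ("signed") and magnitude-only ("abs").
    """

    use_outcome: bool = False
    include_u: bool = True
    pe_parametrization: str = "signed_abs"  # signed_abs | signed | abs | none

    def __post_init__(self) -> None:
        if self.pe_parametrization not in ("signed_abs", "signed", "abs", "none"):
            raise ValueError(f"unknown pe_parametrization {self.pe_parametrization!r}")
        if not self.predictors():
            raise ValueError("model spec selects no predictors")

    def predictors(self) -> list[str]:
        preds: list[str] = []
        if self.use_outcome:
            preds.append("outcome")
        else:
            preds.append("ev")
        if self.include_u:
            preds.append("u_trans")
        if not self.use_outcome:
            if self.pe_parametrization in ("signed_abs", "signed"):
                preds.append("pe")
            if self.pe_parametrization in ("signed_abs", "abs"):
                preds.append("abs_pe")
        return preds


@dataclass(frozen=True)
class AffectTrace:
    """Predicted affect trajectory, optionally paired with observed ratings."""

    predicted: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.observed is not None and len(self.observed) != len(self.predicted):
            raise ValueError("observed and predicted traces must align")


def decay_sum(x: np.ndarray, gamma: float) -> np.ndarray:
    """Exponentially decaying running sum S_t = gamma*S_{t-1} + x_t, S_0 = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    s = 0.0
    for t in range(x.shape[0]):
        s = gamma * s + x[t]
        out[t] = s
    return out


def _predictor_matrix(dv, spec: AffectModelSpec) -> dict[str, np.ndarray]:
    """Assemble predictor series from a DecisionVariables sequence or a dict."""
    if isinstance(dv, dict):
        series = {k: np.asarray(v, dtype=float) for k, v in dv.items()}
    else:
        series = {
            "ev": np.array([d.ev for d in dv]),
            "u_trans": np.array([d.u_trans for d in dv]),
            "pe": np.array([d.pe for d in dv]),
            "abs_pe": np.array([d.abs_pe for d in dv]),
        }
    missing = [p for p in spec.predictors() if p not in series]
    if missing:
        raise ValueError(f"decision variables missing predictors {missing}")
    return {p: series[p] for p in spec.predictors()}


_WEIGHT_OF = {
    "ev": "w_ev",
    "outcome": "w_ev",  # the outcome variant reuses the expectation slot
    "u_trans": "w_u",
    "pe": "w_pe",
    "abs_pe": "w_abs_pe",
}


def integrate_affect(
    params: AffectParams, dv, spec: AffectModelSpec | None = None
) -> AffectTrace:
    """Predicted affect trace for one session (deterministic given params)."""
    spec = spec or AffectModelSpec()
    preds = _predictor_matrix(dv, spec)
    n = len(next(iter(preds.values())))
    if n == 0:
        raise ValueError("empty decision-variable sequence")
    ae = np.full(n, params.w0, dtype=float)
    for name, series in preds.items():
        w = getattr(params, _WEIGHT_OF[name])
        ae += w * decay_sum(series, params.gamma)
    return AffectTrace(predicted=ae)


def simulate_ratings(
    rng: np.random.Generator, params: AffectParams, trace: AffectTrace
) -> np.ndarray:
    """Observed ratings: predicted trace plus iid Gaussian noise of scale sigma."""
    return trace.predicted + rng.normal(0.0, params.sigma, size=trace.predicted.shape)


def loglik_affect(params: AffectParams, ratings: np.ndarray, dv, spec=None) -> float:
    """Gaussian log-likelihood of standardized ratings under the predicted trace."""
    ratings = np.asarray(ratings, dtype=float)
    trace = integrate_affect(params, dv, spec)
    if ratings.shape != trace.predicted.shape:
        raise ValueError("ratings and decision-variable sequence must align")
    resid = ratings - trace.predicted
    n = ratings.size
    return float(
        -0.5 * n * _LOG_2PI - n * np.log(params.sigma) - 0.5 * np.sum(resid**2) / params.sigma**2
    )


def build_affect_variant(spec: AffectModelSpec) -> dict:
    """Metadata for a model variant: predictor list and free-parameter names.

    Used by the inference module to assemble the hierarchical model for any of
    the tested variants; the default spec reproduces the full model (five
    weights plus gamma and the noise scale).
    """
    preds = spec.predictors()
    params = ["w0"] + [_WEIGHT_OF[p] for p in preds] + ["gamma", "sigma"]
    return {"spec": spec, "predictors": preds, "parameters": params}
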