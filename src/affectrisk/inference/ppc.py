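"""Posterior-predictive checks for the affect model.

Simulates full-cohort rating trajectories from posterior draws, standardizes
them the way the observed ratings are, and summarizes the cross-participant
average per trial: the envelope of the simulations, their median, and the
observed trajectory for overlay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AffectData
from .models import HierarchicalModel
from .sampler import PosteriorDraws

__all__ = ["PPCResult", "posterior_predictive", "prior_predictive", "plot_ppc"]


@dataclass
class PPCResult:
    observed_mean: np.ndarray  # (T,)
    median: np.ndarray  # (T,)
    band_low: np.ndarray  # (T,) envelope of simulated averages
    band_high: np.ndarray
    sims: np.ndarray  # (n_sims, T)

    @property
    def coverage(self) -> float:
        """Fraction of trials where the observed average falls inside the envelope."""
        inside = (self.observed_mean >= self.band_low) & (self.observed_mean <= self.band_high)
        return float(inside.mean())


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=1, keepdims=True)) / sd


def posterior_predictive(
    draws: PosteriorDraws,
    model: HierarchicalModel,
    data: AffectData,
    rng: np.random.Generator,
    n_sims: int = 500,
) -> PPCResult:
    """Simulate ``n_sims`` cohort trajectories from the fitted affect model."""
    if draws.individual is None:
        raise ValueError("posterior predictive needs stored individual draws")
    c, d, n, k = draws.individual.shape
    t = data.n_trials
    idx_c = rng.integers(0, c, size=n_sims)
    idx_d = rng.integers(0, d, size=n_sims)

    predictors = model.meta["predictors"]
    sims = np.empty((n_sims, t))
    names = draws.param_names
    for s in range(n_sims):
        nat = {name: draws.individual[idx_c[s], idx_d[s], :, j] for j, name in enumerate(names)}
        ae = np.repeat(nat["w0"][:, None], t, axis=1)
        for pred in predictors:
            w = nat[{"ev": "w_ev", "outcome": "w_ev", "u_trans": "w_u", "pe": "w_pe", "abs_pe": "w_abs_pe"}[pred]]
            series = data.predictors[pred]
            acc = np.zeros(n)
            trace = np.empty((n, t))
            for j in range(t):
                acc = nat["gamma"] * acc + series[:, j]
                trace[:, j] = acc
            ae += w[:, None] * trace
        ratings = ae + rng.normal(0.0, nat["sigma"][:, None], size=(n, t))
        sims[s] = _standardize_rows(ratings).mean(axis=0)

    return PPCResult(
        observed_mean=data.ratings.mean(axis=0),
        median=np.median(sims, axis=0),
        band_low=sims.min(axis=0),
        band_high=sims.max(axis=0),
        sims=sims,
    )


def prior_predictive(model: HierarchicalModel, rng: np.random.Generator, n: int = 1000) -> dict:
    """Natural-scale individual parameters drawn from the hierarchical prior.

    Used to verify that the prior respects every parameter bound (gamma in
    [0,1], c in [0,20], positive scales) before any data enter.
    """
    k = model.n_params
    mu = rng.normal(0.0, 1.0, size=k)
    tau = np.abs(rng.normal(0.0, 1.0, size=k))
    theta = mu + tau * rng.normal(size=(n, k))
    return model.natural(theta)


def plot_ppc(result: PPCResult, ax=None, label: str = "affect"):
    """Trial-average observed trajectory against the simulated envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = np.arange(1, result.observed_mean.size + 1)
    ax.fill_between(t, result.band_low, result.band_high, color="0.8", label="simulations")
    ax.plot(t, result.median, color="k", lw=1.5, label="median prediction")
    ax.plot(t, result.observed_mean, color="crimson", lw=1.5, label="observed")
    ax.set_xlabel("trial")
    ax.set_ylabel(f"mean {label} (z)")
    ax.legend(frameon=False, fontsize=8)
    return ax
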