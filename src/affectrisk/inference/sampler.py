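"""Blocked MCMC for the hierarchical models.

Every individual-level parameter theta_{i,k} is sampled on an unconstrained
scale with a normal population distribution theta_{i,k} ~ N(mu_k, tau_k),
standard-normal hyperpriors on mu_k and half-normal(1) hyperpriors on tau_k.

One sweep combines four moves:

1. component-wise adaptive random-walk Metropolis on theta, vectorized across
   participants (each participant's likelihood is independent given the
   hyperparameters, so all N proposals for one component are evaluated in a
   single likelihood call and accepted independently);
2. a conjugate Gibbs draw for each group mean mu_k;
3. univariate slice sampling for each group scale tau_k (on log tau);
4. an interweaved non-centered update: with z = (theta - mu) / tau held
   fixed, (mu_k, log tau_k) take a joint Metropolis step through the data
   likelihood.  This is the ancillarity–sufficiency interweaving strategy;
   the non-centered half is what lets the hyperparameters mix when the
   individual-level data are weak.

Proposal scales adapt during warmup only (diminishing Robbins–Monro updates),
so the post-warmup chain is a valid fixed-kernel Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import links
from .models import HierarchicalModel

__all__ = ["SamplerConfig", "PosteriorDraws", "fit_hierarchical"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.  The default profile mirrors the study (8 chains x 3000
    iterations, 1000 warmup = 16,000 retained draws); :meth:`fast` is the
    desk/test profile."""

    chains: int = 8
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.35
    init_scale: float = 0.3
    store_individual: bool = True
    store_pointwise: bool = True

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(chains=4, iterations=1000, warmup=500, seed=seed, **kw)

    def with_seed(self, seed: int) -> "SamplerConfig":
        return replace(self, seed=seed)


@dataclass
class PosteriorDraws:
    """Labelled posterior draws: (chains, draws, ...) arrays.

    ``mu`` and ``tau`` are the group mean/scale on the unconstrained scale;
    ``individual`` holds natural-scale individual parameters; ``pointwise``
    is the log-likelihood at the model's WAIC grain (participant level for
    choice models, trial level for affect models).
    """

    param_names: list[str]
    param_links: list[str]
    mu: np.ndarray  # (C, D, K)
    tau: np.ndarray  # (C, D, K)
    individual: np.ndarray | None  # (C, D, N, K) natural scale
    pointwise: np.ndarray | None  # (C, D, M)
    model_name: str
    config: SamplerConfig
    participants: np.ndarray | None = None
    divergences: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def _k(self, name: str) -> int:
        return self.param_names.index(name)

    def group_location(self, name: str) -> np.ndarray:
        """Group-level location on the natural scale, link(mu_k); (C, D)."""
        k = self._k(name)
        return links.forward(self.mu[:, :, k], self.param_links[k])

    def hyper(self, name: str, which: str = "mu") -> np.ndarray:
        k = self._k(name)
        return (self.mu if which == "mu" else self.tau)[:, :, k]

    def individual_means(self, name: str) -> np.ndarray:
        """Posterior-mean natural-scale parameter per participant; (N,)."""
        if self.individual is None:
            raise ValueError("individual draws were not stored")
        return self.individual[:, :, :, self._k(name)].mean(axis=(0, 1))

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled for one group-location parameter; (C*D,)."""
        return self.group_location(name).reshape(-1)


def _slice_sample_log_tau(resid_ss: float, n: int, tau: float, rng) -> float:
    """Slice sample tau (group scale) on eta = log tau.

    Target: product of N(theta | mu, tau), half-normal(1) prior on tau, and
    the log-transform Jacobian.
    """

    def logf(eta: float) -> float:
        if eta < -9.0 or eta > 6.0:
            return -np.inf
        t2 = np.exp(2.0 * eta)
        return -n * eta - 0.5 * resid_ss / t2 - 0.5 * t2 + eta

    eta0 = np.log(tau)
    logy = logf(eta0) + np.log(rng.random())
    w, m = 1.0, 50
    lo = eta0 - w * rng.random()
    hi = lo + w
    j = int(np.floor(m * rng.random()))
    k = m - 1 - j
    while j > 0 and logf(lo) > logy:
        lo -= w
        j -= 1
    while k > 0 and logf(hi) > logy:
        hi += w
        k -= 1
    for _ in range(100):
        eta1 = lo + (hi - lo) * rng.random()
        if logf(eta1) > logy:
            return float(np.exp(eta1))
        if eta1 < eta0:
            lo = eta1
        else:
            hi = eta1
    return tau  # pathological shrinkage; keep current value


def _run_chain(model: HierarchicalModel, data, cfg: SamplerConfig, rng: np.random.Generator):
    n = data.n_participants
    k_par = model.n_params
    n_keep = cfg.iterations - cfg.warmup

    mu = rng.normal(0.0, 0.1, size=k_par)
    tau = np.full(k_par, 0.5)
    theta = mu + tau * 0.3 * rng.normal(size=(n, k_par))
    ll = model.participant_loglik(model.natural(theta), data)

    scale_ind = np.full((n, k_par), cfg.init_scale)
    scale_hyp = np.full(k_par, 0.2)

    mu_out = np.empty((n_keep, k_par))
    tau_out = np.empty((n_keep, k_par))
    ind_out = np.empty((n_keep, n, k_par)) if cfg.store_individual else None
    pw_out = None

    for it in range(cfg.iterations):
        adapting = it < cfg.warmup
        kappa = min(0.6, 3.0 / np.sqrt(it + 5.0)) if adapting else 0.0

        # -- individual parameters, one component at a time, all participants at once
        for k in range(k_par):
            prop = theta.copy()
            prop[:, k] = theta[:, k] + scale_ind[:, k] * rng.normal(size=n)
            ll_new = model.participant_loglik(model.natural(prop), data)
            d_prior = -0.5 * ((prop[:, k] - mu[k]) ** 2 - (theta[:, k] - mu[k]) ** 2) / tau[k] ** 2
            acc = np.log(rng.random(n)) < (ll_new - ll + d_prior)
            theta[acc, k] = prop[acc, k]
            ll[acc] = ll_new[acc]
            if adapting:
                scale_ind[:, k] = np.clip(
                    scale_ind[:, k] * np.exp(kappa * (acc.astype(float) - cfg.target_accept)),
                    1e-3,
                    10.0,
                )

        # -- conjugate group means (prior N(0, 1))
        for k in range(k_par):
            var = 1.0 / (n / tau[k] ** 2 + 1.0)
            mean = var * theta[:, k].sum() / tau[k] ** 2
            mu[k] = rng.normal(mean, np.sqrt(var))

        # -- group scales by slice sampling (prior half-normal(1))
        for k in range(k_par):
            ss = float(((theta[:, k] - mu[k]) ** 2).sum())
            tau[k] = _slice_sample_log_tau(ss, n, tau[k], rng)

        # -- interweaved non-centered hyperparameter move
        z = (theta - mu) / tau
        ll_sum = ll.sum()
        for k in range(k_par):
            mu_p = mu[k] + scale_hyp[k] * rng.normal()
            eta = np.log(tau[k])
            eta_p = eta + scale_hyp[k] * rng.normal()
            tau_p = np.exp(eta_p)
            prop = theta.copy()
            prop[:, k] = mu_p + tau_p * z[:, k]
            ll_new = model.participant_loglik(model.natural(prop), data)
            logr = (
                ll_new.sum()
                - ll_sum
                - 0.5 * (mu_p**2 - mu[k] ** 2)
                - 0.5 * (tau_p**2 - tau[k] ** 2)
                + (eta_p - eta)
            )
            accepted = np.log(rng.random()) < logr
            if accepted:
                mu[k], tau[k] = mu_p, tau_p
                theta[:, k] = prop[:, k]
                ll = ll_new
                ll_sum = ll.sum()
            if adapting:
                scale_hyp[k] = np.clip(
                    scale_hyp[k] * np.exp(kappa * (float(accepted) - 0.234)), 1e-3, 5.0
                )

        if it >= cfg.warmup:
            j = it - cfg.warmup
            mu_out[j] = mu
            tau_out[j] = tau
            nat = model.natural(theta)
            if ind_out is not None:
                for k, name in enumerate(model.param_names):
                    ind_out[j, :, k] = nat[name]
            if cfg.store_pointwise:
                pw = model.pointwise_loglik(nat, data)
                if pw_out is None:
                    pw_out = np.empty((n_keep, pw.size))
                pw_out[j] = pw

    return mu_out, tau_out, ind_out, pw_out


def fit_hierarchical(
    model: HierarchicalModel, data, config: SamplerConfig | None = None
) -> PosteriorDraws:
    """Fit a hierarchical model by MCMC; returns labelled posterior draws.

    Chains are seeded independently from ``config.seed`` and run sequentially;
    two runs with the same seed produce identical draws.
    """
    cfg = config or SamplerConfig()
    if data.n_participants < 2:
        raise ValueError("hierarchical fit needs at least 2 participants")
    mus, taus, inds, pws = [], [], [], []
    for chain in range(cfg.chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), chain]))
        mu, tau, ind, pw = _run_chain(model, data, cfg, rng)
        mus.append(mu)
        taus.append(tau)
        inds.append(ind)
        pws.append(pw)
    return PosteriorDraws(
        param_names=model.param_names,
        param_links=[p.link for p in model.params],
        mu=np.stack(mus),
        tau=np.stack(taus),
        individual=np.stack(inds) if cfg.store_individual else None,
        pointwise=np.stack(pws) if cfg.store_pointwise else None,
        model_name=model.name,
        config=cfg,
        participants=getattr(data, "participants", None),
        meta=dict(model.meta),
    )
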