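"""Convergence diagnostics, interval summaries and WAIC model comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sampler import PosteriorDraws

__all__ = ["rhat", "hdi", "waic", "WaicResult", "FitReport", "summarize", "compare_waic"]

RHAT_THRESHOLD = 1.01


def rhat(draws: np.ndarray) -> float:
    """Split-R-hat (potential scale reduction) for one parameter.

    ``draws`` has shape (chains, draws).  Each chain is split in half, and the
    classic between/within-chain variance ratio is computed on the 2C half
    chains; values near 1 indicate adequate mixing (< 1.01 by convention).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat needs a (chains, draws) array with >= 2 chains")
    c, d = draws.shape
    half = d // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws.

    Computed by scanning contiguous windows of the sorted sample; exact for
    unimodal posteriors, which is how it is used here.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for a stable HDI")
    m = int(np.floor(mass * n))
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


@dataclass(frozen=True)
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    n_points: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"WaicResult(waic={self.waic:.2f}, lppd={self.lppd:.2f}, p_waic={self.p_waic:.2f}, n={self.n_points})"


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC on the deviance scale, -2 * (lppd - p_waic); lower is better.

    ``pointwise_loglik`` has shape (draws, points) — for the choice models a
    point is one participant (trial log-likelihoods summed within participant
    before aggregation), for the affect models one trial.  ``p_waic`` is the
    variance-based effective-parameter estimate.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, points) -> pool chains
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("expected a (draws, points) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p = float(np.sum(ll.var(axis=0, ddof=1))) if s > 1 else 0.0
    return WaicResult(waic=-2.0 * (lppd - p), lppd=lppd, p_waic=p, n_points=ll.shape[1])


@dataclass
class FitReport:
    """Posterior summary: per-parameter mean, 95% HDI and split-R-hat, plus
    model WAIC and a convergence flag over the group-level parameters."""

    summary: pd.DataFrame
    waic: WaicResult | None
    converged: bool
    model_name: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w = f", waic={self.waic.waic:.1f}" if self.waic else ""
        return f"FitReport({self.model_name}, converged={self.converged}{w})\n{self.summary}"


def summarize(draws: PosteriorDraws, mass: float = 0.95) -> FitReport:
    """Build a :class:`FitReport` from posterior draws.

    Rows are the natural-scale group locations (``group_<name>``) and the
    unconstrained hyperparameters (``mu_<name>``, ``tau_<name>``); the
    convergence flag requires split-R-hat < 1.01 on every hyperparameter.
    """
    rows = []
    converged = True
    for k, name in enumerate(draws.param_names):
        for label, arr in (
            (f"group_{name}", draws.group_location(name)),
            (f"mu_{name}", draws.mu[:, :, k]),
            (f"tau_{name}", draws.tau[:, :, k]),
        ):
            r = rhat(arr) if arr.shape[0] >= 2 else np.nan
            lo, hi = hdi(arr.ravel(), mass)
            rows.append(
                {"parameter": label, "mean": float(arr.mean()), "hdi_low": lo, "hdi_high": hi, "rhat": r}
            )
            if label.startswith(("mu_", "tau_")) and np.isfinite(r) and r >= RHAT_THRESHOLD:
                converged = False
    w = waic(draws.pointwise) if draws.pointwise is not None else None
    return FitReport(
        summary=pd.DataFrame(rows).set_index("parameter"),
        waic=w,
        converged=converged,
        model_name=draws.model_name,
    )


def compare_waic(fits: dict[str, PosteriorDraws | WaicResult]) -> pd.DataFrame:
    """Rank models by WAIC (lower is better)."""
    rows = []
    for name, f in fits.items():
        w = f if isinstance(f, WaicResult) else waic(f.pointwise)
        rows.append({"model": name, "waic": w.waic, "lppd": w.lppd, "p_waic": w.p_waic})
    return pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
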