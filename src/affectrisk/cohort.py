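"""Synthetic study cohorts with the statistical structure the analysis assumes.

A cohort is simulated participant by participant: individual affect and
choice parameters are drawn from group-level distributions (normal on each
parameter's link scale), the closed choice–outcome–affect loop generates
choices and ratings, and the two exclusion rules of the study design are
applied afterwards:

* participants giving the same accept/reject response in more than 80% of
  trials, and
* participants whose affect ratings were given without moving the scale
  sliders in more than 80% of trials (observable as ratings stuck at the
  slider default position).

The default configuration emulates the recruited cohort: 108 participants of
whom one is a same-response contaminant and six are static-slider
contaminants, leaving ~101 after exclusion.  Generating values sit near the
published group posteriors and are illustrative, not ground truth; the SEK
unit weights are scaled so that generated (pre-standardization) ratings have
roughly unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .affect import AffectModelSpec, AffectParams
from .choice import AffectRegressionWeights, ChoiceParams, simulate_choices
from .gambles import GambleConfig, generate_session
from .tables import TRIAL_COLUMNS

__all__ = [
    "AffectGroupConfig",
    "ChoiceGroupConfig",
    "CohortConfig",
    "CohortData",
    "simulate_cohort",
    "standardize_ratings",
    "apply_exclusions",
]

EXCLUSION_THRESHOLD = 0.8  # strict: "more than 80% of the trials"


@dataclass(frozen=True)
class AffectGroupConfig:
    """Group-level generating distribution for one affect dimension.

    Means are on the natural scale; spreads are standard deviations on each
    parameter's link scale (identity for weights, logit for gamma, log for
    the rating-noise sigma).
    """

    w0: float = 0.0
    w_ev: float = 0.026
    w_u: float = -0.04
    w_pe: float = 0.049
    w_abs_pe: float = -0.004
    gamma: float = 0.25
    sigma: float = 0.8
    weight_sd: float = 0.008
    w0_sd: float = 0.1
    w_u_sd: float = 0.03
    gamma_logit_sd: float = 0.5
    sigma_log_sd: float = 0.2

    def draw(self, rng: np.random.Generator) -> AffectParams:
        return AffectParams(
            w0=rng.normal(self.w0, self.w0_sd),
            w_ev=rng.normal(self.w_ev, self.weight_sd),
            w_u=rng.normal(self.w_u, self.w_u_sd),
            w_pe=rng.normal(self.w_pe, self.weight_sd),
            w_abs_pe=rng.normal(self.w_abs_pe, self.weight_sd),
            gamma=float(expit(rng.normal(logit(self.gamma), self.gamma_logit_sd))),
            sigma=float(np.exp(rng.normal(np.log(self.sigma), self.sigma_log_sd))),
        )


# arousal defaults follow the published arousal column the same way the
# valence defaults follow the valence column
AROUSAL_DEFAULTS = dict(w0=-0.23, w_ev=0.021, w_u=0.06, w_pe=0.015, w_abs_pe=0.016, gamma=0.49, sigma=0.8)


@dataclass(frozen=True)
class ChoiceGroupConfig:
    """Group-level generating distribution for the choice parameters.

    ``lam``/``rho``/``c`` are natural-scale group locations (the hierarchy is
    normal on the log / scaled-logit link); betas are identity-scale.  The
    default modulation pattern is the adjusted-model finding: arousal raises
    loss aversion and consistency and lowers curvature, valence does nothing.
    """

    lam: float = 1.02
    rho: float = 0.55
    c: float = 1.8
    lam_log_sd: float = 0.3
    rho_log_sd: float = 0.25
    c_link_sd: float = 0.4
    beta_a_lam: float = 0.04
    beta_a_rho: float = -0.085
    beta_a_c: float = 0.37
    beta_v_lam: float = 0.0
    beta_v_rho: float = 0.0
    beta_v_c: float = 0.0
    beta_a_lam_sd: float = 0.03
    beta_a_rho_sd: float = 0.05
    beta_a_c_sd: float = 0.25
    beta_v_sd: float = 0.02

    def draw(self, rng: np.random.Generator) -> tuple[ChoiceParams, AffectRegressionWeights]:
        base = ChoiceParams(
            lam=float(np.exp(rng.normal(np.log(self.lam), self.lam_log_sd))),
            rho=float(np.exp(rng.normal(np.log(self.rho), self.rho_log_sd))),
            c=float(20.0 * expit(rng.normal(logit(self.c / 20.0), self.c_link_sd))),
        )
        weights = AffectRegressionWeights(
            beta_a_lam=rng.normal(self.beta_a_lam, self.beta_a_lam_sd),
            beta_a_rho=rng.normal(self.beta_a_rho, self.beta_a_rho_sd),
            beta_a_c=rng.normal(self.beta_a_c, self.beta_a_c_sd),
            beta_v_lam=rng.normal(self.beta_v_lam, self.beta_v_sd),
            beta_v_rho=rng.normal(self.beta_v_rho, self.beta_v_sd),
            beta_v_c=rng.normal(self.beta_v_c, self.beta_v_sd),
        )
        return base, weights

    def null_modulation(self) -> "ChoiceGroupConfig":
        """Same base parameters with every modulation weight pinned to zero."""
        return replace(
            self,
            beta_a_lam=0.0, beta_a_rho=0.0, beta_a_c=0.0,
            beta_v_lam=0.0, beta_v_rho=0.0, beta_v_c=0.0,
            beta_a_lam_sd=0.0, beta_a_rho_sd=0.0, beta_a_c_sd=0.0, beta_v_sd=0.0,
        )


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 108
    n_trials: int = 50
    valence: AffectGroupConfig = field(default_factory=AffectGroupConfig)
    arousal: AffectGroupConfig = field(default_factory=lambda: AffectGroupConfig(**AROUSAL_DEFAULTS))
    choice: ChoiceGroupConfig = field(default_factory=ChoiceGroupConfig)
    gambles: GambleConfig = field(default_factory=GambleConfig)
    affect_spec: AffectModelSpec = field(default_factory=AffectModelSpec)
    n_same_response: int = 1
    n_slider_static: int = 6
    slider_default: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 2:
            raise ValueError("need at least 1 participant and 2 trials")
        if self.n_same_response + self.n_slider_static > self.n_participants:
            raise ValueError("more contaminants than participants")


@dataclass
class CohortData:
    trials: pd.DataFrame  # tidy per-trial table
    truth: pd.DataFrame  # one row per participant: generating parameters + flags
    config: CohortConfig


def standardize_ratings(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Within-participant z-score (sample SD, denominator n-1).

    A constant series cannot be scaled; it maps to zeros with a
    degenerate-variance flag so callers can decide what to do.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 ratings to standardize")
    sd = raw.std(ddof=1)
    # an exactly constant series has zero range but may carry float noise in sd
    if np.ptp(raw) == 0 or sd == 0:
        return np.zeros_like(raw), True
    return (raw - raw.mean()) / sd, False


def _participant_rows(pid, sess, sim) -> list[dict]:
    rows = []
    for t, g in enumerate(sess):
        row = {"participant_id": pid, "trial": t + 1}
        row.update({f"x{i+1}": g.outcomes[i] for i in range(4)})
        row.update({f"p{i+1}": g.probabilities[i] for i in range(4)})
        row.update(
            choice=int(sim.choices[t]),
            outcome=float(sim.outcomes[t]),
            valence=float(sim.valence[t]),
            arousal=float(sim.arousal[t]),
        )
        rows.append(row)
    return rows


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortData:
    """Simulate a full study dataset plus its ground-truth parameter table."""
    cfg = config or CohortConfig()
    master = np.random.SeedSequence([cfg.seed if seed is None else int(seed), 2_020])
    rng = np.random.default_rng(master)

    n = cfg.n_participants
    kinds = ["same_response"] * cfg.n_same_response + ["slider_static"] * cfg.n_slider_static
    kinds += ["compliant"] * (n - len(kinds))

    all_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(n):
        pid = f"P{i+1:03d}"
        kind = kinds[i]
        sess = generate_session(rng, cfg.n_trials, cfg.gambles)
        val_p = cfg.valence.draw(rng)
        aro_p = cfg.arousal.draw(rng)
        base, weights = cfg.choice.draw(rng)
        if kind == "same_response":
            # a careless always-accepter: gains weighted fully, losses ignored
            base = ChoiceParams(lam=0.0, rho=1.0, c=20.0)
            weights = AffectRegressionWeights()
        sim = simulate_choices(rng, base, weights, sess, val_p, aro_p, cfg.affect_spec)
        if kind == "slider_static":
            stuck = rng.random(cfg.n_trials) < 0.95
            sim.valence[stuck] = cfg.slider_default
            sim.arousal[stuck] = cfg.slider_default
        all_rows.extend(_participant_rows(pid, sess, sim))
        row = {"participant_id": pid, "kind": kind, "lam": base.lam, "rho": base.rho, "c": base.c}
        row.update({f"choice_{k}": getattr(weights, k) for k in vars(weights)})
        for dim, p in (("valence", val_p), ("arousal", aro_p)):
            row.update({f"{dim}_{k}": getattr(p, k) for k in vars(p)})
        truth_rows.append(row)

    trials = pd.DataFrame(all_rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return CohortData(trials=trials, truth=truth, config=cfg)


def apply_exclusions(
    trials: pd.DataFrame,
    slider_default: float = 0.0,
    threshold: float = EXCLUSION_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two participant-exclusion rules; returns (kept, report).

    Both rules use a strict inequality ("more than 80% of the trials"): a
    participant at exactly the threshold is retained.
    """
    reports = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        same = max(grp["choice"].mean(), 1.0 - grp["choice"].mean())
        static = float(
            ((grp["valence"] == slider_default) & (grp["arousal"] == slider_default)).mean()
        )
        if same > threshold:
            reports.append({"participant_id": pid, "rule": "same_response", "rate": same})
        elif static > threshold:
            reports.append({"participant_id": pid, "rule": "static_slider", "rate": static})
    report = pd.DataFrame(reports, columns=["participant_id", "rule", "rate"])
    kept = trials[~trials["participant_id"].isin(report["participant_id"])].reset_index(drop=True)
    return kept, report
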