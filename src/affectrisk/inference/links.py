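"""Link functions mapping unconstrained sampler space to natural parameter space.

Individual-level parameters are sampled on an unconstrained scale where the
group hierarchy is normal; each parameter declares a link:

* ``identity`` — regression weights (affect weights, modulation betas)
* ``log``      — positive scales (lam, rho, rating noise sigma)
* ``unit``     — the forgetting factor gamma in (0, 1)
* ``unit20``   — choice consistency c in (0, 20)
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["forward", "inverse", "LINKS"]

LINKS = ("identity", "log", "unit", "unit20")


def forward(x, link: str):
    """Unconstrained -> natural."""
    x = np.asarray(x, dtype=float)
    if link == "identity":
        return x
    if link == "log":
        # capped so extreme proposals stay finite (and get rejected on merit)
        return np.exp(np.minimum(x, 50.0))
    if link == "unit":
        return expit(x)
    if link == "unit20":
        return 20.0 * expit(x)
    raise ValueError(f"unknown link {link!r}")


def inverse(y, link: str):
    """Natural -> unconstrained."""
    y = np.asarray(y, dtype=float)
    if link == "identity":
        return y
    if link == "log":
        return np.log(y)
    if link == "unit":
        return logit(y)
    if link == "unit20":
        return logit(y / 20.0)
    raise ValueError(f"unknown link {link!r}")
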