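"""Fecundity likelihood from brood surveys.

Annual fledgling totals J_t are Poisson with mean R_t * f_t, where R_t
is the number of surveyed broods whose fledging success was known and
f_t the year's fecundity per breeding pair.  Year-specific fecundities
are shrunk through a log-normal random-year effect:
log f_t ~ Normal(mu, sigma2).
"""

from __future__ import annotations

import numpy as np
from ._stats import norm_logpdf, poisson_logpmf

__all__ = ["fecundity_loglik", "fecundity_hyperprior"]


def fecundity_loglik(R, J, f) -> float:
    """Sum of log Poisson(J_t; R_t * f_t); years with R_t = 0 contribute 0."""
    R = np.asarray(R, dtype=float)
    J = np.asarray(J)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fecundity must be positive")
    mean = R * f
    ll = np.where(
        (mean == 0) & (J > 0), -np.inf, poisson_logpmf(J, np.maximum(mean, 1e-300))
    )
    ll = np.where((R == 0) & (J == 0), 0.0, ll)
    return float(ll.sum())


def fecundity_hyperprior(f, mu: float, sigma2: float) -> float:
    """Sum of log Normal(log f_t; mu, sigma2) — the random-year effect."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    logf = np.log(np.asarray(f, dtype=float))
    return float(norm_logpdf(logf, mu, np.sqrt(sigma2)).sum())
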