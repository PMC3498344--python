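"""Likelihood for unmarked birds recovered dead.

Each year the population of size Ntot splits into three fates — died by
poison, died by another cause, survived — with probabilities
((1-phi)*mbar, (1-phi)*(1-mbar), phi), where mbar is the arithmetic
mean of the age-specific poison fractions.  The latent yearly death
counts (xP, xO) are multinomial draws; recovered carcasses are binomial
thinnings of them with reporting rates rP (poison) and rO (other).

This stream shares phi, the m_a and the reporting rates with the
multistate model, which is what sharpens the reporting-rate posteriors
in the full integrated model.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._stats import binom_logpmf

__all__ = [
    "mean_poison_fraction",
    "death_cell_probs",
    "recovery_loglik",
    "recovery_year_loglik",
]


def mean_poison_fraction(m_juv: float, m_1y: float, m_2my: float) -> float:
    """Arithmetic mean of the age-specific poison fractions."""
    return (m_juv + m_1y + m_2my) / 3.0


def death_cell_probs(phi: float, mbar: float) -> tuple[float, float, float]:
    """(P(die by poison), P(die by other), P(survive)); sums to one."""
    return ((1.0 - phi) * mbar, (1.0 - phi) * (1.0 - mbar), phi)


def recovery_year_loglik(
    RP: int, RO: int, xP: int, xO: int, Ntot: int, phi: float, mbar: float,
    rP: float, rO: float,
) -> float:
    """Augmented log-likelihood for a single year.

    log Multinomial((xP, xO, Ntot-xP-xO); Ntot, cells)
    + log Binomial(RP; xP, rP) + log Binomial(RO; xO, rO).
    -inf outside the support (xP+xO > Ntot, RP > xP or RO > xO).
    """
    if xP < 0 or xO < 0 or xP + xO > Ntot:
        return -np.inf
    pP, pO, _ = death_cell_probs(phi, mbar)
    ll = stats.multinomial.logpmf(
        [xP, xO, Ntot - xP - xO], Ntot, [pP, pO, 1.0 - pP - pO]
    )
    ll += stats.binom.logpmf(RP, xP, rP)
    ll += stats.binom.logpmf(RO, xO, rO)
    return float(ll)


def recovery_loglik(RP, RO, xP, xO, Ntot, phi, mbar, rP, rO) -> float:
    """Augmented log-likelihood summed over years (vectorized)."""
    RP, RO, xP, xO, Ntot = (np.asarray(a) for a in (RP, RO, xP, xO, Ntot))
    if np.any(xP < 0) or np.any(xO < 0) or np.any(xP + xO > Ntot):
        return -np.inf
    pP, pO, _ = death_cell_probs(phi, mbar)
    # multinomial factored as sequential binomials to vectorize over years
    ll = (
        binom_logpmf(xP, Ntot, pP)
        + binom_logpmf(xO, Ntot - xP, pO / (1.0 - pP))
        + binom_logpmf(RP, xP, rP)
        + binom_logpmf(RO, xO, rO)
    )
    return float(ll.sum())
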