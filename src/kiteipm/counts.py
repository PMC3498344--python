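"""State-space model for breeding-pair counts.

The true female population is split into 1-year-olds (N1), 2-year-olds
(N2) and older birds (N3).  Dynamics follow the female-based
pre-breeding projection structure with demographic stochasticity:
recruitment of 1-year-olds is Poisson with mean phi*(f_t/2)*B_t,
ageing/survival are binomial thinnings, and the observed count of
breeding pairs is Poisson around the expected number of breeding
females B_t = beta2*N2 + gamma*N3.

Fecundity f_t is the full brood per pair; it is halved here because the
model tracks females only (even fledgling sex ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from ._stats import binom_logpmf, poisson_logpmf

__all__ = ["SsmParams", "breeders", "state_loglik", "count_loglik", "simulate_trajectory"]

DEFAULT_BETA2 = 0.1


@dataclass(frozen=True)
class SsmParams:
    """Demographic parameters of the count state-space model.

    phi : annual survival (shared with the multistate model).
    gamma : proportion of 3+ females that breed (latent, in [0.5, 1]).
    beta2 : breeding propensity of 2-year-olds, a fixed field constant.
    """

    phi: float
    gamma: float
    beta2: float = DEFAULT_BETA2

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi outside [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma outside [0, 1]")
        if not 0.0 <= self.beta2 <= 1.0:
            raise ValueError("beta2 outside [0, 1]")


def breeders(N: np.ndarray, params: SsmParams) -> np.ndarray:
    """Expected breeding females B_t = beta2*N2 + gamma*N3.

    ``N`` is (..., 3) with columns (N1, N2, N3); returns the matching
    leading shape.
    """
    N = np.asarray(N, dtype=float)
    return params.beta2 * N[..., 1] + params.gamma * N[..., 2]


def state_loglik(traj: np.ndarray, f: np.ndarray, params: SsmParams) -> float:
    """Log-density of a latent trajectory under the stochastic dynamics.

    traj : integer array (T, 3); f : fecundity per pair, length >= T-1.
    Transitions t -> t+1 use f[t].  Returns -inf off the binomial
    support (more survivors than candidates).
    """
    traj = np.asarray(traj)
    f = np.asarray(f, dtype=float)
    T = traj.shape[0]
    if T < 2:
        return 0.0
    B = breeders(traj[:-1], params)
    mean1 = params.phi * (f[: T - 1] / 2.0) * B
    ll = poisson_logpmf(traj[1:, 0], mean1).sum()
    ll += binom_logpmf(traj[1:, 1], traj[:-1, 0], params.phi).sum()
    ll += binom_logpmf(traj[1:, 2], traj[:-1, 1] + traj[:-1, 2], params.phi).sum()
    return float(ll)


def count_loglik(y: np.ndarray, traj: np.ndarray, params: SsmParams) -> float:
    """Poisson observation log-likelihood of breeding-pair counts."""
    B = breeders(np.asarray(traj), params)
    return float(poisson_logpmf(np.asarray(y), B).sum())


def simulate_trajectory(
    N0: np.ndarray, f: np.ndarray, params: SsmParams, rng: np.random.Generator
) -> np.ndarray:
    """Simulate (T, 3) latent states forward from N0; f has length T-1."""
    f = np.asarray(f, dtype=float)
    T = len(f) + 1
    traj = np.zeros((T, 3), dtype=np.int64)
    traj[0] = np.asarray(N0, dtype=np.int64)
    for t in range(T - 1):
        B = breeders(traj[t], params)
        traj[t + 1, 0] = rng.poisson(params.phi * (f[t] / 2.0) * B)
        traj[t + 1, 1] = rng.binomial(traj[t, 0], params.phi)
        traj[t + 1, 2] = rng.binomial(traj[t, 1] + traj[t, 2], params.phi)
    return traj
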