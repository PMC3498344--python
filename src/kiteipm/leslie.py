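"""Deterministic Leslie-matrix analysis of poison-related mortality.

The female population is projected with a pre-breeding, three-age-class
matrix.  Realized survival in age class a is phi_a = phi*_a * (1 - D_a),
where phi*_a is survival in the absence of poisoning and D_a the
proportional reduction caused by it (additive-mortality assumption).
Fertility terms carry first-year survival because the census is
pre-breeding: 2-year-olds breed with propensity beta2, older females
with probability gamma, each fledging f/2 daughters.

    A = [[0,        beta2*(f/2)*phi_juv,  gamma*(f/2)*phi_juv],
         [phi_1y,   0,                    0                  ],
         [0,        phi_2my,              phi_2my            ]]

The module provides the dominant eigenvalue (asymptotic growth rate),
matrix-element and lower-level vital-rate sensitivities/elasticities,
break-even poisoning levels at which growth crosses 1, and the grid
surfaces relating growth, fecundity and poisoning pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "VitalRates",
    "VITAL_RATE_NAMES",
    "poison_free_survival",
    "proportional_reduction",
    "build_matrix",
    "growth_rate",
    "matrix_sensitivity",
    "matrix_elasticity",
    "vital_rate_perturbation",
    "breakeven_reduction",
    "lambda_surfaces",
]

AGE_KEYS = ("juv", "1y", "2my")

#: the eight lower-level vital rates of the perturbation analysis
VITAL_RATE_NAMES = (
    "phi_star_juv", "phi_star_1y", "phi_star_2my",
    "delta_juv", "delta_1y", "delta_2my",
    "f", "gamma",
)


def poison_free_survival(phi: float, m: float) -> float:
    """Survival with poison deaths removed: phi* = phi + (1-phi)*m."""
    if not (0.0 <= phi <= 1.0 and 0.0 <= m <= 1.0):
        raise ValueError("phi and m must lie in [0, 1]")
    return phi + (1.0 - phi) * m


def proportional_reduction(phi: float, phi_star: float) -> float:
    """Proportional survival loss to poisoning: D = 1 - phi/phi*."""
    if phi_star == 0.0:
        raise ValueError("phi_star must be positive")
    return 1.0 - phi / phi_star


@dataclass(frozen=True)
class VitalRates:
    """Lower-level parameterization of the projection matrix.

    Survivals are factored as phi_a = phi_star_a * (1 - delta_a) so that
    poisoning pressure (delta) can be perturbed independently of the
    baseline (poison-free) survival.
    """

    phi_star_juv: float
    phi_star_1y: float
    phi_star_2my: float
    delta_juv: float = 0.0
    delta_1y: float = 0.0
    delta_2my: float = 0.0
    f: float = 1.825
    gamma: float = 0.631
    beta2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("phi_star_juv", "phi_star_1y", "phi_star_2my",
                     "delta_juv", "delta_1y", "delta_2my", "gamma", "beta2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f < 0:
            raise ValueError("f must be non-negative")

    @classmethod
    def from_estimates(
        cls, phi: float, m_juv: float, m_1y: float, m_2my: float,
        f: float, gamma: float, beta2: float = 0.1,
    ) -> "VitalRates":
        """Back-transform shared survival + poison fractions into the
        (poison-free survival, proportional reduction) parameterization."""
        stars = [poison_free_survival(phi, m) for m in (m_juv, m_1y, m_2my)]
        deltas = [proportional_reduction(phi, s) for s in stars]
        return cls(*stars, *deltas, f=f, gamma=gamma, beta2=beta2)

    def survival(self, age: str) -> float:
        """Realized survival phi_a = phi*_a * (1 - delta_a)."""
        i = AGE_KEYS.index(age)
        star = (self.phi_star_juv, self.phi_star_1y, self.phi_star_2my)[i]
        delta = (self.delta_juv, self.delta_1y, self.delta_2my)[i]
        return star * (1.0 - delta)


def build_matrix(v: VitalRates, *, beta2_on_first_class: bool = False) -> np.ndarray:
    """3x3 pre-breeding female projection matrix.

    The canonical structure puts the early-breeding term beta2 on the
    2-year-old class; ``beta2_on_first_class`` moves it to the 1-yr
    column (the alternative reading of "bred in their second year of
    life"), which does not reproduce the published growth rate and is
    provided for comparison only.
    """
    s_juv = v.survival("juv")
    s_1y = v.survival("1y")
    s_2my = v.survival("2my")
    half_f = v.f / 2.0
    early = v.beta2 * half_f * s_juv
    first_row = (
        [early, 0.0, v.gamma * half_f * s_juv]
        if beta2_on_first_class
        else [0.0, early, v.gamma * half_f * s_juv]
    )
    return np.array(
        [
            first_row,
            [s_1y, 0.0, 0.0],
            [0.0, s_2my, s_2my],
        ]
    )


def growth_rate(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant eigenvalue with stable age structure and reproductive values.

    Returns (lambda, w, v): w the right eigenvector normalized to sum 1,
    v the left eigenvector scaled so <v, w> = 1.
    """
    A = np.asarray(A, dtype=float)
    vals, right = np.linalg.eig(A)
    k = int(np.argmax(vals.real))
    if abs(vals[k].imag) > 1e-9:
        raise ValueError("dominant eigenvalue is not real; matrix not primitive?")
    lam = float(vals[k].real)
    w = np.abs(right[:, k].real)
    if w.sum() == 0:
        raise ValueError("degenerate dominant eigenvector")
    w = w / w.sum()
    lvals, left = np.linalg.eig(A.T)
    kl = int(np.argmin(np.abs(lvals - vals[k])))
    vv = np.abs(left[:, kl].real)
    scale_vw = float(vv @ w)
    if scale_vw == 0.0:
        raise ValueError("reducible or defective matrix: <v, w> = 0")
    vv = vv / scale_vw
    return lam, w, vv


def _dominant_eigenvalue(A: np.ndarray) -> float:
    """Largest real eigenvalue only; tolerant of reducible grid corners."""
    return float(np.max(np.linalg.eigvals(A).real))


def matrix_sensitivity(A: np.ndarray) -> np.ndarray:
    """Sensitivities s_ij = v_i w_j / <v, w> of lambda to matrix cells."""
    _, w, v = growth_rate(A)
    return np.outer(v, w)


def matrix_elasticity(A: np.ndarray) -> np.ndarray:
    """Elasticities e_ij = (a_ij / lambda) * s_ij; they sum to one."""
    lam, w, v = growth_rate(A)
    return np.asarray(A) * np.outer(v, w) / lam


def _matrix_partials(v: VitalRates, name: str) -> np.ndarray:
    """Exact dA/dtheta for each lower-level vital rate."""
    half_f = v.f / 2.0
    s_juv = v.survival("juv")
    dA = np.zeros((3, 3))
    if name == "phi_star_juv":
        dA[0, 1] = v.beta2 * half_f * (1.0 - v.delta_juv)
        dA[0, 2] = v.gamma * half_f * (1.0 - v.delta_juv)
    elif name == "delta_juv":
        dA[0, 1] = -v.beta2 * half_f * v.phi_star_juv
        dA[0, 2] = -v.gamma * half_f * v.phi_star_juv
    elif name == "phi_star_1y":
        dA[1, 0] = 1.0 - v.delta_1y
    elif name == "delta_1y":
        dA[1, 0] = -v.phi_star_1y
    elif name == "phi_star_2my":
        dA[2, 1] = dA[2, 2] = 1.0 - v.delta_2my
    elif name == "delta_2my":
        dA[2, 1] = dA[2, 2] = -v.phi_star_2my
    elif name == "f":
        dA[0, 1] = v.beta2 * s_juv / 2.0
        dA[0, 2] = v.gamma * s_juv / 2.0
    elif name == "gamma":
        dA[0, 2] = half_f * s_juv
    elif name == "beta2":
        dA[0, 1] = half_f * s_juv
    else:
        raise ValueError(f"unknown vital rate {name!r}")
    return dA


def vital_rate_perturbation(v: VitalRates, name: str) -> tuple[float, float]:
    """(sensitivity, elasticity) of lambda to one lower-level vital rate.

    Chain rule through the matrix cells: dlambda/dtheta = sum_ij s_ij *
    da_ij/dtheta.  Both are reported as absolute values (the magnitude
    of the response is what matters; lower-level derivatives can be
    negative, e.g. for the delta terms).
    """
    A = build_matrix(v)
    lam, w, vv = growth_rate(A)
    S = np.outer(vv, w)
    dlam = float((S * _matrix_partials(v, name)).sum())
    theta = getattr(v, name)
    return abs(dlam), abs(theta / lam * dlam)


def breakeven_reduction(v: VitalRates, age: str, tol: float = 1e-8) -> float:
    """Proportional reduction delta_a at which lambda = 1.

    Other classes keep their input reductions.  Raises if lambda never
    crosses 1 on delta in [0, 1] (reduction unattainable).
    """
    field = {"juv": "delta_juv", "1y": "delta_1y", "2my": "delta_2my"}[age]

    def g(d: float) -> float:
        return _dominant_eigenvalue(build_matrix(replace(v, **{field: d}))) - 1.0

    if g(0.0) * g(1.0) > 0:
        raise ValueError(f"lambda does not cross 1 on delta_{age} in [0, 1]")
    return float(brentq(g, 0.0, 1.0, xtol=tol))


def lambda_surfaces(
    v: VitalRates,
    delta_grid: np.ndarray | None = None,
    f_grid: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Growth-rate surfaces for the perturbation figures.

    Returns a dict with:

    ``curves``
        (3, len(delta_grid)) lambda vs delta_a, one age class at a time
        (others at their current values).
    ``contours``
        (3, len(delta_grid), len(f_grid)) lambda over (delta_a, f) per
        age class; the lambda = 1 level set is the break-even locus.
    ``surface``
        (len(delta_grid), len(f_grid)) lambda with a common delta
        applied to all three classes.
    """
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 1.0, 101)
    if f_grid is None:
        f_grid = np.linspace(0.0, 2.5, 51)
    delta_grid = np.asarray(delta_grid, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if delta_grid.size == 0 or f_grid.size == 0:
        raise ValueError("empty grid")
    fields = ("delta_juv", "delta_1y", "delta_2my")

    def lam_of(vr: VitalRates) -> float:
        return _dominant_eigenvalue(build_matrix(vr))

    curves = np.array(
        [[lam_of(replace(v, **{fld: d})) for d in delta_grid] for fld in fields]
    )
    contours = np.array(
        [
            [
                [lam_of(replace(v, **{fld: d}, f=f)) for f in f_grid]
                for d in delta_grid
            ]
            for fld in fields
        ]
    )
    surface = np.array(
        [
            [
                lam_of(replace(v, delta_juv=d, delta_1y=d, delta_2my=d, f=f))
                for f in f_grid
            ]
            for d in delta_grid
        ]
    )
    return {
        "delta_grid": delta_grid,
        "f_grid": f_grid,
        "curves": curves,
        "contours": contours,
        "surface": surface,
    }
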