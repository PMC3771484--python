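"""Seeded synthetic scenarios: parameter sets and initial profiles.

The model has no measured parameter values — its claims are structural — so
every test and demonstration runs on synthetic scenarios drawn from the
admissible parameter region.  Generation is dimensionless-first (the
constraints are simplest there): theta and gamma log-uniform on [1/4, 4],
eta uniform on [0, 0.8], lam uniform on (eta, 1) for zone-forming draws
(else on (0, 2), so no-zone regimes are represented), and the domain length
Lambda placed a uniform [0.5, 2.5] beyond x* for zone-forming draws so the
length condition holds by construction.  Dimensional parameter sets are
produced by inverting the nondimensionalization with seeded positive
scales.  One integer seed drives a single counter-based generator, so
identical seeds give bit-identical scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    DimensionalParams,
    DimensionlessParams,
    GridFunction,
    check_zone_conditions,
    uniform_grid,
)
from .stationary import stationary_profile

__all__ = [
    "FAMILIES",
    "Scenario",
    "sample_dimensionless",
    "sample_dimensional",
    "make_initial",
    "make_scenario",
]

FAMILIES = (
    "equal-constant",
    "equal-gaussian",
    "equal-ramp",
    "distinct-constants",
    "perturbed-stationary",
)


@dataclass(frozen=True)
class Scenario:
    """A fully specified synthetic experiment: parameters, initial profiles,
    and the seed/family that reproduce it."""

    params: DimensionlessParams
    v10: GridFunction
    v20: GridFunction
    seed: int
    family: str
    zone_forming: bool
    dimensional: DimensionalParams | None = None


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def sample_dimensionless(seed: int, zone_forming: bool = True) -> DimensionlessParams:
    """Draw a dimensionless parameter set; zone-forming draws satisfy the
    full zone predicate by construction."""
    rng = np.random.default_rng(seed)
    theta = _loguniform(rng, 0.25, 4.0)
    gamma = _loguniform(rng, 0.25, 4.0)
    eta = float(rng.uniform(0.0, 0.8))
    if zone_forming:
        lam = float(rng.uniform(eta, 1.0))
        x_star = math.log((1.0 - eta) / (lam - eta))
        Lambda = x_star + float(rng.uniform(0.5, 2.5))
    else:
        lam = float(rng.uniform(0.0, 2.0))
        if lam == 0.0:  # lam must be strictly positive
            lam = 1e-6
        Lambda = float(rng.uniform(1.0, 4.0))
    return DimensionlessParams(theta=theta, gamma=gamma, lam=lam, eta=eta, Lambda=Lambda)


def sample_dimensional(seed: int) -> DimensionalParams:
    """Draw a dimensional parameter set satisfying viability and the strict
    zone-ordering inequalities (A > 0, B > 0, nu1 c2 > nu2 c1).

    A zone-forming dimensionless draw is inverted through the
    nondimensionalization with seeded positive scales: given (theta, gamma,
    lam, eta, Lambda) and free choices of K1, sigma, nu1, k1, f, c0 and
    c1 in (0, K1 sigma), the remaining constants follow as K2 = gamma K1,
    k2 = theta k1, nu2 = eta gamma nu1, mu_i = K_i sigma - c_i with
    c2 = lam gamma c1, and L = Lambda f K1/(nu1 k1).
    """
    q = sample_dimensionless(seed, zone_forming=True)
    rng = np.random.default_rng((int(seed), 0x5CA1E))
    K1 = _loguniform(rng, 0.25, 4.0)
    sigma = _loguniform(rng, 0.5, 4.0)
    nu1 = _loguniform(rng, 0.25, 4.0)
    k1 = _loguniform(rng, 0.25, 4.0)
    f = _loguniform(rng, 0.5, 2.0)
    c0 = _loguniform(rng, 0.5, 2.0)
    c1 = float(rng.uniform(0.1, 0.9)) * K1 * sigma
    K2 = q.gamma * K1
    k2 = q.theta * k1
    nu2 = q.eta * q.gamma * nu1
    c2 = q.lam * q.gamma * c1
    mu1 = K1 * sigma - c1
    mu2 = K2 * sigma - c2
    L = q.Lambda * f * K1 / (nu1 * k1)
    return DimensionalParams(
        K1=K1, K2=K2, sigma=sigma, mu1=mu1, mu2=mu2, nu1=nu1, nu2=nu2,
        k1=k1, k2=k2, f=f, c0=c0, L=L,
    )


def make_initial(
    family: str,
    params: DimensionlessParams,
    grid: np.ndarray | int,
    seed: int,
    amplitude: float = 0.01,
) -> tuple[GridFunction, GridFunction]:
    """Build a seeded pair of initial profiles on [0, Lambda].

    Families: ``equal-constant`` / ``equal-gaussian`` / ``equal-ramp``
    return identical pairs (the equal-initial-profile assumption of the
    low-order closed forms); ``distinct-constants`` returns two different
    constants; ``perturbed-stationary`` returns the stationary zone profile
    plus a smooth nonnegative perturbation of the given amplitude (default
    0.01) on both species.  All profiles are nonnegative and bounded by 1.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown initial-profile family {family!r}; choose from {FAMILIES}")
    x = uniform_grid(0.0, params.Lambda, grid) if isinstance(grid, (int, np.integer)) else np.asarray(grid, dtype=float)
    rng = np.random.default_rng((int(seed), FAMILIES.index(family)))
    if family == "equal-constant":
        level = float(rng.uniform(0.05, 0.3))
        v = GridFunction(x, np.full_like(x, level))
        return v, v
    if family == "equal-gaussian":
        peak = float(rng.uniform(0.1, 0.5))
        center = float(rng.uniform(0.25, 0.75)) * params.Lambda
        width = float(rng.uniform(0.05, 0.15)) * params.Lambda
        v = GridFunction(x, peak * np.exp(-0.5 * ((x - center) / width) ** 2))
        return v, v
    if family == "equal-ramp":
        level = float(rng.uniform(0.05, 0.3))
        v = GridFunction(x, level * x / params.Lambda)
        return v, v
    if family == "distinct-constants":
        a = float(rng.uniform(0.05, 0.3))
        b = float(rng.uniform(0.05, 0.3))
        if a == b:
            b = b * 1.5 + 0.01
        return GridFunction(x, np.full_like(x, a)), GridFunction(x, np.full_like(x, b))
    # perturbed-stationary
    zones = stationary_profile(params, x)
    bump = amplitude * np.sin(math.pi * x / params.Lambda) ** 2
    return (
        zones.profile.species1.with_values(zones.profile.species1.values + bump),
        zones.profile.species2.with_values(zones.profile.species2.values + bump),
    )


def make_scenario(
    seed: int,
    family: str = "equal-constant",
    zone_forming: bool = True,
    n_points: int = 401,
) -> Scenario:
    """Draw parameters and matching initial profiles in one call."""
    q = sample_dimensionless(seed, zone_forming=zone_forming)
    if family == "perturbed-stationary" and not check_zone_conditions(q).zone_forming:
        raise ValueError("perturbed-stationary initial profiles need zone-forming parameters")
    v10, v20 = make_initial(family, q, n_points, seed)
    return Scenario(
        params=q, v10=v10, v20=v20, seed=seed, family=family, zone_forming=zone_forming
    )
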