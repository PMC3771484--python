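"""Stationary (long-time) zone solutions of the zonation model.

As t -> infinity the competitive-exclusion mechanism splits the capillary at
a boundary x*: upstream only the first cell type survives, downstream only
the second.  In dimensionless variables the stationary state is

    v1 = exp(-x),                                  0 <= x < x*,
    v2 = ((lam - eta)/(1 - eta)) exp(-eta theta (x - x*)),   x* < x <= Lambda,

with the complementary species zero in each zone, and

    x* = ln((1 - eta)/(lam - eta)).

Each zone profile solves a linear Volterra integral equation of the second
kind; the Adomian decomposition of those equations generates the exponential
term by term, term n proportional to x^n/n! (first zone) or (x - x*)^n/n!
(second zone) with alternating signs.  This module computes x* in both
frames, assembles the piecewise profile, and builds the two stationary
Adomian series either by the package's trapezoid quadrature (the main path)
or from the closed-form term formulas (used as an independent check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .model_core import (
    DensityPair,
    DimensionalParams,
    DimensionlessParams,
    GridFunction,
    check_zone_conditions,
    derive_constants,
    uniform_grid,
    _as_grid,
)

__all__ = [
    "StationaryZones",
    "StationarySeries",
    "DimensionalBoundary",
    "x_star_dimensionless",
    "x_star_dimensional",
    "stationary_profile",
    "stationary_profile_dimensional",
    "adm_stationary_first",
    "adm_stationary_second",
]


@dataclass(frozen=True)
class StationaryZones:
    """The piecewise stationary state: boundary, downstream plateau and the
    assembled two-species profile.

    ``amplitude2`` is the value of the second species just downstream of the
    boundary; in the dimensionless frame it equals (lam-eta)/(1-eta), which
    coincides with exp(-x*) — the total density is continuous across x*
    even though each species jumps.
    """

    x_star: float
    amplitude2: float
    profile: DensityPair
    frame: str = "dimensionless"


@dataclass(frozen=True)
class DimensionalBoundary:
    """Zone boundary in physical units, with the domain check against L."""

    x_star: float
    within_domain: bool


@dataclass(frozen=True)
class StationarySeries:
    """Adomian series for one stationary zone profile.

    ``terms[n]`` is the n-th series term tabulated on the zone's grid;
    ``closed_form`` is the exponential the series sums to.  ``method``
    records whether terms were generated by cumulative trapezoid quadrature
    (the main path) or from the analytic x^n/n! formulas (check path).
    """

    terms: list[GridFunction]
    closed_form: GridFunction
    n_terms: int
    method: str

    def partial_sum(self, k: int | None = None) -> GridFunction:
        k = self.n_terms if k is None else k
        if not 1 <= k <= self.n_terms:
            raise ValueError("partial sum order out of range")
        out = self.terms[0]
        for term in self.terms[1:k]:
            out = out + term
        return out


def x_star_dimensionless(q: DimensionlessParams) -> float:
    """Zone boundary x* = ln((1-eta)/(lam-eta)) in dimensionless units.

    Defined (and positive) exactly when eta < lam < 1.
    """
    if not q.eta < q.lam:
        raise ValueError("no interior zone boundary: eta < lam fails")
    if not q.lam < 1.0:
        raise ValueError("no interior zone boundary: lam < 1 fails")
    return math.log((1.0 - q.eta) / (q.lam - q.eta))


def x_star_dimensional(p: DimensionalParams) -> DimensionalBoundary:
    """Zone boundary in physical units.

    x* = (f K1/(nu1 k1)) * ln( B c1 / (K1 (nu1 c2 - nu2 c1)) ), requiring
    A > 0, B > 0 and nu1 c2 > nu2 c1 (strict zone ordering).  The returned
    report also states whether x* falls inside the capillary (0, L).
    """
    dc = derive_constants(p)
    if not dc.A > 0:
        raise ValueError("no strict zone ordering: A = mu2*K1 - mu1*K2 > 0 fails")
    if not dc.B > 0:
        raise ValueError("no strict zone ordering: B = nu1*K2 - nu2*K1 > 0 fails")
    excess = p.nu1 * dc.c2 - p.nu2 * dc.c1
    if not excess > 0:
        raise ValueError("no strict zone ordering: nu1*c2 > nu2*c1 fails")
    length_scale = p.f * p.K1 / (p.nu1 * p.k1)
    x_star = length_scale * math.log(dc.B * dc.c1 / (p.K1 * excess))
    return DimensionalBoundary(x_star=x_star, within_domain=0.0 < x_star < p.L)


def stationary_profile(
    q: DimensionlessParams, grid: Union[np.ndarray, int] = 401
) -> StationaryZones:
    """Assemble the piecewise dimensionless stationary profile on [0, Lambda].

    Nodes strictly below x* carry (exp(-x), 0); nodes strictly above carry
    (0, amplitude2 * exp(-eta theta (x - x*))).  A node falling exactly at
    x* takes the left-limit value for species 1 and the right-limit value
    for species 2 (the two one-sided values coincide: exp(-x*) equals
    amplitude2).
    """
    report = check_zone_conditions(q)
    if not report.zone_forming:
        raise ValueError(
            "zone conditions fail (eta < lam < 1 and x* < Lambda required): " + repr(report)
        )
    xs = report.x_star
    amp = (q.lam - q.eta) / (1.0 - q.eta)
    x = _as_grid(grid, 0.0, q.Lambda)
    v1 = np.where(x <= xs, np.exp(-x), 0.0)
    v2 = np.where(x >= xs, amp * np.exp(-q.eta * q.theta * (x - xs)), 0.0)
    profile = DensityPair(GridFunction(x, v1), GridFunction(x, v2), frame="dimensionless")
    return StationaryZones(x_star=xs, amplitude2=amp, profile=profile, frame="dimensionless")


def stationary_profile_dimensional(
    p: DimensionalParams, grid: Union[np.ndarray, int] = 401
) -> StationaryZones:
    """Piecewise dimensional stationary profile on [0, L].

    rho1* = (c1/K1) exp(-nu1 k1 x/(f K1)) upstream of x*, rho2* =
    D exp(-nu2 k2 (x - x*)/(f K2)) downstream, with the same node
    convention as :func:`stationary_profile`.
    """
    boundary = x_star_dimensional(p)
    if not boundary.within_domain:
        raise ValueError("x* lies outside (0, L): no interior zone boundary")
    dc = derive_constants(p)
    xs = boundary.x_star
    x = _as_grid(grid, 0.0, p.L)
    rate1 = p.nu1 * p.k1 / (p.f * p.K1)
    rate2 = p.nu2 * p.k2 / (p.f * p.K2)
    rho1 = np.where(x <= xs, (dc.c1 / p.K1) * np.exp(-rate1 * x), 0.0)
    rho2 = np.where(x >= xs, dc.D * np.exp(-rate2 * (x - xs)), 0.0)
    profile = DensityPair(GridFunction(x, rho1), GridFunction(x, rho2), frame="dimensional")
    return StationaryZones(x_star=xs, amplitude2=dc.D, profile=profile, frame="dimensional")


def _build_series(
    seed_value: float,
    rate: float,
    x: np.ndarray,
    offset: float,
    n_terms: int,
    method: str,
) -> StationarySeries:
    """Common series builder: term_{n+1} = -rate * INT_offset^x term_n.

    ``method='quadrature'`` iterates the cumulative trapezoid (the package's
    one quadrature operator); ``method='analytic'`` writes down the closed
    term formula seed * (-rate)^n (x-offset)^n / n! directly.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    if method not in ("quadrature", "analytic"):
        raise ValueError("method must be 'quadrature' or 'analytic'")
    s = x - offset
    terms = [GridFunction(x, np.full_like(x, seed_value))]
    for n in range(1, n_terms):
        if method == "quadrature":
            terms.append(-rate * terms[-1].cumulative_integral())
        else:
            coeff = seed_value * (-rate) ** n / math.factorial(n)
            terms.append(GridFunction(x, coeff * s**n))
    closed = GridFunction(x, seed_value * np.exp(-rate * s))
    return StationarySeries(terms=terms, closed_form=closed, n_terms=n_terms, method=method)


def adm_stationary_first(
    p: DimensionalParams,
    n_terms: int = 25,
    grid: Union[np.ndarray, int] = 401,
    method: str = "quadrature",
) -> StationarySeries:
    """Adomian series for the upstream stationary profile rho1*.

    The upstream zone equation rho1 = c1/K1 - (nu1 k1/(f K1)) INT_0^x rho1
    seeds the series with the constant c1/K1; each later term is the
    cumulative integral of its predecessor scaled by -nu1 k1/(f K1), so term
    n is (c1/K1)(-nu1 k1/(f K1))^n x^n/n! and the series sums to
    (c1/K1) exp(-nu1 k1 x/(f K1)).
    """
    dc = derive_constants(p)
    x = _as_grid(grid, 0.0, p.L)
    rate = p.nu1 * p.k1 / (p.f * p.K1)
    return _build_series(dc.c1 / p.K1, rate, x, 0.0, n_terms, method)


def adm_stationary_second(
    p: DimensionalParams,
    x_star: float,
    n_terms: int = 25,
    grid_points: int = 401,
    method: str = "quadrature",
    x_end: float | None = None,
) -> StationarySeries:
    """Adomian series for the downstream stationary profile rho2* on [x*, L].

    The downstream zone equation rho2 + (nu2 k2/(f K2)) INT_{x*}^x rho2 = D
    seeds the series with the plateau constant D; the series sums to
    D exp(-nu2 k2 (x - x*)/(f K2)).  The series lives on its own uniform
    grid over [x*, L] so that the integral's lower limit x* is a node;
    ``x_end`` (default L) truncates the grid's right end.
    """
    dc = derive_constants(p)
    if not dc.D_defined:
        raise ValueError("D is undefined (B = 0): no downstream series")
    if not 0.0 < x_star < p.L:
        raise ValueError("x_star must lie inside (0, L)")
    x_end = p.L if x_end is None else float(x_end)
    if not x_star < x_end <= p.L:
        raise ValueError("x_end must lie in (x_star, L]")
    x = uniform_grid(x_star, x_end, grid_points)
    rate = p.nu2 * p.k2 / (p.f * p.K2)
    return _build_series(dc.D, rate, x, x_star, n_terms, method)
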