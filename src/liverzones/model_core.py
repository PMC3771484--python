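"""Core model objects for the two-cell-type liver zonation model.

The model describes two hepatocyte subtypes lining a representative liver
capillary (sinusoid) of length ``L``, with blood flowing unidirectionally
from the inlet at ``x = 0``.  Each subtype grows logistically against a
shared ceiling of cell sites ``sigma`` (contact inhibition) and dies at a
rate that increases linearly as the local oxygen concentration ``c`` falls
below the inlet value ``c0``.  Oxygen itself is convected with the blood and
consumed by the cells, so the concentration at ``x`` depends on the total
consumption upstream of ``x`` — an integral coupling that makes the
governing equations integro-partial differential equations:

    drho1/dt = rho1 [ K1 (sigma - rho1 - rho2) - mu1
                      - (nu1/f) INT_0^x (k1 rho1 + k2 rho2) dxi ],
    drho2/dt = rho2 [ K2 (sigma - rho1 - rho2) - mu2
                      - (nu2/f) INT_0^x (k1 rho1 + k2 rho2) dxi ].

Rescaling time, space and density collapses the eleven dimensional rate
constants to four dimensionless groups (theta, gamma, lambda, eta) plus a
dimensionless capillary length Lambda:

    dv1/dt = v1 [ 1      - v1 - v2 -       INT_0^x (v1 + theta v2) dxi ],
    dv2/dt = gamma v2 [ lambda - v1 - v2 - eta INT_0^x (v1 + theta v2) dxi ].

This module holds the parameter containers, the grid-tabulated profile
representation, the nondimensionalization map, the death-rate and oxygen
balance laws, the zone-formation condition checks and the dimensionless
right-hand side shared by the series solver and the reference integrator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GRID_UNIFORMITY_RTOL",
    "DEFAULT_N_POINTS",
    "GridFunction",
    "DensityPair",
    "DimensionalParams",
    "DimensionlessParams",
    "DerivedConstants",
    "Scales",
    "ZoneConditionReport",
    "ModelValidityWarning",
    "uniform_grid",
    "cumulative_integral",
    "derive_constants",
    "nondimensionalize",
    "nondimensionalize_profile",
    "dimensionalize_profile",
    "check_zone_conditions",
    "death_rate",
    "oxygen_profile",
    "rhs_dimensionless",
]

#: Relative tolerance under which node spacing is accepted as uniform.
GRID_UNIFORMITY_RTOL = 1e-9

#: Default number of grid nodes (closed interval, both endpoints included).
DEFAULT_N_POINTS = 401


class ModelValidityWarning(UserWarning):
    """The computed state left the regime in which the model is meaningful
    (e.g. a negative oxygen concentration)."""


def uniform_grid(x0: float, x1: float, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Closed uniform grid on [x0, x1] with ``n_points`` nodes."""
    if n_points < 2:
        raise ValueError("a grid needs at least 2 nodes")
    if not x1 > x0:
        raise ValueError("grid interval must have positive length")
    return np.linspace(float(x0), float(x1), int(n_points))


def _as_grid(grid: Union[np.ndarray, int], x0: float, x1: float) -> np.ndarray:
    """Accept either an explicit node array or a node count on [x0, x1]."""
    if isinstance(grid, (int, np.integer)):
        return uniform_grid(x0, x1, int(grid))
    return np.asarray(grid, dtype=float)


@dataclass(frozen=True)
class GridFunction:
    """A real function of x tabulated on a closed uniform grid.

    This is the basic profile representation: cell densities, oxygen
    concentrations and series coefficients are all `GridFunction`s.  Node
    spacing must be uniform to within :data:`GRID_UNIFORMITY_RTOL`, and both
    interval endpoints are nodes (the inlet node x = 0 is required by the
    cumulative integral term).
    """

    x: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if x.ndim != 1 or v.shape != x.shape:
            raise ValueError("x and values must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("a grid needs at least 2 nodes")
        dx = np.diff(x)
        if np.any(dx <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        h = (x[-1] - x[0]) / (x.size - 1)
        if np.max(np.abs(dx - h)) > GRID_UNIFORMITY_RTOL * max(abs(h), 1e-300):
            raise ValueError("grid nodes must be uniformly spaced")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "values", v)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_callable(
        cls,
        func: Callable[[np.ndarray], np.ndarray],
        x0: float,
        x1: float,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "GridFunction":
        x = uniform_grid(x0, x1, n_points)
        return cls(x, np.broadcast_to(np.asarray(func(x), dtype=float), x.shape).copy())

    @classmethod
    def constant(
        cls, value: float, x0: float, x1: float, n_points: int = DEFAULT_N_POINTS
    ) -> "GridFunction":
        x = uniform_grid(x0, x1, n_points)
        return cls(x, np.full_like(x, float(value)))

    # -- geometry ----------------------------------------------------------

    @property
    def x0(self) -> float:
        return float(self.x[0])

    @property
    def x1(self) -> float:
        return float(self.x[-1])

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    @property
    def h(self) -> float:
        return (self.x1 - self.x0) / (self.n_points - 1)

    def same_grid(self, other: "GridFunction") -> bool:
        return self.x.shape == other.x.shape and bool(
            np.allclose(self.x, other.x, rtol=GRID_UNIFORMITY_RTOL, atol=0.0)
        )

    def _require_same_grid(self, other: "GridFunction") -> None:
        if not self.same_grid(other):
            raise ValueError("operands are tabulated on different grids")

    # -- calculus and algebra ---------------------------------------------

    def cumulative_integral(self) -> "GridFunction":
        """Cumulative composite-trapezoid integral from the left endpoint.

        The value at the first node is exactly 0.  This single quadrature
        operator is used for every integral term in the package.
        """
        return GridFunction(self.x, cumulative_trapezoid(self.values, self.x, initial=0.0))

    def with_values(self, values: np.ndarray) -> "GridFunction":
        return GridFunction(self.x, np.asarray(values, dtype=float))

    def sup_norm(self) -> float:
        return float(np.max(np.abs(self.values)))

    def __add__(self, other):
        if isinstance(other, GridFunction):
            self._require_same_grid(other)
            return self.with_values(self.values + other.values)
        return self.with_values(self.values + other)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, GridFunction):
            self._require_same_grid(other)
            return self.with_values(self.values - other.values)
        return self.with_values(self.values - other)

    def __rsub__(self, other):
        return self.with_values(other - self.values)

    def __mul__(self, other):
        if isinstance(other, GridFunction):
            self._require_same_grid(other)
            return self.with_values(self.values * other.values)
        return self.with_values(self.values * other)

    __rmul__ = __mul__

    def __neg__(self):
        return self.with_values(-self.values)


@dataclass(frozen=True)
class DensityPair:
    """Densities of the two cell types on a shared grid.

    ``frame`` records whether the values are dimensional cell densities
    (rho1, rho2) or rescaled dimensionless ones (v1, v2).  Nonnegativity is
    a modelling invariant of density states; it is checked on demand via
    :meth:`assert_nonnegative` rather than at construction because the same
    container also carries time derivatives (see :func:`rhs_dimensionless`)
    and solver states with tolerable roundoff undershoot.
    """

    species1: GridFunction
    species2: GridFunction
    frame: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.frame not in ("dimensional", "dimensionless"):
            raise ValueError("frame must be 'dimensional' or 'dimensionless'")
        self.species1._require_same_grid(self.species2)

    @property
    def x(self) -> np.ndarray:
        return self.species1.x

    def min_value(self) -> float:
        return float(min(self.species1.values.min(), self.species2.values.min()))

    def assert_nonnegative(self, tol: float = 0.0) -> None:
        m = self.min_value()
        if m < -tol:
            raise ValueError(f"density has negative values (min {m:g}, tolerance {tol:g})")

    def total(self) -> GridFunction:
        return self.species1 + self.species2


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional model.

    K1, K2     growth-rate coefficients (per density per time)
    sigma      maximum density of cell sites along the capillary
    mu1, mu2   baseline death rates at inlet oxygen concentration
    nu1, nu2   death-rate sensitivities to the oxygen deficit c0 - c
    k1, k2     oxygen consumption rates per cell
    f          steady blood flow rate through the capillary
    c0         inlet oxygen concentration
    L          capillary length

    Viability of each cell type requires its maximal specific growth rate to
    exceed its minimal death rate, ``K_i * sigma > mu_i``; otherwise that
    type dies out everywhere.  This is enforced at construction unless
    ``enforce_viability=False`` (exploratory use).
    """

    K1: float
    K2: float
    sigma: float
    mu1: float
    mu2: float
    nu1: float
    nu2: float
    k1: float
    k2: float
    f: float
    c0: float
    L: float
    enforce_viability: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "sigma", "k1", "k2", "f", "c0", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("mu1", "mu2", "nu1", "nu2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.nu1 > 0:
            raise ValueError(
                "nu1 must be strictly positive (the first cell type is taken as the "
                "oxygen-sensitive one; relabel the types if needed)"
            )
        if self.enforce_viability:
            if not self.K1 * self.sigma > self.mu1:
                raise ValueError("viability violated: K1*sigma must exceed mu1")
            if not self.K2 * self.sigma > self.mu2:
                raise ValueError("viability violated: K2*sigma must exceed mu2")


@dataclass(frozen=True)
class DimensionlessParams:
    """The four dimensionless parameter groups plus the scaled length.

    theta   = k2/k1            relative oxygen consumption per cell
    gamma   = K2/K1            relative growth-rate coefficient
    lam     = K1 c2 / (K2 c1)  relative net growth capacity (written lambda)
    eta     = nu2 K1/(nu1 K2)  relative death-rate sensitivity
    Lambda  = nu1 k1 L/(f K1)  capillary length in units of the zone length scale

    Distinct zones form when ``eta < lam < 1`` and the implied boundary
    ``x* = ln((1-eta)/(lam-eta))`` lies inside (0, Lambda); this predicate is
    reported by :func:`check_zone_conditions`, not enforced here.
    """

    theta: float
    gamma: float
    lam: float
    eta: float
    Lambda: float

    def __post_init__(self) -> None:
        for name in ("theta", "gamma", "lam", "Lambda"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")

    @property
    def zone_forming(self) -> bool:
        return check_zone_conditions(self).zone_forming


@dataclass(frozen=True)
class DerivedConstants:
    """Composite constants controlling zone selection.

    c1, c2  net growth capacities c_i = K_i*sigma - mu_i
    A       = mu2*K1 - mu1*K2; A > 0 favours type 1 upstream
    B       = nu1*K2 - nu2*K1; with A > 0 and B > 0 the log-ratio of the two
              densities grows upstream and shrinks downstream of x*
    D       = (nu1*c2 - nu2*c1)/B, the downstream stationary plateau of the
              second species; undefined when B = 0 (``D_defined`` False)
    """

    c1: float
    c2: float
    A: float
    B: float
    D: float
    D_defined: bool
    note: str = ""


@dataclass(frozen=True)
class Scales:
    """Multiplicative scale factors mapping dimensionless quantities back to
    dimensional ones: t = time*t', x = length*x', rho = density*v."""

    time: float
    length: float
    density: float


@dataclass(frozen=True)
class ZoneConditionReport:
    """Outcome of the zone-formation predicate, one boolean per inequality."""

    eta_lt_lam: bool
    lam_lt_1: bool
    length_sufficient: bool
    zone_forming: bool
    x_star: float | None
    boundary_case: bool
    note: str = ""


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def derive_constants(p: DimensionalParams) -> DerivedConstants:
    """Compute the zone-selection constants c1, c2, A, B and the downstream
    plateau D from the dimensional rate constants.

    The net growth capacity of each type is ``c_i = K_i*sigma - mu_i`` (the
    index runs over both types).  ``D`` requires ``B != 0``; a vanishing B is
    reported through ``D_defined`` rather than raised, since A, B and the
    c_i remain meaningful.
    """
    c1 = p.K1 * p.sigma - p.mu1
    c2 = p.K2 * p.sigma - p.mu2
    A = p.mu2 * p.K1 - p.mu1 * p.K2
    B = p.nu1 * p.K2 - p.nu2 * p.K1
    if B == 0.0:
        return DerivedConstants(c1, c2, A, B, math.nan, False, note="B = 0: D undefined")
    return DerivedConstants(c1, c2, A, B, (p.nu1 * c2 - p.nu2 * c1) / B, True)


def nondimensionalize(p: DimensionalParams) -> tuple[DimensionlessParams, Scales]:
    """Map dimensional rate constants to the dimensionless groups.

    Returns the groups (theta, gamma, lam, eta, Lambda) together with the
    scale factors (time 1/c1, length f*K1/(nu1*k1), density c1/K1) needed to
    carry profiles between frames.  Requires c1 > 0 (viability of type 1)
    and nu1, k1 > 0 so the length scale exists.
    """
    dc = derive_constants(p)
    if not dc.c1 > 0:
        raise ValueError("nondimensionalization requires c1 = K1*sigma - mu1 > 0")
    theta = p.k2 / p.k1
    gamma = p.K2 / p.K1
    lam = p.K1 * dc.c2 / (p.K2 * dc.c1)
    eta = p.nu2 * p.K1 / (p.nu1 * p.K2)
    length = p.f * p.K1 / (p.nu1 * p.k1)
    Lambda = p.L / length
    q = DimensionlessParams(theta=theta, gamma=gamma, lam=lam, eta=eta, Lambda=Lambda)
    scales = Scales(time=1.0 / dc.c1, length=length, density=dc.c1 / p.K1)
    return q, scales


def nondimensionalize_profile(d: DensityPair, scales: Scales) -> DensityPair:
    """Rescale a dimensional density pair (rho1, rho2) on [0, L] to the
    dimensionless pair (v1, v2) on [0, Lambda]."""
    if d.frame != "dimensional":
        raise ValueError("profile is already dimensionless")
    x = d.x / scales.length
    return DensityPair(
        GridFunction(x, d.species1.values / scales.density),
        GridFunction(x, d.species2.values / scales.density),
        frame="dimensionless",
    )


def dimensionalize_profile(d: DensityPair, scales: Scales) -> DensityPair:
    """Inverse of :func:`nondimensionalize_profile`."""
    if d.frame != "dimensionless":
        raise ValueError("profile is already dimensional")
    x = d.x * scales.length
    return DensityPair(
        GridFunction(x, d.species1.values * scales.density),
        GridFunction(x, d.species2.values * scales.density),
        frame="dimensional",
    )


def check_zone_conditions(q: DimensionlessParams) -> ZoneConditionReport:
    """Evaluate the zone-formation predicate eta < lam < 1 together with the
    length condition ln((1-eta)/(lam-eta)) < Lambda.

    All comparisons are strict and exact (no epsilon); borderline equalities
    (eta == lam, lam == 1, x* == Lambda) report False with ``boundary_case``
    set.  The implied boundary x* is echoed whenever it is defined.
    """
    eta_lt_lam = q.eta < q.lam
    lam_lt_1 = q.lam < 1.0
    boundary = q.eta == q.lam or q.lam == 1.0
    x_star = None
    length_ok = False
    note = ""
    if eta_lt_lam and lam_lt_1:
        x_star = math.log((1.0 - q.eta) / (q.lam - q.eta))
        length_ok = x_star < q.Lambda
        boundary = boundary or x_star == q.Lambda
    if boundary:
        note = "boundary case: an inequality holds with equality"
    return ZoneConditionReport(
        eta_lt_lam=eta_lt_lam,
        lam_lt_1=lam_lt_1,
        length_sufficient=length_ok,
        zone_forming=eta_lt_lam and lam_lt_1 and length_ok,
        x_star=x_star,
        boundary_case=boundary,
        note=note,
    )


def death_rate(c, mu: float, nu: float, c0: float):
    """Linear death-rate law beta(c) = mu + nu*(c0 - c).

    ``mu`` is the baseline death rate at inlet oxygen and ``nu`` the
    sensitivity to the oxygen deficit; the rate is nondecreasing as the
    concentration falls.  Accepts scalars or arrays for ``c``.
    """
    deficit = c0 - np.asarray(c, dtype=float)
    out = mu + nu * deficit
    return float(out) if out.ndim == 0 else out


def oxygen_profile(d: DensityPair, p: DimensionalParams) -> GridFunction:
    """Quasisteady oxygen concentration along the capillary.

    c(x) = c0 - (1/f) * INT_0^x (k1 rho1 + k2 rho2) dxi, computed with the
    cumulative trapezoid; c(0) = c0 exactly and c is nonincreasing for
    nonnegative densities.  Negative concentrations (consumption exceeding
    supply) are returned as computed but raise a
    :class:`ModelValidityWarning`.
    """
    if d.frame != "dimensional":
        raise ValueError("oxygen balance applies to dimensional densities")
    if abs(d.x[0]) > GRID_UNIFORMITY_RTOL:
        raise ValueError("the density grid must start at the inlet x = 0")
    consumption = p.k1 * d.species1 + p.k2 * d.species2
    c = p.c0 - (1.0 / p.f) * consumption.cumulative_integral()
    if np.any(c.values < 0):
        warnings.warn(
            "oxygen concentration went negative: consumption exceeds supply, "
            "the model is outside its validity regime",
            ModelValidityWarning,
            stacklevel=2,
        )
    return c


def cumulative_integral(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Array-level cumulative trapezoid from x[0], value 0 at the first node."""
    return cumulative_trapezoid(values, x, initial=0.0)


def rhs_dimensionless(d: DensityPair, q: DimensionlessParams) -> DensityPair:
    """Instantaneous time derivatives of the dimensionless system.

    dv1/dt = v1 [ 1   - v1 - v2 -     J(x) ]
    dv2/dt = gamma v2 [ lam - v1 - v2 - eta J(x) ],   J = INT_0^x (v1 + theta v2)

    The integral coupling J is recomputed by cumulative trapezoid on the
    shared grid at every call.  Input values are used as given (no clipping
    of negative excursions): the map is pure, positivity handling belongs to
    the caller.
    """
    if d.frame != "dimensionless":
        raise ValueError("rhs_dimensionless expects a dimensionless density pair")
    v1 = d.species1.values
    v2 = d.species2.values
    J = cumulative_integral(v1 + q.theta * v2, d.x)
    dv1 = v1 * (1.0 - v1 - v2 - J)
    dv2 = q.gamma * v2 * (q.lam - v1 - v2 - q.eta * J)
    return DensityPair(
        d.species1.with_values(dv1), d.species2.with_values(dv2), frame="dimensionless"
    )
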