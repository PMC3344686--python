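"""Steady states of the tumour-angiogenesis model.

Setting the time derivatives to zero and eliminating C, E, P and A leaves a
single polynomial balance in the tumour concentration ``T``:

    f(T) = g1(T) + g2(T)

where ``f`` (degree 4) collects the sprouting influx ``delta*P`` into the
new vasculature, and ``g1 + g2`` (degree 3) the logistic growth/decay of the
new vasculature itself.  Every non-trivial steady state corresponds to a
root ``T`` of ``f - g`` that also respects the feasibility bounds

    T < TC = (alpha1 - mu1)/beta1     (normal cells stay positive)
    T < TE = (alpha2 - mu2)/gamma     (epithelial cells stay positive)
    T < TA = k3                       (tumour below its carrying capacity)
    T < Tg = alpha1*mu3/(beta1*beta2*k1) + TC   (new vessels stay positive)

Inside ``(0, Tm)`` with ``Tm = min(TE, TA)`` there are at most two feasible
roots: the smaller one (the "break-point") is an unstable saddle whose
stable manifold separates the basins of the cancer-free and the cancer
states; the larger one is the cancer equilibrium.  Degenerate branches are
provided for ``gamma = 0`` (vasculogenesis: the quartic collapses to a
quadratic), ``eps = 0`` (no clonal expansion of new vessels) and
``delta -> infinity`` (no pre-angiogenesis delay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize

from .model_core import ParameterSet, State

__all__ = [
    "Constraints",
    "EquilibriumPoint",
    "PolynomialPair",
    "constraints",
    "trivial_equilibrium",
    "build_polynomials",
    "equilibrium_coords",
    "find_cancer_equilibria",
    "displacement_equilibrium",
]

#: relative grid resolution used by the root scanner
GRID_POINTS = 10_000
#: roots closer than this (relative to Tm) are reported as a degenerate pair
COLLISION_RTOL = 1e-6
#: roots within this (relative to Tm) of a feasibility bound are boundary cases
BOUNDARY_RTOL = 1e-9

_VARIANTS = ("general", "gamma0", "eps0", "delta_inf")


@dataclass(frozen=True)
class Constraints:
    """Feasibility bounds on the steady-state tumour concentration."""

    TC: float
    TE: float
    TA: float
    Tg: float

    @property
    def Tm(self) -> float:
        """Upper end of the root-search interval, min(TE, TA)."""
        return min(self.TE, self.TA)


@dataclass(frozen=True)
class EquilibriumPoint:
    """A candidate steady state with its feasibility record."""

    label: str
    coords: State
    feasible: bool
    violated_constraints: tuple[str, ...] = ()
    degenerate: bool = False   # member of a saddle-node (collided) root pair
    boundary: bool = False     # root within tolerance of a feasibility bound
    note: str = ""

    @property
    def T(self) -> float:
        return self.coords.T

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coords": {k: v for k, v in zip("CETPA", self.coords)},
            "feasible": self.feasible,
            "violated_constraints": list(self.violated_constraints),
            "degenerate": self.degenerate,
            "boundary": self.boundary,
            "note": self.note,
        }


@dataclass(frozen=True)
class PolynomialPair:
    """Coefficients (ascending order) of the steady-state balance f = g1 + g2."""

    f: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    variant: str = "general"

    @property
    def g(self) -> np.ndarray:
        return npoly.polyadd(self.g1, self.g2)

    @property
    def g0(self) -> float:
        """g(0) > 0: the vasculature decay term at vanishing tumour load."""
        return float(npoly.polyval(0.0, self.g))

    @property
    def v1(self) -> float:
        """Leading (cubic) coefficient of g1."""
        return float(self.g1[-1]) if len(self.g1) == 4 else 0.0

    @property
    def v2(self) -> float:
        """Leading (cubic) coefficient of g2."""
        return float(self.g2[-1]) if len(self.g2) == 4 else 0.0

    def residual(self, T: float | np.ndarray) -> float | np.ndarray:
        """f(T) - g(T); non-trivial steady states are its roots."""
        return npoly.polyval(T, npoly.polysub(self.f, self.g))


def constraints(params: ParameterSet) -> Constraints:
    """Feasibility bounds TC, TE, TA, Tg (infinite when the rate vanishes)."""
    tc = (params.alpha1 - params.mu1) / params.beta1 if params.beta1 > 0 else math.inf
    te = (params.alpha2 - params.mu2) / params.gamma if params.gamma > 0 else math.inf
    tg = (
        params.alpha1 * params.mu3 / (params.beta1 * params.beta2 * params.k1) + tc
        if params.beta1 > 0 and params.beta2 > 0
        else math.inf
    )
    return Constraints(TC=tc, TE=te, TA=params.k3, Tg=tg)


def trivial_equilibrium(params: ParameterSet) -> EquilibriumPoint:
    """The cancer-free steady state (C0, E0, 0, 0, 0).

    C0 = k1*(alpha1 - mu1)/alpha1 and E0 = k2*(alpha2 - mu2)/alpha2; it
    exists only when both net growth rates are positive, and is then locally
    asymptotically stable.
    """
    if not params.trivial_exists:
        return EquilibriumPoint(
            label="absent",
            coords=State(0.0, 0.0, 0.0, 0.0, 0.0),
            feasible=False,
            note="cancer-free equilibrium requires alpha1 > mu1 and alpha2 > mu2",
        )
    c0 = params.k1 * (params.alpha1 - params.mu1) / params.alpha1
    e0 = params.k2 * (params.alpha2 - params.mu2) / params.alpha2
    return EquilibriumPoint(
        label="trivial", coords=State(c0, e0, 0.0, 0.0, 0.0), feasible=True
    )


def _vessel_balance_terms(params: ParameterSet) -> tuple[float, float]:
    """Coefficients (h0, h1) of h(T) = mu3/alpha3 + beta2*C(T)/alpha3.

    ``A_bar = k3*h(T)/(k3 - T)``; ``h`` vanishes at ``T = Tg``.
    """
    p = params
    h0 = p.mu3 / p.alpha3 + p.beta2 * p.k1 * (p.alpha1 - p.mu1) / (p.alpha3 * p.alpha1)
    h1 = -p.beta1 * p.beta2 * p.k1 / (p.alpha3 * p.alpha1)
    return h0, h1


def build_polynomials(params: ParameterSet, variant: str = "general") -> PolynomialPair:
    """Assemble the steady-state balance polynomials f, g1, g2.

    ``variant`` selects the degenerate limits: ``gamma0`` (f vanishes and the
    balance reduces to a quadratic times the factor h(T)), ``eps0`` (both
    sides share a factor (k3 - T) which is divided out), and ``delta_inf``
    (f loses the sprouting survival probability delta/(mu4 + delta)).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {_VARIANTS}")
    p = params
    if variant == "general" and p.gamma == 0:
        raise ValueError(
            "the general steady-state balance is degenerate at gamma = 0; "
            "use variant='gamma0'"
        )
    if variant == "eps0" and p.eps != 0:
        raise ValueError("variant='eps0' requires params.eps == 0")

    h = np.array(_vessel_balance_terms(p))          # h0 + h1*T
    w = np.array([1.0, -p.eps / p.mu5])             # 1 - (eps/mu5)*T
    k3mT = np.array([p.k3, -1.0])                   # k3 - T
    lin = np.array([p.alpha2 - p.mu2, -p.gamma])    # (alpha2 - mu2) - gamma*T
    tpoly = np.array([0.0, 1.0])                    # T

    if variant == "gamma0":
        # f == 0; g = h * q with q quadratic (the h-root T = Tg is handled
        # separately by the caller).  We store q as "g1" and 0 as "g2" so the
        # residual is the quadratic of the reduced balance.
        q = npoly.polyadd(
            npoly.polymul(w, k3mT),
            p.eps * p.k3 / (p.mu5 * p.k4) * npoly.polymul(tpoly, h),
        )
        return PolynomialPair(f=np.zeros(1), g1=q, g2=np.zeros(1), variant=variant)

    cf = p.gamma * p.delta * p.k2 / ((p.mu4 + p.delta) * p.mu5 * p.alpha2 * p.k3)
    if variant == "delta_inf":
        cf = p.gamma * p.k2 / (p.mu5 * p.alpha2 * p.k3)

    if variant == "eps0":
        # common factor (k3 - T) divided out of f and g1 (g2 == 0 at eps = 0)
        f = cf * npoly.polymul(npoly.polymul(tpoly, lin), k3mT)
        return PolynomialPair(f=f, g1=h.copy(), g2=np.zeros(1), variant=variant)

    f = cf * npoly.polymul(
        npoly.polymul(tpoly, lin), npoly.polymul(k3mT, k3mT)
    )
    g1 = npoly.polymul(npoly.polymul(w, k3mT), h)
    g2 = p.eps * p.k3 / (p.mu5 * p.k4) * npoly.polymul(tpoly, npoly.polymul(h, h))
    return PolynomialPair(f=f, g1=g1, g2=g2, variant=variant)


def equilibrium_coords(
    params: ParameterSet, T: float, variant: str = "general"
) -> State:
    """Coordinates (C, E, T, P, A) of the steady state with tumour level T.

    C, E and P follow from their own balance equations; A from the tumour
    equation.  For ``gamma = 0`` the epithelial cells stay at their
    cancer-free value and there are no pre-angiogenesis cells; for
    ``delta -> infinity`` the pre-angiogenesis pool is empty.
    """
    p = params
    c = p.k1 / p.alpha1 * ((p.alpha1 - p.mu1) - p.beta1 * T)
    if variant == "gamma0":
        e = p.k2 / p.alpha2 * (p.alpha2 - p.mu2)
        pp = 0.0
    else:
        e = p.k2 / p.alpha2 * ((p.alpha2 - p.mu2) - p.gamma * T)
        pp = 0.0 if variant == "delta_inf" else p.gamma * e * T / (p.mu4 + p.delta)
    h0, h1 = _vessel_balance_terms(p)
    a = p.k3 / (p.k3 - T) * (h0 + h1 * T)
    return State(c, e, T, pp, a)


def _feasibility(
    params: ParameterSet, T: float, cons: Constraints
) -> tuple[bool, tuple[str, ...], bool]:
    violated = []
    boundary = False
    tol = BOUNDARY_RTOL * cons.Tm if math.isfinite(cons.Tm) else BOUNDARY_RTOL
    for name in ("TC", "TE", "TA", "Tg"):
        bound = getattr(cons, name)
        if not math.isfinite(bound):
            continue
        if T >= bound:
            violated.append(name)
        elif bound - T < tol:
            boundary = True
    return (not violated and not boundary), tuple(violated), boundary


def _scan_roots(
    residual, t_hi: float, grid_points: int, rtol: float = 1e-12
) -> list[float]:
    """Bracket sign changes of ``residual`` on (0, t_hi) and refine by bisection."""
    t_lo = 1e-12 * t_hi
    grid = np.linspace(t_lo, t_hi * (1.0 - 1e-9), grid_points)
    vals = np.asarray(residual(grid))
    roots: list[float] = []
    sign = np.sign(vals)
    changes = np.nonzero(np.diff(sign) != 0)[0]
    for i in changes:
        a, b = grid[i], grid[i + 1]
        if vals[i] == 0.0:
            roots.append(float(a))
            continue
        roots.append(
            float(optimize.bisect(residual, a, b, xtol=rtol * t_hi, maxiter=200))
        )
    return sorted(roots)


def find_cancer_equilibria(
    params: ParameterSet,
    variant: str | None = None,
    *,
    include_infeasible: bool = False,
    grid_points: int = GRID_POINTS,
) -> list[EquilibriumPoint]:
    """All non-trivial steady states with tumour level in (0, Tm).

    The residual f - g is evaluated on a uniform grid over (0, Tm); each
    sign change is refined by bisection.  Roots are labelled ``small`` /
    ``big`` in increasing order; a pair closer than ``COLLISION_RTOL * Tm``
    is flagged ``degenerate`` (saddle-node collision).  By default only
    feasible points are returned; ``include_infeasible=True`` also returns
    constraint-violating roots with their violation record (used by the
    parameter-continuation routines).
    """
    if variant is None:
        variant = "gamma0" if params.gamma == 0 else "general"
    pair = build_polynomials(params, variant)
    cons = constraints(params)
    t_hi = params.k3 if variant == "gamma0" else cons.Tm
    if not math.isfinite(t_hi) or t_hi <= 0:
        return []

    roots = _scan_roots(pair.residual, t_hi, grid_points)

    points: list[EquilibriumPoint] = []
    labels = ["small", "big"]
    for i, t in enumerate(roots):
        feas, violated, boundary = _feasibility(params, t, cons)
        coords = equilibrium_coords(params, t, variant)
        degenerate = any(
            abs(t - other) < COLLISION_RTOL * t_hi for other in roots if other != t
        )
        label = labels[i] if i < 2 else f"root{i + 1}"
        note = ""
        if boundary:
            note = "root within tolerance of a feasibility bound"
        points.append(
            EquilibriumPoint(
                label=label,
                coords=coords,
                feasible=feas,
                violated_constraints=violated,
                degenerate=degenerate,
                boundary=boundary,
                note=note,
            )
        )

    if variant == "gamma0":
        # the reduced balance factors as h(T) * quadratic; the h-root T = Tg
        # is an algebraic steady state with C < 0 (never biologically viable)
        tg = cons.Tg
        if math.isfinite(tg):
            feas, violated, boundary = _feasibility(params, tg, cons)
            if tg < params.k3:
                coords = equilibrium_coords(params, tg, "gamma0")
            else:
                coords = State(
                    params.k1 / params.alpha1
                    * ((params.alpha1 - params.mu1) - params.beta1 * tg),
                    params.k2 / params.alpha2 * (params.alpha2 - params.mu2),
                    tg,
                    0.0,
                    0.0,
                )
            points.append(
                EquilibriumPoint(
                    label="vasculogenic_p",
                    coords=coords,
                    feasible=False,
                    violated_constraints=violated or ("TC",),
                    note="factor root T = Tg of the gamma = 0 balance; "
                    "normal cells would be negative",
                )
            )

    if not include_infeasible:
        points = [pt for pt in points if pt.feasible]
    return points


def displacement_equilibrium(params: ParameterSet) -> EquilibriumPoint:
    """Steady state with the normal cells displaced to zero (C = 0).

    With C = 0 the tumour balance fixes A = k3*mu3/(alpha3*(k3 - T)) and the
    vessel balance becomes independent of beta1 and beta2, so the tumour
    level is pinned at a constant value for every beta1 above the critical
    value beta1c = (alpha1 - mu1)/T.  The point is feasible (as the
    continuation of the cancer branch) only when beta1 >= beta1c; it is
    flagged infeasible below that, where the interior cancer equilibrium
    with C > 0 exists instead.
    """
    p = params
    if p.gamma == 0:
        raise ValueError("displacement equilibrium requires gamma > 0")
    h0c = p.mu3 / p.alpha3
    w = np.array([1.0, -p.eps / p.mu5])
    k3mT = np.array([p.k3, -1.0])
    lin = np.array([p.alpha2 - p.mu2, -p.gamma])
    tpoly = np.array([0.0, 1.0])
    cf = p.gamma * p.delta * p.k2 / ((p.mu4 + p.delta) * p.mu5 * p.alpha2 * p.k3)
    f = cf * npoly.polymul(npoly.polymul(tpoly, lin), npoly.polymul(k3mT, k3mT))
    g = npoly.polyadd(
        h0c * npoly.polymul(w, k3mT),
        p.eps * p.k3 / (p.mu5 * p.k4) * h0c**2 * tpoly,
    )
    d = npoly.polysub(f, g)
    cons = constraints(params)
    t_hi = cons.Tm
    roots = _scan_roots(lambda t: npoly.polyval(t, d), t_hi, GRID_POINTS)
    if not roots:
        return EquilibriumPoint(
            label="displacement_c",
            coords=State(0.0, 0.0, 0.0, 0.0, 0.0),
            feasible=False,
            note="no displacement steady state inside (0, min(TE, TA))",
        )
    t = roots[-1]  # the stable branch continues through the larger root
    e = p.k2 / p.alpha2 * ((p.alpha2 - p.mu2) - p.gamma * t)
    pp = p.gamma * e * t / (p.mu4 + p.delta)
    a = p.k3 * p.mu3 / (p.alpha3 * (p.k3 - t))
    beta1c = (p.alpha1 - p.mu1) / t
    violated = []
    if t >= cons.TE:
        violated.append("TE")
    if t >= cons.TA:
        violated.append("TA")
    feasible = not violated and p.beta1 >= beta1c
    note = f"tumour level pinned at (alpha1 - mu1)/beta1c with beta1c = {beta1c:.6g}"
    if p.beta1 < beta1c:
        note += "; current beta1 is below beta1c (interior equilibrium applies)"
    return EquilibriumPoint(
        label="displacement_c",
        coords=State(0.0, e, t, pp, a),
        feasible=feasible,
        violated_constraints=tuple(violated),
        note=note,
    )
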