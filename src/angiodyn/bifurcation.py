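"""Parameter continuation: thresholds, critical points and basin boundaries.

One interaction parameter (``beta1``, ``beta2``, ``gamma``, ``eps`` or
``delta``) is swept while the rest stay fixed.  The interesting structure:

* **saddle-node thresholds** -- the small and big tumour equilibria collide
  and vanish as ``beta2`` increases past ``beta2_th`` (or ``gamma``
  decreases past ``gamma_th``; or, at ``gamma = 0``, as ``eps`` decreases
  past ``eps_th``).  Beyond the threshold every mutation pulse regresses.
* **displacement critical value** -- as ``beta1`` grows, the cancer branch
  T>(beta1) rises until it meets the bound TC(beta1) at ``beta1_c``; past
  it the normal cells are excluded (C = 0) and the tumour level stays
  pinned.  A companion value ``beta1_A`` marks where the branch would meet
  Tg (vanishing new vasculature).
* **Hopf window** -- along the ``gamma`` sweep, the leading complex
  eigenvalue pair of the cancer equilibrium crosses the imaginary axis at
  ``gamma_1c`` (oscillation onset) and back at ``gamma_2c`` (cycle
  destruction).
* **basin boundaries** -- the critical mutation-pulse size ``T*`` between
  regression and progression, bracketed by bisection on simulated
  trajectories.

All detections are bisections on a sign predicate; they inherit the
determinism of the underlying root scans and RK4 runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize

from . import equilibria as eqmod
from . import simulate as simmod
from . import stability as stabmod
from .model_core import ParameterSet, pulse_initial_state

__all__ = [
    "SpecialPoint",
    "BifurcationResult",
    "BasinBoundaryResult",
    "sweep",
    "saddle_node_threshold",
    "critical_beta1",
    "critical_beta1_A",
    "hopf_points",
    "limit_cycle_exit",
    "basin_boundary",
]

PARAM_NAMES = ("beta1", "beta2", "gamma", "eps", "delta")

#: relative tolerance of all parameter bisections
PARAM_RTOL = 1e-6
MAX_BISECT = 80


@dataclass(frozen=True)
class SpecialPoint:
    kind: str  # saddle_node | displacement_onset | A_zero | hopf_super | hopf_sub
    param_value: float
    T_value: float


@dataclass(frozen=True)
class BifurcationResult:
    param_name: str
    grid: np.ndarray
    small_branch: np.ndarray      # NaN where no feasible small root
    big_branch: np.ndarray        # NaN where no feasible big/displaced root
    stability_flags: list[str | None]
    special_points: list[SpecialPoint]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": self.grid,
                "T_small": self.small_branch,
                "T_big": self.big_branch,
                "stability": self.stability_flags,
            }
        )


@dataclass(frozen=True)
class BasinBoundaryResult:
    bracket_lo: float
    bracket_hi: float
    attractor_lo: str
    attractor_hi: str
    tolerance: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.bracket_lo + self.bracket_hi)


def _check_param(name: str) -> None:
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown sweep parameter {name!r}; choose from {PARAM_NAMES}")


def _residual_poly(params: ParameterSet) -> tuple[np.ndarray, float]:
    """(ascending coefficients of f - g, upper end of the search interval)."""
    variant = "gamma0" if params.gamma == 0 else "general"
    pair = eqmod.build_polynomials(params, variant)
    cons = eqmod.constraints(params)
    t_hi = params.k3 if variant == "gamma0" else cons.Tm
    return npoly.polysub(pair.f, pair.g), t_hi


def _has_root_pair(params: ParameterSet) -> tuple[bool, float]:
    """Whether the small/big root pair exists; returns (exists, T at interior max).

    The residual f - g is negative at both ends of (0, Tm); the pair exists
    exactly while its interior maximum is positive.  Tracking the maximum
    (rather than counting bracketed sign changes) stays robust arbitrarily
    close to the collision.
    """
    d, t_hi = _residual_poly(params)
    grid = np.linspace(1e-9 * t_hi, t_hi * (1 - 1e-9), 4001)
    vals = npoly.polyval(grid, d)
    i = int(np.argmax(vals))
    t_peak = grid[i]
    # polish the interior maximum via the derivative
    dd = npoly.polyder(d)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    try:
        if npoly.polyval(lo, dd) > 0 > npoly.polyval(hi, dd):
            t_peak = float(optimize.brentq(lambda t: npoly.polyval(t, dd), lo, hi))
    except ValueError:
        pass
    return bool(npoly.polyval(t_peak, d) > 0), float(t_peak)


def _branch_points(
    params: ParameterSet, *, follow_displacement: bool
) -> tuple[eqmod.EquilibriumPoint | None, eqmod.EquilibriumPoint | None]:
    """(small, big-or-displaced) equilibrium points at the current parameters."""
    pts = eqmod.find_cancer_equilibria(params, include_infeasible=True)
    small = next((pt for pt in pts if pt.label == "small" and pt.feasible), None)
    big = next((pt for pt in pts if pt.label == "big" and pt.feasible), None)
    if big is None and follow_displacement:
        big_any = next((pt for pt in pts if pt.label == "big"), None)
        if big_any is not None and "TC" in big_any.violated_constraints:
            disp = eqmod.displacement_equilibrium(params)
            if disp.feasible:
                big = disp
    return small, big


def sweep(
    params: ParameterSet, param_name: str, grid: np.ndarray
) -> BifurcationResult:
    """Track the small/big tumour branches and their stability along a grid.

    For ``beta1`` sweeps the big branch switches to the displacement
    equilibrium (C = 0) once the interior branch violates TC.  Branch
    terminations, the displacement hand-over, the A = 0 crossing and
    stability-class changes are recorded as (grid-resolution) special
    points; use the dedicated detectors to refine them.
    """
    _check_param(param_name)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with at least 2 points")

    follow = param_name == "beta1"
    small_T = np.full(len(grid), np.nan)
    big_T = np.full(len(grid), np.nan)
    flags: list[str | None] = [None] * len(grid)
    big_labels: list[str | None] = [None] * len(grid)

    for i, v in enumerate(grid):
        p_i = params.replace(**{param_name: float(v)})
        small, big = _branch_points(p_i, follow_displacement=follow)
        if small is not None:
            small_T[i] = small.T
        if big is not None:
            big_T[i] = big.T
            big_labels[i] = big.label
            flags[i] = stabmod.stability_report(p_i, big).classification

    specials: list[SpecialPoint] = []
    for i in range(len(grid) - 1):
        mid = 0.5 * (grid[i] + grid[i + 1])
        have = ~np.isnan(big_T[[i, i + 1]])
        if have[0] != have[1] and big_labels[i] != "displacement_c":
            t_ref = big_T[i] if have[0] else big_T[i + 1]
            specials.append(SpecialPoint("saddle_node", float(mid), float(t_ref)))
        if big_labels[i] == "big" and big_labels[i + 1] == "displacement_c":
            specials.append(SpecialPoint("displacement_onset", float(mid), float(big_T[i + 1])))
        cons_i = eqmod.constraints(params.replace(**{param_name: float(grid[i])}))
        cons_j = eqmod.constraints(params.replace(**{param_name: float(grid[i + 1])}))
        if (
            not np.isnan(big_T[i])
            and not np.isnan(big_T[i + 1])
            and (big_T[i] - cons_i.Tg) * (big_T[i + 1] - cons_j.Tg) < 0
        ):
            specials.append(SpecialPoint("A_zero", float(mid), float(big_T[i])))
        if flags[i] and flags[i + 1] and flags[i] != flags[i + 1]:
            if flags[i].startswith("stable") and flags[i + 1] == "unstable":
                specials.append(SpecialPoint("hopf_super", float(mid), float(big_T[i])))
            elif flags[i] == "unstable" and flags[i + 1].startswith("stable"):
                specials.append(SpecialPoint("hopf_sub", float(mid), float(big_T[i + 1])))

    return BifurcationResult(
        param_name=param_name,
        grid=grid,
        small_branch=small_T,
        big_branch=big_T,
        stability_flags=flags,
        special_points=specials,
    )


def saddle_node_threshold(
    params: ParameterSet, param_name: str, bracket: tuple[float, float]
) -> tuple[float, float]:
    """Parameter value at which the small/big root pair collides.

    Bisects the pair-existence predicate over ``bracket`` to relative
    tolerance 1e-6 and returns ``(param_value, T_value)`` with ``T_value``
    the tumour level at the collision (the interior maximum of f - g at
    the threshold).
    """
    _check_param(param_name)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"bracket must be increasing, got {bracket}")
    exists_lo, _ = _has_root_pair(params.replace(**{param_name: lo}))
    exists_hi, _ = _has_root_pair(params.replace(**{param_name: hi}))
    if exists_lo == exists_hi:
        raise ValueError(
            f"no saddle-node of {param_name} inside {bracket}: the root pair "
            f"{'exists' if exists_lo else 'is absent'} at both ends"
        )
    t_star = math.nan
    for _ in range(MAX_BISECT):
        mid = 0.5 * (lo + hi)
        exists_mid, t_peak = _has_root_pair(params.replace(**{param_name: mid}))
        if exists_mid == exists_lo:
            lo = mid
        else:
            hi = mid
        t_star = t_peak
        if hi - lo <= PARAM_RTOL * max(abs(lo), abs(hi)):
            break
    return 0.5 * (lo + hi), float(t_star)


def _big_root_unconstrained(params: ParameterSet) -> float | None:
    """Largest root of f - g in (0, min(TE, TA)), ignoring TC/Tg feasibility."""
    pts = eqmod.find_cancer_equilibria(params, include_infeasible=True)
    roots = [pt.T for pt in pts if pt.label in ("small", "big")]
    if len(roots) < 2:
        return None
    return max(roots)


def critical_beta1(
    params: ParameterSet, scan_hi: float = 0.05
) -> tuple[float, float]:
    """``beta1_c`` where the cancer branch meets TC (normal cells reach 0).

    Bisects ``T>(beta1) - TC(beta1)`` upward from the current ``beta1``;
    returns ``(beta1_c, TC_c)`` with ``TC_c = (alpha1 - mu1)/beta1_c`` the
    pinned tumour level of the displacement state.  Raises if the branch
    never crosses (e.g. no cancer branch at all).
    """

    def gap(b1: float) -> float | None:
        p_i = params.replace(beta1=b1)
        t_big = _big_root_unconstrained(p_i)
        if t_big is None:
            return None
        return t_big - (p_i.alpha1 - p_i.mu1) / b1

    lo = params.beta1
    g_lo = gap(lo)
    if g_lo is None:
        raise ValueError("no cancer branch at the starting beta1; nothing to cross")
    if g_lo >= 0:
        raise ValueError("branch already beyond TC at the starting beta1")
    hi = scan_hi
    g_hi = gap(hi)
    if g_hi is None or g_hi <= 0:
        raise ValueError(f"branch does not cross TC inside ({lo}, {hi})")
    for _ in range(MAX_BISECT):
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid is None or g_mid > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= PARAM_RTOL * hi:
            break
    beta1_c = 0.5 * (lo + hi)
    return beta1_c, (params.alpha1 - params.mu1) / beta1_c


def critical_beta1_A(
    params: ParameterSet, scan_hi: float = 0.05
) -> tuple[float, float]:
    """``beta1_A`` where the (algebraic) cancer branch meets Tg (A = 0).

    A companion of ``beta1_c``: mathematically the branch root crosses the
    vessel-positivity bound Tg at ``beta1_A > beta1_c``, although the
    physical equilibrium is already the displacement state there.  Returns
    ``(beta1_A, Tg_A)``.
    """

    def gap(b1: float) -> float | None:
        p_i = params.replace(beta1=b1)
        t_big = _big_root_unconstrained(p_i)
        if t_big is None:
            return None
        tg = p_i.alpha1 * p_i.mu3 / (b1 * p_i.beta2 * p_i.k1) + (
            p_i.alpha1 - p_i.mu1
        ) / b1
        return t_big - tg

    lo = params.beta1
    g_lo = gap(lo)
    if g_lo is None or g_lo >= 0:
        raise ValueError("branch is absent or already beyond Tg at the starting beta1")
    hi = scan_hi
    g_hi = gap(hi)
    if g_hi is None or g_hi <= 0:
        raise ValueError(f"branch does not cross Tg inside ({lo}, {hi})")
    for _ in range(MAX_BISECT):
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid is None or g_mid > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= PARAM_RTOL * hi:
            break
    beta1_a = 0.5 * (lo + hi)
    p_a = params.replace(beta1=beta1_a)
    tg_a = p_a.alpha1 * p_a.mu3 / (beta1_a * p_a.beta2 * p_a.k1) + (
        p_a.alpha1 - p_a.mu1
    ) / beta1_a
    return beta1_a, tg_a


def _complex_pair_real_part(params: ParameterSet) -> tuple[float, float] | None:
    """(max Re over complex eigenvalues, T_big) at the cancer equilibrium."""
    pts = eqmod.find_cancer_equilibria(params)
    big = next((pt for pt in pts if pt.label == "big"), None)
    if big is None:
        return None
    rep = stabmod.stability_report(params, big)
    complex_re = [ev.real for ev in rep.eigenvalues if abs(ev.imag) > 1e-12]
    if not complex_re:
        return None
    return max(complex_re), big.T


def hopf_points(
    params: ParameterSet,
    bracket: tuple[float, float],
    grid_points: int = 61,
) -> list[tuple[float, float, str]]:
    """Zero crossings of the leading complex pair's real part along ``gamma``.

    Scans ``gamma`` over ``bracket``, bisects each sign change of the
    complex conjugate pair's real part to relative tolerance 1e-6, and
    labels a negative-to-positive crossing ``hopf_super`` (oscillation
    onset) and a positive-to-negative one ``hopf_sub`` (cycle exit).
    Returns a list of ``(gamma, T_big, kind)``.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    grid = np.linspace(lo, hi, grid_points)
    vals: list[float | None] = []
    for g in grid:
        out = _complex_pair_real_part(params.replace(gamma=float(g)))
        vals.append(None if out is None else out[0])

    points: list[tuple[float, float, str]] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a is None or b is None or a * b >= 0:
            continue
        glo, ghi = grid[i], grid[i + 1]
        sign_lo = a
        for _ in range(MAX_BISECT):
            gmid = 0.5 * (glo + ghi)
            vmid = _complex_pair_real_part(params.replace(gamma=gmid))[0]
            if vmid * sign_lo > 0:
                glo = gmid
            else:
                ghi = gmid
            if ghi - glo <= PARAM_RTOL * ghi:
                break
        g_star = 0.5 * (glo + ghi)
        _, t_big = _complex_pair_real_part(params.replace(gamma=g_star))
        kind = "hopf_super" if a < 0 else "hopf_sub"
        points.append((float(g_star), float(t_big), kind))
    return points


def limit_cycle_exit(
    params: ParameterSet,
    bracket: tuple[float, float],
    *,
    cm: float = 0.42,
    rtol: float = 1e-4,
    t_end: float = 20000.0,
    dt: float = 0.01,
    full_c0: bool = True,
) -> tuple[float, float]:
    """``gamma`` at which the stable limit cycle around the tumour state dies.

    Past the oscillation onset the tumour equilibrium stays weakly unstable,
    so the disappearance of sustained oscillations is a global event (the
    cycle grows until its tumour minimum can no longer re-ignite growth) and
    is detected by simulation: a mutation pulse of size ``cm`` is integrated
    at each ``gamma`` and classified; the boundary between ``limit_cycle``
    and ``trivial`` verdicts is bisected to relative tolerance ``rtol``.
    Returns ``(gamma, T_big)`` with ``T_big`` the (unstable) equilibrium
    tumour level at the exit.
    """
    lo, hi = float(bracket[0]), float(bracket[1])

    def is_cycle(g: float) -> bool:
        p_g = params.replace(gamma=g)
        init = pulse_initial_state(p_g, cm, full_c0=full_c0)
        traj = simmod.integrate(p_g, init, t_end, dt)
        cands = [eqmod.trivial_equilibrium(p_g)] + eqmod.find_cancer_equilibria(p_g)
        return simmod.classify_attractor(traj, cands).label == "limit_cycle"

    if not is_cycle(lo) or is_cycle(hi):
        raise ValueError(
            f"bracket {bracket} must enclose the cycle exit "
            "(cycle at the lower end, none at the upper end)"
        )
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if is_cycle(mid):
            lo = mid
        else:
            hi = mid
    g_star = 0.5 * (lo + hi)
    pts = eqmod.find_cancer_equilibria(params.replace(gamma=g_star))
    t_big = next(pt.T for pt in pts if pt.label == "big")
    return g_star, float(t_big)


def _attractor_of_pulse(
    params: ParameterSet,
    cm: float,
    candidates: list[eqmod.EquilibriumPoint],
    *,
    t_end: float,
    dt: float,
    retry_t_end: float,
    full_c0: bool,
) -> str:
    init = pulse_initial_state(params, cm, full_c0=full_c0)
    traj = simmod.integrate(params, init, t_end, dt)
    verdict = simmod.classify_attractor(traj, candidates)
    if verdict.label == "undecided" and retry_t_end > t_end:
        traj = simmod.integrate(params, init, retry_t_end, dt)
        verdict = simmod.classify_attractor(traj, candidates)
    if verdict.label == "undecided":
        raise RuntimeError(
            f"trajectory from cm = {cm} undecided after {retry_t_end} days"
        )
    return verdict.label


def basin_boundary(
    params: ParameterSet,
    cm_bracket: tuple[float, float],
    tol: float = 1e-3,
    *,
    t_end: float = 5000.0,
    dt: float = 0.01,
    retry_t_end: float = 20000.0,
    full_c0: bool = False,
) -> BasinBoundaryResult:
    """Critical mutation-pulse size separating regression from progression.

    The two bracket ends must reach different attractors (the lower one the
    cancer-free state); the boundary is then bisected on ``cm`` until the
    bracket is narrower than ``tol``.  ``full_c0`` selects the
    initial-condition convention ``C(0) = C0`` (see
    ``model_core.pulse_initial_state``).
    """
    lo, hi = float(cm_bracket[0]), float(cm_bracket[1])
    if not 0 <= lo < hi:
        raise ValueError(f"need 0 <= lo < hi, got {cm_bracket}")
    candidates = [eqmod.trivial_equilibrium(params)]
    candidates += eqmod.find_cancer_equilibria(params)
    if params.gamma > 0:
        disp = eqmod.displacement_equilibrium(params)
        if disp.feasible:
            candidates.append(disp)

    kw = dict(t_end=t_end, dt=dt, retry_t_end=retry_t_end, full_c0=full_c0)
    lab_lo = _attractor_of_pulse(params, lo, candidates, **kw)
    lab_hi = _attractor_of_pulse(params, hi, candidates, **kw)
    if lab_lo != "trivial" or lab_hi == "trivial":
        raise ValueError(
            f"bracket ends must separate the attractors; got cm={lo} -> {lab_lo}, "
            f"cm={hi} -> {lab_hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _attractor_of_pulse(params, mid, candidates, **kw) == "trivial":
            lo = mid
        else:
            hi = mid

    # snap the bracket onto the cm-grid of resolution `tol`, so the lower end
    # is the largest grid value whose pulse regresses (as the boundaries are
    # conventionally quoted)
    g = round(math.floor(hi / tol + 1e-9) * tol, 12)
    for _ in range(4):
        if _attractor_of_pulse(params, g, candidates, **kw) == "trivial":
            break
        g = round(g - tol, 12)
    else:
        raise RuntimeError("failed to align the basin bracket to the cm grid")
    g_hi = round(g + tol, 12)
    lab_hi = _attractor_of_pulse(params, g_hi, candidates, **kw)
    if lab_hi == "trivial":
        raise RuntimeError("failed to align the basin bracket to the cm grid")
    return BasinBoundaryResult(
        bracket_lo=g,
        bracket_hi=g_hi,
        attractor_lo="trivial",
        attractor_hi=lab_hi,
        tolerance=tol,
    )
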