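"""Fixed-step integration of the growth model and attractor classification.

The model is bistable over wide parameter ranges, and the quantity of
interest is usually *which* attractor a mutation pulse of size ``Cm``
reaches -- the cancer-free state or the vascularised tumour state -- rather
than high-accuracy path following.  A classical 4th-order Runge-Kutta
scheme with a fixed step (default 0.01 day) is used throughout: it is
deterministic, has no step-control hysteresis near the separatrix, and its
error is easy to audit by step halving.  The inner loop is compiled with
numba; a pure-Python fallback keeps the module importable without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import EquilibriumPoint
from .model_core import ParameterSet, State

__all__ = [
    "Trajectory",
    "AttractorVerdict",
    "integrate",
    "classify_attractor",
    "onset_time",
]

#: components more negative than this abort the run; within (-tol, 0) they
#: are clipped to zero (polynomial right-hand sides can undershoot slightly
#: at a finite step)
NEGATIVE_TOL = 1e-9
#: a component exceeding 1e6 * max carrying capacity is treated as divergence
DIVERGENCE_FACTOR = 1e6


def _rk4_kernel(pv, y, dt, n_steps, rem, stride, cap, out, t_out):
    """RK4 loop on raw floats.  Returns (status, n_stored, t_reached).

    status: 0 ok, 1 divergence, 2 negative component below tolerance.
    Stores the state every ``stride`` steps (plus the initial and final
    states).  Written in no-object style so numba can compile it.
    """
    a1 = pv[0]; a2 = pv[1]; a3 = pv[2]; eps = pv[3]
    m1 = pv[4]; m2 = pv[5]; m3 = pv[6]; m4 = pv[7]; m5 = pv[8]
    k1 = pv[9]; k2 = pv[10]; k3 = pv[11]; k4 = pv[12]
    dlt = pv[13]; gam = pv[14]; b1 = pv[15]; b2 = pv[16]

    C = y[0]; E = y[1]; T = y[2]; P = y[3]; A = y[4]
    out[0, 0] = C; out[0, 1] = E; out[0, 2] = T; out[0, 3] = P; out[0, 4] = A
    t_out[0] = 0.0
    m = 1
    t = 0.0
    total = n_steps + (1 if rem > 0.0 else 0)
    for i in range(total):
        h = dt if i < n_steps else rem
        yC = C; yE = E; yT = T; yP = P; yA = A
        d1C = a1 * yC * (1 - yC / k1) - b1 * yC * yT - m1 * yC
        d1E = a2 * yE * (1 - yE / k2) - gam * yE * yT - m2 * yE
        d1T = a3 * yA * yT * (1 - yT / k3) - b2 * yC * yT - m3 * yT
        d1P = gam * yE * yT - (dlt + m4) * yP
        d1A = dlt * yP + eps * yT * yA * (1 - yA / k4) - m5 * yA
        yC = C + 0.5 * h * d1C; yE = E + 0.5 * h * d1E; yT = T + 0.5 * h * d1T
        yP = P + 0.5 * h * d1P; yA = A + 0.5 * h * d1A
        d2C = a1 * yC * (1 - yC / k1) - b1 * yC * yT - m1 * yC
        d2E = a2 * yE * (1 - yE / k2) - gam * yE * yT - m2 * yE
        d2T = a3 * yA * yT * (1 - yT / k3) - b2 * yC * yT - m3 * yT
        d2P = gam * yE * yT - (dlt + m4) * yP
        d2A = dlt * yP + eps * yT * yA * (1 - yA / k4) - m5 * yA
        yC = C + 0.5 * h * d2C; yE = E + 0.5 * h * d2E; yT = T + 0.5 * h * d2T
        yP = P + 0.5 * h * d2P; yA = A + 0.5 * h * d2A
        d3C = a1 * yC * (1 - yC / k1) - b1 * yC * yT - m1 * yC
        d3E = a2 * yE * (1 - yE / k2) - gam * yE * yT - m2 * yE
        d3T = a3 * yA * yT * (1 - yT / k3) - b2 * yC * yT - m3 * yT
        d3P = gam * yE * yT - (dlt + m4) * yP
        d3A = dlt * yP + eps * yT * yA * (1 - yA / k4) - m5 * yA
        yC = C + h * d3C; yE = E + h * d3E; yT = T + h * d3T
        yP = P + h * d3P; yA = A + h * d3A
        d4C = a1 * yC * (1 - yC / k1) - b1 * yC * yT - m1 * yC
        d4E = a2 * yE * (1 - yE / k2) - gam * yE * yT - m2 * yE
        d4T = a3 * yA * yT * (1 - yT / k3) - b2 * yC * yT - m3 * yT
        d4P = gam * yE * yT - (dlt + m4) * yP
        d4A = dlt * yP + eps * yT * yA * (1 - yA / k4) - m5 * yA
        C += h / 6.0 * (d1C + 2 * d2C + 2 * d3C + d4C)
        E += h / 6.0 * (d1E + 2 * d2E + 2 * d3E + d4E)
        T += h / 6.0 * (d1T + 2 * d2T + 2 * d3T + d4T)
        P += h / 6.0 * (d1P + 2 * d2P + 2 * d3P + d4P)
        A += h / 6.0 * (d1A + 2 * d2A + 2 * d3A + d4A)
        t += h

        if C < 0.0:
            if C < -1e-9:
                return 2, m, t
            C = 0.0
        if E < 0.0:
            if E < -1e-9:
                return 2, m, t
            E = 0.0
        if T < 0.0:
            if T < -1e-9:
                return 2, m, t
            T = 0.0
        if P < 0.0:
            if P < -1e-9:
                return 2, m, t
            P = 0.0
        if A < 0.0:
            if A < -1e-9:
                return 2, m, t
            A = 0.0
        if C > cap or E > cap or T > cap or P > cap or A > cap:
            return 1, m, t

        if (i + 1) % stride == 0 or i == total - 1:
            out[m, 0] = C; out[m, 1] = E; out[m, 2] = T
            out[m, 3] = P; out[m, 4] = A
            t_out[m] = t
            m += 1
    return 0, m, t


try:  # pragma: no cover - exercised implicitly by every integration test
    from numba import njit

    _rk4_compiled = njit(cache=True)(_rk4_kernel)
except ImportError:  # pragma: no cover
    _rk4_compiled = _rk4_kernel


@dataclass(frozen=True)
class Trajectory:
    """A simulated path: states on a (possibly thinned) time grid."""

    times: np.ndarray       # days, strictly increasing, times[0] == 0
    states: np.ndarray      # shape (len(times), 5), columns C, E, T, P, A
    params: ParameterSet
    init: State
    dt: float

    def __post_init__(self) -> None:
        if len(self.times) < 2:
            raise ValueError("a trajectory needs at least two time points")

    @property
    def final_state(self) -> State:
        return State(*self.states[-1])

    def component(self, name: str) -> np.ndarray:
        return self.states[:, "CETPA".index(name)]

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns t, C, E, T, P, A."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, **{c: self.states[:, i] for i, c in enumerate("CETPA")}}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class AttractorVerdict:
    """Where a trajectory ended up."""

    label: str  # trivial | small | big | displacement_c | limit_cycle | undecided
    distance_at_end: float
    oscillation_amplitude: float | None = None


def integrate(
    params: ParameterSet,
    init: State,
    t_end: float,
    dt: float = 0.01,
    *,
    max_stored: int = 200_000,
) -> Trajectory:
    """Integrate the model with classical fixed-step RK4.

    The final step is shortened to land exactly on ``t_end``.  The stored
    grid is thinned to at most ``max_stored`` points (the final state is
    always stored).  Raises on divergence or on a component undershooting
    zero by more than the clipping tolerance.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if dt <= 0 or dt > t_end:
        raise ValueError(f"dt must satisfy 0 < dt <= t_end, got {dt}")
    y0 = np.asarray(init, dtype=np.float64)
    if y0.shape != (5,) or not np.all(np.isfinite(y0)):
        raise ValueError(f"initial state must be 5 finite components, got {init}")

    n_steps = int(math.floor(t_end / dt + 1e-12))
    rem = t_end - n_steps * dt
    if rem < 1e-12 * t_end:
        rem = 0.0
    total = n_steps + (1 if rem else 0)
    stride = max(1, int(math.ceil(total / max_stored)))
    n_slots = total // stride + 3
    out = np.empty((n_slots, 5), dtype=np.float64)
    t_out = np.empty(n_slots, dtype=np.float64)
    cap = DIVERGENCE_FACTOR * max(params.k1, params.k2, params.k3, params.k4)

    status, m, t_reached = _rk4_compiled(
        params.as_array(), y0, float(dt), n_steps, float(rem), stride, cap, out, t_out
    )
    if status == 1:
        raise RuntimeError(
            f"trajectory diverged at t = {t_reached:.3f} days "
            f"(component exceeded {cap:.3g})"
        )
    if status == 2:
        raise RuntimeError(
            f"state component fell below -{NEGATIVE_TOL} at t = {t_reached:.3f} "
            "days; reduce dt"
        )
    times = t_out[:m].copy()
    states = out[:m].copy()
    # de-duplicate a final point that coincides with the last stride point
    if len(times) >= 2 and times[-1] == times[-2]:
        times = times[:-1]
        states = states[:-1]
    return Trajectory(times=times, states=states, params=params, init=State(*y0), dt=dt)


def _window(traj: Trajectory, lo_frac: float, hi_frac: float) -> np.ndarray:
    t_end = traj.times[-1]
    mask = (traj.times >= lo_frac * t_end) & (traj.times <= hi_frac * t_end)
    return traj.states[mask]


def classify_attractor(
    traj: Trajectory,
    candidates: list[EquilibriumPoint],
    *,
    abs_tol: float | None = None,
    cycle_min_amplitude: float = 1e-3,
) -> AttractorVerdict:
    """Decide which attractor (if any) the trajectory has reached.

    The verdict is based on the final 20% of the time span: the trajectory
    is assigned to a candidate equilibrium if it stays within ``abs_tol``
    (default ``1e-3 * max(k1..k4)``) of it over that whole window; it is a
    limit cycle if the tumour component keeps oscillating with
    non-decaying peak-to-peak amplitude; otherwise the verdict is
    ``undecided`` (integrate longer).
    """
    if not candidates:
        raise ValueError("need at least one candidate equilibrium")
    p = traj.params
    if abs_tol is None:
        abs_tol = 1e-3 * max(p.k1, p.k2, p.k3, p.k4)

    final_window = _window(traj, 0.8, 1.0)
    end = traj.states[-1]
    dists_end = {
        c.label: float(np.max(np.abs(end - np.asarray(c.coords)))) for c in candidates
    }
    nearest = min(dists_end, key=dists_end.get)

    for cand in sorted(candidates, key=lambda c: dists_end[c.label]):
        target = np.asarray(cand.coords)
        if np.max(np.abs(final_window - target)) <= abs_tol:
            return AttractorVerdict(label=cand.label, distance_at_end=dists_end[cand.label])

    t_final = _window(traj, 0.8, 1.0)[:, 2]
    t_prev = _window(traj, 0.6, 0.8)[:, 2]
    amp_final = float(np.ptp(t_final)) if len(t_final) else 0.0
    amp_prev = float(np.ptp(t_prev)) if len(t_prev) else 0.0
    if amp_final > cycle_min_amplitude and amp_prev > 0:
        ratio = amp_final / amp_prev
        if 0.99 <= ratio <= 1.01:
            return AttractorVerdict(
                label="limit_cycle",
                distance_at_end=dists_end[nearest],
                oscillation_amplitude=amp_final,
            )
    return AttractorVerdict(label="undecided", distance_at_end=dists_end[nearest])


def onset_time(traj: Trajectory, big: EquilibriumPoint) -> float | None:
    """Time of the first upward crossing of half the equilibrium tumour load.

    An operational definition of "cancer onset": the first stored time at
    which ``T`` crosses ``0.5 * T_big`` from below (a pulse larger than the
    threshold that dips and later relapses is timed at the relapse), or
    ``None`` if the threshold is never reached from below.  Approximate by
    construction -- onset is read off the trajectory, not an intrinsic event.
    """
    threshold = 0.5 * big.coords.T
    above = traj.states[:, 2] >= threshold
    if above.all():
        return 0.0
    crossings = np.nonzero(above[1:] & ~above[:-1])[0]
    if len(crossings) == 0:
        return None
    return float(traj.times[crossings[0] + 1])
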