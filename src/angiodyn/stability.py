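"""Local stability analysis: Jacobian assembly, spectra and M-matrix checks.

At a steady state with all compartments positive, the balance relations let
the diagonal entries collapse to pure self-limitation terms, giving the
sparse 5x5 Jacobian

    [ -a1*C/k1      0        -b1*C      0       0     ]
    [    0      -a2*E/k2     -g*E       0       0     ]
    [  -b2*T        0      -a3*A*T/k3   0       j1    ]
    [    0         g*T        g*E      -j2      0     ]
    [    0          0         j3        d      -j4    ]

with j1 = a3*T*(1 - T/k3), j2 = mu4 + delta, j3 = eps*A*(1 - A/k4) and
j4 = delta*P/A + eps*A*T/k4.  When the normal cells are displaced (C = 0)
the (1,1) entry is (alpha1 - mu1) - beta1*T and (1,3) vanishes; at the
cancer-free state the spectrum is available in closed form:
{-mu5, -(mu4 + delta), -(mu3 + beta2*C0), -(alpha1 - mu1), -(alpha2 - mu2)}.

For the displaced state the 4x4 block obtained by deleting the first row
and column (negated) can be certified stable without computing eigenvalues:
if a positive diagonal matrix D makes A*D strictly (generalised) diagonally
dominant, all eigenvalues of the block have negative real part.  The
``m_matrix_check`` routine constructs the candidate D and reports the
admissible scaling interval and, where the certificate needs it, the
minimum vessel-expansion rate ``eps`` for which it holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibria import EquilibriumPoint, constraints
from .model_core import ParameterSet, State

__all__ = [
    "StabilityReport",
    "MMatrixReport",
    "jacobian",
    "jacobian_at_state",
    "stability_report",
    "m_matrix_check",
]

#: an equilibrium is marginal when |max Re(lambda)| falls below this (1/day).
#: Near the oscillatory instability the leading real part passes through
#: values of order 1e-7, so the tolerance must sit well below that.
MARGINAL_TOL = 1e-8


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum of the Jacobian at an equilibrium, sorted by descending Re."""

    eigenvalues: tuple[complex, ...]
    classification: str  # stable_node | stable_focus | unstable | marginal

    @property
    def max_real_part(self) -> float:
        return max(ev.real for ev in self.eigenvalues)

    @property
    def has_complex_pair(self) -> bool:
        return any(abs(ev.imag) > MARGINAL_TOL for ev in self.eigenvalues)

    @property
    def is_stable(self) -> bool:
        return self.classification in ("stable_node", "stable_focus")

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [(ev.real, ev.imag) for ev in self.eigenvalues],
            "max_real_part": self.max_real_part,
            "classification": self.classification,
            "has_complex_pair": self.has_complex_pair,
        }


@dataclass(frozen=True)
class MMatrixReport:
    is_m_matrix: bool
    d_vector: tuple[float, ...] | None
    phi: float | None
    phi_n: float
    phi_d: float
    epsilon_min: float | None
    case: str
    assumption_a_vs_k4: str  # observed side of the A-bar vs k4 assumption

    def to_dict(self) -> dict:
        return {
            "is_m_matrix": self.is_m_matrix,
            "d_vector": list(self.d_vector) if self.d_vector else None,
            "phi": self.phi,
            "phi_n": self.phi_n,
            "phi_d": self.phi_d,
            "epsilon_min": self.epsilon_min,
            "case": self.case,
            "assumption_a_vs_k4": self.assumption_a_vs_k4,
        }


def jacobian_at_state(params: ParameterSet, state: State | np.ndarray) -> np.ndarray:
    """Exact Jacobian of the vector field at an arbitrary state."""
    p = params
    C, E, T, P, A = np.asarray(state, dtype=float)
    return np.array(
        [
            [
                p.alpha1 * (1 - 2 * C / p.k1) - p.beta1 * T - p.mu1,
                0.0,
                -p.beta1 * C,
                0.0,
                0.0,
            ],
            [
                0.0,
                p.alpha2 * (1 - 2 * E / p.k2) - p.gamma * T - p.mu2,
                -p.gamma * E,
                0.0,
                0.0,
            ],
            [
                -p.beta2 * T,
                0.0,
                p.alpha3 * A * (1 - 2 * T / p.k3) - p.beta2 * C - p.mu3,
                0.0,
                p.alpha3 * T * (1 - T / p.k3),
            ],
            [0.0, p.gamma * T, p.gamma * E, -(p.delta + p.mu4), 0.0],
            [
                0.0,
                0.0,
                p.eps * A * (1 - A / p.k4),
                p.delta,
                p.eps * T * (1 - 2 * A / p.k4) - p.mu5,
            ],
        ]
    )


def jacobian(params: ParameterSet, eq: EquilibriumPoint | State) -> np.ndarray:
    """Jacobian at a steady state, in the balance-reduced form.

    For an interior equilibrium (all compartments positive) the diagonal is
    written with the balance relations substituted, which is exact at the
    root and numerically cleaner than the raw partial derivatives.  With
    C = 0 the first row is modified accordingly; with T = 0 (cancer-free
    state) the reduced form does not apply and the exact Jacobian is used.
    """
    coords = eq.coords if isinstance(eq, EquilibriumPoint) else State(*eq)
    if not all(math.isfinite(v) for v in coords):
        raise ValueError(f"equilibrium coordinates must be finite, got {coords}")
    p = params
    C, E, T, P, A = coords
    if T == 0.0 or A == 0.0:
        return jacobian_at_state(params, coords)
    j1 = p.alpha3 * T * (1 - T / p.k3)
    j2 = p.mu4 + p.delta
    j3 = p.eps * A * (1 - A / p.k4)
    j4 = p.delta * P / A + p.eps * A * T / p.k4
    jac = np.array(
        [
            [-p.alpha1 * C / p.k1, 0.0, -p.beta1 * C, 0.0, 0.0],
            [0.0, -p.alpha2 * E / p.k2, -p.gamma * E, 0.0, 0.0],
            [-p.beta2 * T, 0.0, -p.alpha3 * A * T / p.k3, 0.0, j1],
            [0.0, p.gamma * T, p.gamma * E, -j2, 0.0],
            [0.0, 0.0, j3, p.delta, -j4],
        ]
    )
    if C == 0.0:
        jac[0, 0] = (p.alpha1 - p.mu1) - p.beta1 * T
        jac[0, 2] = 0.0
    return jac


def _classify(eigenvalues: np.ndarray, tol: float = MARGINAL_TOL) -> str:
    max_re = float(eigenvalues.real.max())
    if abs(max_re) <= tol:
        return "marginal"
    if max_re > tol:
        return "unstable"
    if np.any(np.abs(eigenvalues.imag) > tol):
        return "stable_focus"
    return "stable_node"


def stability_report(
    params: ParameterSet, eq: EquilibriumPoint | State
) -> StabilityReport:
    """Eigenvalues (descending real part) and stability class at a steady state."""
    ev = np.linalg.eigvals(jacobian(params, eq))
    order = np.argsort(-ev.real)
    ev = ev[order]
    return StabilityReport(
        eigenvalues=tuple(complex(v) for v in ev),
        classification=_classify(ev),
    )


def _four_by_four_block(params: ParameterSet, coords: State) -> np.ndarray:
    """The negated (E, T, P, A) Jacobian block used for the dominance test."""
    p = params
    _, E, T, _, A = coords
    Pc = coords.P
    j1 = p.alpha3 * T * (1 - T / p.k3)
    j2 = p.mu4 + p.delta
    j3 = p.eps * A * (1 - A / p.k4)
    j4 = p.delta * Pc / A + p.eps * A * T / p.k4
    return np.array(
        [
            [p.alpha2 * E / p.k2, p.gamma * E, 0.0, 0.0],
            [0.0, p.alpha3 * A * T / p.k3, 0.0, -j1],
            [-p.gamma * T, -p.gamma * E, j2, 0.0],
            [0.0, -j3, -p.delta, j4],
        ]
    )


def m_matrix_check(params: ParameterSet, eq: EquilibriumPoint) -> MMatrixReport:
    """Generalised diagonal-dominance certificate for the 4x4 (E,T,P,A) block.

    Constructs the scaling D = diag(d1, 1, d3, d4) with

        d1 = (gamma*k2 + phi)/alpha2
        d3 = (gamma*k2*(alpha2 - mu2) + (gamma*T + alpha2)*phi)
             / (alpha2*(mu4 + delta))
        d4 = (A - phi)/(k3 - T)

    which satisfies the first three dominance inequalities for any phi > 0;
    the fourth holds iff 0 < phi < phi_n/phi_d.  phi is taken at the
    midpoint of the admissible interval.  phi_n is linear in the vessel
    expansion rate ``eps``, so when it is negative at the current ``eps``
    but increasing, the report carries the threshold ``epsilon_min`` above
    which the certificate applies.
    """
    p = params
    coords = eq.coords
    C, E, T, Pc, A = coords
    if T <= 0 or A <= 0 or E <= 0 or T >= p.k3:
        raise ValueError(
            "the dominance certificate needs a steady state with positive "
            "E, T, A and T < k3"
        )
    cons = constraints(params)
    assumption = "A_bar > k4" if A > p.k4 else ("A_bar < k4" if A < p.k4 else "A_bar = k4")

    j4 = p.delta * Pc / A + p.eps * A * T / p.k4
    phi_n = (
        j4 * A / (p.k3 - T)
        - p.eps / p.k4 * A * (A - p.k4)
        - p.delta * p.gamma * p.k2 * (p.alpha2 - p.mu2) / (p.alpha2 * (p.mu4 + p.delta))
    )
    phi_d = j4 / (p.k3 - T) + p.delta * (p.gamma * T + p.alpha2) / (
        p.alpha2 * (p.mu4 + p.delta)
    )

    # phi_n depends linearly on eps (through j4 and the A*(A - k4) term, with
    # A itself eps-independent at fixed T); solve phi_n(eps) = 0 for the
    # certificate threshold.
    slope = A / p.k4 * (A * T / (p.k3 - T) - (A - p.k4))
    intercept = phi_n - slope * p.eps
    epsilon_min = -intercept / slope if slope > 0 else None
    if epsilon_min is not None and epsilon_min <= 0:
        epsilon_min = None  # certificate holds for every eps >= 0

    if cons.TA < cons.TE:
        # weak epithelial recruitment by the tumour
        case = "1.a" if epsilon_min is None else "1.b.2"
        if epsilon_min is not None and p.eps > epsilon_min:
            case = "1.b.1"
    else:
        case = "2"

    if phi_n <= 0:
        return MMatrixReport(
            is_m_matrix=False,
            d_vector=None,
            phi=None,
            phi_n=float(phi_n),
            phi_d=float(phi_d),
            epsilon_min=epsilon_min,
            case=case,
            assumption_a_vs_k4=assumption,
        )

    phi = 0.5 * phi_n / phi_d
    d1 = (p.gamma * p.k2 + phi) / p.alpha2
    d3 = (p.gamma * p.k2 * (p.alpha2 - p.mu2) + (p.gamma * T + p.alpha2) * phi) / (
        p.alpha2 * (p.mu4 + p.delta)
    )
    d4 = (A - phi) / (p.k3 - T)
    d = np.array([d1, 1.0, d3, d4])

    a = _four_by_four_block(params, coords)
    ok = bool(np.all(np.diag(a) > 0) and np.all(d > 0))
    if ok:
        ad = a * d[np.newaxis, :]
        for i in range(4):
            row = np.abs(ad[i])
            if ad[i, i] <= row.sum() - row[i]:
                ok = False
                break
    return MMatrixReport(
        is_m_matrix=ok,
        d_vector=tuple(float(x) for x in d),
        phi=float(phi),
        phi_n=float(phi_n),
        phi_d=float(phi_d),
        epsilon_min=epsilon_min,
        case=case,
        assumption_a_vs_k4=assumption,
    )
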