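"""Five-compartment solid-tumour growth model with angiogenesis.

The state tracks concentrations (cells per unit volume, "cells/uv") of

* ``C`` -- normal cells of the host organ,
* ``E`` -- epithelial (endothelial) cells of the pre-existing vasculature,
* ``T`` -- tumour (cancer) cells,
* ``P`` -- pre-angiogenesis cells (sprouts that have not yet matured into
  functional vessels; maturation takes ``1/delta`` days on average),
* ``A`` -- angiogenesis cells (the new, tumour-induced vasculature).

Normal and epithelial cells follow logistic growth and do not depend on each
other; tumour growth is driven by the new vasculature ``A`` and inhibited by
normal cells; sprouting transfers mass ``gamma*E*T`` into ``P``, which matures
into ``A`` at rate ``delta``.  Cancer initiation is modelled as an
instantaneous mutation pulse: at ``t = 0`` an amount ``Cm`` of normal cells is
re-assigned to the tumour compartment and the system is integrated forward
from that perturbed cancer-free steady state.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "ParameterSet",
    "State",
    "Preset",
    "PRESETS",
    "load_preset",
    "rhs",
    "rhs_array",
    "pulse_initial_state",
]


@dataclass(frozen=True)
class ParameterSet:
    """The 18 rates and capacities of the growth model.

    Units: growth and mortality rates are per day; ``alpha3`` and ``eps`` are
    per unit concentration per day (growth of T driven by A, and of A driven
    by T); ``beta1``/``beta2`` are the cross-inhibition rates per unit
    concentration per day; ``k1..k4`` are carrying capacities in
    concentration units; ``delta`` is the pre-angiogenesis maturation rate
    (per day); ``gamma`` the epithelial sprouting rate per unit T per day.
    """

    alpha1: float  # intrinsic growth rate of normal cells
    alpha2: float  # intrinsic growth rate of epithelial cells
    alpha3: float  # growth of tumour cells per unit angiogenesis
    eps: float     # growth of angiogenesis cells per unit tumour
    mu1: float
    mu2: float
    mu3: float
    mu4: float
    mu5: float
    k1: float
    k2: float
    k3: float
    k4: float
    delta: float
    gamma: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite: {value}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"carrying capacity {name!r} must be > 0")

    @property
    def trivial_exists(self) -> bool:
        """Whether the cancer-free steady state exists (alpha_i > mu_i)."""
        return self.alpha1 > self.mu1 and self.alpha2 > self.mu2

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ParameterSet":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = names - set(data)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "ParameterSet":
        """Load from a flat JSON or YAML mapping keyed by field name."""
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def replace(self, **overrides: float) -> "ParameterSet":
        return dataclasses.replace(self, **overrides)

    def as_array(self) -> np.ndarray:
        """Parameter vector in field order (used by the compiled integrator)."""
        return np.array(
            [getattr(self, f.name) for f in dataclasses.fields(self)], dtype=np.float64
        )


class State(NamedTuple):
    """Concentrations of the five compartments at one time point."""

    C: float
    E: float
    T: float
    P: float
    A: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=np.float64)

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "State":
        vals = tuple(float(v) for v in values)
        if len(vals) != 5:
            raise ValueError(f"a state has 5 components, got {len(vals)}")
        return cls(*vals)


@dataclass(frozen=True)
class Preset:
    name: str
    params: ParameterSet


#: Benchmark parameter values for an illustrative organ.  The ``fixed``
#: preset lets tumour-compartment capacities be comparable to those of the
#: normal tissue; ``alternative`` shrinks the tumour/vessel capacities to a
#: more realistic relative size (and rescales the coupled rates).
_FIXED = ParameterSet(
    alpha1=0.1,
    alpha2=0.1,
    alpha3=0.2,
    eps=0.01,
    mu1=0.01,
    mu2=0.05,
    mu3=0.05,
    mu4=0.01,
    mu5=0.01,
    k1=10.0,
    k2=20.0,
    k3=5.0,
    k4=1.0,
    delta=0.1,
    gamma=0.01,
    beta1=0.01,
    beta2=0.01,
)

_ALTERNATIVE = _FIXED.replace(alpha3=5.0, eps=0.1, mu3=0.005, k3=0.1, k4=0.2, gamma=0.02)

PRESETS: dict[str, Preset] = {
    "fixed": Preset("fixed", _FIXED),
    "alternative": Preset("alternative", _ALTERNATIVE),
}


def load_preset(name: str) -> ParameterSet:
    """Return one of the packaged parameter presets by name."""
    try:
        return PRESETS[name].params
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        ) from None


def rhs(state: State | Iterable[float], params: ParameterSet) -> np.ndarray:
    """Time derivative (dC, dE, dT, dP, dA)/dt of the growth model.

    dC/dt = alpha1*C*(1 - C/k1) - beta1*C*T - mu1*C
    dE/dt = alpha2*E*(1 - E/k2) - gamma*E*T - mu2*E
    dT/dt = alpha3*A*T*(1 - T/k3) - beta2*C*T - mu3*T
    dP/dt = gamma*E*T - (delta + mu4)*P
    dA/dt = delta*P + eps*T*A*(1 - A/k4) - mu5*A
    """
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state components must be finite, got {y}")
    return rhs_array(y, params.as_array())


def rhs_array(y: np.ndarray, pv: np.ndarray) -> np.ndarray:
    """`rhs` on raw arrays (no validation); ``pv`` in ParameterSet field order."""
    a1, a2, a3, eps, m1, m2, m3, m4, m5, k1, k2, k3, k4, dlt, gam, b1, b2 = pv
    C, E, T, P, A = y
    return np.array(
        [
            a1 * C * (1 - C / k1) - b1 * C * T - m1 * C,
            a2 * E * (1 - E / k2) - gam * E * T - m2 * E,
            a3 * A * T * (1 - T / k3) - b2 * C * T - m3 * T,
            gam * E * T - (dlt + m4) * P,
            dlt * P + eps * T * A * (1 - A / k4) - m5 * A,
        ]
    )


def pulse_initial_state(
    params: ParameterSet, cm: float, *, full_c0: bool = False
) -> State:
    """Initial state after an instantaneous mutation pulse of size ``cm``.

    Starting from the cancer-free equilibrium (C0, E0, 0, 0, 0), an amount
    ``cm`` of normal cells is converted into tumour cells at ``t = 0``:
    the state becomes ``(C0 - cm, E0, cm, 0, 0)``.  When ``cm > C0`` the
    conversion cannot be taken out of the normal compartment, and the normal
    cells are left at their equilibrium value ``C0``.  ``full_c0=True``
    forces ``C(0) = C0`` regardless of ``cm`` (tumour cells arriving on top
    of an undisturbed organ), which is how several of the benchmark runs for
    the ``fixed`` preset were set up.
    """
    if cm < 0:
        raise ValueError(f"pulse size cm must be >= 0, got {cm}")
    if not params.trivial_exists:
        raise ValueError(
            "cancer-free equilibrium does not exist "
            "(requires alpha1 > mu1 and alpha2 > mu2)"
        )
    c0 = params.k1 * (params.alpha1 - params.mu1) / params.alpha1
    e0 = params.k2 * (params.alpha2 - params.mu2) / params.alpha2
    c_init = c0 if (full_c0 or cm > c0) else c0 - cm
    return State(c_init, e0, cm, 0.0, 0.0)
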