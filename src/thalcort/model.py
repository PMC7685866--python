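"""Core thalamocortical neural-mass model.

Five interacting populations: cortical pyramidal cells (PY), two inhibitory
interneuron populations with distinct time scales (I1, I2) forming a
disinhibition circuit, the thalamic relay nucleus (TC), and the thalamic
reticular nucleus (RE).  TC projects onto both interneuron populations
(feedforward inhibition, couplings C11/C12) as well as onto PY (C9), while
the TC->PY coupling C7 serves as a proxy for impaired astrocytic glutamate
uptake: the weaker the uptake, the larger C7.

Cortical activity passes through a steep sigmoid transfer function
``f(x) = 1/(1 + eps^(-x))`` and thalamic activity through an affine transfer
``g(y) = a*y + b``.  Each population relaxes toward its external input level
``h`` on its own time scale ``sigma``:

    PY' = sigma1*(hPY - PY + C1*f(PY) - C3*f(I1) + C9*f(TC) - Ciny*f(I2))
    I1' = sigma2*(hI1 - I1 + C2*f(PY) - Cin1*f(I2) + C11*f(TC))
    I2' = sigma3*(hI2 - I2 + C10*f(PY) - Cin2*f(I1) + C12*f(TC))
    TC' = sigma4*(hTC - TC - C6*g(RE) + C7*f(PY) + u2(t))
    RE' = sigma5*(hRE - RE - C4*g(RE) + C5*g(TC) + C8*f(PY) + u1(t))

u1 and u2 are external stimulation inputs to RE and TC respectively.  Time
is measured in seconds, so oscillation frequencies of the model are read
directly in Hz.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "STATE_NAMES",
    "sigmoid_transfer",
    "sigmoid_transfer_deriv",
    "linear_transfer",
    "vector_field",
    "jacobian",
]

#: order of the state-vector components everywhere in the package
STATE_NAMES = ("PY", "I1", "I2", "TC", "RE")


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the model with standard default values.

    ``sigma*`` are per-second relaxation rates, ``h*`` tonic external input
    levels, ``C1..C12`` inter-population coupling strengths, ``Cin1``,
    ``Cin2``, ``Ciny`` the intra-cortical inhibitory couplings of the
    disinhibition circuit, ``epsilon`` the sigmoid steepness base, and
    ``a``/``b`` the slope/intercept of the affine thalamic transfer.
    """

    hPY: float = -0.3
    hI1: float = -3.4
    hI2: float = -2.0
    hTC: float = -2.5
    hRE: float = -4.5
    sigma1: float = 26.0
    sigma2: float = 32.5
    sigma3: float = 30.0
    sigma4: float = 2.6
    sigma5: float = 2.6
    epsilon: float = 2.5e5
    a: float = 2.8
    b: float = 0.5
    C1: float = 1.8
    C2: float = 4.0
    C3: float = 1.5
    C4: float = 0.1
    C5: float = 8.0
    C6: float = 1.0
    C7: float = 2.0
    C8: float = 2.0
    C9: float = 1.0
    C10: float = 2.0
    C11: float = 0.1
    C12: float = 0.05
    Cin1: float = 0.1
    Cin2: float = 0.3
    Ciny: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2", "sigma3", "sigma4", "sigma5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon <= 1:
            raise ValueError("epsilon must exceed 1 for an increasing sigmoid")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **changes)

    # -- flat key-value serialization ------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        """Write the parameter set as a flat YAML/JSON key-value file."""
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    def as_array(self) -> np.ndarray:
        """Pack into a float64 vector in field-declaration order (for the
        compiled integrator core)."""
        return np.array(
            [getattr(self, f.name) for f in dataclasses.fields(self)],
            dtype=np.float64,
        )


#: index of each parameter within :meth:`ModelParameters.as_array`
PARAM_INDEX = {
    f.name: i for i, f in enumerate(dataclasses.fields(ModelParameters))
}


def _check_finite(x, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def sigmoid_transfer(x, epsilon: float):
    """Sigmoid transfer ``f(x) = 1/(1 + epsilon**(-x))``.

    Evaluated in the overflow-safe form ``1/(1 + exp(-x*ln(epsilon)))``;
    with the default steepness base of 2.5e5 the naive power overflows for
    moderately negative ``x``.  Accepts scalars or arrays.
    """
    _check_finite(x, "x")
    if epsilon <= 1:
        raise ValueError("epsilon must exceed 1")
    z = np.multiply(x, math.log(epsilon))
    # piecewise-stable logistic: never exponentiates a large positive number
    out = np.where(
        z >= 0,
        1.0 / (1.0 + np.exp(-np.abs(z))),
        np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))),
    )
    return float(out) if np.isscalar(x) else out


def sigmoid_transfer_deriv(x, epsilon: float):
    """Derivative of the sigmoid transfer, ``f'(x) = ln(eps)*f(x)*(1-f(x))``."""
    fx = sigmoid_transfer(x, epsilon)
    return math.log(epsilon) * fx * (1.0 - fx)


def linear_transfer(y, a: float, b: float):
    """Affine thalamic transfer ``g(y) = a*y + b``."""
    _check_finite(y, "y")
    return a * y + b


def vector_field(
    state, params: ModelParameters, u1: float = 0.0, u2: float = 0.0
) -> np.ndarray:
    """Right-hand side of the model at a given state.

    ``state`` is the 5-vector (PY, I1, I2, TC, RE); ``u1``/``u2`` are the
    instantaneous stimulation inputs to RE and TC.  Each time scale
    multiplies its population's entire bracketed expression, stimulus term
    included.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError("state must have exactly 5 components")
    _check_finite(state, "state")
    _check_finite([u1, u2], "stimulus inputs")
    p = params
    PY, I1, I2, TC, RE = state
    fPY = sigmoid_transfer(PY, p.epsilon)
    fI1 = sigmoid_transfer(I1, p.epsilon)
    fI2 = sigmoid_transfer(I2, p.epsilon)
    fTC = sigmoid_transfer(TC, p.epsilon)
    gTC = linear_transfer(TC, p.a, p.b)
    gRE = linear_transfer(RE, p.a, p.b)
    return np.array(
        [
            p.sigma1 * (p.hPY - PY + p.C1 * fPY - p.C3 * fI1 + p.C9 * fTC - p.Ciny * fI2),
            p.sigma2 * (p.hI1 - I1 + p.C2 * fPY - p.Cin1 * fI2 + p.C11 * fTC),
            p.sigma3 * (p.hI2 - I2 + p.C10 * fPY - p.Cin2 * fI1 + p.C12 * fTC),
            p.sigma4 * (p.hTC - TC - p.C6 * gRE + p.C7 * fPY + u2),
            p.sigma5 * (p.hRE - RE - p.C4 * gRE + p.C5 * gTC + p.C8 * fPY + u1),
        ]
    )


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field` with respect to the state.

    Entry (i, j) is d(RHS_i)/d(state_j).  Independent of u1/u2 since the
    stimulus enters additively.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise ValueError("state must have exactly 5 components")
    _check_finite(state, "state")
    p = params
    PY, I1, I2, TC, RE = state
    dPY = sigmoid_transfer_deriv(PY, p.epsilon)
    dI1 = sigmoid_transfer_deriv(I1, p.epsilon)
    dI2 = sigmoid_transfer_deriv(I2, p.epsilon)
    dTC = sigmoid_transfer_deriv(TC, p.epsilon)
    J = np.zeros((5, 5))
    # PY row
    J[0, 0] = p.sigma1 * (-1.0 + p.C1 * dPY)
    J[0, 1] = -p.sigma1 * p.C3 * dI1
    J[0, 2] = -p.sigma1 * p.Ciny * dI2
    J[0, 3] = p.sigma1 * p.C9 * dTC
    # I1 row
    J[1, 0] = p.sigma2 * p.C2 * dPY
    J[1, 1] = -p.sigma2
    J[1, 2] = -p.sigma2 * p.Cin1 * dI2
    J[1, 3] = p.sigma2 * p.C11 * dTC
    # I2 row
    J[2, 0] = p.sigma3 * p.C10 * dPY
    J[2, 1] = -p.sigma3 * p.Cin2 * dI1
    J[2, 2] = -p.sigma3
    J[2, 3] = p.sigma3 * p.C12 * dTC
    # TC row
    J[3, 0] = p.sigma4 * p.C7 * dPY
    J[3, 3] = -p.sigma4
    J[3, 4] = -p.sigma4 * p.C6 * p.a
    # RE row
    J[4, 0] = p.sigma5 * p.C8 * dPY
    J[4, 3] = p.sigma5 * p.C5 * p.a
    J[4, 4] = p.sigma5 * (-1.0 - p.C4 * p.a)
    return J
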