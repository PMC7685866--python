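"""Equilibrium continuation, linear stability, and bifurcation location.

Equilibria of the model are located by multi-start Newton iteration on the
vector field, tracked along a one-parameter axis by warm-starting each step
from the previous roots, and classified by the eigenvalues of the analytic
Jacobian.  A Hopf point is a sign change of the leading complex eigenvalue
pair's real part along the branch, refined by bisection; the sub- versus
supercritical character is decided by a simulation probe just past the
crossing (a small-amplitude cycle growing from the equilibrium marks a
supercritical Hopf, an immediate jump to a large pre-existing cycle a
subcritical one).

Folds of limit cycles are not continued directly.  Instead,
:func:`oscillation_boundaries` locates the parameter values where sustained
oscillation from the fixed all-zero initial condition switches on or off —
in the bistable windows of this model, the zero state sits on the
limit-cycle side of the separatrix, so these switch points approximate the
fold-of-cycle locations that delimit the oscillatory windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

from .model import ModelParameters, jacobian, vector_field
from .simulate import SimulationConfig, cortical_mean, integrate
from .stimulation import NoStimulus, StepPulse, StimulusProtocol

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "BifurcationKind",
    "BifurcationPoint",
    "RESIDUAL_TOL",
    "find_equilibria",
    "stability",
    "detect_hopf",
    "oscillation_boundaries",
]

RESIDUAL_TOL = 1e-9
MERGE_TOL = 1e-6


class BifurcationKind(enum.Enum):
    HOPF_SUPER = "hopf_super"
    HOPF_SUB = "hopf_sub"
    OSCILLATION_ONSET = "oscillation_onset"
    OSCILLATION_OFFSET = "oscillation_offset"


@dataclass(frozen=True)
class Equilibrium:
    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stable: bool

    @property
    def leading_complex_real(self) -> float:
        """Largest real part among complex eigenvalues (-inf if all real)."""
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > 1e-9]
        return float(cplx.real.max()) if len(cplx) else -np.inf


@dataclass(frozen=True)
class EquilibriumBranch:
    parameter: str
    values: np.ndarray
    equilibria: list  # per value: list of Equilibrium
    warnings: tuple = ()


@dataclass(frozen=True)
class BifurcationPoint:
    kind: BifurcationKind
    parameter: str
    location: float
    eigenvalue_pair: Optional[complex] = None


def _make_equilibrium(x: np.ndarray, params, u1, u2) -> Equilibrium:
    res = float(np.linalg.norm(vector_field(x, params, u1, u2)))
    ev = np.linalg.eigvals(jacobian(x, params))
    return Equilibrium(np.asarray(x, float), res, ev, bool(np.all(ev.real < 0)))


def find_equilibria(params: ModelParameters, u1: float = 0.0, u2: float = 0.0,
                    box: tuple = (-6.0, 4.0), n_grid: int = 3,
                    n_random: int = 60, seed: int = 0,
                    extra_starts: Optional[Sequence[np.ndarray]] = None,
                    ) -> list[Equilibrium]:
    """All equilibria found by multi-start Newton search in a state box.

    Starts on a ``n_grid**5`` lattice over ``box`` plus ``n_random`` draws
    from a seeded generator; converged roots are kept only if the residual
    norm is below 1e-9 and merged when closer than 1e-6.  An empty list
    means no root was found in the box, which is a legitimate outcome.
    """
    rng = np.random.default_rng(seed)
    axes = np.linspace(box[0], box[1], n_grid)
    starts = [np.array(g) for g in np.stack(
        np.meshgrid(*([axes] * 5)), axis=-1).reshape(-1, 5)]
    starts += [rng.uniform(box[0], box[1], 5) for _ in range(n_random)]
    if extra_starts is not None:
        starts = [np.asarray(s, float) for s in extra_starts] + starts
    roots: list[np.ndarray] = []
    for s in starts:
        sol = root(lambda y: vector_field(y, params, u1, u2), s,
                   jac=lambda y: jacobian(y, params), tol=1e-13)
        # accept by residual: hybr sometimes flags a fully converged root as
        # "not making good progress"
        if np.linalg.norm(vector_field(sol.x, params, u1, u2)) > RESIDUAL_TOL:
            continue
        if any(np.linalg.norm(sol.x - r) < MERGE_TOL for r in roots):
            continue
        roots.append(sol.x)
    return [_make_equilibrium(r, params, u1, u2) for r in roots]


def stability(eq_state, params: ModelParameters, u1: float = 0.0,
              u2: float = 0.0, residual_tol: float = 1e-6) -> Equilibrium:
    """Eigenvalues and stability flag of a state that must be an equilibrium."""
    eq_state = np.asarray(eq_state, dtype=float)
    res = float(np.linalg.norm(vector_field(eq_state, params, u1, u2)))
    if res > residual_tol:
        raise ValueError(f"state is not an equilibrium (residual {res:.3g})")
    return _make_equilibrium(eq_state, params, u1, u2)


# --------------------------------------------------------------------------
# one-parameter machinery

def _set_axis(axis: str, value: float, params: ModelParameters):
    """Resolve an axis name to (params, u1, u2). 'A_sps' means a constant
    additive input on the RE equation."""
    if axis == "A_sps":
        return params, float(value), 0.0
    if axis == "A_tcs":
        return params, 0.0, float(value)
    try:
        return params.replace(**{axis: float(value)}), 0.0, 0.0
    except TypeError:
        raise ValueError(f"unknown continuation axis {axis!r}") from None


def _track_root(axis, value, params, x_prev) -> Optional[Equilibrium]:
    p, u1, u2 = _set_axis(axis, value, params)
    sol = root(lambda y: vector_field(y, p, u1, u2), x_prev,
               jac=lambda y: jacobian(y, p), tol=1e-13)
    if np.linalg.norm(vector_field(sol.x, p, u1, u2)) > RESIDUAL_TOL:
        return None
    return _make_equilibrium(sol.x, p, u1, u2)


def track_branch(axis: str, values: Sequence[float], params: ModelParameters,
                 seed_state: Optional[np.ndarray] = None,
                 reseed_every: int = 20, seed: int = 0) -> EquilibriumBranch:
    """Warm-started equilibrium tracking along one axis.

    The branch is seeded by a full multi-start search at the first value (or
    by ``seed_state``), then each subsequent value warm-starts Newton from
    the previous roots; a fresh multi-start search every ``reseed_every``
    steps picks up branches that come into existence mid-range.
    """
    values = np.asarray(list(values), dtype=float)
    per_value: list[list[Equilibrium]] = []
    warnings: list[str] = []
    prev_states: list[np.ndarray] = (
        [np.asarray(seed_state, float)] if seed_state is not None else [])
    for i, v in enumerate(values):
        p, u1, u2 = _set_axis(axis, v, params)
        found: list[Equilibrium] = []
        for x in prev_states:
            eq = _track_root(axis, v, params, x)
            if eq is not None and not any(
                    np.linalg.norm(eq.state - f.state) < MERGE_TOL for f in found):
                found.append(eq)
        if i % reseed_every == 0 or not found:
            for eq in find_equilibria(p, u1, u2, seed=seed):
                if not any(np.linalg.norm(eq.state - f.state) < MERGE_TOL
                           for f in found):
                    found.append(eq)
        if not found:
            warnings.append(f"branch lost at {axis}={v:.6g}")
        per_value.append(found)
        if found:
            prev_states = [e.state for e in found]
    return EquilibriumBranch(axis, values, per_value, tuple(warnings))


def _probe_amplitude(axis, value, params, eq_state, duration=30.0,
                     perturbation=0.05) -> float:
    """Oscillation amplitude reached from a perturbed equilibrium
    (classification probe for Hopf criticality).

    The perturbation must be large enough to escape the slow linear
    dynamics near the crossing within the probe window, yet small enough
    to stay inside the basin of a small supercritical cycle."""
    p, u1, u2 = _set_axis(axis, value, params)
    protocol = StepPulse(A_sps=u1, t_on=0.0) if u1 else NoStimulus()
    cfg = SimulationConfig(
        params=p, protocol=protocol, duration=duration,
        initial_state=tuple(np.asarray(eq_state) + perturbation),
    )
    cm = cortical_mean(integrate(cfg))
    w = cm[int(2 * duration / 3 * cfg.fs):]
    return float(w.max() - w.min())


def detect_hopf(axis: str, prange: tuple, params: Optional[ModelParameters] = None,
                n_scan: int = 101, refine_tol: float = 1e-4,
                classify: bool = True, seed: int = 0,
                ) -> list[BifurcationPoint]:
    """Hopf points along one axis by eigenvalue sign-crossing and bisection.

    Scans ``n_scan`` points of ``prange`` with warm-started equilibrium
    tracking, watching the real part of the leading complex eigenvalue pair
    on each tracked branch; each sign change is bisected to ``refine_tol``
    in the parameter.  Returns an empty list when no crossing occurs.
    """
    params = params if params is not None else ModelParameters()
    lo, hi = float(prange[0]), float(prange[1])
    if not hi > lo:
        raise ValueError("range must be non-degenerate")
    values = np.linspace(lo, hi, n_scan)
    branch = track_branch(axis, values, params, seed=seed)

    points: list[BifurcationPoint] = []
    # follow the principal branch (nearest-state matching step to step)
    prev: Optional[Equilibrium] = None
    prev_v: Optional[float] = None
    for v, eqs in zip(branch.values, branch.equilibria):
        if not eqs:
            prev, prev_v = None, None
            continue
        if prev is None:
            cur = eqs[0]
        else:
            cur = min(eqs, key=lambda e: np.linalg.norm(e.state - prev.state))
        if prev is not None:
            r0, r1 = prev.leading_complex_real, cur.leading_complex_real
            if np.isfinite(r0) and np.isfinite(r1) and r0 * r1 < 0:
                loc, pair = _bisect_crossing(axis, prev_v, v, params,
                                             prev.state, refine_tol)
                if loc is not None:
                    kind = BifurcationKind.HOPF_SUB
                    if classify:
                        kind = _classify_hopf(axis, loc, params, r1 > 0,
                                              pair_state=pair[1])
                    points.append(BifurcationPoint(kind, axis, loc, pair[0]))
        prev, prev_v = cur, v
    return points


def _bisect_crossing(axis, lo, hi, params, x_start, tol):
    eq_lo = _track_root(axis, lo, params, x_start)
    if eq_lo is None:
        return None, (None, None)
    sign_lo = eq_lo.leading_complex_real < 0
    x = eq_lo.state
    eq_mid = eq_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        eq_mid = _track_root(axis, mid, params, x)
        if eq_mid is None:
            return None, (None, None)
        x = eq_mid.state
        if (eq_mid.leading_complex_real < 0) == sign_lo:
            lo = mid
        else:
            hi = mid
    ev = eq_mid.eigenvalues
    cplx = ev[(np.abs(ev.imag) > 1e-9)]
    pair = complex(cplx[np.argmax(cplx.real)]) if len(cplx) else None
    return 0.5 * (lo + hi), (pair, eq_mid.state)


def _classify_hopf(axis, loc, params, unstable_above: bool, pair_state,
                   offset: float = 0.02, small_amp: float = 0.1) -> BifurcationKind:
    """Probe just past the crossing on the unstable-equilibrium side: a
    small-amplitude cycle indicates a supercritical Hopf, a jump to a
    large-amplitude attractor a subcritical one."""
    side = 1.0 if unstable_above else -1.0
    probe = loc + side * offset
    eq = _track_root(axis, probe, params, pair_state)
    state = eq.state if eq is not None else pair_state
    amp = _probe_amplitude(axis, probe, params, state)
    return (BifurcationKind.HOPF_SUPER if amp < small_amp
            else BifurcationKind.HOPF_SUB)


# --------------------------------------------------------------------------
# simulation-based oscillation boundaries

def _oscillates(axis, value, params, protocol, config, discard, tol) -> bool:
    if axis in ("A_sps", "A_tcs"):
        p = params
        proto = StepPulse(A_sps=float(value), t_on=0.0)
    else:
        p = params.replace(**{axis: float(value)})
        proto = protocol
    cfg = SimulationConfig(params=p, protocol=proto,
                           duration=config.duration, dt=config.dt,
                           initial_state=config.initial_state)
    cm = cortical_mean(integrate(cfg))
    w = cm[int(discard * cfg.fs):]
    return float(w.max() - w.min()) > tol


def oscillation_boundaries(axis: str, prange: tuple, step: float,
                           params: Optional[ModelParameters] = None,
                           protocol: Optional[StimulusProtocol] = None,
                           config: Optional[SimulationConfig] = None,
                           discard: float = 10.0,
                           amplitude_tol: float = 0.01,
                           resolution: float = 0.005,
                           ) -> list[BifurcationPoint]:
    """Parameter values where sustained oscillation from the zero state
    switches on or off, bisected to ``resolution``.

    In bistable windows these switch points approximate the fold-of-cycle
    locations bounding the oscillatory regime.  An empty list means the
    oscillation indicator never switched inside the range.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    params = params if params is not None else ModelParameters()
    protocol = protocol if protocol is not None else NoStimulus()
    config = config if config is not None else SimulationConfig()
    lo, hi = float(prange[0]), float(prange[1])
    values = np.arange(lo, hi + 0.5 * step, step)
    flags = [_oscillates(axis, v, params, protocol, config, discard,
                         amplitude_tol) for v in values]
    points: list[BifurcationPoint] = []
    for (v0, f0), (v1, f1) in zip(zip(values, flags), zip(values[1:], flags[1:])):
        if f0 == f1:
            continue
        a, b = v0, v1
        while b - a > resolution:
            mid = 0.5 * (a + b)
            if _oscillates(axis, mid, params, protocol, config, discard,
                           amplitude_tol) == f0:
                a = mid
            else:
                b = mid
        kind = (BifurcationKind.OSCILLATION_ONSET if f1
                else BifurcationKind.OSCILLATION_OFFSET)
        points.append(BifurcationPoint(kind, axis, 0.5 * (a + b)))
    return points
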