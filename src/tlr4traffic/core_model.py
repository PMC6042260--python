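"""Dynamical core: the three-compartment TLR4 trafficking ODE.

The model tracks fold-change deviations of Toll-like receptor 4 (TLR4)
concentration in three cellular pools:

* ``x`` — TLR4 in the trans-Golgi network plus the endosomal recycling
  compartment (the intracellular reservoir),
* ``y`` — TLR4 in the early-endosome / endolysosome system,
* ``z`` — TLR4 on the cell surface,

coupled through five first-order trafficking rates::

    x' = phi*x - y*z
    y' = x - (beta + alpha)*y
    z' = x*y - (gamma - sigma)*z

``phi`` is the rate of *tlr4* mRNA production and acts as the clinical
severity / bifurcation parameter; ``beta`` (endosome → lysosome),
``alpha`` (endosome → recycling compartment), ``gamma`` (surface → Golgi)
and ``sigma`` (surface → endosomes) are held fixed at their calibrated
baseline values.

The system is equivariant under ``(x, y, z) -> (-x, -y, z)``; besides the
origin it has a symmetry-related pair of equilibria whose linear stability
is lost at the Routh–Hurwitz boundary ``phi* = (beta+alpha+gamma-sigma)/3``
through a Hopf bifurcation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TrafficParams",
    "State",
    "Trajectory",
    "FixedPoint",
    "IntegrationConfig",
    "DivergenceError",
    "FIG2_BASE",
    "DEFAULT_INIT",
    "vector_field",
    "jacobian",
    "fixed_points",
    "hopf_threshold",
    "integrate",
]

#: Residual bound certified for returned equilibria.
EQUILIBRIUM_RESIDUAL_TOL = 1e-10


class DivergenceError(RuntimeError):
    """Raised when a trajectory exceeds the overflow guard.

    Carries the time at which the guard tripped in ``t_fail``.
    """

    def __init__(self, t_fail: float, guard: float):
        self.t_fail = float(t_fail)
        self.guard = float(guard)
        super().__init__(
            f"trajectory exceeded |component| > {guard:g} at t = {t_fail:.6g}"
        )


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class TrafficParams:
    """The five trafficking rate constants (arbitrary inverse time units).

    ``gamma - sigma`` must be positive so the surface pool relaxes
    (dissipative ``z`` dynamics), and ``beta + alpha`` must be positive so
    the endosomal pool drains; both are checked at construction.
    """

    phi: float
    beta: float
    alpha: float
    gamma: float
    sigma: float

    def __post_init__(self) -> None:
        vals = (self.phi, self.beta, self.alpha, self.gamma, self.sigma)
        _require_finite("rate", *vals)
        if any(v < 0 for v in vals):
            raise ValueError(f"all rates must be >= 0, got {vals}")
        if self.gamma - self.sigma <= 0:
            raise ValueError(
                f"gamma - sigma must be > 0 (got {self.gamma - self.sigma:g}): "
                "the surface-pool relaxation term would not be dissipative"
            )
        if self.beta + self.alpha <= 0:
            raise ValueError("beta + alpha must be > 0")

    @property
    def endosome_exit(self) -> float:
        """Combined endosomal exit rate B = beta + alpha."""
        return self.beta + self.alpha

    @property
    def surface_relaxation(self) -> float:
        """Net surface relaxation rate G = gamma - sigma."""
        return self.gamma - self.sigma

    def with_phi(self, phi: float) -> "TrafficParams":
        """Copy with a different mRNA-production rate (the varied parameter)."""
        return TrafficParams(phi, self.beta, self.alpha, self.gamma, self.sigma)


#: Baseline rate set calibrated to give low-amplitude steady-state
#: oscillations of TLR4 in unstimulated cells.
FIG2_BASE = TrafficParams(phi=1.2, beta=3.6, alpha=1.2, gamma=2.4, sigma=1.3)


@dataclass(frozen=True)
class State:
    """TLR4 fold-change deviations in (Golgi+recycling, endosomes, surface).

    Components may be negative: they are deviations in fold-change units,
    not absolute receptor copy numbers, and the mirrored equilibrium has
    negative ``x`` and ``y``.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        _require_finite("state component", self.x, self.y, self.z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def mirrored(self) -> "State":
        """Image under the model symmetry (x, y, z) -> (-x, -y, z)."""
        return State(-self.x, -self.y, self.z)


#: Default initial condition: all three pools low and slightly positive,
#: off the origin (the origin is an equilibrium, unstable along x for phi>0).
DEFAULT_INIT = State(0.1, 0.1, 0.1)


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered solution sample: ``states[i]`` at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3), columns x, y, z
    params: TrafficParams

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)
        if t.ndim != 1 or s.shape != (t.size, 3):
            raise ValueError(f"shape mismatch: times {t.shape}, states {s.shape}")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    def final_state(self) -> State:
        return State(*self.states[-1])

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (used to drop burn-in)."""
        keep = self.times >= t0
        return Trajectory(self.times[keep], self.states[keep], self.params)


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium with its Jacobian eigenvalues and stability flag."""

    state: State
    eigenvalues: tuple[complex, complex, complex]
    stable: bool

    @property
    def max_real_part(self) -> float:
        return max(ev.real for ev in self.eigenvalues)


@dataclass(frozen=True)
class IntegrationConfig:
    """Numerical integration settings.

    Tight default tolerances (rtol 1e-9, atol 1e-12) because the regime
    classifier is sensitive to slow amplitude trends; ``dt`` is the uniform
    output grid spacing, not the internal step.  The overflow guard
    distinguishes genuine blow-up from bounded chaotic orbits.
    """

    rtol: float = 1e-9
    atol: float = 1e-12
    dt: float = 0.01
    method: str = "RK45"
    overflow: float = 1e6


# ---------------------------------------------------------------------------
# Vector field and Jacobian
# ---------------------------------------------------------------------------

def vector_field(state: State, params: TrafficParams) -> tuple[float, float, float]:
    """Right-hand side (x', y', z') of the trafficking equations at ``state``."""
    x, y, z = state.x, state.y, state.z
    return (
        params.phi * x - y * z,
        x - params.beta * y - params.alpha * y,
        x * y - z * (params.gamma - params.sigma),
    )


def _rhs(params: TrafficParams):
    phi, b, g = params.phi, params.endosome_exit, params.surface_relaxation

    def f(t, s):
        x, y, z = s
        return (phi * x - y * z, x - b * y, x * y - g * z)

    return f


def jacobian(state: State, params: TrafficParams) -> np.ndarray:
    """3x3 matrix of partial derivatives of the right-hand side.

    Its trace, ``phi - (beta+alpha) - (gamma-sigma)``, is state-independent;
    a negative trace makes the flow volume-contracting (dissipative).
    """
    x, y, z = state.x, state.y, state.z
    return np.array(
        [
            [params.phi, -z, -y],
            [1.0, -(params.beta + params.alpha), 0.0],
            [y, x, -(params.gamma - params.sigma)],
        ]
    )


# ---------------------------------------------------------------------------
# Equilibria and linear stability
# ---------------------------------------------------------------------------

def _make_fixed_point(state: State, params: TrafficParams) -> FixedPoint:
    residual = np.linalg.norm(vector_field(state, params))
    if residual > EQUILIBRIUM_RESIDUAL_TOL:
        raise AssertionError(
            f"equilibrium residual {residual:g} exceeds {EQUILIBRIUM_RESIDUAL_TOL:g}"
        )
    eig = np.linalg.eigvals(jacobian(state, params))
    eig = tuple(sorted((complex(ev) for ev in eig), key=lambda c: -c.real))
    return FixedPoint(state=state, eigenvalues=eig, stable=all(ev.real < 0 for ev in eig))


def fixed_points(params: TrafficParams) -> list[FixedPoint]:
    """All equilibria: the origin plus, for phi > 0, a symmetric pair.

    Setting the right-hand sides to zero gives y = x/B from the endosome
    balance and z = xy/G from the surface balance (B = beta+alpha,
    G = gamma-sigma); substituting into phi*x = y*z leaves y^2 = phi*G, so

        y* = sqrt(phi*G),  x* = B*y*,  z* = B*phi,

    together with its mirror image (-x*, -y*, z*).  Each returned point is
    verified to have vector-field norm <= 1e-10.
    """
    pts = [_make_fixed_point(State(0.0, 0.0, 0.0), params)]
    if params.phi > 0:
        b, g = params.endosome_exit, params.surface_relaxation
        y_star = math.sqrt(params.phi * g)
        x_star = b * y_star
        z_star = b * params.phi
        pts.append(_make_fixed_point(State(x_star, y_star, z_star), params))
        pts.append(_make_fixed_point(State(-x_star, -y_star, z_star), params))
    return pts


def hopf_threshold(params: TrafficParams) -> float:
    """Critical mRNA-production rate phi* = (beta+alpha+gamma-sigma)/3.

    At the nonzero equilibria the characteristic polynomial is
    ``lam^3 + (B+G-phi) lam^2 + B*G lam + 2*B*G*phi`` with B = beta+alpha,
    G = gamma-sigma.  The Routh–Hurwitz condition for all roots in the left
    half-plane reduces to ``(B+G-phi)*B*G > 2*B*G*phi``, i.e.
    ``phi < (B+G)/3``; equality is the Hopf point where a complex pair
    crosses the imaginary axis and the equilibria lose stability.
    """
    return (params.endosome_exit + params.surface_relaxation) / 3.0


# ---------------------------------------------------------------------------
# Numerical integration
# ---------------------------------------------------------------------------

def integrate(
    params: TrafficParams,
    init: State = DEFAULT_INIT,
    t_end: float = 200.0,
    config: IntegrationConfig = IntegrationConfig(),
) -> Trajectory:
    """Integrate the trafficking ODE from ``init`` over [0, t_end].

    Deterministic given identical inputs; returns states on the uniform
    grid ``0, dt, 2*dt, ..., t_end``.  Raises :class:`DivergenceError`
    naming the failing time if any component exceeds ``config.overflow``.
    """
    if not (t_end > 0):
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    guard = config.overflow

    def overflow_event(t, s):
        return guard - float(np.max(np.abs(s)))

    overflow_event.terminal = True
    overflow_event.direction = -1

    n = int(round(t_end / config.dt))
    t_eval = np.linspace(0.0, t_end, n + 1)
    sol = solve_ivp(
        _rhs(params),
        (0.0, t_end),
        init.as_array(),
        method=config.method,
        rtol=config.rtol,
        atol=config.atol,
        t_eval=t_eval,
        events=overflow_event,
        dense_output=False,
    )
    if sol.t_events and len(sol.t_events[0]):
        raise DivergenceError(sol.t_events[0][0], guard)
    if not sol.success:
        raise DivergenceError(sol.t[-1] if sol.t.size else 0.0, guard)
    return Trajectory(sol.t, sol.y.T.copy(), params)
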