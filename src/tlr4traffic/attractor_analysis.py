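"""Long-run orbit classification, basin probing, Lyapunov estimate, phi sweep.

The trafficking model has three clinically meaningful behaviours: orbits
that settle onto one of the symmetric equilibria (resolution), sustained
oscillation around a single equilibrium lobe, and sustained oscillation
that keeps switching between the two symmetry-related lobes (the
"double-attractor" of the non-resolving regime).  All labels produced here
are finite-horizon claims about the integrated window, not statements
about mathematical omega-limit sets: a slowly decaying spiral and a true
limit cycle are indistinguishable on a short window, and the classifier
says ``undecided`` rather than guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .core_model import (
    DEFAULT_INIT,
    DivergenceError,
    FixedPoint,
    IntegrationConfig,
    State,
    TrafficParams,
    Trajectory,
    fixed_points,
    hopf_threshold,
    integrate,
    jacobian,
    vector_field,
)

__all__ = [
    "OrbitLabel",
    "OrbitClass",
    "ClassifierSettings",
    "classify_orbit",
    "basin_probe",
    "BasinReport",
    "lyapunov_max",
    "benettin_lyapunov",
    "scan_phi",
]


class OrbitLabel:
    """Closed vocabulary of orbit classes."""

    CONVERGED = "converged_fixed_point"
    SINGLE_LOBE = "sustained_single_lobe"
    TWO_LOBE = "sustained_two_lobe"
    UNDECIDED = "undecided"
    ALL = (CONVERGED, SINGLE_LOBE, TWO_LOBE, UNDECIDED)


@dataclass(frozen=True)
class OrbitClass:
    """Classifier verdict plus the diagnostics it was based on.

    ``amplitude_ratio`` is the last-quarter peak-to-peak amplitude of x
    divided by the first-quarter amplitude over the post-burn-in window
    (&lt;1 means decaying); ``peak_count`` counts peaks of |x|;
    ``lobe_switches`` counts sign changes of x between successive peaks;
    ``final_distance`` is the distance from the final state to the nearest
    supplied equilibrium.
    """

    label: str
    amplitude_ratio: float
    peak_count: int
    lobe_switches: int
    final_distance: float

    def __post_init__(self) -> None:
        if self.label not in OrbitLabel.ALL:
            raise ValueError(f"unknown orbit label {self.label!r}")
        for v in (self.amplitude_ratio, self.final_distance):
            if not math.isfinite(v):
                raise ValueError("diagnostics must be finite")


@dataclass(frozen=True)
class ClassifierSettings:
    """Tunable thresholds of the orbit classifier.

    burn_in : fraction of the trajectory discarded as transient (default
        0.5 — half the window).
    eps_fp : distance to an equilibrium below which the endpoint counts as
        converged (fold-change units).
    eps_decay : amplitude-trend ratio below which an oscillation is deemed
        decaying.
    min_peaks : minimum post-burn-in peak count required for any
        "sustained" call.
    """

    burn_in: float = 0.5
    eps_fp: float = 1e-3
    eps_decay: float = 0.2
    min_peaks: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < 1):
            raise ValueError(f"burn_in must be in [0, 1), got {self.burn_in}")
        if self.eps_fp <= 0 or self.eps_decay <= 0:
            raise ValueError("tolerances must be > 0")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


def _amplitude_ratio(x: np.ndarray, floor: float) -> float:
    """Last-quarter over first-quarter peak-to-peak amplitude of a signal.

    Amplitudes below ``floor`` (the convergence tolerance) are treated as
    numerically flat — adaptive solvers leave tolerance-level jitter on a
    fully converged orbit, which must not read as sustained oscillation.
    """
    q = max(len(x) // 4, 1)
    amp_first = float(np.ptp(x[:q]))
    amp_last = float(np.ptp(x[-q:]))
    if amp_last < floor:
        return 0.0
    return amp_last / max(amp_first, floor)


def _peaks_of_abs(x: np.ndarray, floor: float) -> np.ndarray:
    """Indices of peaks of |x|, ignoring sub-tolerance solver jitter."""
    span = float(np.ptp(x))
    prominence = max(0.25 * floor, 0.01 * span)
    peaks, _ = find_peaks(np.abs(x), prominence=prominence)
    return peaks


def classify_orbit(
    traj: Trajectory,
    equilibria: Sequence[FixedPoint],
    settings: ClassifierSettings = ClassifierSettings(),
) -> OrbitClass:
    """Classify the long-run behaviour of a trajectory.

    ``converged_fixed_point`` requires the final state to lie within
    ``eps_fp`` of some supplied equilibrium *and* the post-burn-in
    amplitude trend to be decaying (ratio < ``eps_decay``).  Sustained
    labels require at least ``min_peaks`` peaks with non-decaying
    amplitude; the orbit is called two-lobe when the sign of x at
    successive peaks of |x| changes at least twice (the orbit visits both
    symmetry-related lobes — the two nonzero equilibria differ only in the
    signs of x and y, so z is lobe-blind).  Anything else is ``undecided``.
    """
    if not np.all(np.isfinite(traj.states)):
        raise ValueError("trajectory contains non-finite states")
    t0 = traj.times[0] + settings.burn_in * (traj.times[-1] - traj.times[0])
    seg = traj.after(t0)
    x = seg.x

    final = seg.states[-1]
    if equilibria:
        final_distance = min(
            float(np.linalg.norm(final - fp.state.as_array())) for fp in equilibria
        )
    else:
        final_distance = float("inf")

    ratio = _amplitude_ratio(x, settings.eps_fp)
    peaks = _peaks_of_abs(x, settings.eps_fp)
    signs = np.sign(x[peaks])
    lobe_switches = int(np.count_nonzero(np.diff(signs[signs != 0])))

    if final_distance <= settings.eps_fp and ratio < settings.eps_decay:
        label = OrbitLabel.CONVERGED
    elif len(peaks) >= settings.min_peaks and ratio >= settings.eps_decay:
        label = OrbitLabel.TWO_LOBE if lobe_switches >= 2 else OrbitLabel.SINGLE_LOBE
    else:
        label = OrbitLabel.UNDECIDED

    return OrbitClass(
        label=label,
        amplitude_ratio=ratio,
        peak_count=int(len(peaks)),
        lobe_switches=lobe_switches,
        final_distance=final_distance if math.isfinite(final_distance) else 1e300,
    )


# ---------------------------------------------------------------------------
# Basin probing: attractor multiplicity from several initial conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasinReport:
    """Which initial conditions reached which limit set.

    ``assignment[i]`` is the cluster index of ``inits[i]``;
    ``multiplicity`` is the number of distinct limit sets found.
    Converged orbits are clustered by endpoint proximity (within
    ``10 * eps_fp``); sustained orbits by their lobe-occupancy signature.
    """

    inits: tuple[State, ...]
    classes: tuple[OrbitClass, ...]
    assignment: tuple[int, ...]
    multiplicity: int


def _lobe_signature(traj: Trajectory, settings: ClassifierSettings) -> str:
    t0 = traj.times[0] + settings.burn_in * (traj.times[-1] - traj.times[0])
    x = traj.after(t0).x
    peaks = _peaks_of_abs(x, settings.eps_fp)
    signs = set(np.sign(x[peaks]).astype(int)) - {0}
    return {
        frozenset(): "none",
        frozenset({1}): "+",
        frozenset({-1}): "-",
        frozenset({1, -1}): "+-",
    }[frozenset(signs)]


def basin_probe(
    params: TrafficParams,
    inits: Sequence[State] | None = None,
    config: IntegrationConfig = IntegrationConfig(),
    settings: ClassifierSettings = ClassifierSettings(),
    t_end: float = 200.0,
) -> BasinReport:
    """Probe attractor multiplicity by integrating from several initial states.

    Defaults to the symmetric pair (0.1, 0.1, 0.1) and (-0.1, -0.1, 0.1).
    Divergence during any integration propagates as
    :class:`~tlr4traffic.core_model.DivergenceError`.
    """
    if inits is None:
        inits = [DEFAULT_INIT, DEFAULT_INIT.mirrored()]
    inits = list(inits)
    if not inits:
        raise ValueError("need at least one initial state")

    eq = fixed_points(params)
    trajs = [integrate(params, s0, t_end, config) for s0 in inits]
    classes = [classify_orbit(tr, eq, settings) for tr in trajs]

    # cluster keys: converged -> endpoint; sustained/undecided -> lobe signature
    endpoints: list[np.ndarray | None] = []
    signatures: list[str | None] = []
    for tr, oc in zip(trajs, classes):
        if oc.label == OrbitLabel.CONVERGED:
            endpoints.append(tr.states[-1])
            signatures.append(None)
        else:
            endpoints.append(None)
            signatures.append(oc.label + ":" + _lobe_signature(tr, settings))

    assignment = [-1] * len(inits)
    clusters: list[tuple[np.ndarray | None, str | None]] = []
    tol = 10.0 * settings.eps_fp
    for i in range(len(inits)):
        for c, (ep, sig) in enumerate(clusters):
            if endpoints[i] is not None and ep is not None:
                if np.linalg.norm(endpoints[i] - ep) <= tol:
                    assignment[i] = c
                    break
            elif signatures[i] is not None and sig is not None:
                if signatures[i] == sig:
                    assignment[i] = c
                    break
        if assignment[i] == -1:
            assignment[i] = len(clusters)
            clusters.append((endpoints[i], signatures[i]))

    return BasinReport(
        inits=tuple(inits),
        classes=tuple(classes),
        assignment=tuple(assignment),
        multiplicity=len(clusters),
    )


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Benettin tangent-vector renormalization)
# ---------------------------------------------------------------------------

def benettin_lyapunov(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    t_burn: float = 100.0,
    n_intervals: int = 200,
    renorm_dt: float = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    seed: int = 0,
) -> float:
    """Largest Lyapunov exponent of ``rhs`` by tangent-vector renormalization.

    Integrates the state together with a tangent vector evolved by the
    variational equation ``v' = J(state) v``, renormalizing ``v`` to unit
    length every ``renorm_dt`` and averaging the log stretch factors over
    ``n_intervals`` intervals after a burn-in of ``t_burn``.  Deterministic
    given identical arguments (the initial tangent direction is drawn from
    ``seed``).
    """
    init = np.asarray(init, dtype=float)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(init.size)
    v /= np.linalg.norm(v)

    def augmented(t, sv):
        s, vv = sv[: init.size], sv[init.size:]
        return np.concatenate([np.asarray(rhs(t, s), dtype=float), jac(s) @ vv])

    # burn-in of the base orbit only
    sol = solve_ivp(rhs, (0.0, t_burn), init, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise DivergenceError(sol.t[-1], float("inf"))
    state = sol.y[:, -1]

    log_sum = 0.0
    for _ in range(n_intervals):
        sol = solve_ivp(
            augmented,
            (0.0, renorm_dt),
            np.concatenate([state, v]),
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise DivergenceError(sol.t[-1], float("inf"))
        out = sol.y[:, -1]
        state, v = out[: init.size], out[init.size:]
        norm = float(np.linalg.norm(v))
        if norm == 0 or not np.isfinite(norm):
            raise DivergenceError(0.0, float("inf"))
        log_sum += math.log(norm)
        v /= norm
    return log_sum / (n_intervals * renorm_dt)


def lyapunov_max(
    params: TrafficParams,
    init: State = DEFAULT_INIT,
    config: IntegrationConfig = IntegrationConfig(),
    t_burn: float = 100.0,
    n_intervals: int = 200,
    renorm_dt: float = 1.0,
) -> float:
    """Largest Lyapunov exponent of the trafficking flow from ``init``.

    Negative in the fixed-point regime; a positive value diagnoses
    sensitive dependence in the sustained-oscillation regime.  No
    particular value is asserted for the supra-threshold regime — the
    exponent is provided as a diagnostic.
    """
    if np.max(np.abs(init.as_array())) > config.overflow:
        raise DivergenceError(0.0, config.overflow)

    def jac(s):
        return jacobian(State(*s), params)

    from .core_model import _rhs  # same compiled closure as integrate()

    return benettin_lyapunov(
        _rhs(params),
        jac,
        init.as_array(),
        t_burn=t_burn,
        n_intervals=n_intervals,
        renorm_dt=renorm_dt,
        rtol=config.rtol,
        atol=config.atol,
    )


# ---------------------------------------------------------------------------
# Parameter sweep in phi
# ---------------------------------------------------------------------------

def scan_phi(
    base: TrafficParams,
    phi_grid: Sequence[float],
    init: State = DEFAULT_INIT,
    config: IntegrationConfig = IntegrationConfig(),
    settings: ClassifierSettings = ClassifierSettings(),
    t_end: float = 200.0,
):
    """Sweep the mRNA-production rate, classifying the orbit at each value.

    The other four rates are held fixed at ``base``.  Returns a pandas
    DataFrame with one row per phi: columns ``phi``, ``orbit_class``,
    ``max_eig_real`` (largest eigenvalue real part at the nonzero
    equilibria), ``amplitude_ratio``, ``lobe_switches``.  A divergent orbit
    is recorded in its row as ``diverged``, not raised.
    """
    import pandas as pd

    phi_grid = [float(p) for p in phi_grid]
    if any(not (0 < p <= 5) for p in phi_grid):
        raise ValueError("phi grid must lie within (0, 5]")
    if any(b >= a for a, b in zip(phi_grid[1:], phi_grid)):
        raise ValueError("phi grid must be strictly increasing")

    rows = []
    for phi in phi_grid:
        p = base.with_phi(phi)
        nonzero = [fp for fp in fixed_points(p) if abs(fp.state.x) > 0]
        max_eig = max(fp.max_real_part for fp in nonzero) if nonzero else float("nan")
        try:
            traj = integrate(p, init, t_end, config)
            oc = classify_orbit(traj, fixed_points(p), settings)
            rows.append(
                dict(
                    phi=phi,
                    orbit_class=oc.label,
                    max_eig_real=max_eig,
                    amplitude_ratio=oc.amplitude_ratio,
                    lobe_switches=oc.lobe_switches,
                )
            )
        except DivergenceError:
            rows.append(
                dict(
                    phi=phi,
                    orbit_class="diverged",
                    max_eig_real=max_eig,
                    amplitude_ratio=float("nan"),
                    lobe_switches=-1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["phi", "orbit_class", "max_eig_real", "amplitude_ratio", "lobe_switches"],
    )
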