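import numpy as np
import pytest

from tlr4traffic import FIG2_BASE, State, TrafficParams


@pytest.fixture
def base_params() -> TrafficParams:
    """Calibrated baseline rate set (steady-state oscillation regime)."""
    return FIG2_BASE


def sample_params(rng: np.random.Generator) -> TrafficParams:
    """Random valid rate set in a range where orbits stay bounded over short runs."""
    sigma = rng.uniform(0.1, 2.0)
    return TrafficParams(
        phi=rng.uniform(0.2, 2.0),
        beta=rng.uniform(0.5, 4.0),
        alpha=rng.uniform(0.1, 2.0),
        gamma=sigma + rng.uniform(0.2, 2.0),
        sigma=sigma,
    )


def rk4_endpoint(params: TrafficParams, init, t_end: float, h: float) -> np.ndarray:
    """Independent fixed-step classical 4th-order Runge-Kutta integrator."""
    phi, b, g = params.phi, params.beta + params.alpha, params.gamma - params.sigma

    def f(s):
        x, y, z = s
        return np.array([phi * x - y * z, x - b * y, x * y - g * z])

    s = np.asarray(init, dtype=float).copy()
    for _ in range(int(round(t_end / h))):
        k1 = f(s)
        k2 = f(s + h / 2 * k1)
        k3 = f(s + h / 2 * k2)
        k4 = f(s + h * k3)
        s = s + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return s
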