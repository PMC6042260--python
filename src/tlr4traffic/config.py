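"""Flat TOML configuration for model, integration, and regime settings.

Sections and keys::

    [model]
    phi = 1.2        # mRNA production rate (baseline)
    beta = 3.6       # endosome -> lysosome
    alpha = 1.2      # endosome -> recycling compartment
    gamma = 2.4      # surface -> Golgi
    sigma = 1.3      # surface -> endosomes
    init = [0.1, 0.1, 0.1]
    t_end = 200.0

    [integration]
    rtol = 1e-9
    atol = 1e-12
    dt = 0.01
    method = "RK45"
    overflow = 1e6

    [regime]
    threshold = 1.2
    tolerance = 0.02

Any key may be omitted (defaults apply) and overridden by CLI flags.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .core_model import DEFAULT_INIT, FIG2_BASE, IntegrationConfig, State, TrafficParams
from .regime_rules import DEFAULT_THRESHOLD, DEFAULT_TOL

__all__ = ["RunConfig", "load_config", "default_config", "format_config"]


@dataclass(frozen=True)
class RunConfig:
    params: TrafficParams
    init: State
    t_end: float
    integration: IntegrationConfig
    threshold: float
    tolerance: float


def default_config() -> RunConfig:
    return RunConfig(
        params=FIG2_BASE,
        init=DEFAULT_INIT,
        t_end=200.0,
        integration=IntegrationConfig(),
        threshold=DEFAULT_THRESHOLD,
        tolerance=DEFAULT_TOL,
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a TOML file; missing keys fall back to defaults."""
    if path is None:
        return default_config()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    model = raw.get("model", {})
    integ = raw.get("integration", {})
    regime = raw.get("regime", {})
    base = default_config()

    params = TrafficParams(
        phi=float(model.get("phi", base.params.phi)),
        beta=float(model.get("beta", base.params.beta)),
        alpha=float(model.get("alpha", base.params.alpha)),
        gamma=float(model.get("gamma", base.params.gamma)),
        sigma=float(model.get("sigma", base.params.sigma)),
    )
    init_vals = model.get("init", [base.init.x, base.init.y, base.init.z])
    if len(init_vals) != 3:
        raise ValueError(f"model.init must have 3 components, got {init_vals}")
    return RunConfig(
        params=params,
        init=State(*map(float, init_vals)),
        t_end=float(model.get("t_end", base.t_end)),
        integration=IntegrationConfig(
            rtol=float(integ.get("rtol", base.integration.rtol)),
            atol=float(integ.get("atol", base.integration.atol)),
            dt=float(integ.get("dt", base.integration.dt)),
            method=str(integ.get("method", base.integration.method)),
            overflow=float(integ.get("overflow", base.integration.overflow)),
        ),
        threshold=float(regime.get("threshold", base.threshold)),
        tolerance=float(regime.get("tolerance", base.tolerance)),
    )


def format_config(cfg: RunConfig) -> str:
    """Render a RunConfig as the TOML the loader accepts."""
    p, i = cfg.params, cfg.integration
    return (
        "[model]\n"
        f"phi = {p.phi}\nbeta = {p.beta}\nalpha = {p.alpha}\n"
        f"gamma = {p.gamma}\nsigma = {p.sigma}\n"
        f"init = [{cfg.init.x}, {cfg.init.y}, {cfg.init.z}]\n"
        f"t_end = {cfg.t_end}\n\n"
        "[integration]\n"
        f"rtol = {i.rtol}\natol = {i.atol}\ndt = {i.dt}\n"
        f'method = "{i.method}"\noverflow = {i.overflow}\n\n'
        "[regime]\n"
        f"threshold = {cfg.threshold}\ntolerance = {cfg.tolerance}\n"
    )
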