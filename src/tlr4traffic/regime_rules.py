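"""Clinical regime assignment from the mRNA-production rate phi.

Three regions of the phase space are distinguished by where phi sits
relative to the calibrated baseline value 1.2: at baseline the model shows
low-amplitude steady-state oscillations (unstimulated physiology); below
baseline the orbit settles on a fixed point, interpreted as sepsis that
progresses and resolves; above baseline the orbit oscillates irreversibly
between the surface and endosomal pools ("double attractor"), interpreted
as non-resolving sepsis.  The rule is a literal phi partition, deliberately
decoupled from the numerical orbit classifier (linear stability places the
oscillation onset above 1.2; see the methods note).

Exact equality with the baseline is measure-zero on noisy qPCR input, so a
relative equality band (default 2%) maps near-baseline measurements to the
steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Regime",
    "RegimeLabel",
    "Prognosis",
    "DEFAULT_THRESHOLD",
    "DEFAULT_TOL",
    "regime_from_phi",
    "prognosis",
]

DEFAULT_THRESHOLD = 1.2
DEFAULT_TOL = 0.02


class Regime:
    STEADY_STATE = "steady_state"
    RESOLVING = "resolving"
    NON_RESOLVING = "non_resolving"
    ALL = (STEADY_STATE, RESOLVING, NON_RESOLVING)


class Outcome:
    SURVIVAL = "survival"
    DEATH = "death"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class RegimeLabel:
    """A regime call together with the phi value that produced it."""

    label: str
    phi_used: float

    def __post_init__(self) -> None:
        if self.label not in Regime.ALL:
            raise ValueError(f"unknown regime label {self.label!r}")


@dataclass(frozen=True)
class Prognosis:
    """Predicted clinical outcome and the regime that implied it."""

    prediction: str
    rationale: str  # the regime label

    def __post_init__(self) -> None:
        expected = {
            Regime.RESOLVING: Outcome.SURVIVAL,
            Regime.NON_RESOLVING: Outcome.DEATH,
            Regime.STEADY_STATE: Outcome.NOT_APPLICABLE,
        }
        if expected.get(self.rationale) != self.prediction:
            raise ValueError(
                f"prediction {self.prediction!r} inconsistent with regime {self.rationale!r}"
            )


def regime_from_phi(
    phi: float,
    threshold: float = DEFAULT_THRESHOLD,
    tol: float = DEFAULT_TOL,
) -> RegimeLabel:
    """Assign the clinical regime from the mRNA-production rate.

    ``|phi - threshold| <= tol*threshold`` maps to ``steady_state``;
    below the band to ``resolving`` (fixed-point attractor); above it to
    ``non_resolving`` (double attractor).  Total and deterministic:
    exactly one label for every positive phi.
    """
    if not (isinstance(phi, (int, float)) and math.isfinite(phi) and phi > 0):
        raise ValueError(f"mRNA production rate phi must be positive, got {phi!r}")
    if threshold <= 0 or tol < 0:
        raise ValueError("threshold must be > 0 and tol >= 0")
    band = tol * threshold
    if abs(phi - threshold) <= band:
        label = Regime.STEADY_STATE
    elif phi < threshold:
        label = Regime.RESOLVING
    else:
        label = Regime.NON_RESOLVING
    return RegimeLabel(label=label, phi_used=float(phi))


def prognosis(regime: RegimeLabel) -> Prognosis:
    """Map a regime to the predicted sepsis outcome.

    Resolving (single fixed-point attractor) predicts survival;
    non-resolving (double attractor) predicts death within days of ICU
    admission; steady state corresponds to unstimulated physiology, where
    there is no sepsis outcome to predict.
    """
    mapping = {
        Regime.RESOLVING: Outcome.SURVIVAL,
        Regime.NON_RESOLVING: Outcome.DEATH,
        Regime.STEADY_STATE: Outcome.NOT_APPLICABLE,
    }
    return Prognosis(prediction=mapping[regime.label], rationale=regime.label)
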