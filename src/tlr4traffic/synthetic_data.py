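"""Synthetic cohorts and trajectory fixtures with the assumed structure.

The real supplementary cohort tables are not machine-available, so this
module generates stand-ins with the statistical shape the analysis
assumes: a survivor group and a non-survivor group whose *tlr4*
fold-change medians lie on opposite sides of the regime threshold,
multiplicative lognormal measurement noise (equivalently Gaussian noise on
ddCt), optional emission as raw Ct columns, and a configurable fraction of
confounder patients whose recorded outcome contradicts their regime —
emulating the published fungal-infection and culture-negative cases.
All outputs are pure functions of their spec (seeded determinism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attractor_analysis import OrbitLabel
from .core_model import (
    DEFAULT_INIT,
    FIG2_BASE,
    IntegrationConfig,
    State,
    TrafficParams,
    Trajectory,
    integrate,
)
from .patient_pipeline import PHI_BASELINE, PatientRecord

__all__ = ["CohortSpec", "gen_cohort", "gen_trajectory_fixtures", "LabelledTrajectory"]

# Arbitrary realistic calibrator anchors (cycles); only Ct differences matter.
CT_TLR4_CAL = 25.0
CT_REF_CAL = 20.0
CT_REF_PATIENT = 20.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic sepsis cohort.

    phi medians are model rates; the survivor median should sit below the
    regime threshold and the deceased median above it for a learnable
    cohort.  ``lognormal_sigma`` is the SD of log fold change (default
    0.25, i.e. ~±28% multiplicative noise, a standard qPCR error scale);
    ``ct_noise_sd`` (cycles) applies only when Ct columns are emitted.
    ``confounder_fraction`` of patients get their outcome flipped relative
    to their regime and a pathogen note marking them.
    """

    n_patients: int = 10
    survivor_fraction: float = 0.4
    phi_median_survivor: float = 0.8
    phi_median_deceased: float = 1.8
    lognormal_sigma: float = 0.25
    ct_noise_sd: float = 0.2
    confounder_fraction: float = 0.0
    seed: int = 0
    emit: str = "fold_change"  # or "ct"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("survivor_fraction", "confounder_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.phi_median_survivor <= 0 or self.phi_median_deceased <= 0:
            raise ValueError("phi medians must be > 0")
        if self.lognormal_sigma < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.emit not in ("fold_change", "ct"):
            raise ValueError(f"emit must be 'fold_change' or 'ct', got {self.emit!r}")


def gen_cohort(
    spec: CohortSpec, phi_baseline: float = PHI_BASELINE
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a synthetic cohort and its design truth table.

    Group sizes are ``round(survivor_fraction * n)`` survivors (the rest
    deceased), shuffled into a random patient order.  Each patient's fold
    change is drawn lognormally about their group median divided by the
    baseline rate, so the noise-free phi equals the group median.  Exactly
    ``round(confounder_fraction * n)`` patients (sampled across the
    cohort) have their outcome flipped relative to their designed regime
    and are tagged in ``pathogen_note``.

    Returns the records plus a truth DataFrame with columns patient_id,
    group, designed_phi, fold_change, phi, outcome, confounder.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_surv = int(round(spec.survivor_fraction * n))
    groups = np.array(["survivor"] * n_surv + ["deceased"] * (n - n_surv))
    rng.shuffle(groups)

    n_conf = int(round(spec.confounder_fraction * n))
    conf_idx = set(rng.choice(n, size=n_conf, replace=False).tolist())

    medians = {
        "survivor": spec.phi_median_survivor,
        "deceased": spec.phi_median_deceased,
    }
    base_outcome = {"survivor": "survived", "deceased": "deceased"}
    flip = {"survived": "deceased", "deceased": "survived"}
    conf_note = {
        # flipped deceased->survived emulates the culture-negative survivor;
        # flipped survived->deceased the fungal non-TLR4 death
        "survivor": "confounder: fungal infection",
        "deceased": "confounder: culture-negative",
    }

    records, truth = [], []
    for i in range(n):
        group = groups[i]
        fc_median = medians[group] / phi_baseline
        noise = math.exp(rng.normal(0.0, spec.lognormal_sigma)) if spec.lognormal_sigma else 1.0
        fc = fc_median * noise
        phi = phi_baseline * fc
        outcome = base_outcome[group]
        note = ""
        if i in conf_idx:
            outcome = flip[outcome]
            note = conf_note[group]

        pid = f"S{i + 1:03d}"
        if spec.emit == "fold_change":
            rec = PatientRecord(
                patient_id=pid, fold_change=fc, outcome=outcome, pathogen_note=note
            )
        else:
            # invert fold change to Ct space: ddCt = -log2(fc)
            ddct = -math.log2(fc)
            ct_ref = CT_REF_PATIENT + rng.normal(0.0, spec.ct_noise_sd)
            ct_tlr4 = (
                CT_TLR4_CAL - CT_REF_CAL + ct_ref + ddct + rng.normal(0.0, spec.ct_noise_sd)
            )
            rec = PatientRecord(
                patient_id=pid,
                ct_tlr4=ct_tlr4,
                ct_ref=ct_ref,
                ct_tlr4_cal=CT_TLR4_CAL + rng.normal(0.0, spec.ct_noise_sd),
                ct_ref_cal=CT_REF_CAL + rng.normal(0.0, spec.ct_noise_sd),
                outcome=outcome,
                pathogen_note=note,
            )
        records.append(rec)
        truth.append(
            dict(
                patient_id=pid,
                group=group,
                designed_phi=medians[group],
                fold_change=fc,
                phi=phi,
                outcome=outcome,
                confounder=i in conf_idx,
            )
        )
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Trajectory fixtures for the orbit classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelledTrajectory:
    """A fixture trajectory with its ground-truth (or regression) label.

    ``asserted`` is False for labels recorded from the classifier itself
    for regression tracking rather than derived from construction or
    linear-stability analysis.
    """

    name: str
    trajectory: Trajectory
    label: str
    asserted: bool = True


def _signal_trajectory(t: np.ndarray, x: np.ndarray, params: TrafficParams) -> Trajectory:
    # synthetic analytic signal, applied to all three components
    return Trajectory(t, np.column_stack([x, x, x]), params)


def gen_trajectory_fixtures(
    seed: int = 0,
    t_end: float = 60.0,
    dt: float = 0.01,
    include_integrations: bool = True,
) -> list[LabelledTrajectory]:
    """Labelled fixtures exercising every orbit class.

    Emits analytic signals with labels known by construction — constants
    (converged), damped sinusoids (converged), undamped offset sinusoids
    (sustained single-lobe), square-wave lobe-switching signals (sustained
    two-lobe) — plus, when ``include_integrations`` is set, genuine model
    integrations at phi in {0.6, 1.2, 2.5}.  The phi=0.6 label follows
    from linear stability (both nonzero equilibria attract below the Hopf
    threshold); the phi=1.2 and phi=2.5 labels are recorded from the
    classifier for regression, not asserted as ground truth.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    p = FIG2_BASE
    out: list[LabelledTrajectory] = []

    out.append(
        LabelledTrajectory(
            "constant_at_origin",
            _signal_trajectory(t, np.zeros_like(t), p),
            OrbitLabel.CONVERGED,
        )
    )
    from .core_model import fixed_points as _fps

    # seed picks which symmetry lobe the constant fixture sits on
    eq = next(fp for fp in _fps(p) if fp.state.x > 0)
    eq_state = eq.state if rng.integers(2) else eq.state.mirrored()
    out.append(
        LabelledTrajectory(
            "constant_at_equilibrium",
            Trajectory(t, np.tile(eq_state.as_array(), (t.size, 1)), p),
            OrbitLabel.CONVERGED,
        )
    )
    out.append(
        LabelledTrajectory(
            "damped_sinusoid_0.3",
            _signal_trajectory(t, np.exp(-0.3 * t) * np.sin(2 * t), p),
            OrbitLabel.CONVERGED,
        )
    )
    out.append(
        LabelledTrajectory(
            "undamped_offset_sinusoid",
            _signal_trajectory(t, 1.0 + 0.5 * np.sin(2 * t), p),
            OrbitLabel.SINGLE_LOBE,
        )
    )
    phase = rng.uniform(0.0, 20.0)
    square = np.sign(np.sin(2 * np.pi * (t + phase) / 20.0))
    square[square == 0] = 1.0
    out.append(
        LabelledTrajectory(
            "square_wave_lobe_switching",
            _signal_trajectory(t, square * (1.0 + 0.5 * np.sin(2 * t)), p),
            OrbitLabel.TWO_LOBE,
        )
    )

    if include_integrations:
        from .attractor_analysis import ClassifierSettings, classify_orbit
        from .core_model import fixed_points

        cfg = IntegrationConfig()
        tr = integrate(p.with_phi(0.6), DEFAULT_INIT, 200.0, cfg)
        out.append(
            LabelledTrajectory("model_phi_0.6", tr, OrbitLabel.CONVERGED, asserted=True)
        )
        for phi in (1.2, 2.5):
            pp = p.with_phi(phi)
            tr = integrate(pp, DEFAULT_INIT, 200.0, cfg)
            observed = classify_orbit(tr, fixed_points(pp), ClassifierSettings()).label
            out.append(
                LabelledTrajectory(f"model_phi_{phi}", tr, observed, asserted=False)
            )
    return out
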