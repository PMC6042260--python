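# Methods

## Model

TLR4 concentration is tracked as fold-change deviations in three pools:
the trans-Golgi network plus endosomal recycling compartment (x), the
early-endosome/endolysosome system (y), and the cell surface (z), coupled
by

    x' = φx − yz
    y' = x − (β + α)y
    z' = xy − (γ − σ)z

with five non-negative first-order rates: φ (mRNA production), β
(endosome → lysosome), α (endosome → recycling compartment), γ (surface →
Golgi), σ (surface → endosomes). Two structural constraints are enforced
at construction: γ − σ > 0 (the surface pool must relax; otherwise the z
equation is anti-dissipative) and β + α > 0 (the endosomal pool must
drain). States are *deviations*, not copy numbers, so components may be
negative and no positivity clamp is applied — the mirrored equilibrium
genuinely has negative x and y, and clamping would change the model.

The flow is equivariant under (x, y, z) → (−x, −y, z). Its equilibria are
the origin and, for φ > 0, the symmetric pair

    y* = √(φ(γ−σ)),  x* = (β+α)·y*,  z* = (β+α)·φ,

obtained by eliminating x and z from the stationarity conditions. At the
nonzero equilibria the characteristic polynomial reduces to
λ³ + (B+G−φ)λ² + BGλ + 2BGφ with B = β+α, G = γ−σ (the two mixed
principal minors of the Jacobian cancel exactly), and the Routh–Hurwitz
condition (B+G−φ)·BG > 2BGφ gives the stability boundary

    φ* = (B + G)/3.

For the baseline rates (β=3.6, α=1.2, γ=2.4, σ=1.3) this is φ* = 5.9/3 ≈
1.967: a Hopf bifurcation where a complex pair crosses the imaginary
axis. The Jacobian trace φ − B − G is state-independent and negative for
every φ considered here, so the flow is volume-contracting and
supra-threshold orbits remain bounded (they oscillate between the two
symmetry lobes rather than diverging).

Note an honest discrepancy between the two regime notions the package
exposes. The *clinical* rule places the regime boundary at the baseline
φ = 1.2, while linear stability places the oscillation onset at φ* ≈
1.967; numerically, orbits at φ = 1.2 converge (slowly) to a fixed point
rather than tracing a limit cycle. The two rules are therefore kept
deliberately separate: `regime_rules` implements the literal φ partition
used for prognosis, and `attractor_analysis` reports what the integrated
orbit actually does. The numerical classifier is never forced to
reproduce the clinical labels near φ = 1.2.

## Numerics

Integration uses adaptive Runge–Kutta (scipy `solve_ivp`, RK45 by
default) with rtol 1e−9 / atol 1e−12 and a uniform output grid of
dt = 0.01 — tight, because the classifier is sensitive to slow amplitude
trends. The model has no physical time scale; the default horizon is 200
model-time units with the first half discarded as burn-in, which spans
more than 20 linearized periods (ω ≈ √(BG) ≈ 2.3) for the baseline rates.
The default initial condition (0.1, 0.1, 0.1) encodes "all pools low":
small, positive, and off the origin (which is itself an equilibrium,
unstable along x for φ > 0). An overflow guard at |component| > 1e6
raises a divergence error naming the failing time; it separates genuine
blow-up (possible for invalid or extreme rate sets) from bounded chaotic
orbits.

## Orbit classification

Labels are finite-horizon claims about the integrated window, not ω-limit
sets. After discarding the burn-in fraction (default 0.5):

* **converged_fixed_point** — the final state lies within `eps_fp`
  (default 1e−3) of an equilibrium *and* the amplitude trend ratio
  (last-quarter peak-to-peak amplitude of x over first-quarter) is below
  `eps_decay` (default 0.2);
* **sustained_single_lobe / sustained_two_lobe** — at least `min_peaks`
  (default 4) peaks of |x| with a non-decaying amplitude trend; two-lobe
  when the sign of x at successive peaks changes at least twice. Lobe
  membership is read off the sign of x because the two nonzero equilibria
  differ only in the signs of x and y; z is fixed by the symmetry and is
  lobe-blind;
* **undecided** — anything else (in particular, too-short windows).

Amplitudes below `eps_fp` are treated as numerically flat: an adaptive
solver leaves tolerance-level jitter on a fully converged orbit, and
without this floor that jitter reads as sustained oscillation. The same
floor feeds the peak-prominence threshold. Consequence: a genuine limit
cycle with amplitude below `eps_fp` would be classified as converged;
at the default tolerances no such orbit arises in the studied range.

The "double attractor" of the non-resolving regime is operationalized as
two-lobe behaviour of a *single* orbit. Basin multiplicity is probed
separately (`basin_probe`), because the symmetric equilibrium pair makes
multiplicity 2 generic even in the resolving regime: converged endpoints
are clustered within 10·eps_fp, sustained orbits by lobe-occupancy
signature. The largest Lyapunov exponent (`lyapunov_max`) uses Benettin
tangent-vector renormalization (default: 1-time-unit intervals, 200
repetitions after a 100-unit burn-in) and is reported as a diagnostic
only; no value is asserted for the supra-threshold regime, whose precise
character (chaotic, quasi-periodic, or long transient) is left open.

## Patient pipeline

Measured *tlr4* expression enters the model through the simplest monotone
map consistent with "expression sets the production rate": φ =
φ_baseline × fold change, with φ_baseline = 1.2 (the calibrated
steady-state value) and fold change = 2^(−ΔΔCt) when raw cycle thresholds
are supplied (ΔΔCt = (Ct_tlr4 − Ct_ref) − (Ct_tlr4_cal − Ct_ref_cal)).
An explicitly supplied φ takes precedence, then fold change, then the Ct
pathway. No amplification-efficiency correction beyond the 2^(−ΔΔCt)
model is applied.

The regime rule partitions φ at the threshold 1.2 with a relative
equality band (default 2%): exact equality is measure-zero on noisy qPCR
input, and without the band the steady state would be unreachable.
Prognosis: resolving → survival, non-resolving → death, steady state →
not_applicable (unstimulated physiology; the model offers no prediction).
For a patient with a recorded outcome a not_applicable prediction counts
as incorrect — the conservative choice. The pipeline carries pathogen
annotations (fungal, culture-negative) through to the output but applies
no pathogen-specific logic: non-LPS stimulation is outside the model, and
such patients are exactly the expected misses.

## Synthetic data

The generator emulates a two-group sepsis cohort: survivor and deceased
groups with φ medians on opposite sides of the threshold (defaults 0.8
and 1.8), multiplicative lognormal noise on fold change (default σ =
0.25, ≈ ±28%, equivalently Gaussian noise on ΔΔCt — the standard qPCR
error structure; the source cohort reports none), optional emission as
raw Ct columns (calibrator anchored at Ct 25/20 cycles — arbitrary
realistic values, only differences matter; additive Ct noise default 0.2
cycles), and a confounder fraction whose outcome is flipped relative to
their regime, emulating the fungal and culture-negative cases. Group
sizes and the confounder subset are rounded deterministically
(`round(fraction·n)`), so a 10-patient, 20%-confounder design yields
exactly two confounders and — with zero noise — exactly 8/10 agreement by
construction.

The recovery check uses n = 500, equal groups, no confounders, and σ =
0.12, putting the group medians ≈ 6.8 noise-sigmas apart. At exactly 4σ
separation with the threshold midway, Gaussian tails put ≈ 2% of each
group across the boundary, so a ≥ 99% recovery claim needs the comfortably
wider separation; 6.8σ leaves ≈ 0.1% tail mass per group.

What the generator does *not* emulate: assay efficiency curves, plate
effects, longitudinal sampling, or any realistic dispersion of the true
patient φ values (unknown — the defaults are labelled placeholders).
Passing the recovery tests therefore shows the pipeline is correct and
well-conditioned under its own assumptions, not that real cohorts are
this separable.

## Problem sizes

Default runs integrate 3-dimensional ODEs over 200 time units (20 001
output samples); the acceptance script uses 200 random rate sets for
residual checks, 20 trajectory pairs for the symmetry check, a 1e−3
fixed-step RK4 run to t = 50 as the integrator oracle, and 500-patient
synthetic cohorts. The whole suite runs in well under a minute.

## Known limitations

* The mapping from measured mRNA to φ is an assumption (linear, anchored
  at baseline); the source data that would pin it down is not
  machine-available, so the ten-patient cohort is encoded from its
  published outcome categories, not from raw per-patient measurements.
* Clinical regime boundary (1.2) and dynamical boundary (≈1.967)
  disagree; both are reported, neither is hidden.
* No stochastic (Gillespie) variant, no spatial or volume effects, no
  unit conversion to receptor copy numbers, no time-varying φ, no
  survival-time modelling.
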