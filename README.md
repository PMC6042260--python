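# tlr4traffic

Dynamical model of Toll-like receptor 4 (TLR4) intracellular trafficking,
with attractor-regime analysis and a patient-level sepsis-prognosis
pipeline.

TLR4 is the innate-immune sensor of Gram-negative bacterial
lipopolysaccharide (LPS). Where the receptor sits inside the cell decides
what it signals: surface TLR4 drives the pro-inflammatory response, while
endosomal TLR4 drives the anti-inflammatory phase and signal termination.
This package models the receptor fluxes between three pools — the
trans-Golgi network plus endosomal recycling compartment (*x*), the early
endosome/endolysosome system (*y*), and the cell surface (*z*) — as a
three-equation ODE system:

```
x' = φx − yz
y' = x − (β + α)y
z' = xy − (γ − σ)z
```

where φ is the rate of *tlr4* mRNA production and β, α, γ, σ are
trafficking rates (endosome→lysosome, endosome→recycling compartment,
surface→Golgi, surface→endosomes). The four trafficking rates are held at
their calibrated baseline (β=3.6, α=1.2, γ=2.4, σ=1.3); φ is the
clinical-severity parameter, set per patient from measured *tlr4*
expression. The system is equivariant under (x, y, z) → (−x, −y, z) and,
besides the origin, has a symmetric pair of equilibria
±((β+α)√(φ(γ−σ)), √(φ(γ−σ)), (β+α)φ) that lose stability at the
Routh–Hurwitz / Hopf boundary φ\* = (β+α+γ−σ)/3.

The clinical rule maps φ relative to the baseline 1.2 to three regimes:
below baseline → *resolving* (fixed-point attractor, predicted survival);
near baseline → *steady state* (unstimulated physiology, no prediction);
above baseline → *non-resolving* ("double attractor" — oscillation between
surface and endosomal pools, predicted death). Patient φ values come from
qPCR via φ = 1.2 × fold change, with fold change = 2^(−ΔΔCt) when raw
cycle thresholds are supplied.

## Worked example

```python
import tlr4traffic as tt

# dynamics: where is the oscillation onset?
print(tt.hopf_threshold(tt.FIG2_BASE))        # 1.9666666666666666

# classify one orbit below threshold
p = tt.FIG2_BASE.with_phi(0.6)
orbit = tt.classify_orbit(tt.integrate(p), tt.fixed_points(p))
print(orbit.label)                            # converged_fixed_point

# the ten-patient cohort
result = tt.classify_cohort(tt.reference_cohort())
print(result.n_correct, "/", result.n_total)  # 8 / 10
print(result.disagreeing)                     # ('2', '9')
```

The threshold 1.967 is the φ value where the nonzero equilibria lose
linear stability. At φ=0.6 (moderate stimulation) the orbit settles on an
equilibrium — the resolving regime. On the encoded ten-patient cohort the
prognosis agrees with the recorded outcome for 8 of 10 patients; the two
misses are patient 2 (a fungal infection, outside the Gram-negative
LPS/TLR4 axis the model covers) and patient 9 (culture-negative, assigned
a near-baseline φ and hence no applicable prediction).

From the shell:

```
tlr4traffic scan --phi-min 0.5 --phi-max 2.5 --phi-steps 5 --out scan.csv
tlr4traffic synth cohort --n 10 --seed 7 --out synth.csv
tlr4traffic cohort --in synth.csv --out result.csv
```

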