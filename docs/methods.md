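# Methods

## Model structure and assumptions

The kinetic core is a three-compartment linear model of an extracellular
gadolinium agent: plasma (volume V_p per kg body weight), a lumped body
EES (V_e), and the myocardial EES (fractional volume v_e per unit tissue).
Key assumptions, each of which bounds where the model applies:

- **Instantaneous bolus at t = 0.** First-pass redistribution and
  recirculation are not modelled; curves are meaningful from roughly one
  minute post injection. There is no infusion-duration parameter.
- **Passive myocardium.** The myocardial compartments are driven by the
  plasma concentration but do not feed back into it — their exchange flux
  is small against the whole-body interstitial pool. As a consequence the
  dose mass balance closes over plasma + body EES + renal clearance only,
  and this is what the conservation tests assert.
- **Linear exchange and clearance.** All fluxes are concentration-driven
  with constant coefficients (K, PS, GFR); no saturation, protein binding,
  or flow limitation.
- **Well-stirred compartments**, optionally relaxed for the tissue EES by
  the catenary split (below).

Under these assumptions the plasma curve is an exact biexponential and the
tissue EES curve a triexponential. The implementation carries these around
symbolically as exponential mixtures (amplitudes, rates), so evaluation,
time-integration (for cumulative renal clearance) and convolution against
a new compartment are all closed-form. Confluent (repeated-rate) cases are
resolved with t·e^(−mt) terms, triggered when rates coincide within a
relative 1e-10.

An independent verification path (`ode_oracle`) integrates the full
coupled system with LSODA at rtol 1e-11 / atol 1e-13; the test suite holds
the closed forms to within 1e-8 mmol/L of it on a 0–60 min grid for every
shipped preset.

## Parameters, units, defaults

All body quantities are per kg so that weight cancels in concentrations.

| parameter | meaning | unit | calibrated normal value |
|---|---|---|---|
| D | injected dose | mmol/kg | 0.1 |
| Hct / Hct_m | large-vessel / tissue hematocrit | — | 0.42 / 0.24 |
| GFR | renal clearance (stored total) | mL/min at 70 kg | 90 |
| V_b | blood volume | L/kg | 0.100 |
| V_e | body EES volume | L/kg | 0.09 |
| K | plasma↔body-EES exchange | L/min/kg | 0.0108 |
| v_mb | fractional tissue blood volume | — | 0.15 |
| v_e | fractional tissue EES | — | 0.17 |
| PS | permeability–surface product | mL/min per mL ≡ min⁻¹ | 1.3 |
| r1 | relaxivity | L/(mmol·ms) | 0.0042 |
| T1_b0 / T1_m0 | native blood / myocardial T1 | ms | 1535 / 962 |

Unit interpretations worth stating explicitly: K is an exchange coefficient
per kg body weight (L·min⁻¹·kg⁻¹), which puts the fast distribution
half-time in the minutes range consistent with the simulated curves; r1 is
stored in per-ms units (0.0042 L/(mmol·ms) ≡ 4.2 L/(mmol·s), the accepted
Gd-DTPA value at 1.5 T) so that T1 in ms needs no conversion; GFR is stored
as a total mL/min at the stated weight and converted internally to
L/min/kg.

Shipped presets: `initial` (literature starting values), `normal`
(calibrated to control-subject T1 curves), `scar` (expanded EES v_e = 0.95,
reduced PS = 0.41 and blood volume 0.05, native T1 1000 ms, overlaid on the
normal scenario), and `amyloid_midwall` / `amyloid_subendo` (expanded body
spaces V_b = 0.115, V_e = 0.13; diffusely infiltrated reference tissue
v_e = 0.75, PS = 0.32, native T1 1100 ms; subendocardial tissue v_e = 0.96,
PS = 0.44, v_mb = 0.04). The subendocardial native T1 is taken equal to the
mid-wall's 1100 ms, and the scar/amyloid tissue hematocrit equal to the
normal 0.24, since no separate values are established for them.

### Catenary tissue EES

For strongly expanded interstitium, a well-stirred single pool understates
late retention: agent must diffuse back toward the capillary before it can
clear. The catenary option splits v_e into a pericapillary pool (fraction
`f_peri`, default 0.25) exchanging with plasma, chained to a remote pool
through the coefficient `PS_ee` (default 0.1 min⁻¹). These defaults encode
only the qualitative constraint that the pericapillary pool is the smaller,
faster one; they are exposed in the scenario schema and are deliberately
not fitted — the late-time data cannot separate them from PS. The scalar
diffusion utilities (t = d²/4D, length = 2√(Dt), D defaulting to
2×10⁻⁴ mm²/s) give the order-of-magnitude justification: ~0.5 s across a
20 µm intercapillary distance, 100× that across 200 µm.

## Signal model

One T1 per channel from the volume-weighted total concentration (fast
water exchange); blood uses whole-blood concentration C_b = (1−Hct)C_p
with the native blood T1. The IR signal is the ideal single-inversion,
full-recovery form S = 1 − 2e^(−TI/T1) with unit proton density — no
readout perturbation, no Look-Locker/MOLLI specifics, no noise. Nulling is
recomputed per time point (TI = T1_ref·ln2 tracks the reference T1 as
contrast washes out), as TI is adjusted in practice; a fixed-TI mode
exists. These choices reproduce the qualitative orderings the package
tests: early-peaking scar enhancement over slowly falling blood signal,
and the amyloid blood-signal sign flip.

A consequence worth knowing: with the amyloid parameters the reference
tissue's distribution space (v_e + v_mb(1−Hct_m) ≈ 0.83) exceeds blood's
(1−Hct = 0.58), so the reference T1 falls *below* blood T1 at all matched
times. The "contrast collapse" between blood and myocardium is therefore
an ordering inversion — blood goes from the shortest-T1 channel (bright
when the reference is nulled) to longer-than-reference (negative PSIR
signal, dark) — rather than the two T1 curves meeting pointwise.

## Calibration design

The objective is (optionally sd-weighted) SSE on T1 in ms — T1 being the
measured quantity — minimized by bounded trust-region least squares
(SciPy), with the v_mb + v_e ≤ 1 constraint enforced by an SLSQP polish
step when the unconstrained optimum violates it. Stages freeze their
result; a plan cannot free the same parameter twice, and a stage that
fails to improve its own starting objective keeps its starting values and
records a warning.

Design choices that were genuinely open:

- **t = 0 extrapolation.** A biexponential is fitted to *all* blood
  points (initialized by curve peeling) and evaluated at t = 0; log-linear
  extrapolation of the first three points is the fallback when that fit
  degenerates. Fitting all points is markedly more robust to noise than
  any fixed-few-points rule, though back-extrapolation remains the
  noise-limiting step of the whole pipeline (the fast mode must be
  extrapolated from t ≥ 1 min data).
- **Joint {K, V_e} body stage.** With V_p fixed by extrapolation and GFR
  held at its configured value, K and V_e are jointly identifiable from
  the biexponential blood curve, and the default plan fits them together
  on the full window: noiseless recovery is then exact to machine
  precision. The more interpretable one-parameter-at-a-time alternative
  (`windowed_plan`: V_e on the late window t ≥ 15 min, where the curve
  level is set by V_p + V_e; then K on the early window t ≤ 10 min) is
  provided and tested, but a single pass of it carries an order-induced
  bias of a few percent — the window of each stage is not perfectly blind
  to the other stage's parameter. Fitting K *first*, with V_e still at a
  wrong value, is substantially worse (tens of percent) and is not
  offered as a default.
- **GFR frozen by default.** The renal tail is weakly identified on a
  45-min record; freeing GFR is an explicit plan choice.
- **Confounded pair v_mb/Hct_m.** The tissue signal constrains only the
  plasma-volume product v_mb(1−Hct_m). The default plan frees v_mb with
  Hct_m fixed (supplying the assumed tissue hematocrit); freeing Hct_m
  with v_mb fixed is the documented alternative. Recovered v_mb is
  meaningful only relative to the assumed Hct_m.
- Convergence: relative objective change below 1e-12 or 500 evaluations;
  bound-hitting parameters are reported as stage warnings rather than
  silently accepted.

## Synthetic data

The generator forward-simulates T1 and adds independent Gaussian noise on
T1 per point and channel (defaults 20 ms blood / 30 ms myocardium,
plausible T1-mapping precision), floored at 1 ms, fully determined by a
seed. The default grid is 1, 2, 3, 5, 7, 10, 15, 20, 30, 45 min — serial
post-bolus sampling starting after the first-pass window.

What it does *not* emulate: Rician magnitude-image noise, inter-subject
parameter variability, respiratory/cardiac-motion artifacts, partial-volume
contamination between blood pool and subendocardium, or measurement-grid
irregularity. Passing recovery tests therefore demonstrate the internal
consistency and identifiability of the pipeline under its own noise model,
not performance on clinical T1-mapping data.

Monte-Carlo behavior (computed by the test suite at 8 replicates per
level; problem size chosen to keep the default run in seconds): recovery
error grows continuously with noise sd, with median K error ~10–15% at
sd = 10 ms and degraded-but-bounded behavior at sd = 50 ms; the dominant
error source is the V_p back-extrapolation, whose error anti-correlates
with the K error.

## Known limitations

- Single linear-relaxivity agent; no transcytolemmal water-exchange model.
- The catenary sub-parameters are not identifiable from the data the
  fitting consumes and are never fitted.
- The ideal IR signal model omits proton-density weighting and readout
  effects; absolute signal levels are comparative, not quantitative.
- Renal clearance is single-exponential glomerular filtration; no
  tubular or hepatic pathways.
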