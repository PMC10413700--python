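# lgesim

Compartmental pharmacokinetic simulation of **late gadolinium enhancement
(LGE)** in cardiac MRI: contrast-agent kinetics, T1 relaxometry, inversion-
recovery / PSIR signal synthesis with reference-tissue nulling, and a staged
calibration of the model parameters to serial blood and myocardial T1
measurements.

It is aimed at quantitative-MRI and cardiac-imaging researchers who want to
understand — and numerically reproduce — why LGE looks the way it does in
normal myocardium, focal scar, and diffuse infiltration such as cardiac
amyloid (the characteristic faint subendocardial enhancement and the "dark
blood" appearance of PSIR images).

## Model

A dose *D* (mmol/kg) is injected into the plasma space *V_p = V_b(1−Hct)* at
*t = 0*. Plasma exchanges with a lumped body extravascular-extracellular
space (EES) and is cleared by the kidneys:

    V_p dC_p/dt = −K (C_p − C_e) − GFR · C_p
    V_e dC_e/dt =  K (C_p − C_e)

so the plasma concentration is an exact biexponential decay. The myocardial
EES is a passive tracer compartment driven by plasma through the
permeability–surface-area product *PS*:

    v_e dC_me/dt = PS (C_p − C_me)

giving a triexponential tissue curve; its feedback into plasma is neglected
(small against the whole-body interstitial pool). Total tissue concentration
is *C_t = v_mb(1−Hct_m) C_p + v_e C_me*. An optional **catenary** split of the
tissue EES (pericapillary pool exchanging with a larger, slower remote pool)
approximates diffusion-limited access to an expanded interstitium.

Concentrations map to relaxation via the linear-relaxivity relation
*1/T1 = 1/T1₀ + r1·C*, and image contrast via the ideal inversion-recovery
signal *S = 1 − 2 e^(−TI/T1)*, with *TI = T1_ref·ln 2* nulling a chosen
reference tissue (signed for PSIR, |S| for magnitude reconstruction).

Calibration is staged: back-extrapolation of blood concentration to the
injection time fixes *V_p*; bounded least squares then fits the body exchange
parameters {K, V_e} on the blood channel and {v_mb, v_e, PS} per tissue
channel, each stage freezing its result before the next runs.

## Worked example

Simulate a chronic-scar scenario and the corresponding PSIR time course:

```bash
lgesim psir --scenario scar --times 1,5,10,20,45 --out .
```

`scar_psir.csv`:

```
# units: time_min in minutes; TI in ms; S dimensionless in [-1, 1]
time_min,TI_null_ms,S_blood,S_myocardium,S_scar
1.0,251.74198703850217,0.2876533884749042,0.0,0.14917572144262614
5.0,343.1264682678985,0.19130642894685868,0.0,0.6046191258095146
10.0,390.9161516717376,0.13562035298501296,0.0,0.5550622076682994
20.0,416.02841783374754,0.10405160859551921,0.0,0.4797491847643508
45.0,448.13978535987167,0.06078764538451642,0.0,0.42888691951763824
```

The reference (normal) myocardium is nulled at every time point (S = 0, with
the nulling TI tracking its recovering T1); the scar signal peaks early
(~5 min, S ≈ 0.60) and then declines as contrast washes out, while the blood
signal falls slowly — the classic bright-scar/gray-blood LGE pattern. Running
the same command with `--scenario amyloid_subendo` gives a *negative* blood
signal: with a diffusely infiltrated reference myocardium the blood T1 is
longer than the nulled reference's, which is the "dark blood" sign of cardiac
amyloid.

Close the simulation→calibration loop on synthetic data:

```bash
lgesim generate --scenario normal --noiseless --out .
lgesim fit normal_observations.csv --scenario initial --out .
# RMSE 0.000 ms; wrote fit_result.json, fit_overlay.csv
```

The stage ledger in `fit_result.json` shows the recovered parameters
(V_b = 0.100 L/kg, K = 0.0108 L/min/kg, V_e = 0.090 L/kg,
v_e = 0.17, PS = 1.3 min⁻¹ — the generating values). The fitted
v_mb = 0.163 differs from the generating 0.15 exactly by the tissue-
hematocrit ratio (0.76/0.70): the data constrain only the product
v_mb(1−Hct_m), so v_mb is recovered when Hct_m is supplied.

See `docs/methods.md` for the model assumptions, parameter units and
defaults, and numerical choices.

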