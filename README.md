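# psmadyn

Quantitative analysis of short-term androgen-blockade effects on PSMA
expression and tumour cellularity, as measured by dynamic
[⁶⁸Ga]Ga-PSMA-11 PET/MR in hormone-sensitive prostate cancer.

Short-term non-steroidal antiandrogen (NSAA) treatment is hypothesised to
transiently *upregulate* the PSMA receptor even while tumour cellularity
falls — which matters for scheduling PSMA-targeted imaging and radioligand
therapy. Testing this requires more than static SUV readouts: it needs the
receptor-specific binding potential from dynamic PET, the apparent diffusion
coefficient from MR, and longitudinal statistics that respect the
repeated-measures design. This package implements that full chain for
researchers working with dynamic PET/MR response data, together with a
synthetic-data backbone so every stage is testable without patient data.

## What it computes

**Binding potential (SRTM).** For a lesion time–activity curve C_T(t) and a
receptor-free reference curve C_R(t) (gluteus maximus), the simplified
reference tissue model

C_T(t) = R₁ C_R(t) + (k₂ − R₁k₂ₐ) · (C_R ⊗ e^(−k₂ₐt)),  k₂ₐ = k₂/(1 + BP_ND)

is fitted by weighted Levenberg–Marquardt (weights from PET frame duration
and counts), yielding the non-displaceable binding potential BP_ND — the
equilibrium ratio of specifically bound to non-displaceable tracer, a proxy
for available PSMA density.

**Image quantification.** Decay correction to injection time, adaptive
lesion segmentation at a 40% relative threshold, TAC extraction from the
VOI, mono-exponential ADC fitting (S(b) = S₀e^(−b·ADC)), and SUVpeak as the
maximum mean SUV in a 1-ml sphere inside the lesion VOI.

**Longitudinal statistics.** Per-lesion/per-patient percent fold changes
from baseline (ΔBP_ND%, ΔADC%, ΔSUV%, ΔPSA%) at treatment days 0/7/21/28;
median (IQR) group summaries; linear mixed-effects trajectory models with
polynomial time terms up to cubic and patient/lesion random intercepts
(REML); mixed-model Bland–Altman bias and limits of agreement; and a
concordance correlation coefficient for repeated measures.

**Synthetic data.** A tri-exponential plasma input drives one-tissue
reference kinetics and the SRTM forward model on a fine time grid,
frame-averaged to the 55-frame dynamic protocol (15×20 s, 15×40 s, 25×60 s);
4D phantoms and multi-b DWI stacks exercise the image chain; a cohort
generator reproduces the study's trajectory shapes with per-patient random
effects. The study's printed serum-PSA table ships as a package fixture.

## Worked example

```
$ python analysis/04_psa_response.py
7/8 patients below baseline PSA at week 4
day-28 dPSA%: median -88.3 (IQR -89.7 to -29.1), n=7
LME: dPSA% declines -2.17 %/day (95% CI -2.79 to -1.56, p=1.1e-07; 28 of 32 scheduled visits had PSA values)
```

Seven of the eight patients respond biochemically; by day 28 the median PSA
has fallen 88.3% from baseline among the seven patients with PET-visible
disease (the PET-negative patient is excluded from imaging-linked
summaries), and the mixed model estimates a 2.17 %/day decline.

```
$ python analysis/03_fit_kinetics.py --seed 1
extracted-TAC fit: R1=1.199 k2=0.301/min BPnd=1.999 (truth 2.0)
50 noisy replicates: mean BPnd 1.991 (bias -0.45%), SD 0.048
```

The phantom round trip — simulate kinetics, voxelize, segment at the 40%
threshold, extract the TAC, fit SRTM — recovers the generating BP_ND of 2.0
essentially exactly, and stays unbiased under realistic frame noise.

The other drivers follow the same pattern: `01_simulate_cohort.py` writes
the synthetic TACs and visit table, `02_quantify_phantom.py` runs the
segmentation/SUVpeak chain, and `05_trajectory_models.py` fits the cubic
ΔBP_ND% model, the ΔADC% slope, the extended model with ΔADC% as covariate,
and the ΔSUV%-vs-ΔBP_ND% agreement analysis on a simulated cohort. A thin
`psmadyn` CLI (`simulate`, `quantify`, `fit-kinetics`, `adc`, `analyze`,
`run-all`) wraps the same library calls for file-based use.

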