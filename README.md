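# senoscope

Multiparametric imaging analysis of cellular senescence phenotypes.

Senescent fibroblasts remodel their lysosomal and mitochondrial compartments:
acidotropic dyes (LysoTracker) report lysosome mass and acidification,
potentiometric dyes (MitoTracker) report mitochondrial membrane potential
(Δψ_M), SA-β-galactosidase staining marks the senescent fraction, and
p16^INK4a nuclear partitioning confirms proliferative arrest.  `senoscope`
turns single-cell fluorescence images of such experiments — across donors of
different ages (YD, OD), replicative senescence (RS), and genotoxic inducers
(doxorubicin, cisplatin, etoposide, bleomycin) under serum starvation — into
reproducible quantitative endpoints.  It is written for imaging labs that
quantify senescence induction and for method developers who need a fully
synthetic, ground-truth-bearing test bed for distributional single-cell
analyses.

## What it computes

**Area-normalised intensity densities.**  Raw fluorescence inside a manually
drawn cell mask is divided by the projected cell area
(pixel count × pixel size², µm²), yielding per-pixel intensity densities
(a.u./µm²) for the lysosomal arm and one mean density per cell for the
mitochondrial arm.  This decouples organelle readouts from cell spreading.

**Multimodal histogram profiling.**  Per-condition densities are binned into
30,000 log-spaced intervals and averaged across cells (counts·bin⁻¹·cell⁻¹).
Local maxima of each curve — detected by prominence and minimum distance —
mark lysosomal subpopulations.  Peak positions are modelled with a linear
mixed model fitted by maximum likelihood,

```
log10(X_peak) ~ C_donor + C_inducer + peak_id + (1 | curve)
```

with Wald 95% CIs, Shapiro–Wilk residual normality and Levene variance
homogeneity diagnostics.  Distribution *shape* differences between donors are
tested per inducer with the k-sample Anderson–Darling test (only where every
donor contributes ≥ 2 peaks) under Benjamini–Hochberg FDR control.

**CDF inflexion-point segmentation.**  Per-cell mitochondrial densities X are
summarised as an empirical CDF α(u), u = log10(X), scaled 0–100% of cells.
The local maxima of dα/du (θ₁ < θ₂) partition the population into
depolarised / mid / hyperpolarised fractions

```
Δψ1 = α(θ1),   Δψ2 = α(θ2) − α(θ1),   Δψ3 = 100 − α(θ2),
```

which sum to 100 for every curve; condition contrasts are pure
redistributions of percent (|Δ| ≤ 5 pp treated as insignificant).

**SA-β-Gal scoring.**  From per-field counts: positive fraction
S% (mean ± SE across fields), relative survival V%rel, and the selectivity
index SI = S% / (100 − V%rel) — the yield of induced senescent cells per
unit of cell loss.  Flow-cytometry readouts are summarised as MFI ± IQR.

**Synthetic studies.**  Because such raw imaging data are rarely shareable,
`senoscope.synthetic` generates every input with known ground truth: masked
cell images, lognormal-mixture event populations with donor/inducer/curve
structure, bimodal Δψ_M populations with analytic fractions, and count/flow
tables — all byte-reproducible from a single seed.

## Worked example

```python
import numpy as np
import senoscope as ss

spec = ss.ScenarioSpec(seed=42)                      # 3 donors x 6 inducers
cells, truth = ss.generate_intensity_population(spec, "RS", "Bleo")
profile = ss.build_profile(cells, n_bins=30_000, curve_id="RS:Bleo")
peaks = ss.detect_peaks(profile, smooth_window=600)
print(len(peaks), np.round(peaks.positions, 3), np.round(truth.modes, 3))

obs, _ = ss.generate_peak_observations(spec, n_curves=60)
fit = ss.fit_peak_lmm(obs)
print(fit.fixed_effects.round(4))

values, _ = ss.generate_mito_population(spec, "RS", "Bleo")
cdf = ss.segment_profile(ss.build_cdf(values, condition="RS:Bleo"))
print(np.round(cdf.thetas, 3), np.round(cdf.fractions, 1))

print(ss.selectivity_index(80.0, 50.0).value)
```

prints

```
2 [1.939 3.429] [1.916 3.416]
         term  estimate     se     p  ci_low  ci_high
    Intercept    1.0031 0.0394 0.000  0.9259   1.0803
    donor[OD]    0.2862 0.0336 0.000  0.2204   0.3520
    donor[RS]    0.4684 0.0333 0.000  0.4031   0.5337
...
      peak_id    0.4068 0.0076 0.000  0.3920   0.4217
[2.132 3.945] [20. 48. 32.]
1.6
```

Both lysosomal modes of the RS:Bleo curve are recovered within ~0.02 log10
units of the generating truth; the fitted donor offsets (+0.29 OD, +0.47 RS)
and per-peak slope (+0.41) bracket the generating values (+0.3, +0.5, +0.4);
the Δψ fractions sum to exactly 100; SI(80, 50) = 1.6 by definition.

A full run — quantification, profiling, statistics, segmentation, scoring,
figures — is one call (or `senoscope run --config run.json` from a shell):

```python
report = ss.run_pipeline(ss.RunConfig(out_dir="out", seed=7))
```

`senoscope synthesize --out study/` writes a complete on-disk study (TIFF +
masks + manifest + counts) that the same pipeline consumes in manifest mode.

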