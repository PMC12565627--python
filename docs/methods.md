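# Methods

This note records the statistical models, the numerical choices and the
limits of what the synthetic test bed can demonstrate.

## Image reduction and normalisation

Confocal stacks are reduced to one analysis plane before quantification:
4-D `(channel, z, y, x)` arrays have their first channel summed over z
(an extended-depth-of-focus-style projection that conserves integrated
signal), 3-D arrays contribute their first channel, 2-D planes pass
through.  The isotropic pixel size is the arithmetic mean of the X and Y
physical pixel sizes when both are present (they differ only by metadata
rounding on square-pixel detectors), otherwise whichever axis is known.

Masks are drawn manually and stored as rasters; any value above 50% of the
raster maximum counts as cell, which makes the same threshold work for
8-bit (255) and 16-bit (65535) exports.  Masks are conformed to the image
grid by nearest-neighbour interpolation, which preserves the binary label
set and is idempotent when shapes already match.  Mask pixels are treated
as the filled cell *region*; an optional hole-filling step
(`fill_holes=True`) converts outline-style masks, since both the area and
the per-pixel normalisation require a region, not a contour.

All readouts are normalised by the 2-D projected area
A = N_px · s² (µm², s = pixel size).  Two normalisations coexist by
design: the lysosomal arm is distributional (one density per in-mask
pixel, raw/A), the mitochondrial arm is scalar (integrated in-mask
intensity / A, one value per cell).  Both derive from the same in-mask sum,
which the tests assert as a cross-consistency invariant.

## Histogram profiling and peak detection

Per-condition ("curve") histograms use n_bins = 30,000 log-spaced bins.
Log spacing cannot reach zero, so the lower edge is placed at the smallest
positive observed value × (1 − 10⁻⁶); zero-valued events are excluded and
their count is reported on the profile and in the run log.  Counts are
pooled over cells and divided by the cell count, which equals the per-cell
average because all cells share one set of edges.

Local maxima are detected on the counts-per-bin-per-cell curve by
prominence and minimum distance (`scipy.signal.find_peaks`).  Defaults:
prominence = 2% of the curve maximum, minimum distance = 1% of the bin
count; plateaus resolve to their left-most bin; positions are reported at
bin centres on the log10 axis.  Detection runs on the raw curve by
default.  An optional moving-average window is exposed for event counts of
a few hundred per cell: at ~10⁵ events spread over 30,000 bins a mode bin
holds only ~13 counts, so Poisson fluctuations (~30% relative) would
otherwise satisfy any max-relative prominence rule; the window used
throughout the pipeline and the acceptance analyses is 2% of the bin count
(600 bins ≈ 0.03 log10 units), chosen from that counts-per-bin calculation
— it suppresses shot noise ~25-fold while biasing symmetric mode positions
negligibly relative to the ±0.05 log10 recovery tolerance.  Peak positions
are invariant under vertical rescaling of the curve when the prominence
threshold is scaled along, matching the percent-based reasoning of the
downstream analyses.

## Mixed model on peak positions

Peak positions are modelled as

    log10(X_peak) ~ C_donor + C_inducer + peak_id + (1 | curve)

fitted by maximum likelihood (`statsmodels.MixedLM`).  `peak_id` enters as
a numeric ordinal because successive maxima occur at systematically higher
intensities and the trend, not the level set, is of interest.  The donor
reference is YD; the inducer reference is configurable and defaults to the
10%-serum control C10 (the 1%-serum condition C1 is itself a treatment —
starvation — so offsets are most interpretable against full serum).
Fixed-effect inference is large-sample Wald (z): coverage of the 95% CIs
measured over 100 replicated synthetic studies is 92–95% per term, i.e.
mildly anti-conservative, as expected for ML variance estimates without
small-sample df corrections, which are out of scope.  The design matrix is
built explicitly; a rank-deficient design (a level perfectly aliased with
the rest) raises an estimability error naming the offending term.

Residual normality (Shapiro–Wilk) and across-donor variance homogeneity
(Levene) accompany every fit.  Distribution shape across donors is
compared per inducer with the k-sample Anderson–Darling test on pooled
peak positions, restricted to inducers where *every* donor contributes at
least `min_peaks = 2` peaks; exclusions are results, not errors.  The
scipy implementation tabulates p only within [0.001, 0.25]; values outside
are clamped and flagged `p_clamped`.  Because one curve can contribute
several peaks, the AD test treats dependent observations as independent;
every shape-test report carries this pseudo-replication caveat, and
main-factor inference rests on the mixed model, whose random intercept
absorbs the within-curve dependence.

## CDF segmentation of Δψ_M

Per-cell mean densities X are summarised as the empirical CDF α(u),
u = log10(X), in percent of cells on a uniform 1,000-point grid spanning
the positive data range.  Inflexion points θ_M are the local maxima of
dα/du — i.e. the modes of the per-cell density — estimated by central
finite differences after moving-average smoothing (default window 2% of
the grid).  Three numerical guards keep mode counting honest on empirical
derivatives:

* a minimum distance between accepted maxima (default 10% of the grid), so
  sampling bumps riding one density mode collapse to the strongest;
* a relative-prominence filter (each retained mode must reach 25% of the
  strongest mode's prominence), which removes shoulder noise but also
  means minority modes lighter than roughly a tenth of the population are
  not resolved;
* a flatness guard: when the derivative maximum is below 1.5× its median
  the density has no real interior mode (a uniform-in-u sample), and the
  curve is flagged single-population with fractions (100, 0, 0).

Segment fractions are evaluated on the *exact* empirical CDF at θ, not the
gridded curve, to avoid grid bias.  Δψ₃ is computed as the complement of
the rounded partial sum 100 − (Δψ₁ + Δψ₂), which is algebraically the
defining 100 − α(θ₂) and makes the triple sum to exactly 100.0 in floating
point; redistribution deltas use the same construction so they sum to
exactly 0.  Two θ give the standard three segments; exactly one interior
mode yields a documented two-segment fallback.  The three-segment
partition (from two thresholds) is the primary output; θ are computed
per curve.  Differences of at most 5 percentage points between conditions
are reported as insignificant.

## SA-β-Gal scoring

Fields are the replication unit: S% is the mean of per-field percentages
and its SE is computed across fields, not from a pooled binomial (wells
and fields carry shared technical variation that a pooled binomial would
understate).  Zero-total fields are excluded with a warning.  V%rel
averages per-field treated totals over the mean control total (×100) and
may legally exceed 100.  SI = S% / (100 − V%rel) is returned as an
undefined-but-explained result (never an exception) when V%rel ≥ 100.
Flow summaries use linear-interpolation quartiles, declared on the output.

## The synthetic test bed

The generator emulates the statistical *structure* of the study, not the
appearance of micrographs: lognormal mixtures (1–3 components) on the
log10 density axis, because the analyses operate in the log domain and
multimodality reflects coexisting resident lysosomes and stress-induced
autolysosomes; additive donor offsets (YD 0, OD +0.3, RS +0.5 log10) and
inducer offsets relative to C10, sized so that ageing shifts are
detectable at desk scale; a per-curve random intercept (SD 0.1 log10)
matching the mixed model's grouping; 200 cells per condition × 500 events
per cell (within the study-scale 95–600 cells, enforced by validation);
bimodal Δψ_M mixtures (modes u = 1 and 3, SDs 0.25, weights 0.3/0.7) with
analytically known segment probabilities; binomial field counts around
known S% (donor baselines 2.5 / 9.1 / 16.3%) with Poisson totals around
known V%rel; lognormal flow events around condition MFIs.  A single seed
fans out to named child streams (CRC-keyed), so any module's inputs can be
regenerated independently and identically.

Cell-field images paint non-overlapping ellipses whose in-mask pixel value
is density-draw × cell-area, so the quantification stage recovers the
generating mixture draws exactly — a closure test of the whole image path.

What passing tests therefore show: the pipeline recovers known mixture
structure, fixed effects, segment fractions and scores from data that obey
its model assumptions, deterministically.  What they cannot show: behaviour
under optical artefacts absent from the generator — background and
photobleaching gradients, detector saturation, segmentation errors,
overlapping cells, spatially correlated noise — nor the biological
validity of any threshold.  Real-image conclusions still require the
acquisition-matched controls the assay itself prescribes.

## Problem sizes and determinism

The default pipeline scenario is the full 3 × 6 factorial at 200 cells ×
500 events per condition; unit tests run reduced factorials (2 × 2, 95
cells) and coarser binning, sizes chosen to exercise every code path at
interactive turnaround.  Simulation-based checks use 100 replicates for
mixed-model coverage/bias, 1,000 for test calibrations.  All randomness
flows from explicit seeds; rerunning any configuration reproduces CSV
outputs byte-for-byte (asserted in the tests and recomputed by
`scripts/acceptance.py`).

## Known limitations

* Peak detection parameters (prominence, distance, smoothing) are declared
  defaults, not estimates; curves with modes closer than the smoothing
  window will merge.
* The AD test's tabulated p-range forces clamping at both extremes; very
  strong or very weak evidence is reported at the bounds.
* Mode counting on empirical CDF derivatives cannot resolve minority
  subpopulations below ~10% weight (relative-prominence filter).
* The two-segment fallback and the single-population flag change the
  meaning of the fraction columns; downstream consumers must check
  `single_population` and the theta count.
* CZI reading requires the optional `czifile` dependency; without it, use
  TIFF plus sidecar metadata.
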