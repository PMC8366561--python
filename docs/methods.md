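# Methods

`texhist` implements a filtration-histogram texture-analysis pipeline for
paired 2D CT/PET tumor slices and the downstream prognostic screen, together
with a synthetic phantom/cohort generator that provides ground truth for
every stage.

## The filtration-histogram technique

Each lesion is represented by one 2D CT slice (Hounsfield units) and the
corresponding most-avid 2D PET slice (standardized uptake values), each with
a manually drawn binary ROI on its own pixel grid. No cross-modality
resampling or registration is performed: features are computed per modality
on the native grid.

**Filtration.** The CT slice is convolved with a Laplacian-of-Gaussian (LoG)
band-pass kernel at spatial scale filter (SSF) values of 2 mm (fine),
3–5 mm (medium), and 6 mm (coarse), plus an unfiltered control (SSF 0, an
exact identity). PET is analyzed unfiltered only; at 4 mm pixels the fine
and medium scales are unresolvable and filtration adds nothing at the coarse
one.

Kernel details, all configurable via `FilterConfig`:

- σ mapping: `sigma_mm = 0.5 * ssf_mm`. Commercial implementations do not
  publish their constant; absolute filtered values depend on this choice but
  the cross-patient orderings the survival analysis consumes do not.
- Anisotropic pixel spacing is handled by a per-axis σ in pixels
  (`sigma_mm / spacing_mm`); construction refuses scales whose σ falls below
  0.4 px (unresolvable on the grid).
- The sampled kernel is σ²-scale-normalized. This is what makes the bank
  *band-pass* in the scale-selection sense: the normalized center response to
  a Gaussian blob of width σ_b is ∝ σ_b²σ_f²/(σ_b²+σ_f²)², peaking at
  σ_f = σ_b, i.e. at SSF equal to the blob "diameter" 2σ_b under the default
  mapping. Without the normalization the response decreases monotonically
  with scale and no scale selectivity exists.
- The kernel is negated (bright blobs respond positively) and shifted to sum
  exactly to zero, so responses are invariant to additive intensity offsets
  and a constant image filters to zero. Truncation at 4σ; reflect padding by
  default (constant padding available for phantoms with known background).
- Responses below a machine-noise floor (100·eps·max|input|) are snapped to
  exactly zero, so a constant slice yields genuinely degenerate filtered
  statistics rather than ±1e-13 summation residue.

**Quantification.** Within the ROI, each map is summarized by six
first-order statistics: mean, SD, entropy, mean of positive pixels (MPP),
skewness, and kurtosis. Conventions (configurable via `StatConfig`):

- Population (1/n) moments throughout, matching classical texture-analysis
  practice; no small-sample bias correction.
- Kurtosis is *excess* kurtosis by default (normal → 0); Pearson selectable.
- Entropy is Shannon entropy in bits over 64 equal-width bins spanning the
  ROI's own [min, max]; a single-valued input has entropy 0. Bin count is
  configurable since the analysis uses only relative orderings. Note that
  this estimator is invariant under positive affine rescaling of the values.
- MPP is the mean over strictly positive values and is reported missing when
  none exist (on unfiltered all-positive maps it degenerates to the mean but
  is computed anyway for vector completeness). Skewness and kurtosis are
  missing at zero SD. Missing values are explicit NaNs, never dropped
  columns: the CT block always has 36 entries and the PET block 6.
- CT ROI pixels below −50 HU (air, gas) are excluded. Eligibility is decided
  once on the *unfiltered* HU values and reused for every filtered map of
  the lesion, so all scales summarize the same pixel set. Whether exclusion
  should instead precede filtration is unknowable from published
  descriptions; applying it only at the statistics stage is the
  implementation here and the exclusion threshold is a config knob for
  sensitivity analysis.

Conventional PET metrics complete the 45-entry feature vector: SUVmax,
SUVmean, and tracer-uptake tumor area as the ROI pixel count (mm² conversion
available via the pixel area).

## Patient-level aggregation

Per patient, up to the five most PET-avid lesions (largest in-ROI SUVmax)
enter the analysis; each feature is averaged over the lesions where it is
present and is missing only if missing everywhere. Aggregation is
permutation-invariant and bounded by the per-lesion range. A hook accepts
alternative aggregators, but only the mean ships.

## Survival screen

For each endpoint (PFS, OS) and each candidate marker:

1. **Median dichotomization.** Threshold = sample median; "above" means
   strictly greater (ties fall below). Markers with all-identical values are
   skipped with a log entry, never silently dropped.
2. **Kaplan-Meier + log-rank.** Product-limit curves per group (lifelines);
   median survival is the smallest t with S(t) ≤ 0.5, reported "Not
   reached" when the curve stays above 0.5. Groups are compared with the
   standard 1-df log-rank test. The reported poor-prognosis direction is the
   side of the cut-off with the shorter median survival (restricted-mean
   survival breaks median ties).
3. **Benjamini-Hochberg.** One step-up family per endpoint across all
   markers tested there, at FDR level q = 0.30 by default. The family
   membership is config-listable.
4. **Forward-Wald Cox selection.** BH-significant markers enter as their
   median-split binaries. At each step, every remaining candidate is added
   to the current model in turn and the one with the largest Wald statistic
   enters if its conditional Wald p < 0.05; there is no removal step (the
   procedure is pure forward; a backward-elimination criterion would be a
   different method). Partial-likelihood maximization uses Breslow tie
   handling by default with Efron selectable (statsmodels `PHReg`);
   Wald p = (β/SE)² on χ²(1) and CI95 = exp(β ± 1.96·SE). Monotone
   likelihood (separation) is reported as a warning with the diverging
   coefficient, and candidates whose trial fit fails are skipped for that
   step.

With fixed inputs and configuration the whole pipeline is deterministic;
every report carries the package version and a hash of the analysis
parameters.

## Synthetic data: what it emulates and what it does not

`PhantomSpec`/`CohortSpec` defaults are the reference study conditions:
44 patients with 1–7 lesions each, CT at 0.98 × 0.98 mm pixels, PET at
4 × 4 mm (deliberately coarse, which is why PET is analyzed unfiltered),
soft-tissue CT background ≈ 40 HU, PET background ≈ 1 SUV with plateau
uptake ≈ 8 SUV, baseline exponential hazards calibrated so the null cohort
has median PFS ≈ 22 and median OS ≈ 37 months, administrative censoring at
82 months plus independent uniform dropout, and a latent per-patient
heterogeneity score z (standard normal, standardized within-cohort) entering
the hazard as log-HR = log 2.5 per SD for both endpoints.

The generator's construction links z to the texture features on purpose:

- **CT**: a sparse, z-independent number of Gaussian blobs (Poisson rate 2,
  diameters 3–6 mm) whose signed amplitude SD scales as `35·exp(z)` HU over
  6 HU pixel noise. Sparse high-amplitude blobs give heavy-tailed filtered
  response histograms, so filtered SD and kurtosis rise with z. (Scaling
  blob *density* instead would push the maps toward Gaussianity and lower
  kurtosis — the opposite of the intended construction.) An optional air
  pocket (−1000 HU) exercises the HU-exclusion rule.
- **PET**: a flat-topped hot disc with per-pixel texture SD `0.35·exp(0.9z)`
  SUV, point-spread blurred. The ROI is drawn ~15% outside the lesion edge,
  as a manual ROI would be; the captured background pixels anchor the
  histogram range so entropy rises with texture amplitude (the 64-bin
  entropy over the ROI's own range is scale-invariant and would otherwise
  not respond).

`heterogeneity_markers()` returns exactly the features this construction
drives upward (CT SD/kurtosis at all scales, unfiltered PET entropy);
skewness is direction-ambiguous under signed blobs and CT entropy is not
monotone under amplitude scaling, so both are excluded from ground-truth
scoring.

Survival times: death ~ Exp(λ_OS·e^{β·z}) with λ_OS = ln2/37 mo⁻¹;
progression ~ Exp(λ_prog·e^{β·z}) with λ_prog = ln2·(1/22 − 1/37), so that
PFS = min(progression, death) has median ≈ 22 months at z = 0 and the PFS
event time never exceeds the OS event time. Censoring is
min(82, U(0, 164)) months, independent of z.

What the phantoms do **not** model: anatomical realism, PET reconstruction
physics and partial-volume effects, inter-lesion heterogeneity within a
patient (all of a patient's lesions share one z), correlated clinical
covariates, and non-proportional hazards. Passing the end-to-end tests
therefore shows that the pipeline recovers a known imaging-to-outcome signal
under its own assumptions — not that the specific markers are prognostic in
real patients.

## Problem sizes used in the test suite

The suite exercises frequentist calibration at sizes chosen to keep
Monte-Carlo error well below the tested tolerances: log-rank type-I error
with 2000 null replicates at 50 subjects/arm; Cox recovery of HR 2.5 with
200 replicates at n = 500 and ~30% censoring; end-to-end ground-truth
recovery on single simulated cohorts of n = 300 (one with β = log 2.5, one
null). The statistics oracle comparison uses 1000 random pixel sets at
1e-10 relative tolerance.

## Known limitations

- The σ-per-SSF constant and entropy binning of commercial texture software
  are unpublished; absolute feature values here are not interchangeable with
  TexRAD-style outputs, though orderings should be comparable.
- The forward-Wald procedure has no removal step and a fixed 0.05 entry
  threshold; published descriptions of such analyses rarely state either.
- DICOM support is read-only (single-frame, slope/intercept rescale); SUV
  normalization from injected dose and body weight is out of scope — PET
  inputs are assumed to already be in SUV.
- Median-split Cox covariates discard within-group information by design
  (that is the method being reproduced), and the log-rank χ² approximation
  is mildly anti-conservative below ~50 events/arm.
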