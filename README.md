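# texhist

Filtration-histogram texture analysis of paired CT/PET tumor slices with a
median-split prognostic screen — an open, tested implementation of the
radiomics workflow used in single-slice heterogeneity studies of solid
tumors (e.g. neuroendocrine cancers imaged with somatostatin-receptor PET),
for imaging scientists who want to run, audit, or simulate that workflow
without access to proprietary texture software or patient data.

## What it computes

**Texture features.** Each lesion is a 2D CT slice (HU) and its most-avid
2D PET slice (SUV), each with a binary ROI on its native grid. The CT slice
is band-pass filtered with a zero-mean Laplacian-of-Gaussian kernel at
spatial scale filter (SSF) values 2 mm (fine), 3–5 mm (medium) and 6 mm
(coarse), plus an unfiltered control; ROI pixels below −50 HU (air/gas) are
excluded. Each map is summarized by six first-order statistics

- mean, SD (population), entropy `−Σ pᵢ log₂ pᵢ` over 64 equal-width bins,
  mean of positive pixels (MPP), skewness, excess kurtosis,

giving 36 CT features (6 statistics × 6 scales) and, because 4 mm PET pixels
cannot support mm-scale filtration, 6 unfiltered PET features — plus
SUVmax, SUVmean, and tracer-uptake tumor area in pixels.

**Prognostic screen.** Lesion features are averaged to patient level (up to
the 5 most avid lesions). For each endpoint (PFS, OS) every marker is
dichotomized at its median, the groups are compared by Kaplan-Meier curves
and the log-rank test, p-values are Benjamini-Hochberg adjusted within the
endpoint's family (FDR q = 0.30), and the significant markers enter a
forward-Wald Cox proportional-hazards selection (entry p < 0.05, Breslow
ties, HR = exp(β) with normal-approximation 95% CI).

**Synthetic ground truth.** A phantom generator produces textured CT
lesions and coarse flat-top PET lesions whose heterogeneity is driven by a
latent per-patient score z, and survival times with hazard
λ·exp(β·z) under independent censoring — so the whole
imaging-to-survival chain can be validated against known truth. See
`docs/methods.md` for the model, parameter defaults, and what the phantoms
do and do not emulate.

## Worked example

```python
import texhist as th
from texhist.cohort import analysis_table_from_records

# simulate a 44-patient cohort with log-HR = log 2.5 per SD of heterogeneity
patients, _ = th.make_cohort(th.CohortSpec(n_patients=44, seed=7))
table = analysis_table_from_records(patients)   # extract + aggregate

results, _ = th.run_univariate_screen(
    table, "os", ["ct_ssf6_kurtosis", "pet_ssf0_entropy", "suv_max"], q=0.30
)
for r in results:
    print(f"{r.marker:18s} cutoff={r.threshold:5.2f}  poor={r.poor_prognosis:5s}  "
          f"median below/above = {r.median_below:4.0f}/{r.median_above:4.0f} mo  "
          f"(n={r.n_below}/{r.n_above})  p={r.p_raw:.3f}  p_BH={r.p_adjusted:.3f}")
```

prints

```
ct_ssf6_kurtosis   cutoff= 3.60  poor=below  median below/above =   31/  39 mo  (n=22/22)  p=0.884  p_BH=0.884
pet_ssf0_entropy   cutoff= 4.20  poor=above  median below/above =   65/  27 mo  (n=22/22)  p=0.040  p_BH=0.120
suv_max            cutoff= 9.20  poor=above  median below/above =   57/  20 mo  (n=22/22)  p=0.182  p_BH=0.273
```

Patients above the median unfiltered-PET entropy (the cut-off 4.20) have a
median overall survival of 27 months versus 65 below it — high heterogeneity
is the poor-prognosis side, as built into the generator — and the marker
survives BH at q = 0.3 (adjusted p = 0.12) even at pilot-study size, while
coarse-CT kurtosis does not reach significance at n = 44 for this draw.

The same pipeline runs from the shell on a written cohort
(`texhist simulate`, `texhist extract`, `texhist survival`, or
`texhist run-all`); outputs are deterministic for a fixed seed and every
report embeds the package version and a hash of the analysis parameters.

Estimator-style interfaces (`TextureFeatureExtractor`, `MedianSplitScreen`,
`ForwardWaldCoxSelector`) expose the same stages with scikit-learn
`fit`/`transform` semantics for use inside sklearn pipelines.

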