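# radstab

Test–retest repeatability analysis of radiomics features on volumetric
MR images.

Radiomics converts medical images into large panels of quantitative
descriptors — first-order intensity statistics, shape descriptors, and
grey-level texture features (GLCM, GLRLM, GLSZM).  Before any such
feature can serve as an imaging biomarker it must be *repeatable*: its
value must stay stable when the same subject is scanned twice under
unchanged conditions.  Repeatability, however, depends heavily on the
processing chain — intensity normalization, pre-filtering, the
discretization bin width, and whether texture is computed in 2D or 3D.
`radstab` is for imaging scientists who want to quantify that
dependence: it runs a full feature-extraction grid over a test–retest
cohort and estimates per-feature repeatability under every processing
configuration.

## The measure

For two scans per subject, with both between-subject and within-subject
variability modelled as independent random effects, repeatability is the
one-way random-effects intraclass correlation

```
ICC(1,1) = (BMS − WMS) / (BMS + WMS)
```

where BMS and WMS are the between- and within-subjects mean squares of
the one-way ANOVA.  The ICC is invariant under affine rescaling of the
feature, so features living on arbitrary scales can be compared by it.
Because absolute ICC thresholds are population-dependent, each feature's
ICC is compared to an in-study reference: the ICC of the tumor **Volume**.
Confidence intervals use the Shrout–Fleiss F-based construction.

## The processing grid

* **Normalization** — none; whole-image scale-and-shift to mean 300 /
  SD 100; or an affine map fitted on a homogeneous muscle-like reference
  region to mean 100 / SD 10, applied image-wide.
* **Pre-filters** (18 by default in 3D) — original; Laplacian-of-Gaussian
  at σ = 1–5 mm; the 8 sub-bands of a single-level stationary wavelet
  transform; and four single-voxel transforms (square, square root,
  logarithm, exponential) rescaled back to the original intensity range.
* **Discretization** — fixed bin widths 10, 15, 20 and 40, anchored at
  the ROI minimum, computed from ROI intensities only.
* **Texture dimensionality** — 2D (per-slice, merged) or 3D.

Because no real test–retest MR cohort ships with known ground truth, the
package includes a synthetic phantom generator with an explicit variance
decomposition (between-subject anatomy vs per-scan noise, gain/offset
drift and contour jitter), for which the theoretical ICC of the ROI-mean
feature is available in closed form.

## Worked example

```python
from radstab import demo_config, icc_1_1, run_study

# repeatability of one hand-entered feature
res = icc_1_1([(1, 2), (4, 5), (7, 9)], alpha=0.1)
print(f"ICC(1,1) = {res.icc:.3f}  (BMS={res.bms:.3f}, WMS={res.wms:.3f}, "
      f"90% CI {res.ci_low:.3f}..{res.ci_high:.3f}, n={res.n_subjects})")

# a reduced synthetic study, end to end
report = run_study(demo_config(n_subjects=5, seed=7), "out/readme_demo")
print(f"Tumor Volume reference ICC: {report.references[('tumor', 'synthetic')]:.3f}")
print(report.top3[report.top3.roi == "tumor"].head(6).to_string(index=False))
```

prints

```
ICC(1,1) = 0.910  (BMS=21.167, WMS=1.000, 90% CI 0.378..0.995, n=3)
Tumor Volume reference ICC: 0.607
  roi image_type feature_class      feature  best_icc   icc_min  icc_max
tumor  synthetic    firstorder         Mean  0.939208  0.255195 0.939208
tumor  synthetic    firstorder 90Percentile  0.936925 -0.289403 0.936925
tumor  synthetic    firstorder     Skewness  0.913101 -0.440933 0.913101
tumor  synthetic          glcm JointEntropy  0.910346 -0.196573 0.910346
tumor  synthetic          glcm  JointEnergy  0.881026  0.017575 0.881026
tumor  synthetic          glcm  Correlation  0.848979 -0.100224 0.848979
```

The first line is the ICC of three subjects measured twice: the
between-subject spread (BMS ≈ 21.2) dwarfs the scan-to-scan disagreement
(WMS = 1), giving high repeatability with a wide interval at n = 3.  The
study report then shows, for a 5-subject synthetic cohort, the tumor
Volume reference ICC and the three most repeatable features per class at
their best pre-filter — together with how far their ICC falls under the
worst filter (`icc_min`), illustrating how strongly repeatability
depends on the processing choice.

A command-line interface mirrors the pipeline stages
(`radstab simulate | extract | icc | report | run`); images travel as
NRRD/NIfTI, tables as CSV.

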