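# habitat-ppa

Spatial point-pattern analysis of MR-derived tumor intensity habitats.

## The problem

Glioblastomas are radiologically heterogeneous: contrast enhancement and
edema vary across the tumor, and the *spatial arrangement* of these
subregions — not just their volume — may carry prognostic information.
`habitat-ppa` implements a complete, tested pipeline that turns a pair of
co-registered MR slices (T1 post-contrast and T2-FLAIR) with a tumor ROI
into a multitype spatial point pattern and quantifies the arrangement of
intensity "habitats" with the toolbox of multitype point-process
statistics, then relates those measures to overall survival and molecular
subtype. It is aimed at quantitative-imaging researchers who want the
habitat/point-pattern methodology as a reusable library rather than a
one-off analysis.

## The method

1. **Habitat segmentation.** Within the ROI, each channel's intensities
   are min–max scaled to 256 gray levels and fit with a two-component
   Gaussian mixture (EM, median-split initialization). The low/high
   threshold is the average of the two component means, giving four pixel
   habitats: T1-low, T1-high, T2-low, T2-high (each channel's pair
   partitions the ROI; T1 and T2 habitats may overlap).
2. **Spatial map.** An 8×8-pixel grid is laid over the ROI bounding box;
   in each grid box, each habitat present contributes the centroid of its
   pixels. The result is a planar point pattern `{x_i}` with marks
   `t(x_i) ∈ {1..4}` in a rectangular window.
3. **27 spatial features.** Neighbor abundances
   `δ(x_i), δ_τ(x_i), δ_=(x_i)` (closed r-ball neighborhoods) drive the
   mingling index, local Shannon/Simpson curves, mean composite
   information (MCI) and ISAR; the marked summary functions `G_uv`, `F_v`,
   `K_uv` and `J_uv = (1−G_uv)/(1−F_v)` plus an inhomogeneous empty-space
   function complete the set. Every distance-dependent quantity is a curve
   over r, summarized by its mean and standard deviation, yielding exactly
   27 named features per patient.
4. **Statistics.** Each feature is dichotomized at the ROC (Youden)
   cutoff against the 12-month survival class, the induced groups compared
   by Kaplan–Meier/log-rank with Benjamini–Hochberg FDR control, and the
   top-5 features by coefficient of variation feed an L2-logistic,
   3-fold-stratified-CV classifier of 12-month status and one-vs-rest
   molecular subtype (TPR, TNR, ACC = (TP+TN)/(TP+FN+TN+FP), AUC).

A synthetic cohort generator (bimodal Gaussian-mixture channels with
spatially coherent habitats, exponential survival with a log-linear link
to a spatial summary) makes every stage testable without patient data.

## Worked example

```python
import habitat_ppa as hp

cfg = hp.SyntheticConfig(n_patients=1, image_side=96,
                         roi_radius_range=(14, 18), seed=202)
pairs, records = hp.generate_cohort(cfg)
fv, pattern, habitats = hp.analyze_patient(pairs[0])
print(pattern.n_points, "points")
print(fv.values[["Simpson index", "Mean mingling", "Mean K", "Mean J"]])
```

prints

```
63 points
Simpson index     0.749811
Mean mingling     0.893118
Mean K           65.100807
Mean J            0.807337
dtype: float64
```

Here the Gini–Simpson index 0.750 (maximum 0.75 for four marks) says the
four habitats are near-equally abundant; mingling 0.89 means a point's
neighbors usually carry a different mark (the habitats interleave at the
grid scale); mean J below 1 indicates between-mark clustering relative to
complete spatial randomness.

The same stages run from the shell:

```bash
habitat-ppa simulate --config cfg.json --out cohort/
habitat-ppa run-all --input-dir cohort/ --out run/
```

producing `features.csv` (one row per patient, 27 columns), `screen.csv`
(per-feature cutoff, log-rank p, BH-adjusted p, group sizes),
`classification.json` and a `manifest.json` recording every tunable
decision.

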