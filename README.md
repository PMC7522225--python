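# retdens

Density-based analysis of retinal-layer thickness maps from OCT.

Most OCT studies of diabetic retinopathy (DR) reduce a macular thickness
map to summary statistics — the mean thickness of a layer inside the ETDRS
grid, say — and lose the shape of the pixel-thickness distribution in the
process.  `retdens` implements the alternative: treat each subject's
distribution of pixel-wise layer thickness as the data object, compare
distributions with the geometry of the space of probability densities, and
ask which retinal layers discriminate between disease groups (healthy
controls, diabetes without retinopathy "NoDR", non-proliferative DR
"NPDR").  It is aimed at researchers with per-subject thickness maps (or
exported heatmap images) and group labels.

## The statistical core

For subject *i*, the thickness values of the pixels inside the 6 mm ETDRS
disc are mapped to [0, 1] by a pooled affine transform and smoothed into a
density *fᵢ* by kernel density estimation.  The square-root transform
*hᵢ = √fᵢ* places each subject on the positive orthant of the unit Hilbert
sphere in L²([0, 1]), where the Fisher–Rao metric between densities becomes
the ordinary L² metric and everything has closed form:

- geodesic distance d(h₁, h₂) = arccos ⟨h₁, h₂⟩,
- exponential map exp_h(v) = cos‖v‖ h + sin‖v‖ v/‖v‖,
- inverse-exponential log_{h₁}(h₂) = θ (h₂ − cos θ h₁)/sin θ.

A group's average density is the Karcher mean h̄ = argmin Σᵢ d(h̄, hᵢ)²
(computed by tangent-space gradient descent; f̄ = h̄²).  PCA on the
log-mapped sample at h̄ yields Euclidean scores X = VŨ (components kept to
99.99% cumulative variance), which feed a logistic model of the log-odds
log(p/(1−p)) = xᵀβ.  Evaluation is leave-one-out cross-validation with the
mean, PCA and classifier all refitted per fold; performance is the
Mann–Whitney AUC with a Wald confidence interval from DeLong's variance at
the Bonferroni-corrected 98.3% level (overall 95% across the three pairwise
comparisons), plus sensitivity, specificity and the Brier score.  Group
differences are additionally tested by permuting labels and recomputing the
geodesic distance d₀ between group Karcher means.  A five-number-summary
baseline (mean, min, max, Q1, Q3) runs through the identical classifier
path for comparison.

Because clinical OCT cohorts are rarely shareable, the package ships a
calibrated synthetic-cohort generator (`retdens.synthetic_data`): mixtures
peaked near 40 µm with configurable mass above 50 µm, rendered to thickness
maps or TIFF heatmaps, with the study-shaped default of 41 controls /
28 NoDR / 38 NPDR.  See `docs/methods.md` for the model and its limits.

## Worked example

```python
import retdens as rd
from retdens.synthetic_data import default_cohort_config, generate_cohort

cohort = generate_cohort(default_cohort_config(seed=1, layers=["INL", "NFL"]))
cfg = rd.AnalysisConfig(grid_size=512, n_perm=500, seed=1)

res = rd.run_pairwise(cohort, "INL", ("controls", "NPDR"), cfg)
print(f"AUC {res.density_report.auc:.3f} "
      f"(98.3% CI {res.density_report.ci_low:.3f}-{res.density_report.ci_high:.3f})")
print("tail mass >50um:",
      {g: round(t, 3) for g, t in res.tail_mass_above_50.items()})
print("permutation p (adjusted):", res.perm_result.p_adjusted)
```

prints

```
AUC 0.798 (98.3% CI 0.672-0.925)
tail mass >50um: {'controls': 0.289, 'NPDR': 0.401}
permutation p (adjusted): 0.0
```

The inner nuclear layer (INL) is generated with a heavier right tail in
NPDR (40% of the ETDRS region above 50 µm vs 29% in controls); the pipeline
recovers those tail masses from the group Karcher means, the classifier
separates the groups with a CI that excludes 0.5, and the permutation test
finds no permuted labelling as separated as the observed one.  Running the
same analysis on the null layer NFL (identical generator parameters in both
groups) gives an AUC near 0.5 with a CI straddling it and a large p-value.

There is also a CLI for the file-based workflow:

```sh
retdens simulate --config cfg.yaml --out cohort/          # TIFFs + manifest
retdens extract  --manifest cohort/manifest.csv --out pixels.csv
retdens analyze  --pixels pixels.csv --config cfg.yaml --out analysis/
retdens report   --analysis-dir analysis/ --out tables.csv
```

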