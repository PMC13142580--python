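# iscn — individualized structural covariance networks

`iscn` is an analysis pipeline for **individualized cortical-network
analysis of regional cortical thickness**, of the kind used in large
multi-site psychiatric imaging consortia. Starting from a subject-level
table of 68 Desikan–Killiany regional thickness values plus demographics,
it builds group- and subject-level structural covariance networks and
characterizes their organization, case–control differences, symptom
coupling, patient subtypes, and normative deviations.

It is aimed at researchers in network neuroscience / psychiatric imaging
who have regional morphometry tables (not raw images) and want a tested,
scriptable implementation of this analysis family — plus a synthetic
multi-site cohort generator with planted ground truth for every stage, so
the whole pipeline can be validated end-to-end without access to clinical
data.

## What it computes

**Individual difference networks.** Each subject's regional thickness is
z-scored against the control reference, `z_i = (t_i − μ_i)/σ_i`, and the
subject's 68×68 network has edges

```
s_ij = exp(−|z_i − z_j|)
```

so regions deviating coherently from the norm are strongly connected.
Group-level networks are inter-subject Pearson correlations of
residualized thickness. Both are row-thresholded at sparsity 0.8 (top 20%
of entries per row retained).

**Gradients.** Diffusion-map embedding (anisotropy α = 0.5) of the
normalized-angle affinity between sparsified row profiles yields
macroscale gradients G1, G2; individual gradient sets are aligned to the
control template by orthogonal Procrustes rotation.

**Small-world topology.** Nodal clustering coefficient (CC, local
segregation) and mean shortest path length (SPL, integration) on the
binarized network; min–max rescaled within subject, or normalized against
degree-preserving rewired surrogates at the group level.

**Inference.** Per-region OLS (`feature ~ age + sex + DX`, optional ICV /
interactions / duration), covariate-adjusted Cohen's
`d = t·(n₁+n₂)/(√(n₁n₂)·√df)`, Benjamini–Hochberg FDR within metric, and
spatial-map correspondence tested against a spin-permutation null built
from mirrored random rotations of spherical parcel centroids.

**Symptom coupling.** PLS correlation (SVD of the brain × PANSS-factor
cross-correlation matrix) with bootstrap loading CIs (default 5,000
resamples, 90% intervals) and permutation latent-variable p-values.

**Subtyping.** K-means (k = 2, SSE scan 2–9) on the FDR-significant
network features after PCA reduction, validated by 1:1 split-half
assignment concordance with optimal centroid matching.

**Normative modeling.** Penalized-spline GAM of thickness on age (smooth),
sex and ICV fitted in controls; deviations are
`z = (observed − predicted) × 4 / (upper − lower 95% prediction interval)`,
and heterogeneity is the fraction of a group with |z| > 2.

## Worked example

```bash
iscn simulate --seed 3 --n-cases 60 --n-controls 80 --n-sites 2 --symptoms --out sim1
# wrote sim1/cohort.csv (140 subjects) and ground_truth.json
```

or, in Python, the packaged demonstration cohort (400 cases / 400
controls, 3 sites, strong planted diagnosis and subtype effects) through
the full pipeline:

```python
from iscn.pipeline import PipelineConfig, run_pipeline
from iscn.simulate import demo_cohort

cohort, truth = demo_cohort(seed=0)
run_dir = run_pipeline(PipelineConfig.demo(), cohort, "demo_run")
```

The run takes a few seconds on one CPU and writes a checksummed
`manifest.json` whose `counts` summarize the science; a representative
run prints:

```json
{
  "n_significant_features": 11,
  "split_half_concordance": [0.86, 0.89],
  "subtype_sizes": {"S1": 174, "S2": 226},
  "heterogeneity": {"controls": 0.035, "S1": 1.0, "S2": 1.0},
  "pls_SPL_lv1_p_perm": 0.005, "pls_G1_lv1_p_perm": 0.274,
  "template_variance_explained_G1_G2": [0.1542, 0.1432]
}
```

Reading: 11 region×metric features separate cases from controls after
FDR; the two recovered subtypes split 174/226 with 86–89% split-half
concordance at this small demonstration scale; control heterogeneity is
3.5% (near the ~5% a calibrated |z| > 2 rule implies) while the planted
patient subtypes deviate massively; and the symptom latent variable loads
on topology (SPL permutation p ≈ 0.005) but not on gradients (p ≈ 0.27),
exactly as planted.

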