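# Methods

This note documents the models implemented in `iscn`, their assumptions,
the defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical choices that
matter for reproducing results.

## The analysis model

The pipeline treats regional cortical thickness (68 Desikan–Killiany
parcels) as the observable of an underlying coordinated anatomical
system. Its stages, in order:

1. **Preprocessing.** Subjects missing ≥ 10% of regions are dropped;
   remaining cells are imputed by round-robin chained linear regression
   (each region on all 67 others, mean-initialized, fixed atlas order,
   tolerance 1e-3, ≤ 10 sweeps — scikit-learn's IterativeImputer with a
   plain linear estimator). Site batch effects in location and scale are
   removed by parametric empirical-Bayes harmonization (the ComBat
   model): per region, data are standardized on the grand mean plus the
   preserved-covariate fit (diagnosis, age, sex), per-site location and
   scale estimates are shrunk toward moment-matched pooled priors
   (normal / inverse-gamma, iterated conditional modes), and the shrunken
   effects are removed. Age and sex are then residualized out by OLS
   fitted on the pooled sample (diagnosis is never in that design, so
   case–control differences survive; a controls-only fit is available).

2. **Networks.** Group covariance = inter-subject Pearson correlation of
   residualized thickness. Individual networks: z-score each region
   against the control mean/SD, edge `s_ij = exp(−|z_i − z_j|)` (an
   alternative `1/(1+|z_i−z_j|)` kernel is provided; both map coherent
   deviation to high similarity). Sparsification is row-wise: keep the
   top `ceil((1−s)·67)` entries per row (s = 0.8 by default, i.e. top
   20%), ties broken deterministically toward the lower region index.
   The raw row-sparse matrix feeds the gradient affinity; the symmetric
   union of the row masks, binarized, feeds graph topology.

3. **Gradients.** Affinity between sparsified row profiles is the
   normalized angle `1 − arccos(ρ)/π` of their cosine similarity ρ
   (negatives clamped to zero). Diffusion-map embedding uses anisotropic
   normalization `W = D^−α A D^−α` with α = 0.5 (approximating the
   Laplace–Beltrami operator, separating geometry from sampling
   density), the Markov operator `P = D_W^{−1} W`, eigenvectors via the
   symmetric conjugate, the trivial constant mode dropped, and
   diffusion-time-0 scaling `λ/(1−λ)` per component. Individual
   embeddings are aligned to the control template by orthogonal
   Procrustes rotation of the first k = 2 centered components (no
   scaling); template signs are fixed so each column's max-|loading|
   region is positive. Variance explained (`λ_i/Σλ`) is reported
   pre-alignment.

4. **Topology.** Nodal clustering coefficient
   `CC_v = 2·triangles(v)/(d(d−1))` (0 for degree < 2) and nodal mean
   shortest path length over reachable nodes (BFS distances; component
   sizes logged if the graph disconnects — it does not at sparsity 0.8
   in practice). Individual maps are min–max rescaled to 0–1 within
   subject and metric; group maps are divided by the mean over
   degree-preserving Maslov–Sneppen rewired surrogates (100 surrogates,
   10·|E| attempted swaps each, seeded).

5. **Case–control inference.** Vectorized per-region OLS
   (`feature ~ age + sex + DX`; variants add ICV, age×DX, sex×DX, or
   replace DX with illness duration within cases). The adjusted Cohen's
   d is `t·(n₁+n₂)/(√(n₁n₂)·√df)` — the consortium convention for
   covariate-adjusted effect sizes; its sign always matches t. FDR is
   Benjamini–Hochberg within each metric (family = 68 regions).
   Spatial correspondence between cortical maps uses a spin-permutation
   null: a uniform random 3D rotation is applied to the left-hemisphere
   parcel centroids and its mirror conjugate (M R M, M = diag(−1,1,1))
   to the right; each parcel takes the value of the nearest rotated
   centroid within its hemisphere, preserving the map's spatial
   autocorrelation; `p_spin = (1 + #{|r_null| ≥ |r_obs|})/(n_rot + 1)`,
   two-sided by default. The centroids are synthetic Fibonacci-lattice
   points on the unit sphere with exact hemispheric mirror symmetry —
   the test needs a spherical parcel layout, not a reconstructed
   surface; this is a deliberate dialect of surface-based spinning.

6. **Symptom PLS.** PANSS items are summed into five factors (positive
   6, negative 8, cognitive/disorganization 6, depression/anxiety 3,
   hostility 5; 28 of 30 items assigned, the map is config-driven).
   PLS correlation is the SVD of the z-scored brain × factor
   cross-correlation matrix, run separately per metric; covariance
   explained is `σ_ℓ²/Σσ²`. Stability: subject bootstrap (default
   5,000), replicate saliences sign-aligned to the point estimate,
   percentile 90% CIs; a loading is "significant" when its CI excludes
   zero. Latent-variable significance comes from row-permutation of the
   symptom block (the mechanically unambiguous test); both summaries are
   emitted.

7. **Subtyping.** Patients are described by their FDR-significant
   region×metric features (column-standardized), reduced to 5 principal
   components, and clustered by k-means (k-means++ seeding, best of 50
   restarts; SSE reported for k = 2…9). Clustering in PC space is the
   default because the reduced space is where a two-cluster solution is
   adoptable; raw-feature clustering is available by flag. Subtype
   identity is anchored by the anterior-cingulate contrast (S1 = lower
   ACC values; otherwise labels are arbitrary). Validation: random 1:1
   split; k-means on half A; half B assigned to nearest A-centroids and
   independently clustered; labels matched by optimal (Hungarian)
   centroid assignment; concordance = fraction identically labeled;
   repeated with roles swapped.

8. **Normative modeling.** Per target (mean thickness and each region), a
   penalized B-spline GAM in controls: 20 cubic basis functions in age
   with a second-difference penalty, sex and centered ICV linear. The
   penalty weight is chosen by generalized cross-validation
   (`n·RSS/(n−edf)²` over a log grid) on the mean-thickness model and
   shared across regions — all targets share the same age design, so a
   shared smoothness is stable and fast. The 95% interval is the
   **prediction interval for a new observation** (mean-CI variance plus
   residual variance): only this reading makes the deviation score

   `z = (obs − pred) × 4/(upper − lower)`

   behave like a z-score — the width is ≈ 2·1.96·σ, so control z-scores
   have SD ≈ 4/3.92 = 1.02; a mean-CI reading would inflate z by ≈ √n.
   Controls are scored in-sample by default (a held-out option exists).
   Heterogeneity = fraction of a group with |z| > 2; under a calibrated
   Gaussian model this is ≈ 2Φ(−2/1.02) ≈ 5.0%. Subtype profiles use
   Welch t per region with BH-FDR and a Cohen's d map correlated
   (Spearman + spin p) against the group G1/G2/SPL/CC templates, overall
   and within illness-duration bins (0–1, 1–5, 5–10, 10–20, 20–55 years)
   or age bins (15–65 by 10); bins are half-open [lo, hi) with the final
   bin closed.

## The synthetic cohort generator

`iscn.simulate` generates, per subject: thickness = smooth regional
baseline + low-rank latent factors + smooth age decline + sex and ICV
terms + site location shift + diagnosis effect (cases) + subtype effect
(cases, per planted label) + site-scaled Gaussian residual.

* **Spatial covariance** comes from a rank-10 factor model whose
  loadings are polynomial functions of parcel position, so the group
  covariance has smooth macroscale axes (the kind of structure gradient
  analysis assumes) without any empirical input data.
* **Effect maps are in Cohen's d units** relative to the total
  (latent + residual) SD, so planted effects are recoverable on the d
  scale downstream. Defaults: widespread case thinning (d = −0.1,
  −0.3 in cingulo-temporo-parietal hubs and insula); subtype S1 =
  diffuse thinning with extra anterior-cingulate thinning, S2 =
  temporoparietal/central thinning with anterior-cingulate sparing.
* **Defaults**: residual SD 0.12 mm and latent SD 0.08 mm (total ≈
  0.14 mm, typical for DK thickness), site shift SD 0.05 mm, site scale
  SD 0.10, age slope −0.003 mm/yr with mild curvature, sex offset
  0.05 mm, ICV slope 5×10⁻⁸ mm/mm³, ages uniform 15–70, ICV ~ N(1.55M,
  0.13M) mm³ (M) / N(1.40M, 0.12M) (F), illness duration a truncated
  exponential (scale 8 y) on [0, age−15].
* **Symptoms**: a latent severity score (z-scored linear combination of
  supplied per-case features) drives all 30 PANSS items with ordinal
  noise, discretized to 1–7; cases only.
* **Missingness** marks exactly ⌊rate×68⌋ cells per affected subject;
  the affected fraction is a separate parameter so the invariant is
  explicit.

**What it does not emulate** — and hence what passing tests do not show
about real data: scanner physics and site-by-covariate confounding
(sites differ only in location/scale, independently of demographics);
non-Gaussian or heavy-tailed regional noise; genuinely nonlinear
age×disease interactions; spatially heterogeneous noise; longitudinal
change; symptom structure beyond a single latent severity dimension.
Calibration results (e.g. control z SD ≈ 1.02) certify the estimators
under their own assumptions, not the biology of any clinical sample.

## Numerical choices and degenerate inputs

* Sparsify ties break toward the lower region index; negative
  covariance entries compete on signed value and are effectively gone
  at sparsity ≥ 0.6. Re-thresholding is a no-op only when retained
  entries are positive (always true for similarity matrices).
* Zero-variance regions, all-missing regions, constant PLS columns,
  single-subject sites, disconnected affinity graphs, and zero-width
  prediction intervals raise errors naming the offending object.
* ComBat's EB shrinkage deliberately leaves the per-region,
  sampling-level component of site differences in place (it is treated
  as noise, not batch); a second harmonization pass therefore changes
  values slightly — far below the batch effects themselves — rather
  than being an exact no-op. Single-site input passes through
  unchanged.
* BH-FDR is computed by the canonical step-up expression
  `min_{j≥i} m·p_(j)/j` so that it is bit-identical to the definition.
* Bootstrap PLS under a *global* null is conservative for loading CIs
  (the latent direction is unidentified and CIs balloon); loading-CI
  calibration is therefore assessed with an identified latent variable
  plus truly-null features, where the 90% CI exceedance is ≈ 10%.
* Spin p-values are permutation-valid by construction
  (≥ 1/(n_rot+1), ≤ 1).
* All stochastic steps (generator, rewiring, bootstrap, permutation,
  spin, k-means, splits) take explicit seeds; pipeline runs are
  byte-reproducible and manifest-checksummed.

## Problem sizes used for validation

The packaged demonstration run uses 400 cases / 400 controls across 3
sites with doubled diagnosis and tripled subtype effect maps, and
reduced resampling depths (200 rotations, 300 bootstraps, 200
permutations, 20 rewired surrogates); it completes in seconds. The
calibration studies use 3,000 controls for the normative model and
2,000 patients for subtyping; statistical calibration uses 2,000 null
simulations (type-I error), 200 spin replicates, and 12 bootstrap-PLS
runs. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances.

## Known limitations

* The individual-network edge kernel `exp(−|z_i − z_j|)` is one member
  of a family used in the inter-individual covariance literature; the
  alternative reciprocal kernel is provided, and results at a fixed
  sparsity are qualitatively similar but not identical.
* The spin null rotates synthetic spherical centroids, not a cortical
  surface; it preserves the autocorrelation logic but distances between
  parcels are idealized.
* The GAM penalty is selected once (on mean thickness) and shared
  across regions; regions with atypical age trajectories would receive
  a slightly suboptimal smoothness.
* Harmonization assumes site effects are location/scale only and that
  preserved covariates are correctly specified; ICV is not preserved by
  default (it enters only the sensitivity models and the normative GAM).
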