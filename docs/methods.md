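# Methods

## Similarity estimation

Each region contributes a sample of vertex-wise values of one morphological
feature.  For every unordered pair of regions the two samples are compared
as probability distributions:

1. **Shared support.** 256 equally spaced points spanning the pooled range
   of the two samples, padded by 10% of that range on each side.  The
   support is chosen per *pair* rather than globally: a global grid wastes
   resolution on regions with narrow value ranges, and the divergence is a
   pairwise quantity.  Degenerate (zero-variance) samples are rejected.
2. **Density.** Gaussian KDE with the Silverman bandwidth
   `sd · (3n/4)^(−1/5)` (identical to `scipy.stats.gaussian_kde` with
   `bw_method="silverman"`, which the tests use as an oracle), evaluated on
   the grid and renormalized so the 256 probabilities sum to one.  The
   divergence formulas operate on these discrete distributions.
3. **Divergence and similarity.** JSD with log base 2, which bounds the
   divergence by 1 and makes `similarity = 1 − sqrt(JSD)` a value in
   [0, 1].  The kernel, bandwidth rule, grid placement and padding are
   declared design choices — the divergence-based similarity method itself
   does not prescribe them.  The diagonal is set to 1 by definition (the
   self-divergence is analytically zero).

Node order is canonical everywhere: gyral regions first (ascending region
id), then sulcal.  Ambiguous regions of the parcellation are excluded
before construction.

## Graph topology

Weighted similarity matrices are binarized by proportional thresholding:
the `round(s·N(N−1)/2)` strongest edges are kept (round half away from
zero), with ties at the cutoff broken by ascending node index so that
nested sparsities give exactly nested edge sets and results are
deterministic.

The usable sparsity floor is the **estimability criterion**: average degree
`s·(N−1)` at least `ln N`, giving 0.071 for 58-node and 0.068 for 62-node
networks.  Cp is the mean nodal clustering (nodes of degree < 2 contribute
0); Lp is the mean shortest-path length over *reachable* unordered pairs —
when a thresholded graph is disconnected the value is computed over
reachable pairs and a disconnection flag is raised, keeping sweep curves
finite rather than infinite or restricted to the giant component.
Normalization uses 100 degree-preserving double-edge-swap null networks
(networkx `double_edge_swap`; 10 swaps per edge per null).  When the null
ensemble has zero mean clustering (possible for very small or very sparse
graphs) γ is reported as NaN with a warning rather than inventing a value.
Curves are summarized by the trapezoidal AUC over the sparsity range.

## Test-retest reliability

One-way random-effects ICC(1,1) per edge:
`ICC = (MS_b − MS_w)/(MS_b + (k−1)·MS_w)` with between/within-subject
*mean* squares from the one-way ANOVA on subjects.  Negative values are
reported unclamped but binned as "poor".  Bins are half-open `[lo, hi)`
with breakpoints 0.25 / 0.4 / 0.6 / 0.75 so that every value ≤ 1 is
classified exactly once; values ≤ 0 fall in "poor" and 1.0 in "excellent".
With more than two sessions, reliability is computed per requested session
pair.  The gyral-vs-sulcal reliability comparison treats edges as
exchangeable units: the two edge lists are pooled and re-split at the
original sizes, with a two-tailed add-one p-value.

## Behavioral variance components

Behavior items are z-scored across subjects and averaged within domains.
The between-subject similarity `M` is the Pearson correlation of subjects'
edge profiles, with each edge z-scored across subjects first so that
high-variance edges do not dominate.  Under the model
`Y = B + E, B ~ N(0, σ_b² M), E ~ N(0, σ_e² I)`, each phenotype's
components solve the method-of-moments system

```
[tr(M²)  tr(M)] [σ_b²]   [yᵀMy]
[tr(M)   n   ] [σ_e²] = [yᵀy ]
```

on the column-centered phenotype.  A moment estimator was chosen over REML
for determinism and testability; only the traces of Σ_B and Σ_E are
estimated because V depends on traces alone.  Negative solutions are
clamped to zero (the clamp count is reported) before forming
`V = tr(Σ_B)/(tr(Σ_B)+tr(Σ_E))`.  With `M = I` the system is singular —
network and environmental variance are indistinguishable — and the fit
raises a non-identifiability error (condition-number guard).  The
permutation p for V shuffles subject rows of Y jointly across phenotypes
and is one-sided (V is nonnegative).  Multiple domains are corrected with
Benjamini–Hochberg FDR; edgewise localization uses Pearson correlations
with BH-FDR across edges and attributes significant edges to their two
endpoint regions.

## Group comparisons

Patient-control contrasts residualize the per-subject summary on an
intercept plus age and sex (OLS) and then permute group labels
(residualize-then-permute; Freedman–Lane is a noted alternative).
Contrasts *within* subjects — between subnetwork blocks, or a region's
intra-class vs inter-class similarity — use paired sign-flip permutations,
because an unpaired shuffle would be mis-specified for paired summaries.
Per-region contrasts are FDR-corrected within each class.  All permutation
p-values use the add-one convention `(1 + #extreme)/(1 + n_perm)` and are
reproducible under a fixed seed.  Clinical correlations default to Pearson
with Spearman available.

## Synthetic cohorts

The generator emulates what the analysis assumes about real vertex-wise
feature maps, with every ground-truth quantity recorded:

- **Region means**: class base 2.5 (gyral) / 2.0 (sulcal) in CT-like
  feature units, plus a class-level spread `τ = 0.2` drawn once per
  cohort.  The 0.5 base gap between classes produces the higher
  within-class than between-class similarity seen in real data.
- **Region shapes**: each region's vertex distribution is a mean-preserving
  two-component Gaussian mixture (half-separation `|N(0, 0.3)|`, weight
  `U(0.3, 0.7)`) with region-specific spread `0.5 · LogNormal(0, 0.2)`.
  Shape diversity matters: if similarity depended on region means alone it
  would be a monotone function of |Δμ| and thresholded networks would be
  one-dimensional lattices (λ far above 1).  With shape diversity the
  similarity structure is higher-dimensional, and thresholded synthetic
  networks are genuinely small-world (γ ≈ 1.3–5 with λ ≈ 1.0–1.6 across
  the sparsity range at the default sizes).  Setting both shape parameters
  to zero recovers a plain Normal model.
- **Subject and session effects**: a stable subject×region shift
  (SD 0.1) and a session×region shift (SD 0.05), so the true reliability
  ratio σ_subj²/(σ_subj²+σ_sess²) is known (0.8 at defaults).  The vertex
  pattern is drawn once per subject — it is stable anatomy — and sessions
  shift it; with zero session noise, repeat sessions are bit-identical and
  every edge ICC is exactly 1.  Parameter-recovery tests use
  σ_subj = σ_sess = 0.1 (ratio 0.5); note that edge-level ICC is
  structurally attenuated below the latent ratio because pairs whose base
  separation is small respond quadratically (through |Δcenter|) to the
  latent effects — measured mean edge ICC under ratio 0.5 is ≈ 0.42–0.49.
- **Group effects**: patients receive an extra subject-stable perturbation
  `N(0, group_effect²)` of each sulcal region's mean.  A uniform shift of
  all sulcal means would leave pairwise similarity unchanged; added
  dispersion lowers S-S similarity monotonically in the effect size.
- **Behavior**: items drawn under the variance component model from a
  PSD-repaired `M` (negative eigenvalues clipped, diagonal renormalized to
  1) with σ_b² = V_true, σ_e² = 1 − V_true.
- **Covariates**: age and sex independent of group by default, so group
  tests are not confounded unless a confound is deliberately constructed.

What the generator does **not** emulate: cortical geometry and spatial
smoothing, spatially correlated noise, scanner/site effects, and realistic
vertex counts (200 per region by default vs thousands in real meshes).
Passing tests therefore demonstrate correctness of the estimators under
the generative model, not robustness to those real-data complications.

## Problem sizes used by the test suite

Unit tests run on a bilateral 3+3+1-regions-per-hemisphere atlas (12
retained regions).  The end-to-end checks use: full 120-region networks
for dimension and small-world checks (one to two subjects); a 300-subject
cohort on the small atlas for variance-component recovery (20 replicates
at V_true ∈ {0, 0.5}); 50-subject two-session cohorts (3 seeds) for
reliability recovery; 500 null simulations at 199 permutations each for
type-I calibration of the permutation tests; and exhaustive enumeration of
all graphs on up to 6 nodes for the graph-metric oracles.

## Known limitations

- The KDE support, padding, kernel and bandwidth are declared choices;
  other choices shift absolute similarity values (comparisons between
  blocks are much less sensitive).
- Lp on disconnected graphs is a reachable-pairs mean; alternatives
  (harmonic mean, giant component) would change low-sparsity values.
- The moment estimator of (σ_b², σ_e²) is unbiased but less efficient than
  REML; per-phenotype clamping can bias V upward slightly near V = 0.
- The reliability comparison and edgewise FDR treat edges as independent
  units; spatial/topological dependence between edges is not modeled.
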