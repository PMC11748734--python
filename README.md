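# morphnet

Single-subject **morphological brain networks** and the question of how they
differ between **gyri** (the convex ridges of the cortical sheet) and
**sulci** (the concave grooves).

A morphological brain network is a graph whose nodes are cortical regions
and whose edges quantify how similar two regions' distributions of a
morphological feature are — cortical thickness (CT), fractal dimension (FD),
gyrification index (GI), or sulcal depth (SD). `morphnet` implements the
whole analysis as a tested, reusable library plus CLI:

- **Network construction** — for each pair of regions, a Gaussian KDE of the
  vertex-wise feature values is evaluated on a shared 256-point grid,
  renormalized to a discrete distribution, and compared with the
  Jensen–Shannon divergence (log base 2, so JSD ∈ [0, 1]):

  JSD(P‖Q) = ½ KLD(P‖M) + ½ KLD(Q‖M),  M = (P+Q)/2,
  KLD(P‖Q) = Σᵢ P(i) log₂ P(i)/Q(i)

  and similarity = 1 − √JSD.  Over the 58 gyral + 62 sulcal regions of a
  Destrieux-style parcellation (ambiguous regions excluded) this gives a
  120×120 "GS-GS" matrix that decomposes into G-G (58×58), S-S (62×62), and
  G-S (58×62) blocks.
- **Graph topology** — proportional thresholding over a sparsity range
  (default 0.08–0.40, step 0.02), clustering coefficient Cp and
  characteristic path length Lp, normalized (γ, λ) against 100
  degree-preserving rewired null networks, and AUC summaries.  The sparsity
  floor comes from the estimability criterion: average degree ≥ ln N, i.e.
  0.071 for 58-node gyral and 0.068 for 62-node sulcal networks.
- **Test-retest reliability** — one-way random-effects ICC of every edge
  across repeated scan sessions, ICC = (MS_b − MS_w)/(MS_b + (k−1) MS_w),
  binned poor/low/fair/good/excellent, with permutation comparison of gyral
  vs sulcal edge reliability.
- **Behavioral variance components (morphometricity)** — the model
  Y = B + E, B ~ N(0, σ_b² M), E ~ N(0, σ_e² I), where M is the
  between-subject correlation of network edge profiles; the variance
  explained V = tr(Σ_B)/(tr(Σ_B) + tr(Σ_E)) is estimated by a
  method-of-moments solve of the trace equations, with a 1000-shuffle
  permutation p-value, BH-FDR across behavioral domains, and edgewise
  correlation to localize associations.
- **Group comparison** — covariate-adjusted (age/sex GLM residuals)
  permutation tests of mean block similarity between patients and controls,
  paired sign-flip contrasts between subnetworks, per-region intra- vs
  inter-class contrasts with FDR, and clinical correlations.
- **Synthetic cohorts** — a generator that emulates vertex-wise feature maps
  with known ground truth (class-structured region means and shapes, stable
  subject effects vs session noise with a known reliability ratio, group
  effects on sulcal regions, behavior with known V), so every stage is
  testable without access to the original MRI datasets.

## Worked example

```python
import numpy as np
import morphnet as mn
from morphnet.simulate import SimulationConfig, make_default_atlas, simulate_cohort
from morphnet.network import build_network, extract_subcomponents, mean_similarity

atlas = make_default_atlas()                      # 29G + 31S + 14A per hemisphere
cohort = simulate_cohort(SimulationConfig(n_subjects=4, seed=7), atlas)
net = build_network(cohort.feature_map(0, 0), atlas, feature="CT")
gg, ss, gs = extract_subcomponents(net)
print(f"GS-GS network: {net.weights.shape}")
print(f"mean similarity  G-G: {mean_similarity(gg, square=True):.3f}")
print(f"mean similarity  S-S: {mean_similarity(ss, square=True):.3f}")
print(f"mean similarity  G-S: {mean_similarity(gs, square=False):.3f}")

w_gg = net.weights[np.ix_(net.gyral_mask, net.gyral_mask)]
res = mn.sparsity_sweep(w_gg, n_null=20, seed=0)
print(f"G-G small-world: gamma AUC {res.auc['gamma']:.3f}, "
      f"lambda AUC {res.auc['lambda']:.3f} over [0.08, 0.40]")
```

prints

```
GS-GS network: (120, 120)
mean similarity  G-G: 0.734
mean similarity  S-S: 0.739
mean similarity  G-S: 0.627
G-G small-world: gamma AUC 0.513, lambda AUC 0.411 over [0.08, 0.40]
```

The within-class blocks (G-G, S-S) are more similar than the between-class
block (G-S), because gyral and sulcal regions have systematically different
feature levels.  The γ AUC of 0.513 over the 0.32-wide sparsity range means
the normalized clustering averages ≈ 1.6 (well above 1) while the λ AUC of
0.411 means the normalized path length averages ≈ 1.3 (near 1): the
thresholded gyral network is small-world.

The same stages are available from the shell:

```sh
morphnet simulate --out cohort/ --seed 1
morphnet build-network --features cohort/ --atlas cohort/atlas.tsv --out nets/
morphnet topology --networks nets/ --atlas cohort/atlas.tsv --block gg --out topo.tsv
morphnet run --config pipeline.yaml --out results/ --seed 1   # full pipeline + manifest
```

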