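# Methods

This note documents the statistical model behind `mendriver`, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions.

## Network inference

**Pearson route.** The adjacency is `A_ij = PCC(X_i, X_j)` over samples;
the clustering distance is the sign-blind `D_ij = 1 − |A_ij|`, so
strongly anti-correlated features are *close* — co-regulation in either
direction is membership evidence. Zero-variance features yield a zero
association with a warning rather than an abort: trimmed real profiles
occasionally retain constant rows, and aborting an entire run on one
degenerate feature helps nobody.

**MMI route.** Microbiome abundance vectors are often multi-modal (zero
inflation, sub-population structure), which a single correlation
coefficient under-reads. Each feature's sample vector is therefore
decomposed into `c_i` Gaussian-mixture bins, `c_i` selected by BIC over
1..`max_components` (default 3; k-means initialization, fixed seed;
degenerate fits fall back to fewer components; empty components are
dropped so every bin holds ≥ 1 sample). The mutual information between
two features is estimated as

    MMI = MMI_outer + MMI_inner

* `MMI_outer`: discrete MI of the joint bin-label contingency table —
  the maximum-likelihood plug-in estimator, natural log (nats
  throughout).
* `MMI_inner`: Σ over joint bins (k,l) of `p_kl · I_G`, with
  `I_G = −½·ln(1 − ρ²)` from the within-bin Pearson ρ. Joint bins with
  fewer than 4 samples contribute 0 — two or three points cannot
  support a correlation estimate, and small-bin noise would otherwise
  dominate. ρ² is capped just below 1 to keep the log finite. The sum
  is clipped below at 0.

The weighting by the *joint*-bin proportion (rather than marginal bins)
was a genuinely open choice; it makes the inner term a proper
conditional-MI-style average over the joint partition and reduces to the
plain Gaussian MI when both features are unimodal, which is the
closed-form limit the tests pin (`−½ln(1−ρ²)` within 0.05 at n = 2000).

**CLR background normalization.** The raw MMI matrix M is z-scored
against each row's off-diagonal background:
`Z_i = (M_ij − mean(M_i))/sd(M_i)`, and the normalized weight is
`sqrt(max(0,Z_i)² + max(0,Z_j)²)` — negative z-scores are floored at 0
so only above-background association counts. Rows with zero background
spread get zero z-scores with a warning. This suppresses promiscuous
features that associate with everything.

**MMI distance.** Hierarchical clustering needs a dissimilarity; CLR
weights are unbounded above, so the conversion is
`D = (max(CLR) − CLR) / max(CLR)`: monotone decreasing,
order-preserving, and mapped onto [0, 1] so that the clustering cut
height has the same meaning for both inference routes. If the CLR
matrix is identically zero the distance degenerates to 1 off-diagonal.

## Preprocessing

Features are trimmed on two per-feature statistics computed from the
per-sample relative-abundance matrix (each sample column normalized to
sum 1): mean relative abundance ≥ 1e−5 and prevalence (fraction of
samples with nonzero abundance) ≥ 0.1 by default. Both thresholds are
exposed; the defaults reflect common microbiome practice rather than any
universal rule.

Quantile normalization then forces every sample column to share the
across-sample mean of the order statistics, preserving within-column
ranks. Ties receive the mean of the reference values over the tied
ranks — the deterministic standard convention. Note the trade-off: with
ties, equal inputs map to equal outputs, so the column value multisets
are identical only for tie-free (continuous) data; idempotence likewise
holds exactly in the tie-free case and to floating tolerance otherwise.

## Partitioning

Agglomerative clustering (scipy) on the distance matrix; average linkage
by default (standard for co-occurrence distances; complete and Ward are
options). The dendrogram is cut at a static height (default 0.8) or into
a target cluster count. Clusters below `min_size` (default 5) are
unassigned background, excluded from association testing — eigengenes
and permutation p-values of 2–3-member "modules" are too unstable to
interpret. Each retained subnetwork becomes a complete weighted graph
with edge weight |A_ij| (or the CLR weight); no edge threshold is
applied for analysis, because PageRank consumes weights directly — a
display threshold exists only in the GraphML export.

## Delegated phenotype

Phenotype variables are digitized (categoricals coded in sorted-category
order, the disease column Y→1/N→0), standardized, and the disease column
itself participates in the PCA by default (a flag excludes it). Variables
missing in more than 1/3 of samples are dropped; remaining missing
values are imputed by column median (numeric) or mode (categorical,
smallest on ties). Multiple imputation was deliberately not used: it
would add a heavy dependency for a step that is not the method's
contribution, and the ablation facility (below) measures robustness to
exactly this kind of perturbation.

PCA sample scores on the first two components are scaled to **unit
variance per axis** before the rotation. This is a deliberate
convention: with unit-variance axes, maximizing

    f(θ) = Σ_{N}(x_k cosθ + y_k sinθ) − Σ_{Y}(x_k cosθ + y_k sinθ)

is *equivalent* to maximizing the correlation of the projection with
the disease indicator (the projection's variance is independent of θ),
which is the stated purpose of the rotation. With raw scores the two
objectives can disagree whenever the disease signal sits on the
lower-variance axis. Under this convention the delegated phenotype's
correlation with the disease indicator provably dominates either
unrotated axis — a property the tests verify.

The maximizer is closed-form: `θ = atan2(Δy, Δx)` with
`Δx = Σ_N x_k − Σ_Y x_k`, `Δy` analogous (f(θ) = Δx·cosθ + Δy·sinθ).
The tests check it against a 3600-point grid search to 1e−9. θ is
reported in (−π, π]; swapping the Y/N coding flips θ by π and negates
the scores. If both group sums coincide (Δx = Δy = 0) the groups are
indistinguishable in the PC plane and the rotation raises an error. A
second PC with negligible variance is zeroed (with a warning) instead of
being blown up by the scaling.

The construction is inherently two-dimensional; with many phenotype
variables a two-PC summary may be insufficient, and choosing the number
of components automatically is out of scope.

**Ablation.** `ablate_phenotypes` recomputes the delegated phenotype
under removal of every combination of `n_remove` non-disease variables
(random subsample of combinations above a cap, default 200) and reports
|correlation| of supplied eigengenes with each ablated version —
quantifying how much the phenotype summary depends on any single
variable.

## Association and selection

A subnetwork's eigengene is the first principal component of its
standardized member × sample matrix, scaled to unit variance, with the
sign fixed so it correlates non-negatively with the mean standardized
member profile. Significance of the eigengene–delegated-phenotype
correlation uses a permutation null: B = 1000 random same-size feature
sets drawn without replacement from the post-filter feature universe,
and the add-one two-sided p-value

    p = (1 + #{b : |r_b| ≥ |r_obs|}) / (B + 1)

Two-sided on |r| because an eigengene's sign carries no meaning.
Selection: p ≤ α (default 0.05), ordered by |r| descending, optional
top-k truncation. No multiple-testing correction is applied by default;
a Benjamini–Hochberg flag exists for users who test many subnetworks.

## Key drivers

Damped PageRank on the undirected weighted subnetwork graph: power
iteration on the weighted-degree-normalized transition operator with
teleport mass `1 − c` (default c = 0.85) spread uniformly (a custom
teleport vector is accepted); dangling mass is redistributed by the
teleport vector; convergence when the successive L1 change drops below
1e−10, error on non-convergence. Scores sum to 1. Ties in the ranking
break lexicographically by node id, so reruns are stable. The weighted
degree (adjacency row sum) is provided as the baseline scorer.

A caveat worth stating: on an undirected graph the un-teleported random
walk's stationary distribution is exactly proportional to weighted
degree, so PageRank at c = 0.85 and the degree ranking usually agree;
in the recovery benchmark their exclusive-correct counts differ by at
most a replicate or two per grid. The teleport correction is what can
separate them, and only in small, noisy networks.

## Simulators

**Tree networks.** The root (planted key driver) is i.i.d. Uniform(1,10)
per sample — a positive support is required because the driving noise
variance is `β·x`. Each gene drives k sub-genes via `y = A·x + n`,
`n ~ N(0, β·x)` per sample, A = 1 by default; expressions are floored at
0.01 before serving as parents so the variance stays positive. Gene
count is Σ_{d≤depth} k^d. A moment check (regression of squared driving
residuals on the parent level recovers β) pins the noise model.

**Recovery benchmark.** Scoring cannot run on the true topology — there,
the root's degree is fixed by construction and noise would be
irrelevant — so each replicate re-infers the complete |PCC|-weighted
graph over all simulated genes, mirroring the pipeline's own inference,
and asks whether each scorer's top-1 node is the root ("prediction
precision" = top-1 recovery rate across replicates, 100 by default; the
shipped validation uses 50 per cell to keep the run inside a few
minutes, which is ample for the qualitative contrasts tested). Precision
rises with the sub-gene count k and degrades slowly with noise.

**Planted studies.** Background features are i.i.d. lognormal; each
planted module is a hub plus hub-driven members (star-shaped driving
with the same `β·x` noise, β = 0.1); the first module's hub is shifted
upward in disease samples by `effect_size` standard deviations of its
base expression, so the disease association propagates through the
module. The phenotype table carries the Y/N label, label-correlated
nuisance variables (numeric and categorical) and pure-noise variables.
What this does *not* emulate: compositionality and sequencing-depth
artifacts, zero inflation, overlapping modules, phylogenetic
correlation among background features, and confounded phenotype
structure. Passing the planted-recovery tests therefore demonstrates
the machinery is correct and well-calibrated under its own model — not
that any particular real dataset will yield stable modules.

## Numerical conventions and defaults

| parameter | default | meaning |
|---|---|---|
| `min_mean_rel_abundance` | 1e−5 | trimming threshold on mean relative abundance |
| `min_prevalence` | 0.1 | minimum nonzero fraction of samples |
| `max_components` | 3 | largest mixture bin count per feature (BIC selects) |
| `linkage` / `cut_height` / `min_size` | average / 0.8 / 5 | partitioning |
| `max_missing_frac` | 1/3 | phenotype-variable missingness cutoff |
| `n_permutations` (B) | 1000 | permutation-null size |
| `alpha` / `top_k` | 0.05 / none | subnetwork selection |
| `damping` (c) | 0.85 | PageRank teleport complement |
| tolerances | 1e−10 (PageRank L1), 1e−12 (ρ² cap offset) | |

All randomness (mixture initialization, permutation draws, simulators)
derives from a single seed via spawned generator streams, so results are
bit-reproducible and independent of processing order.

## Known limitations

* Hierarchical-cut parameters (linkage, cut height, minimum module
  size) have no data-driven defaults here; module boundaries on real
  data are sensitive to them.
* The MMI estimator's inner term ignores joint bins with < 4 samples;
  with few samples and many mixture components the estimate is biased
  toward the outer (discretized) term.
* The delegated phenotype is a two-dimensional summary; disease signal
  spread over many phenotype PCs will be under-captured.
* Permutation p-values are not corrected for testing many subnetworks
  unless the BH flag is enabled.
* PageRank and weighted degree nearly coincide on undirected graphs
  (see above); the key-driver machinery supports custom teleport
  vectors where prior knowledge should be injected.
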