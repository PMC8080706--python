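# Methods

## Model

The input is a binary somatic-mutation matrix `X` with m samples as rows
and p genes as columns; entry `(s, g) = 1` iff gene g carries a qualifying
somatic mutation in sample s. The model assumes the cohort decomposes into
k latent subgroups, each characterized by a set of genes recurrently
mutated within it, and approximates `X ≈ U Zᵀ` with non-negative `U`
(m × k) and `Z` (p × k). Row `z_i` of `Z` is gene i's embedding; because
the factorization concentrates mass on few coordinates, the dominant
coordinate of `z_i` carries both the gene's mutation score and its
subgroup identity.

Real cohorts contain structure that is not subgroup signal: hypermutated
or mislabelled samples (dense rows) and genes mutated frequently for
reasons unrelated to any subgroup (dense unstructured columns). Left
alone, such rows and columns attract factors — with only k of them, one
factor lost to noise means one subgroup lost. The objective therefore
weights the residual on both sides with learned diagonal matrices:

    f(U, Z, W, M) = Σ_{s,g} M_s W_g (X_{sg} − (U Zᵀ)_{sg})²
                    + λ Tr(Zᵀ L_S Z) + α ‖W‖² + β ‖M‖²

subject to `U, Z ≥ 0`, `W ≥ 0, Σ W = C_w`, `M ≥ 0, Σ M = C_m`.
The simplex constraints make the weights a fixed trust budget: the solver
cannot evade the data term by shrinking all weights, only re-allocate
trust from poorly explained genes/samples to well explained ones. The
ridge terms (α, β) control how aggressively the budget concentrates.

`L_S = D_S − S` is the graph Laplacian of a similarity graph over gene
profiles; `Tr(Zᵀ L_S Z) = ½ Σ_{ij} S_ij ‖z_i − z_j‖²` penalizes dissimilar
embeddings for genes with similar mutation patterns, propagating signal
between co-mutated genes.

### Notation

| symbol | object | shape | constraint |
|---|---|---|---|
| `U` | basis (sample loadings per subgroup) | m × k | ≥ 0 |
| `Z` | gene coefficients / embeddings | p × k | ≥ 0 |
| `W` | instance (gene) weights | p | ≥ 0, Σ = C_w |
| `M` | feature (sample) weights, also the diagonal distance metric | m | ≥ 0, Σ = C_m |
| `S`, `D_S`, `L_S` | similarity, degree, Laplacian over genes | p × p | L_S PSD |

Some robust-NMF formulations reuse one letter for both a basis matrix and
a weight matrix; here the basis is always `U` and `W`/`M` are strictly the
diagonal robust weights.

## The similarity graph

Distance between gene profiles uses the learned sample weights as a
diagonal metric, `d²(x_i, x_j) = (x_i − x_j)ᵀ diag(M) (x_i − x_j)`, so
samples the model distrusts also count less toward gene similarity.
Similarity is the Gaussian kernel `S_ij = exp(−d²_ij / 2σ²)` — the
exponent is negative; a similarity growing with distance would invert the
penalty. Self-similarity is 1 and kept in both `S` and the degrees, which
cancels in `L_S = D_S − S`.

σ defaults to the median heuristic (square root of the median non-zero
squared pairwise distance); if every pairwise distance is zero it falls
back to σ = 1 with a warning.

The solver sparsifies the graph to symmetric 5-nearest-neighbours before
forming the Laplacian (`knn=5`). On binary profiles, the full Gaussian
graph under the median bandwidth is near-uniform (mean similarity ≈ 0.5,
degrees ≈ p/2): the penalty then degenerates into global shrinkage of all
embeddings toward their mean with strength growing like λ·p, which both
washes out per-gene signal and paralyzes the multiplicative `Z` update
(each step's relative movement scales like the data-to-degree ratio). The
sparse graph keeps the penalty local and the data term in charge.
`build_graph` itself defaults to the full graph; only the solver's config
chooses sparsification.

By default the graph is built once, from the initial (uniform) `M`, and
frozen (`refresh_graph=False`): the objective is then a fixed function and
every update provably descends it. Setting `refresh_graph=True` rebuilds
graph and bandwidth from the current `M` each iteration — the fully
adaptive metric — at the cost that the objective changes between
iterations (the recorded trace is then only piecewise monotone, with
occasional cross-refresh increases of order 1e-5 relative) and roughly an
order of magnitude more compute. On the synthetic cohorts the frozen
graph recovers planted structure equally well, so it is the default.

## Optimization

One outer iteration runs, in order: multiplicative update of `U`,
multiplicative update of `Z`, exact update of `W`, exact update of `M`,
then records the objective.

* `U ← U ⊙ [diag(M) X diag(W) Z] ⊘ [diag(M) U Zᵀ diag(W) Z]` — the
  weighted-NMF majorize–minimize step; with uniform weights it is the
  classical NMF basis update.
* `Z ← Z ⊙ [diag(W) Xᵀ diag(M) U + λ S Z] ⊘ [diag(W) Z Uᵀ diag(M) U + λ diag(D_S) Z]`
  — the Laplacian enters via the split `L_S = D_S − S` (similarity part in
  the numerator, degree part in the denominator) so every factor stays
  non-negative; this is the standard multiplicative form for a
  `Tr(Zᵀ L Z)` penalty.
* `W`: the subproblem `min Tr[E^M W] + α‖W‖²` over the scaled simplex,
  with per-gene cost `E^M_g = Σ_s M_s R²_{sg}` (R the residual), completes
  the square to `min ‖W + E^M/2α‖²` — an exact Euclidean projection of
  `−E^M/2α` onto the simplex, computed by the sorting algorithm
  (O(q log q), exact). Genes with larger weighted residual get smaller
  weight. `M` is the mirror image with `E^W_s = Σ_g W_g R²_{sg}` and β.

Denominators are floored at ε = 1e-12. Initial `U`, `Z` are drawn
uniform(0,1) + 0.1 — strictly positive, since zeros are absorbing under
multiplicative updates — and `W`, `M` start uniform.

**Weight warm-up.** The weight updates are skipped for the first
`weight_warmup = 30` iterations. At a random initialization every gene is
poorly predicted, so immediate weighting cannot distinguish a subgroup
driver from an unstructured column and prunes both (empirically this
collapses recovery entirely). After a short unweighted phase the residual
costs separate: a well-fit gene pays only its Bernoulli variance, a
subgroup driver about m/(4k) above background, an unstructured dense
column about m/5.

**Restarts.** Alternating NMF updates find local minima; a poor basin can
leave one subgroup without a dedicated factor. `fit` therefore runs
`n_init = 4` restarts, drawing all initializations from one seeded stream,
and keeps the run with the lowest final objective (lower objective tracks
better recovery on planted cohorts). Results are fully determined by
`seed`.

**Stopping.** After each iteration the relative change
`|f_t − f_{t−1}| / max(f_{t−1}, 1e-12)` is compared to `tol = 1e-6`
(stop when ≤ tol, or after `max_iter = 500` iterations). Note the
objective includes the near-constant α/β terms, which damp the relative
change; the default tolerance accounts for this.

**Balancing.** After convergence the columns of `U` are scaled to unit
Euclidean norm and the inverse scale folded into `Z`. The product `U Zᵀ`
is unchanged; gene scores become comparable across factors and runs. The
recorded objective trace refers to the pre-balancing iterates (the graph
term is not scale-invariant).

**Degenerate modes.** `mode="gnmf"` freezes `W`, `M` at uniform — with the
default budgets `C_w = p`, `C_m = m` uniform weights equal 1, so the data
term is exactly the unweighted Frobenius loss and the α/β terms are known
constants. `mode="driversub"` additionally applies an L1 penalty on `Z`
(as a post-update soft-threshold at λ_z) and a Frobenius penalty on the
basis (λ_w added to the basis-update denominator), with uniform weights.
An optional Nesterov-style extrapolation with objective-increase restart
is available (`accelerate=True`) but off by default.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 4 | subspace dimension = assumed number of latent subgroups; user-set, not estimated |
| `lambda_graph` | 1.0 | strength of the Laplacian smoothness penalty |
| `alpha` | m/12 | gene-weight ridge. While all weights are positive, `w_g = C_w/p + (mean E − E_g)/2α`, so a gene hits weight 0 once its cost exceeds the average by 2α = m/6 — several times a subgroup driver's excess (~m/(4k)) but below an unstructured dense column's (~m/5). Scaling with m keeps this geometry cohort-size independent; the plateau m/14–m/11 behaves equivalently |
| `beta` | p/12 | sample-weight ridge, mirror argument in p |
| `C_w`, `C_m` | p, m | weight budgets; uniform weights are then exactly 1 and the unweighted objective is a special case |
| `weight_warmup` | 30 | iterations before weighting activates (see above) |
| `knn` | 5 | graph sparsification (see above) |
| `n_init` | 4 | random restarts, best final objective kept |
| `max_iter`, `tol` | 500, 1e-6 | stopping rule |
| `lambda_z`, `lambda_w` | 0.1, 0.1 | driversub-mode penalties only |

## Scoring, ranking, subgroups

The mutation score of gene i is `max_r z_ir` (default); `l2` and `sum`
are available alternatives. The max is the natural choice when embeddings
align with coordinate axes: one coordinate carries the signal, and its
index doubles as the subgroup label (`assign_subgroups`; ties resolve to
the lowest dimension, an all-zero row is "unassigned", label 0). Rankings
sort by descending score with ties broken by ascending gene symbol, so
output is deterministic. Candidate lists are ranking prefixes; 100, 200
and 500 are the conventional sizes.

## Benchmark overlap testing

A candidate list is tested against each benchmark set with the one-sided
(upper-tail) hypergeometric test — the standard over-representation test,
and the only direction consistent with "more overlap → smaller p". The
universe is the set of genes present in the filtered mutation matrix;
benchmark genes outside it are dropped before testing since no candidate
list can reach them. The tail probability is computed in log space
(log-gamma binomial coefficients + logsumexp), exact to ~1e-13 relative
for small universes and underflow-free deep in the tail. Per-collection
reports include the arithmetic mean of per-set p-values as the headline
summary and the minimum; Benjamini–Hochberg-adjusted p-values are reported
as a supplementary column but never enter the summary.

## Synthetic cohorts

`simulate_cohort` draws the simplest generative model consistent with the
subgroup-heterogeneity setting: samples partitioned near-evenly into k
subgroups; each subgroup owns a disjoint set of driver genes mutated
Bernoulli(driver_rate_in) within the subgroup; everything else mutates at
Bernoulli(background_rate); a fraction of noisy genes mutate at
noisy_gene_rate across the whole cohort; a fraction of outlier samples
mutate at outlier_sample_rate across all genes (overriding gene identity).
Defaults: 120 samples, 400 genes, k = 4, 10 drivers/subgroup, rates
0.5 vs 0.02, 5% outliers and 5% noisy genes at rate 0.3.

The generator does **not** model mutational signatures, gene length or
expression covariates, copy-number events, or correlations between
passenger genes. Consequently, passing recovery tests demonstrates that
the method separates planted subgroup structure from unstructured
binary noise at realistic sparsity — not that it reproduces driver calls
on real tumors, where confounders like gene length dominate raw mutation
counts.

`recovery_metrics` reports precision@n and recall@n against the union of
planted drivers and the adjusted Rand index between recovered and planted
driver subgroups (scikit-learn's chance-corrected ARI).

## Numerical choices and degenerate inputs

* multiplicative-update denominators floored at 1e-12; initialization
  strictly positive (zeros are absorbing).
* simplex projection is the exact sorting algorithm; no iterative solver.
* hypergeometric tail: `x = 0` returns exactly 1; infeasible index ranges
  are excluded analytically before exponentiation.
* all-zero gene columns are rejected by the matrix invariant; removal is
  an explicit, logged `filter_genes` step, never silent.
* all-equal gene profiles make every pairwise distance zero: the median
  bandwidth falls back to 1.0 with a warning.
* ties everywhere break deterministically (gene symbol ascending; lowest
  factor index).
* score/rank ties and restart ties (equal final objectives) keep the
  first candidate, preserving seed determinism.

## Problem sizes used in the test suite

Oracle-equivalence checks run on instances up to 8×10 (exhaustive
double loops) and 30×40 (solver traces); recovery and robustness checks
run the default 120×400 cohorts over ten seeds; the hypergeometric tail
is verified exhaustively for all feasible configurations with universe
size ≤ 60 and spot-checked at N = 2000. These sizes were chosen so the
full suite exercises every pipeline stage end-to-end in a few minutes on
one CPU while keeping the brute-force oracles exact.

## Known limitations

* k is user-set; the package provides no model-order selection.
* Scores carry no significance calibration — the ranking is relative, and
  candidate-list sizes are conventions, not thresholds.
* The instance-weight mechanism assumes noise is *less* structured than
  signal; a confounder that mimics subgroup structure (e.g. a batch
  effect aligned with a sample cluster) will be kept, not down-weighted.
* Binarization discards mutation multiplicity, type and position;
  per-sample subgroup assignment from `U` is not exposed.
* The adaptive (per-iteration) graph refresh is available but makes the
  objective non-stationary; convergence is then assessed only informally.
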