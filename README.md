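# ragnmf — robust driver-gene prioritization from somatic mutation matrices

Somatic mutations accumulate in every tumor, but only a minority of mutated
genes (*drivers*) contribute to tumor growth; the rest are *passengers*.
Because cancers of one type split into latent molecular subgroups, a driver
may be recurrent only within its subgroup and invisible in cohort-wide
mutation frequencies — and subgroup labels are usually not available.

`ragnmf` prioritizes driver genes from a **binary samples × genes somatic
mutation matrix alone**, with no subtype annotation, using robust adaptive
graph-regularized non-negative matrix factorization. It is a library first
(importable API plus `examples/` scripts), with a thin `ragnmf` command-line
wrapper for shell pipelines.

## The model

Given a binary matrix `X` (m samples × p genes), the solver finds
non-negative factors `U` (m × k) and `Z` (p × k) together with diagonal
robust weights — `W` over genes ("instances") and `M` over samples
("features") — by minimizing

```
min  Tr[ diag(M) (X − U Zᵀ) diag(W) (X − U Zᵀ)ᵀ ]
     + λ · Tr(Zᵀ L_S Z)  +  α‖W‖²  +  β‖M‖²
s.t. U, Z, W, M ≥ 0,   ΣW = C_w,   ΣM = C_m
```

* the **weighted residual** lets the solver spend its k dimensions on
  reproducible subgroup structure: a gene (or sample) whose profile cannot
  be explained is down-weighted instead of distorting the factors;
* `L_S = D_S − S` is the **graph Laplacian** of a Gaussian-kernel
  similarity graph over gene profiles (distances use the learned sample
  weights `M` as a diagonal metric), which smooths the gene embeddings `Z`
  along the graph;
* the weight vectors live on **scaled simplices**, so down-weighting one
  gene necessarily re-allocates trust to others; their updates are exact
  closed forms via Euclidean projection onto the simplex.

`U` and `Z` are updated multiplicatively (majorize–minimize steps, so the
objective never increases); `W` and `M` by exact simplex-projected
minimizers. Each row `z_i` of `Z` embeds gene *i*: its largest coordinate
is the gene's **mutation score** (drivers score high) and the coordinate's
index is the gene's **subgroup**. Candidate lists (top 100/200/500 genes)
are evaluated against benchmark gene sets (GMT/MSigDB format) with the
upper-tail hypergeometric over-representation test.

Degenerate modes recover simpler published objectives: `mode="gnmf"` (plain
graph-regularized NMF, uniform weights) and `mode="driversub"` (adds an L1
sparsity penalty on `Z` and a Frobenius penalty on the basis).

## Worked example

```sh
python examples/simulate_fit_rank.py
```

```
cohort: 120 samples x 400 genes, 4 subgroups, 40 planted drivers
solver: 225 iterations, converged=True, final objective 9509.1
top 5 genes: ['G030', 'G007', 'G001', 'G032', 'G008'] (scores [3.62, 3.39, 3.35, 3.23, 3.22])
precision@40 = 0.825  recall@40 = 0.825  subgroup ARI = 0.718
```

The synthetic cohort plants 10 driver genes per subgroup (within-subgroup
mutation rate 0.5, background 0.02) plus 5% outlier samples and 5% noisy
genes mutated unstructuredly at rate 0.3. Of the 40 top-scoring genes, 33
are planted drivers (precision 0.825), and the dominant subspace dimension
of the recovered drivers matches their planted subgroup (ARI 0.718).
`examples/robust_weights.py` shows the mechanism: the noisy genes' learned
weights end at 0.000 (all 20 driven exactly to zero) versus 1.053 for
clean genes. `examples/benchmark_enrichment.py` scores the candidate list
against benchmark sets — planted driver sets come back with hypergeometric
p-values around 3e-11 — and `examples/maf_binarization.py` shows MAF input.

The same pipeline from the shell:

```sh
ragnmf simulate cohort/                      # matrix.tsv + truth.json + drivers.gmt
ragnmf fit cohort/matrix.tsv model.npz --k 4 --seed 0
ragnmf rank model.npz ranking.tsv --top 500
ragnmf enrich ranking.tsv.top500.txt cohort/drivers.gmt report.tsv \
       --universe-ranking ranking.tsv
```

Real cohorts enter either as a mutation-matrix TSV or as a MAF file via
`ragnmf binarize` (default filter: nonsilent coding variant classes).

## Layout

```
src/ragnmf/
  io.py          MAF / matrix-TSV / GMT / ranking readers and writers
  graph.py       metric-weighted gene similarity graph and Laplacian
  solver.py      the factorization: objective, updates, outer loop
  scoring.py     mutation scores, rankings, candidate lists, subgroups
  enrichment.py  hypergeometric overlap tests and benchmark reports
  simulate.py    synthetic heterogeneous cohorts with planted truth
  cli.py         thin click wrapper (simulate/binarize/fit/rank/enrich)
docs/methods.md  model, assumptions, parameter choices, limitations
```
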