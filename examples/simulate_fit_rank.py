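"""Simulate a heterogeneous cohort, factorize it, and rank driver candidates.

Builds a 120-sample x 400-gene binary mutation cohort with 4 latent
subgroups (10 planted drivers each), runs the robust graph-regularized
factorization, and reports how well the top-ranked genes recover the
planted drivers.
"""

from ragnmf import (
    CohortSpec,
    RagnmfConfig,
    fit,
    rank_from_state,
    recovery_metrics,
    simulate_cohort,
)

spec = CohortSpec(seed=0)
X, truth = simulate_cohort(spec)
print(f"cohort: {X.n_samples} samples x {X.n_genes} genes, "
      f"{spec.k_subgroups} subgroups, {len(truth.all_drivers())} planted drivers")

state = fit(X, RagnmfConfig(k=4, seed=0))
print(f"solver: {state.n_iter} iterations, converged={state.converged}, "
      f"final objective {state.objective_history[-1]:.1f}")

ranking = rank_from_state(state, X.genes)
metrics = recovery_metrics(ranking, truth, n_top=40)

print(f"top 5 genes: {ranking.genes[:5]} (scores {[round(float(s), 2) for s in ranking.scores[:5]]})")
print(f"precision@40 = {metrics['precision']:.3f}  "
      f"recall@40 = {metrics['recall']:.3f}  subgroup ARI = {metrics['ari']:.3f}")
print("precision/recall measure how many of the 40 top-ranked genes are planted")
print("drivers; the ARI measures whether their dominant subspace dimension")
print("matches their planted subgroup.")
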