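"""Robust adaptive graph-regularized NMF solver.

The model factorizes a binary samples x genes mutation matrix X as
X ~ U Z^T with U (samples x k) and Z (genes x k) nonnegative, minimizing

    Tr[diag(M) (X - U Z^T) diag(W) (X - U Z^T)^T]
        + lambda Tr(Z^T L_S Z) + alpha ||W||^2 + beta ||M||^2

subject to U, Z >= 0 and the diagonal weight vectors W (per gene) and
M (per sample) lying on scaled simplices: W >= 0, sum W = C_w and
M >= 0, sum M = C_m. The weighted residual lets the solver discount noisy
genes (instances) and outlier samples (features) instead of fitting them;
the graph term smooths gene embeddings Z along the similarity graph.

Optimization alternates multiplicative updates for U and Z (each a
majorize-minimize step for its weighted subproblem) with exact
closed-form solutions of the two simplex-constrained quadratic weight
subproblems.

Notation note: some presentations use W for the basis matrix; here the
basis is U, the coefficients Z, and W / M are strictly the diagonal
instance / feature weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .exceptions import ConfigurationError, NumericalError
from .graph import SimilarityGraph, build_graph

EPS = 1e-12

_MODES = ("gnmf", "driversub", "ragnmf")


@dataclass
class RagnmfConfig:
    """Hyperparameters of the factorization.

    Parameters
    ----------
    k : int
        Subspace dimension (number of latent subgroups). Default 4.
    lambda_graph : float
        Weight of the Laplacian smoothness penalty Tr(Z^T L_S Z).
    alpha, beta : float or None
        Ridge penalties on the instance weights W and feature weights M.
        ``None`` (default) resolves to m/12 and p/12 at fit time. While
        every weight is positive the update gives
        w_g = C_w/p + (mean(E) - E_g)/(2 alpha), so a gene reaches weight
        zero once its cost exceeds the cohort average by 2 alpha = m/6.
        Costs are sums of per-sample squared residuals (each about r(1-r)
        for a well-fit Bernoulli entry), so the cut-off sits well above
        the excess cost of a subgroup-confined driver (~ m/(4k)) but
        below that of a cohort-wide unstructured dense column (~ m/5 at
        mutation rates near 0.3): genuine subgroup signal keeps its weight
        while dense noise is driven to zero. Scaling with the opposite
        dimension keeps this behaviour independent of cohort size.
    C_w, C_m : float or None
        Simplex budgets for W and M. ``None`` resolves to p and m, so
        uniform weights equal 1 and the unweighted objective is recovered
        as a special case.
    lambda_z, lambda_w : float
        Sparsity (L1 on Z) and Frobenius (on U) penalties used only in
        ``driversub`` mode.
    mode : {"ragnmf", "gnmf", "driversub"}
        ``gnmf`` freezes W and M at uniform (plain graph-regularized NMF);
        ``driversub`` additionally applies the sparse/Frobenius penalties
        with uniform weights; ``ragnmf`` runs the full robust model.
    weight_warmup : int
        Outer iterations to run with W and M frozen at uniform before the
        weight updates activate (ragnmf mode only). At a random
        initialization every gene is poorly predicted, so immediate
        weighting would prune drivers and noise alike; after a short
        unweighted phase the residual costs separate structure from
        noise. Default 30.
    refresh_graph : bool
        If True, rebuild the gene graph with the current feature weights M
        at each outer iteration (re-estimating the bandwidth too), making
        the similarity metric adaptive. Off by default: a refreshed graph
        changes the objective between iterations, so the trace is only
        piecewise monotone and convergence is harder to assess, while on
        binary cohorts the frozen iteration-0 graph recovers planted
        structure equally well at a fraction of the cost.
    sigma : float or "median"
        Kernel bandwidth passed to the graph builder.
    knn : int or None
        Sparsify the gene graph to symmetric k-nearest neighbours before
        forming the Laplacian. Default 5. ``None`` keeps the full graph;
        on binary profiles the Gaussian kernel with a median bandwidth is
        then near-uniform, which turns the smoothness penalty into global
        shrinkage with strength growing like p and stalls the
        multiplicative Z update, so the sparse graph is the default.
    tol : float
        Relative objective-change stopping tolerance
        |f_t - f_{t-1}| / max(f_{t-1}, 1e-12) <= tol.
    n_init : int
        Number of random restarts; the run with the lowest final
        objective is kept. Alternating NMF updates only find local
        minima, and a poor basin can leave a subgroup without a dedicated
        factor, so a handful of restarts markedly stabilizes recovery.
        All restarts draw their initializations from one seeded stream,
        so results remain fully determined by ``seed``. Default 4.
    accelerate : bool
        Nesterov-style extrapolation on U and Z with restart on objective
        increase. Off by default (plain alternating updates).
    """

    k: int = 4
    lambda_graph: float = 1.0
    alpha: float | None = None
    beta: float | None = None
    C_w: float | None = None
    C_m: float | None = None
    lambda_z: float = 0.1
    lambda_w: float = 0.1
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    mode: str = "ragnmf"
    weight_warmup: int = 30
    refresh_graph: bool = False
    sigma: float | str = "median"
    knn: int | None = 5
    n_init: int = 4
    accelerate: bool = False

    def resolve(self, m: int, p: int) -> "RagnmfConfig":
        """Return a copy with data-dependent defaults made concrete."""
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.k >= min(m, p):
            raise ConfigurationError(
                f"k={self.k} must be smaller than min(n_samples, n_genes)={min(m, p)}"
            )
        out = replace(
            self,
            alpha=float(self.alpha) if self.alpha is not None else m / 12.0,
            beta=float(self.beta) if self.beta is not None else p / 12.0,
            C_w=float(self.C_w) if self.C_w is not None else float(p),
            C_m=float(self.C_m) if self.C_m is not None else float(m),
        )
        for name in ("lambda_graph", "lambda_z", "lambda_w"):
            if getattr(out, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if out.mode == "ragnmf" and (out.alpha <= 0 or out.beta <= 0):
            raise ConfigurationError("alpha and beta must be positive in ragnmf mode")
        if out.C_w <= 0 or out.C_m <= 0:
            raise ConfigurationError("weight budgets C_w, C_m must be positive")
        if out.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if out.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if out.weight_warmup < 0:
            raise ConfigurationError("weight_warmup must be >= 0")
        if out.knn is not None and out.knn < 1:
            raise ConfigurationError("knn must be >= 1 or None")
        if out.n_init < 1:
            raise ConfigurationError("n_init must be >= 1")
        return out


@dataclass
class FactorizationState:
    """Learned factors, weights and the optimization trace.

    ``U`` is the samples x k basis, ``Z`` the genes x k coefficient matrix
    whose rows embed genes in the subspace; ``W`` (length genes) and ``M``
    (length samples) are the diagonal robust weights. After ``fit`` the
    basis columns are normalized to unit Euclidean norm with the scale
    folded into Z, so coefficient magnitudes are comparable across runs.
    """

    U: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    M: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    graph: SimilarityGraph | None = None
    config: RagnmfConfig | None = None


def objective(X, state: FactorizationState, graph: SimilarityGraph, config: RagnmfConfig) -> float:
    """Evaluate the full objective at the given state.

    Data term computed as sum_{s,g} M_s W_g R_{sg}^2 with R = X - U Z^T,
    i.e. Tr[diag(M) R diag(W) R^T]. In ``driversub`` mode the sparse and
    Frobenius penalties are added; the alpha/beta ridge terms are always
    included (they are constants when the weights are frozen).
    """
    X = np.asarray(X, dtype=float)
    U, Z, W, M = state.U, state.Z, state.W, state.M
    m, p = X.shape
    if U.shape[0] != m or Z.shape[0] != p or U.shape[1] != Z.shape[1]:
        raise ConfigurationError(
            f"shape mismatch: X {X.shape}, U {U.shape}, Z {Z.shape}"
        )
    if W.shape != (p,) or M.shape != (m,):
        raise ConfigurationError(f"weight shapes W {W.shape}, M {M.shape} do not match X {X.shape}")
    for arr in (U, Z, W, M):
        if not np.isfinite(arr).all():
            raise NumericalError("non-finite value in factorization state")
    R = X - U @ Z.T
    data = float(M @ (R**2) @ W)
    value = data + config.alpha * float(W @ W) + config.beta * float(M @ M)
    if config.lambda_graph > 0:
        value += config.lambda_graph * float(np.sum(Z * (graph.laplacian @ Z)))
    if config.mode == "driversub":
        value += config.lambda_z * float(np.abs(Z).sum())
        value += config.lambda_w * float(np.sum(U**2))
    return value


def update_basis(X, state: FactorizationState, config: RagnmfConfig) -> np.ndarray:
    """Multiplicative update of the basis U with Z, W, M fixed.

    U <- U * [diag(M) X diag(W) Z] / [diag(M) U Z^T diag(W) Z], elementwise,
    denominator floored at EPS. With uniform weights this is the classical
    NMF basis update.
    """
    X = np.asarray(X, dtype=float)
    U, Z, W, M = state.U, state.Z, state.W, state.M
    XW = X * W[np.newaxis, :]
    num = M[:, np.newaxis] * (XW @ Z)
    den = M[:, np.newaxis] * (((U @ Z.T) * W[np.newaxis, :]) @ Z)
    if config.mode == "driversub":
        den = den + config.lambda_w * U
    return U * num / np.maximum(den, EPS)


def update_coefficients(
    X, state: FactorizationState, graph: SimilarityGraph, config: RagnmfConfig
) -> np.ndarray:
    """Multiplicative update of the coefficients Z with U, W, M fixed.

    The Laplacian penalty enters through the standard split L_S = D_S - S:
    the similarity part lands in the numerator and the degree part in the
    denominator, so every factor stays nonnegative:

    Z <- Z * [diag(W) X^T diag(M) U + lambda S Z]
           / [diag(W) Z U^T diag(M) U + lambda diag(D_S) Z]

    In ``driversub`` mode the L1 penalty is applied afterwards as a
    soft-threshold (proximal step) at lambda_z, clipped at zero.
    """
    X = np.asarray(X, dtype=float)
    U, Z, W, M = state.U, state.Z, state.W, state.M
    MU = M[:, np.newaxis] * U
    num = W[:, np.newaxis] * (X.T @ MU)
    den = W[:, np.newaxis] * (Z @ (U.T @ MU))
    if config.lambda_graph > 0:
        num = num + config.lambda_graph * (graph.similarity @ Z)
        den = den + config.lambda_graph * graph.degrees[:, np.newaxis] * Z
    Z_new = Z * num / np.maximum(den, EPS)
    if config.mode == "driversub" and config.lambda_z > 0:
        Z_new = np.maximum(Z_new - config.lambda_z, 0.0)
    return Z_new


def instance_weight_costs(X, state: FactorizationState) -> np.ndarray:
    """Per-gene weighted residual cost E^M_g = sum_s M_s R_{sg}^2."""
    X = np.asarray(X, dtype=float)
    R = X - state.U @ state.Z.T
    return state.M @ (R**2)


def feature_weight_costs(X, state: FactorizationState) -> np.ndarray:
    """Per-sample weighted residual cost E^W_s = sum_g W_g R_{sg}^2."""
    X = np.asarray(X, dtype=float)
    R = X - state.U @ state.Z.T
    return (R**2) @ state.W


def project_to_scaled_simplex(v, budget: float) -> np.ndarray:
    """Euclidean projection of v onto {w : w >= 0, sum w = budget}.

    Exact sorting algorithm: with u the coordinates of v sorted in
    decreasing order, the threshold is theta = (sum_{i<=rho} u_i - budget)/rho
    for the largest rho with u_rho > (sum_{i<=rho} u_i - budget)/rho, and
    the projection is max(v - theta, 0).
    """
    v = np.asarray(v, dtype=float)
    if budget <= 0:
        raise ConfigurationError(f"budget must be positive, got {budget}")
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, v.size + 1)
    cond = u - (css - budget) / idx > 0
    rho = int(np.nonzero(cond)[0][-1]) + 1
    theta = (css[rho - 1] - budget) / rho
    return np.maximum(v - theta, 0.0)


def update_instance_weights(costs, config: RagnmfConfig) -> np.ndarray:
    """Exact minimizer of sum_g E_g W_g + alpha ||W||^2 on the C_w-simplex.

    Completing the square gives argmin ||W + E/(2 alpha)||^2 over the
    simplex, i.e. the projection of -E/(2 alpha). Genes with larger
    weighted residual cost receive smaller weight.
    """
    costs = np.asarray(costs, dtype=float)
    if config.alpha is None or config.alpha <= 0:
        raise ConfigurationError("alpha must be positive to update instance weights")
    return project_to_scaled_simplex(-costs / (2.0 * config.alpha), config.C_w)


def update_feature_weights(X, state: FactorizationState, config: RagnmfConfig) -> np.ndarray:
    """Exact minimizer of sum_s E^W_s M_s + beta ||M||^2 on the C_m-simplex.

    Structurally the mirror image of :func:`update_instance_weights` under
    transposing X and swapping (W, alpha) with (M, beta).
    """
    if config.beta is None or config.beta <= 0:
        raise ConfigurationError("beta must be positive to update feature weights")
    costs = feature_weight_costs(X, state)
    return project_to_scaled_simplex(-costs / (2.0 * config.beta), config.C_m)


def fit(X, config: RagnmfConfig | None = None) -> FactorizationState:
    """Run the alternating solver on a binary mutation matrix.

    Per outer iteration: (1) rebuild the gene graph with the current
    feature weights M (if ``refresh_graph``, else reuse the iteration-0
    graph), (2) update U, (3) update Z, (4) update W, (5) update M,
    (6) record the objective. Steps 4-5 run only in ``ragnmf`` mode and
    only after ``weight_warmup`` iterations; in ``gnmf`` and ``driversub``
    modes W and M stay uniform throughout. Stops when the relative
    objective change falls below ``tol`` or after ``max_iter`` iterations.
    Fully determined by ``config.seed``.
    """
    if config is None:
        config = RagnmfConfig()
    values = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    Xv = np.asarray(values, dtype=float)
    m, p = Xv.shape
    cfg = config.resolve(m, p)

    rng = np.random.default_rng(cfg.seed)
    best: FactorizationState | None = None
    for _ in range(cfg.n_init):
        # strictly positive init keeps multiplicative updates away from absorbing zeros
        U = rng.uniform(0.0, 1.0, size=(m, cfg.k)) + 0.1
        Z = rng.uniform(0.0, 1.0, size=(p, cfg.k)) + 0.1
        state = _fit_single(Xv, U, Z, cfg)
        if best is None or state.objective_history[-1] < best.objective_history[-1]:
            best = state
    _balance_columns(best)
    return best


def _fit_single(Xv: np.ndarray, U: np.ndarray, Z: np.ndarray, cfg: RagnmfConfig) -> FactorizationState:
    m, p = Xv.shape
    W = np.full(p, cfg.C_w / p)
    M = np.full(m, cfg.C_m / m)
    state = FactorizationState(U=U, Z=Z, W=W, M=M, config=cfg)

    graph: SimilarityGraph | None = None
    history: list[float] = []
    knn = None if cfg.knn is None else min(cfg.knn, p - 1)
    # Nesterov bookkeeping (used only when cfg.accelerate)
    U_prev, Z_prev, t_prev = U, Z, 1.0

    for it in range(cfg.max_iter):
        if graph is None or cfg.refresh_graph:
            graph = build_graph(Xv, feature_weights=state.M, sigma=cfg.sigma, knn=knn)

        if cfg.accelerate and it > 0:
            t = (1.0 + np.sqrt(1.0 + 4.0 * t_prev**2)) / 2.0
            coef = (t_prev - 1.0) / t
            U_look = np.maximum(state.U + coef * (state.U - U_prev), 0.0)
            Z_look = np.maximum(state.Z + coef * (state.Z - Z_prev), 0.0)
            U_prev, Z_prev = state.U, state.Z
            trial = replace_factors(state, U_look, Z_look)
            trial.U = update_basis(Xv, trial, cfg)
            trial.Z = update_coefficients(Xv, trial, graph, cfg)
            if cfg.mode == "ragnmf" and it >= cfg.weight_warmup:
                trial.W = update_instance_weights(instance_weight_costs(Xv, trial), cfg)
                trial.M = update_feature_weights(Xv, trial, cfg)
            f_trial = objective(Xv, trial, graph, cfg)
            if history and f_trial > history[-1]:
                # restart: plain update from the previous iterate
                t_prev = 1.0
            else:
                t_prev = t
                state = trial
                _finish_iteration(state, history, f_trial, it)
                if _converged(history, cfg.tol):
                    state.converged = True
                    break
                continue
        else:
            U_prev, Z_prev = state.U, state.Z

        state.U = update_basis(Xv, state, cfg)
        state.Z = update_coefficients(Xv, state, graph, cfg)
        if cfg.mode == "ragnmf" and it >= cfg.weight_warmup:
            state.W = update_instance_weights(instance_weight_costs(Xv, state), cfg)
            state.M = update_feature_weights(Xv, state, cfg)
        f = objective(Xv, state, graph, cfg)
        _finish_iteration(state, history, f, it)
        if _converged(history, cfg.tol):
            state.converged = True
            break

    state.objective_history = history
    state.n_iter = len(history)
    state.graph = graph
    return state


def replace_factors(state: FactorizationState, U: np.ndarray, Z: np.ndarray) -> FactorizationState:
    return FactorizationState(
        U=U, Z=Z, W=state.W.copy(), M=state.M.copy(), config=state.config
    )


def _finish_iteration(state, history, f, it) -> None:
    if not np.isfinite(f):
        raise NumericalError(f"objective diverged at iteration {it}", iteration=it)
    history.append(float(f))
    state.objective_history = history
    state.n_iter = len(history)


def _converged(history: list[float], tol: float) -> bool:
    if not history:
        return False
    if len(history) == 1:
        return np.isinf(tol)
    prev, cur = history[-2], history[-1]
    rel = abs(cur - prev) / max(prev, 1e-12)
    return rel <= tol


def _balance_columns(state: FactorizationState) -> None:
    """Normalize basis columns to unit L2 norm, folding the scale into Z.

    The product U Z^T is unchanged; coefficient magnitudes become
    comparable across runs and factors, which matters for gene scoring.
    """
    norms = np.linalg.norm(state.U, axis=0)
    safe = np.where(norms > EPS, norms, 1.0)
    state.U = state.U / safe
    state.Z = state.Z * safe


def save_state(state: FactorizationState, path, genes=None, samples=None) -> None:
    """Save a fitted state as an .npz checkpoint (matrices + config + trace)."""
    cfg = state.config
    payload = {
        "U": state.U,
        "Z": state.Z,
        "W": state.W,
        "M": state.M,
        "objective_history": np.asarray(state.objective_history),
        "n_iter": np.asarray(state.n_iter),
        "converged": np.asarray(state.converged),
        "config_json": np.frombuffer(
            json.dumps(asdict(cfg) if cfg else {}).encode(), dtype=np.uint8
        ),
    }
    if genes is not None:
        payload["genes"] = np.asarray(list(genes), dtype=str)
    if samples is not None:
        payload["samples"] = np.asarray(list(samples), dtype=str)
    np.savez(path, **payload)


def load_state(path):
    """Load a checkpoint saved by :func:`save_state`.

    Returns ``(state, genes, samples)``; genes/samples are ``None`` when the
    checkpoint was saved without identifiers.
    """
    with np.load(path, allow_pickle=False) as npz:
        cfg_raw = json.loads(bytes(npz["config_json"]).decode()) if "config_json" in npz else {}
        config = RagnmfConfig(**cfg_raw) if cfg_raw else None
        state = FactorizationState(
            U=npz["U"],
            Z=npz["Z"],
            W=npz["W"],
            M=npz["M"],
            objective_history=[float(x) for x in npz["objective_history"]],
            n_iter=int(npz["n_iter"]),
            converged=bool(npz["converged"]),
            config=config,
        )
        genes = [str(g) for g in npz["genes"]] if "genes" in npz else None
        samples = [str(s) for s in npz["samples"]] if "samples" in npz else None
    return state, genes, samples


def run_summary(state: FactorizationState) -> dict:
    """JSON-serializable summary of a fit (objective trace, convergence)."""
    cfg = state.config
    return {
        "n_iter": state.n_iter,
        "converged": state.converged,
        "final_objective": state.objective_history[-1] if state.objective_history else None,
        "objective_history": list(state.objective_history),
        "config": asdict(cfg) if cfg else None,
    }
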