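"""Gene mutation scores, rankings, candidate lists and subgroup labels.

A fitted factorization embeds every gene as a nonnegative k-vector (a row
of Z). Because the solver drives these rows toward the coordinate axes, a
gene's dominant coordinate serves double duty: its magnitude is the gene's
mutation score (drivers score high) and its index is the gene's subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

#: Candidate-list sizes commonly reported for this kind of pipeline.
TOP_N_PRESETS = (100, 200, 500)

SCORE_METHODS = ("max", "l2", "sum")


@dataclass
class GeneRanking:
    """Genes ordered by descending mutation score.

    ``ranks`` are 1-based; ties in score are broken by ascending gene
    symbol so output is deterministic. ``subgroups`` holds each gene's
    dominant subspace dimension (1..k), 0 meaning unassigned.
    """

    genes: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    subgroups: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.subgroups = np.asarray(self.subgroups, dtype=int)
        p = len(self.genes)
        if not (self.scores.shape == self.ranks.shape == self.subgroups.shape == (p,)):
            raise ConfigurationError("ranking field lengths disagree")
        if p and (np.diff(self.scores) > 0).any():
            raise ConfigurationError("scores must be non-increasing in rank order")
        if p and sorted(self.ranks) != list(range(1, p + 1)):
            raise ConfigurationError("ranks must be a permutation of 1..p")

    def __len__(self) -> int:
        return len(self.genes)


def gene_scores(Z, method: str = "max") -> np.ndarray:
    """Per-gene mutation score from the coefficient matrix Z (genes x k).

    ``max`` (default) takes each gene's dominant coordinate; ``l2`` the
    Euclidean norm of its embedding; ``sum`` the coordinate total.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ConfigurationError(f"Z must be 2-D (genes x k), got shape {Z.shape}")
    if (Z < 0).any():
        raise ConfigurationError("Z must be nonnegative")
    if method == "max":
        return Z.max(axis=1)
    if method == "l2":
        return np.linalg.norm(Z, axis=1)
    if method == "sum":
        return Z.sum(axis=1)
    raise ConfigurationError(f"unknown score method {method!r}; choose from {SCORE_METHODS}")


def assign_subgroups(Z) -> np.ndarray:
    """Label each gene with its dominant subspace dimension (1..k).

    Ties resolve to the lowest dimension index (numpy argmax convention);
    an all-zero row is unassigned and labelled 0.
    """
    Z = np.asarray(Z, dtype=float)
    if (Z < 0).any():
        raise ConfigurationError("Z must be nonnegative")
    labels = Z.argmax(axis=1) + 1
    labels[Z.max(axis=1) == 0] = 0
    return labels


def rank_genes(genes, scores, subgroups=None) -> GeneRanking:
    """Order genes by descending score, ties broken by ascending symbol."""
    genes = list(genes)
    scores = np.asarray(scores, dtype=float)
    if len(genes) != scores.size:
        raise ConfigurationError(
            f"{len(genes)} genes but {scores.size} scores"
        )
    if subgroups is None:
        subgroups = np.zeros(len(genes), dtype=int)
    subgroups = np.asarray(subgroups, dtype=int)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return GeneRanking(
        genes=[genes[i] for i in order],
        scores=scores[order],
        ranks=np.arange(1, len(genes) + 1),
        subgroups=subgroups[order],
    )


def rank_from_state(state, genes, method: str = "max") -> GeneRanking:
    """Convenience: score, label and rank genes straight from a fitted state."""
    return rank_genes(genes, gene_scores(state.Z, method), assign_subgroups(state.Z))


def top_candidates(ranking: GeneRanking, n: int) -> list[str]:
    """First n genes of the ranking — the candidate driver list."""
    if n < 1 or n > len(ranking):
        raise ConfigurationError(
            f"n must be in [1, {len(ranking)}], got {n}"
        )
    return ranking.genes[:n]
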