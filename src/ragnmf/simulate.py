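"""Synthetic heterogeneous mutation cohorts with planted ground truth.

Emulates the setting the factorization targets: a cohort split into k
latent subgroups, each with its own driver genes mutated at an elevated
rate within the subgroup, a low background passenger rate everywhere
else, plus two nuisance structures the robust weights are meant to
absorb — outlier samples (dense unstructured rows) and noisy genes
(dense unstructured columns). Everything is Bernoulli given the planted
structure and fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .exceptions import ConfigurationError
from .io import GeneSetCollection, MutationMatrix
from .scoring import GeneRanking


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults describe a small but non-trivial cohort: 120 samples in 4
    subgroups of 30, 400 genes of which each subgroup owns 10 drivers
    mutated at 0.5 within the subgroup against a 0.02 passenger
    background, with 5% outlier samples and 5% noisy genes mutated
    unstructuredly at 0.3.
    """

    n_samples: int = 120
    n_genes: int = 400
    k_subgroups: int = 4
    drivers_per_subgroup: int = 10
    driver_rate_in: float = 0.5
    background_rate: float = 0.02
    outlier_sample_fraction: float = 0.05
    outlier_sample_rate: float = 0.3
    noisy_gene_fraction: float = 0.05
    noisy_gene_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "driver_rate_in": self.driver_rate_in,
            "background_rate": self.background_rate,
            "outlier_sample_rate": self.outlier_sample_rate,
            "noisy_gene_rate": self.noisy_gene_rate,
            "outlier_sample_fraction": self.outlier_sample_fraction,
            "noisy_gene_fraction": self.noisy_gene_fraction,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {r}")
        if self.driver_rate_in <= self.background_rate:
            raise ConfigurationError(
                "driver_rate_in must exceed background_rate "
                f"({self.driver_rate_in} <= {self.background_rate})"
            )
        if self.n_samples < 1 or self.n_genes < 1 or self.k_subgroups < 1:
            raise ConfigurationError("cohort dimensions must be positive")
        if self.k_subgroups * self.drivers_per_subgroup > self.n_genes:
            raise ConfigurationError(
                f"{self.k_subgroups} subgroups x {self.drivers_per_subgroup} drivers "
                f"exceed {self.n_genes} genes"
            )
        if self.k_subgroups > self.n_samples:
            raise ConfigurationError("more subgroups than samples")


@dataclass
class CohortTruth:
    """Planted structure of a simulated cohort."""

    sample_subgroups: np.ndarray  # length n_samples, labels 1..k
    driver_genes: dict[int, list[str]] = field(default_factory=dict)
    noisy_genes: list[str] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)

    def all_drivers(self) -> set[str]:
        return {g for genes in self.driver_genes.values() for g in genes}

    def driver_subgroup_of(self) -> dict[str, int]:
        return {g: c for c, genes in self.driver_genes.items() for g in genes}


def simulate_cohort(spec: CohortSpec) -> tuple[MutationMatrix, CohortTruth]:
    """Draw one cohort.

    Entry (s, g) is Bernoulli with rate: ``outlier_sample_rate`` if s is an
    outlier (overriding the gene's identity), else ``noisy_gene_rate`` if g
    is noisy, ``driver_rate_in`` if g drives s's subgroup, and
    ``background_rate`` otherwise. Samples are partitioned near-evenly
    into subgroups in order; drivers and noisy genes are disjoint.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, p, k = spec.n_samples, spec.n_genes, spec.k_subgroups

    width = len(str(p))
    genes = [f"G{j + 1:0{width}d}" for j in range(p)]
    samples = [f"S{i + 1:0{len(str(m))}d}" for i in range(m)]

    sample_subgroups = np.concatenate(
        [np.full(len(chunk), c + 1) for c, chunk in enumerate(np.array_split(np.arange(m), k))]
    )

    # drivers first (disjoint across subgroups), noisy genes from the rest
    driver_genes = {
        c + 1: genes[c * spec.drivers_per_subgroup : (c + 1) * spec.drivers_per_subgroup]
        for c in range(k)
    }
    n_drivers = k * spec.drivers_per_subgroup
    n_noisy = int(round(spec.noisy_gene_fraction * p))
    n_noisy = min(n_noisy, p - n_drivers)
    noisy_idx = rng.choice(np.arange(n_drivers, p), size=n_noisy, replace=False)
    noisy_idx.sort()
    noisy_genes = [genes[j] for j in noisy_idx]

    n_outliers = int(round(spec.outlier_sample_fraction * m))
    outlier_idx = rng.choice(m, size=n_outliers, replace=False)
    outlier_idx.sort()
    outlier_samples = [samples[i] for i in outlier_idx]

    rates = np.full((m, p), spec.background_rate)
    for c in range(k):
        block = sample_subgroups == c + 1
        cols = slice(c * spec.drivers_per_subgroup, (c + 1) * spec.drivers_per_subgroup)
        rates[np.ix_(block, np.arange(p)[cols])] = spec.driver_rate_in
    rates[:, noisy_idx] = spec.noisy_gene_rate
    rates[outlier_idx, :] = spec.outlier_sample_rate

    values = (rng.random((m, p)) < rates).astype(np.int8)
    matrix = MutationMatrix(genes=genes, samples=samples, values=values)
    truth = CohortTruth(
        sample_subgroups=sample_subgroups,
        driver_genes=driver_genes,
        noisy_genes=noisy_genes,
        outlier_samples=outlier_samples,
    )
    return matrix, truth


def truth_to_gene_sets(truth: CohortTruth) -> GeneSetCollection:
    """Planted driver sets as a benchmark collection (one set per subgroup)."""
    return GeneSetCollection(
        sets={f"PLANTED_DRIVERS_SG{c}": set(genes) for c, genes in truth.driver_genes.items()},
        descriptions={
            f"PLANTED_DRIVERS_SG{c}": f"planted driver genes of subgroup {c}"
            for c in truth.driver_genes
        },
    )


def write_truth_json(truth: CohortTruth, path) -> None:
    payload = {
        "sample_subgroups": [int(c) for c in truth.sample_subgroups],
        "driver_genes": {str(c): list(g) for c, g in truth.driver_genes.items()},
        "noisy_genes": list(truth.noisy_genes),
        "outlier_samples": list(truth.outlier_samples),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_truth_json(path) -> CohortTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return CohortTruth(
        sample_subgroups=np.asarray(payload["sample_subgroups"], dtype=int),
        driver_genes={int(c): list(g) for c, g in payload["driver_genes"].items()},
        noisy_genes=list(payload["noisy_genes"]),
        outlier_samples=list(payload["outlier_samples"]),
    )


def recovery_metrics(ranking: GeneRanking, truth: CohortTruth, n_top: int) -> dict:
    """Precision/recall of the top of a ranking against planted drivers.

    Returns precision@n_top and recall@n_top against the union of planted
    driver genes, plus the adjusted Rand index between the ranking's
    subgroup labels (restricted to the true drivers) and the planted
    driver-subgroup memberships.
    """
    if n_top < 1 or n_top > len(ranking):
        raise ConfigurationError(f"n_top must be in [1, {len(ranking)}], got {n_top}")
    drivers = truth.all_drivers()
    missing = drivers - set(ranking.genes)
    if missing:
        raise ConfigurationError(
            f"ranking does not cover {len(missing)} planted driver(s), e.g. {sorted(missing)[:3]}"
        )
    top = set(ranking.genes[:n_top])
    hits = top & drivers
    precision = len(hits) / n_top
    recall = len(hits) / len(drivers) if drivers else 0.0

    subgroup_of = truth.driver_subgroup_of()
    planted, predicted = [], []
    label_by_gene = dict(zip(ranking.genes, ranking.subgroups))
    for g in sorted(drivers):
        planted.append(subgroup_of[g])
        predicted.append(int(label_by_gene[g]))
    ari = float(adjusted_rand_score(planted, predicted)) if drivers else 0.0
    return {
        "n_top": n_top,
        "precision": precision,
        "recall": recall,
        "ari": ari,
        "n_drivers": len(drivers),
    }


def spec_to_json(spec: CohortSpec) -> dict:
    return asdict(spec)
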