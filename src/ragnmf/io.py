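"""Readers and writers for the formats the pipeline touches.

Supported formats: binary mutation-matrix TSV, MAF (cBioPortal tab-separated
dialect), GMT gene-set files (MSigDB interchange format) and ranked-gene
output tables.

The in-memory mutation matrix is always oriented samples x genes, so that
each gene's mutation profile across the cohort is one column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Nonsilent coding variant classes counted when binarizing a MAF.
#: Configurable because published binary matrices rarely state their rule.
DEFAULT_QUALIFYING_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


@dataclass
class MutationMatrix:
    """Binary somatic-mutation matrix over a cohort.

    Attributes
    ----------
    genes : list of str
        Gene symbols, one per column. Unique.
    samples : list of str
        Sample identifiers, one per row. Unique.
    values : ndarray of shape (n_samples, n_genes)
        Entry ``(s, g)`` is 1 iff gene ``g`` carries a qualifying somatic
        mutation in sample ``s``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        m, p = self.values.shape
        if len(self.samples) != m or len(self.genes) != p:
            raise FormatError(
                f"identifier counts ({len(self.samples)} samples, {len(self.genes)} genes) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.genes)) != p:
            raise FormatError("duplicate gene symbols")
        if len(set(self.samples)) != m:
            raise FormatError("duplicate sample identifiers")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise FormatError(
                f"non-binary entry at sample {self.samples[bad[0]]!r}, "
                f"gene {self.genes[bad[1]]!r}: {self.values[bad[0], bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    def gene_mutation_counts(self) -> np.ndarray:
        """Number of mutated samples per gene (column sums)."""
        return self.values.sum(axis=0)

    def filter_genes(self, min_mutations: int = 1) -> "MutationMatrix":
        """Drop genes mutated in fewer than ``min_mutations`` samples.

        Filtering is explicit and logged; readers never drop columns silently.
        """
        keep = self.gene_mutation_counts() >= min_mutations
        dropped = [g for g, k in zip(self.genes, keep) if not k]
        if dropped:
            logger.info(
                "filter_genes(min_mutations=%d): dropping %d/%d genes",
                min_mutations,
                len(dropped),
                self.n_genes,
            )
        return MutationMatrix(
            genes=[g for g, k in zip(self.genes, keep) if k],
            samples=list(self.samples),
            values=self.values[:, keep],
        )


@dataclass
class GeneSetCollection:
    """Named benchmark gene sets, e.g. parsed from an MSigDB GMT file."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_matrix_tsv(path, orientation: str = "genes_in_rows") -> MutationMatrix:
    """Read a binary mutation matrix from TSV.

    ``orientation`` states what the file's rows are; the result is always
    normalized to samples x genes internally. Row/column order is preserved.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate row identifier {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate column identifier {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        cell = df[col].to_numpy()
        ok = np.isin(cell, ("0", "1"))
        if not ok.all():
            i = int(np.argmin(ok))
            raise FormatError(
                f"non-binary cell at row {df.index[i]!r}, column {col!r}: "
                f"{cell[i]!r} in {path}"
            )
        values[:, j] = cell == "1"
    if orientation == "genes_in_rows":
        return MutationMatrix(
            genes=list(df.index), samples=list(df.columns), values=values.T
        )
    return MutationMatrix(genes=list(df.columns), samples=list(df.index), values=values)


def write_matrix_tsv(matrix: MutationMatrix, path, orientation: str = "genes_in_rows") -> None:
    """Write a mutation matrix as TSV in the requested orientation."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = matrix.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def maf_to_matrix(maf_path, qualifying_classes=DEFAULT_QUALIFYING_CLASSES) -> MutationMatrix:
    """Binarize a MAF into a samples x genes mutation matrix.

    Entry ``(s, g)`` is 1 iff at least one MAF record for sample ``s`` and
    gene ``g`` has ``Variant_Classification`` in ``qualifying_classes``.
    Samples and genes are sorted lexicographically for determinism; the
    result is invariant to the record order of the input file.
    """
    qualifying_classes = set(qualifying_classes)
    if not qualifying_classes:
        raise ConfigurationError("qualifying_classes must be non-empty")
    df = pd.read_csv(maf_path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {maf_path} is missing required column(s): {', '.join(missing)}")
    n_records = len(df)
    df = df[df["Variant_Classification"].isin(qualifying_classes)]
    logger.info(
        "maf_to_matrix: %d/%d records qualify under %d classes",
        len(df),
        n_records,
        len(qualifying_classes),
    )
    pairs = set(zip(df["Tumor_Sample_Barcode"], df["Hugo_Symbol"]))
    samples = sorted({s for s, _ in pairs})
    genes = sorted({g for _, g in pairs})
    s_idx = {s: i for i, s in enumerate(samples)}
    g_idx = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for s, g in pairs:
        values[s_idx[s], g_idx[g]] = 1
    return MutationMatrix(genes=genes, samples=samples, values=values)


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file: per line a set name, a description, then gene symbols."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{gmt_path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_ranking(ranking, path) -> None:
    """Write a gene ranking as TSV (columns gene, score, rank, subgroup), rank order."""
    if len(ranking.genes) == 0:
        raise ConfigurationError("refusing to write an empty ranking")
    df = pd.DataFrame(
        {
            "gene": ranking.genes,
            "score": ranking.scores,
            "rank": ranking.ranks,
            "subgroup": ranking.subgroups,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ranking(path):
    """Read a ranking TSV written by :func:`write_ranking`."""
    from .scoring import GeneRanking

    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return GeneRanking(
        genes=list(df["gene"]),
        scores=df["score"].to_numpy(dtype=float),
        ranks=df["rank"].to_numpy(dtype=int),
        subgroups=df["subgroup"].to_numpy(dtype=int),
    )


def read_gene_list(path) -> list[str]:
    """Read a plain text file with one gene symbol per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
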