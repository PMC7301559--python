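"""Core data containers shared across the pipeline.

These are thin, validated wrappers around pandas/numpy/networkx objects.
All tabular I/O for them lives in :mod:`gwascomp.io_formats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

__all__ = [
    "GwasSummary",
    "PredictionModel",
    "SnpCovariance",
    "ExpressionMatrix",
    "DirectedNetwork",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """An in-memory object violates one of its invariants."""


class FormatError(ValueError):
    """A file on disk does not conform to the expected schema."""


@dataclass
class GwasSummary:
    """Per-SNP association summary statistics.

    ``table`` has columns ``snp_id``, ``effect_allele``, ``non_effect_allele``
    and ``z`` (beta/se when the study reports effect sizes).  One row per SNP;
    z-scores are unitless Wald statistics for the effect-allele dosage.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "effect_allele", "non_effect_allele", "z"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"GWAS summary is missing columns: {missing}")
        tab = self.table.reset_index(drop=True)
        if tab["snp_id"].duplicated().any():
            dups = tab.loc[tab["snp_id"].duplicated(), "snp_id"].unique()
            raise ValidationError(f"duplicate snp_id in GWAS summary: {list(dups[:5])}")
        if not np.isfinite(tab["z"].to_numpy(float)).all():
            raise ValidationError("non-finite z-scores in GWAS summary")
        for col in ("effect_allele", "non_effect_allele"):
            bad = ~tab[col].isin(VALID_ALLELES)
            if bad.any():
                raise ValidationError(
                    f"invalid {col} values: {sorted(tab.loc[bad, col].unique())[:5]}"
                )
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    def z_by_snp(self) -> pd.Series:
        return self.table.set_index("snp_id")["z"]


@dataclass
class PredictionModel:
    """Sparse SNP-to-gene expression prediction weights.

    ``table`` columns: ``gene``, ``rsid``, ``weight``, ``ref_allele``,
    ``eff_allele``.  Weights are expression units per effect-allele dose.
    Per-gene SNP lists are kept in lexicographic rsid order so downstream
    linear algebra is deterministic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "rsid", "weight", "ref_allele", "eff_allele"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"prediction model is missing columns: {missing}")
        tab = self.table.sort_values(["gene", "rsid"], kind="stable").reset_index(drop=True)
        if tab.duplicated(subset=["gene", "rsid"]).any():
            pairs = tab.loc[tab.duplicated(subset=["gene", "rsid"]), ["gene", "rsid"]]
            raise ValidationError(
                f"duplicate (gene, rsid) pairs in prediction model: {pairs.values[:3].tolist()}"
            )
        if not np.isfinite(tab["weight"].to_numpy(float)).all():
            raise ValidationError("non-finite weights in prediction model")
        self.table = tab
        if len(tab) == 0:
            logger.warning("prediction model is empty")

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def gene_entries(self, gene: str) -> pd.DataFrame:
        """Rows for one gene, rsid-sorted."""
        return self.table[self.table["gene"] == gene]

    def snps(self, gene: str) -> list[str]:
        return self.gene_entries(gene)["rsid"].tolist()

    def weights(self, gene: str) -> np.ndarray:
        return self.gene_entries(gene)["weight"].to_numpy(float)


@dataclass
class SnpCovariance:
    """Per-gene SNP dosage covariance blocks (the LD reference Γ).

    ``blocks`` maps a gene id to ``(snp_ids, matrix)`` with ``matrix``
    symmetric over ``snp_ids``.  A block may also hold a full reference panel
    under a caller-chosen key (see ``panel=`` arguments downstream), in which
    case per-gene lookups can be sliced out of it.
    """

    blocks: dict[str, tuple[list[str], np.ndarray]]
    psd_tol: float = 1e-8

    def __post_init__(self) -> None:
        for gene, (snps, mat) in self.blocks.items():
            mat = np.asarray(mat, float)
            if mat.shape != (len(snps), len(snps)):
                raise ValidationError(f"covariance block for {gene!r} has wrong shape")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValidationError(f"covariance block for {gene!r} is not symmetric")
            if np.any(np.diag(mat) < 0):
                raise ValidationError(f"negative diagonal in covariance block for {gene!r}")
            if len(snps) and np.linalg.eigvalsh(mat).min() < -self.psd_tol:
                raise ValidationError(
                    f"covariance block for {gene!r} is not positive semidefinite"
                )
            self.blocks[gene] = (list(snps), mat)

    @property
    def genes(self) -> list[str]:
        return sorted(self.blocks)

    def block(self, gene: str) -> tuple[list[str], np.ndarray]:
        if gene not in self.blocks:
            raise KeyError(f"no covariance block for gene {gene!r}")
        return self.blocks[gene]

    def submatrix(
        self, snp_ids: list[str], gene: str | None = None, panel: str | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Covariance among ``snp_ids`` from a gene block or the panel.

        Returns the subset of ``snp_ids`` actually present (in input order)
        and their covariance.  Prefers the gene's own block; falls back to
        the panel block when given.
        """
        source = None
        if gene is not None and gene in self.blocks:
            source = self.blocks[gene]
        elif panel is not None and panel in self.blocks:
            source = self.blocks[panel]
        if source is None:
            raise KeyError(f"no covariance source for gene {gene!r} (panel={panel!r})")
        ids, mat = source
        index = {s: k for k, s in enumerate(ids)}
        present = [s for s in snp_ids if s in index]
        idx = [index[s] for s in present]
        return present, mat[np.ix_(idx, idx)]

    def lookup(self, snp1: str, snp2: str) -> float | None:
        """Covariance of a SNP pair from the first block containing both."""
        for ids, mat in self.blocks.values():
            if snp1 in ids and snp2 in ids:
                return float(mat[ids.index(snp1), ids.index(snp2)])
        return None


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix of normalized expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression values shape does not match id lists")
        if len(self.sample_ids) < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.values).all():
            raise ValidationError("missing or non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows(self, gene_ids: list[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in expression matrix") from None
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DirectedNetwork:
    """A directed acyclic gene network (e.g. a Bayesian network structure)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        loops = list(nx.nodes_with_selfloops(self.graph))
        if loops:
            raise ValidationError(f"self-loops in network: {loops[:5]}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(f"network contains a cycle: {cycle}")

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "DirectedNetwork":
        g = nx.DiGraph()
        seen = set()
        n_dup = 0
        for parent, child in edges:
            if (parent, child) in seen:
                n_dup += 1
                continue
            seen.add((parent, child))
            g.add_edge(parent, child)
        if n_dup:
            logger.warning("deduplicated %d repeated edges", n_dup)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.graph
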