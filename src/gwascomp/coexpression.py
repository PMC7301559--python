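"""Co-expression module detection and eigengene models.

The pipeline mirrors weighted correlation network analysis (WGCNA): genes are
standardized, an unsigned adjacency ``|cor|^beta`` is built, converted to a
topological-overlap similarity, and average-linkage clustering of the
TOM-dissimilarity is cut at a fixed height.  Each module's eigengene is the
first principal component of its standardized expression profiles; the loading
vector ``R_l`` (unit Euclidean norm) defines the module's activity
``L_l = sum_g R_lg T~_g`` over standardized profiles ``T~``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "ModuleWeights",
    "EigengeneModel",
    "detect_modules",
    "fit_eigengene_weights",
    "eigengene_activity",
    "topological_overlap",
]

UNASSIGNED = 0


@dataclass
class ModuleAssignment:
    """Partition of genes into modules; module id 0 means unassigned."""

    gene_ids: list[str]
    module_ids: np.ndarray

    def __post_init__(self) -> None:
        self.module_ids = np.asarray(self.module_ids, int)
        if len(self.gene_ids) != len(self.module_ids):
            raise ValidationError("gene/module id lengths differ")

    @property
    def modules(self) -> dict[int, list[str]]:
        """Assigned module id -> member gene list (input order)."""
        out: dict[int, list[str]] = {}
        for g, m in zip(self.gene_ids, self.module_ids):
            if m != UNASSIGNED:
                out.setdefault(int(m), []).append(g)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)


@dataclass
class ModuleWeights:
    """Eigengene loadings for one module."""

    genes: list[str]
    weights: np.ndarray  # unit Euclidean norm
    gene_sds: np.ndarray  # per-gene SDs of the fitting expression
    gene_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.gene_sds = np.asarray(self.gene_sds, float)
        if self.gene_means is None:
            self.gene_means = np.zeros_like(self.weights)

    @property
    def is_unit_norm(self) -> bool:
        """Fitted loadings satisfy ||R_l|| = 1 within 1e-10."""
        return abs(np.linalg.norm(self.weights) - 1.0) <= 1e-10


@dataclass
class EigengeneModel:
    """Gene-to-component weight matrix R, one ``ModuleWeights`` per module."""

    modules: dict[int, ModuleWeights]

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.modules)


def _standardize(x: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    return (x - mean[:, None]) / sd[:, None], mean, sd


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological-overlap similarity of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with shared-neighbor
    count l_ij = sum_u a_iu a_uj (u != i, j) and connectivity k_i = sum_u a_iu.
    Diagonal is 1 by convention.
    """
    a = np.array(adjacency, float)
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    expr: ExpressionMatrix,
    soft_power: float = 6.0,
    min_module_size: int = 5,
    cut_height: float = 0.98,
) -> ModuleAssignment:
    """Detect co-expression modules from an expression matrix.

    Pipeline: row-standardize -> Pearson correlation -> unsigned adjacency
    ``|cor|^soft_power`` -> topological overlap -> average-linkage clustering
    of (1 - TOM) -> static cut at ``cut_height``.  Clusters smaller than
    ``min_module_size`` are left unassigned (module id 0).  Module ids are
    assigned 1..K by decreasing size (ties broken by first member's row
    index), so the labelling is deterministic and permutation-equivariant.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    if soft_power <= 0:
        raise ValueError("soft_power must be positive")
    if expr.n_samples < 3:
        raise ValidationError("module detection needs at least 3 samples")
    if expr.n_genes < min_module_size:
        raise ValidationError("fewer genes than min_module_size")

    sd = expr.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValidationError(f"zero-variance gene(s): {bad[:5]}")

    cor = np.corrcoef(expr.values)
    adjacency = np.abs(cor) ** soft_power
    tom = topological_overlap(adjacency)
    diss = np.clip(1.0 - tom, 0.0, None)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)

    tree = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")

    # keep clusters >= min_module_size; relabel by (size desc, first index asc)
    labels = np.zeros(expr.n_genes, dtype=int)
    clusters = []
    for lab in np.unique(raw):
        idx = np.flatnonzero(raw == lab)
        if len(idx) >= min_module_size:
            clusters.append(idx)
    clusters.sort(key=lambda idx: (-len(idx), idx[0]))
    for new_id, idx in enumerate(clusters, start=1):
        labels[idx] = new_id
    n_unassigned = int((labels == UNASSIGNED).sum())
    if n_unassigned:
        logger.info("%d genes left unassigned", n_unassigned)
    return ModuleAssignment(list(expr.gene_ids), labels)


def _leading_direction(std_rows: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector/eigenvalue of the gene correlation matrix."""
    n = std_rows.shape[1]
    corr = std_rows @ std_rows.T / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    return eigvecs[:, -1], float(eigvals[-1])


def fit_eigengene_weights(expr: ExpressionMatrix, modules: ModuleAssignment) -> EigengeneModel:
    """Fit eigengene loading vectors R_l for every assigned module.

    R_l is the leading eigenvector of the module's gene correlation matrix
    (equivalently, the leading right-singular direction over standardized
    profiles).  The sign is fixed so the eigengene correlates non-negatively
    with the module's mean standardized profile; exact zero correlation keeps
    the first nonzero loading positive.  Per-gene means/SDs used for
    standardization are stored for later raw-scale propagation.
    """
    fitted: dict[int, ModuleWeights] = {}
    for module_id, genes in sorted(modules.modules.items()):
        rows = expr.rows(genes)
        sds = rows.std(axis=1, ddof=1)
        if np.any(sds == 0):
            if np.all(sds == 0):
                raise ValidationError(f"module {module_id} has only constant genes")
            bad = [g for g, s in zip(genes, sds) if s == 0]
            raise ValidationError(f"constant gene(s) in module {module_id}: {bad[:5]}")
        if len(genes) == 1:
            fitted[module_id] = ModuleWeights(
                genes, np.array([1.0]), sds, rows.mean(axis=1)
            )
            continue
        std, means, _ = _standardize(rows)
        w, _ = _leading_direction(std)
        # sign convention: correlate positively with the mean profile
        score = float(w @ (std @ std.mean(axis=0)))
        if score < 0:
            w = -w
        elif score == 0:
            nz = np.flatnonzero(w)
            if len(nz) and w[nz[0]] < 0:
                w = -w
        w = w / np.linalg.norm(w)
        fitted[module_id] = ModuleWeights(genes, w, sds, means)
    return EigengeneModel(fitted)


def eigengene_activity(model: EigengeneModel, expr: ExpressionMatrix) -> tuple[np.ndarray, list[int]]:
    """Evaluate eigengene activities L (modules x samples) on ``expr``.

    Member profiles are standardized on the evaluation data; row ``l`` is
    ``R_l`` applied to the standardized profiles of module ``l``'s genes.
    Returns the activity matrix and the module id order of its rows.
    """
    ids = model.module_ids
    out = np.empty((len(ids), expr.n_samples))
    for row, module_id in enumerate(ids):
        mw = model.modules[module_id]
        if not mw.is_unit_norm:
            raise ValidationError(f"module {module_id} weights are not unit-norm")
        std, _, _ = _standardize(expr.rows(mw.genes))
        out[row] = mw.weights @ std
    return out, ids
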