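"""Hierarchical z-score propagation: SNP -> gene -> eigengene component.

Stage one is the summary-statistic TWAS relation

    Z_g = sum_{i in Model_g} W_gi (sigma_i / sigma_g) Z_i,
    sigma_g^2 = sum_ij W_gi Gamma_ij W_gj,

with Gamma the reference-panel SNP dosage covariance.  Stage two applies the
same relation once more to the eigengene, a linear combination of predicted
gene expression:

    Z_l = sum_{g in Module_l} v_lg (sigma_g / sigma_l) Z_g,
    sigma_l^2 = v_l^T Gamma^G v_l,      Gamma^G = W Gamma W^T.

Because eigengene loadings R_l are fitted on *standardized* gene profiles,
the raw-scale combination weights are v_lg = R_lg / sd_g using the per-gene
SDs stored in the eigengene model; with unit SDs this reduces to R itself.
Both stages leave the z-score invariant under positive rescaling of the
weight row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coexpression import EigengeneModel
from .datatypes import GwasSummary, PredictionModel, SnpCovariance, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAssociation",
    "GeneCovariance",
    "ComponentAssociation",
    "harmonize_alleles",
    "compute_gene_z",
    "predicted_gene_covariance",
    "compute_component_z",
    "holm_sidak_adjust",
    "call_gwas_components",
]

#: complementary-allele pairs that cannot be strand-resolved
STRAND_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}

DEGENERATE_VARIANCE = 1e-12


@dataclass
class GeneAssociation:
    """Gene-level association: z-score and predicted-expression SD."""

    gene_id: str
    z: float
    sigma: float
    n_snps_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise ValidationError(f"non-finite z for gene {self.gene_id}")
        if self.sigma <= 0:
            raise ValidationError(f"non-positive sigma for gene {self.gene_id}")


@dataclass
class GeneCovariance:
    """Predicted-expression covariance Gamma^G = W Gamma W^T over a gene list."""

    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.genes), len(self.genes)):
            raise ValidationError("gene covariance shape mismatch")
        self.matrix = (self.matrix + self.matrix.T) / 2.0

    def submatrix(self, genes: list[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.genes)}
        idx = [index[g] for g in genes]
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class ComponentAssociation:
    """Component-level association with significance bookkeeping."""

    module_id: int
    z: float
    sigma: float
    n_genes_used: int
    p_raw: float = field(default=None)  # type: ignore[assignment]
    p_adjusted: float | None = None
    is_gwas_component: bool = False

    def __post_init__(self) -> None:
        if self.p_raw is None:
            self.p_raw = two_sided_p(self.z)


def two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail probability, kept strictly positive."""
    return max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny)


def harmonize_alleles(gwas: GwasSummary, model: PredictionModel) -> GwasSummary:
    """Align GWAS effect alleles to the prediction model's coding.

    Keeps only model SNPs found in the GWAS summary.  z is kept when the
    GWAS effect allele matches the model effect allele, negated when the
    effect/non-effect pair is swapped relative to the model, and the SNP is
    dropped when the pair is strand-ambiguous (A/T or C/G) or does not match
    the model alleles at all.  Dropped counts are logged.
    """
    alleles = (
        model.table[["rsid", "ref_allele", "eff_allele"]]
        .drop_duplicates(subset="rsid")
        .set_index("rsid")
    )
    merged = gwas.table.merge(alleles, left_on="snp_id", right_index=True, how="inner")
    n_absent = len(alleles) - merged["snp_id"].nunique()

    ambiguous = merged.apply(
        lambda r: frozenset((r["effect_allele"], r["non_effect_allele"])) in STRAND_AMBIGUOUS,
        axis=1,
    )
    aligned = (merged["effect_allele"] == merged["eff_allele"]) & (
        merged["non_effect_allele"] == merged["ref_allele"]
    )
    swapped = (merged["effect_allele"] == merged["ref_allele"]) & (
        merged["non_effect_allele"] == merged["eff_allele"]
    )
    keep = ~ambiguous & (aligned | swapped)
    n_ambiguous = int(ambiguous.sum())
    n_mismatch = int((~ambiguous & ~aligned & ~swapped).sum())
    if n_absent or n_ambiguous or n_mismatch:
        logger.info(
            "allele harmonization: %d model SNPs absent from GWAS, "
            "%d strand-ambiguous dropped, %d allele-mismatched dropped",
            n_absent, n_ambiguous, n_mismatch,
        )

    out = merged.loc[keep].copy()
    flip = swapped.loc[keep]
    out.loc[flip, "z"] = -out.loc[flip, "z"]
    # report in the model's coding
    out["effect_allele"] = out["eff_allele"]
    out["non_effect_allele"] = out["ref_allele"]
    return GwasSummary(out[list(gwas.table.columns)].reset_index(drop=True))


def compute_gene_z(
    gwas: GwasSummary,
    model: PredictionModel,
    cov: SnpCovariance,
    panel: str | None = None,
) -> list[GeneAssociation]:
    """Stage-one propagation: per-gene association z from SNP z-scores.

    ``gwas`` must already be harmonized to the model's allele coding.  SNPs
    missing from the gene's covariance block are excluded with a warning;
    genes with no usable SNP or degenerate predicted variance are omitted.
    """
    z_lookup = gwas.z_by_snp()
    out: list[GeneAssociation] = []
    for gene in model.genes:
        snps = model.snps(gene)
        weights = model.weights(gene)
        in_gwas = [s in z_lookup.index for s in snps]
        snps_avail = [s for s, ok in zip(snps, in_gwas) if ok]
        w_avail = weights[np.asarray(in_gwas, bool)]
        if not snps_avail:
            logger.info("gene %s omitted: no model SNP present in GWAS", gene)
            continue
        try:
            present, gamma = cov.submatrix(snps_avail, gene=gene, panel=panel)
        except KeyError:
            logger.warning("gene %s omitted: no covariance block", gene)
            continue
        if len(present) < len(snps_avail):
            logger.warning(
                "gene %s: %d SNP(s) missing from covariance block, excluded",
                gene, len(snps_avail) - len(present),
            )
        if not present:
            logger.info("gene %s omitted: no SNP with covariance", gene)
            continue
        keep = [snps_avail.index(s) for s in present]
        w = w_avail[keep]
        z = z_lookup.loc[present].to_numpy(float)
        var_g = float(w @ gamma @ w)
        if var_g <= DEGENERATE_VARIANCE:
            logger.info("gene %s omitted: degenerate predicted variance", gene)
            continue
        sigma_g = np.sqrt(var_g)
        sigma_i = np.sqrt(np.diag(gamma))
        z_g = float(np.sum(w * sigma_i * z) / sigma_g)
        out.append(GeneAssociation(gene, z_g, sigma_g, len(present)))
    return out


def predicted_gene_covariance(
    model: PredictionModel,
    cov: SnpCovariance,
    genes: list[str],
    panel: str | None = None,
) -> GeneCovariance:
    """Predicted-expression covariance Gamma^G = W Gamma W^T over ``genes``.

    With a full-panel block the product is computed exactly in one shot.
    Otherwise cross-gene SNP covariances are looked up in any per-gene block
    containing both SNPs and default to zero when the pair never co-occurs.
    """
    if not genes:
        raise ValueError("empty gene list")
    if panel is not None:
        panel_ids, gamma = cov.block(panel)
        index = {s: k for k, s in enumerate(panel_ids)}
        w = np.zeros((len(genes), len(panel_ids)))
        for gi, gene in enumerate(genes):
            for snp, weight in zip(model.snps(gene), model.weights(gene)):
                if snp in index:
                    w[gi, index[snp]] = weight
        return GeneCovariance(list(genes), w @ gamma @ w.T)

    mat = np.zeros((len(genes), len(genes)))
    entries = {g: (model.snps(g), model.weights(g)) for g in genes}
    for i, g in enumerate(genes):
        for j in range(i, len(genes)):
            h = genes[j]
            total = 0.0
            for si, wi in zip(*entries[g]):
                for sj, wj in zip(*entries[h]):
                    value = cov.lookup(si, sj)
                    if value is not None:
                        total += wi * value * wj
            mat[i, j] = mat[j, i] = total
    return GeneCovariance(list(genes), mat)


def compute_component_z(
    gene_assoc: list[GeneAssociation],
    eg_model: EigengeneModel,
    gene_cov: GeneCovariance,
    gene_sds: str = "model",
) -> list[ComponentAssociation]:
    """Stage-two propagation: component z from gene-level associations.

    ``gene_sds`` selects the gene SDs used to convert standardized-scale
    eigengene loadings to raw-scale weights: ``"model"`` uses the SDs stored
    at eigengene fit time (default), ``"unit"`` treats the loadings as
    raw-scale weights directly.  Module genes without an association or
    covariance entry are dropped from the sum (no imputation); modules with
    no usable gene or degenerate variance are omitted.
    """
    if gene_sds not in ("model", "unit"):
        raise ValueError("gene_sds must be 'model' or 'unit'")
    assoc = {a.gene_id: a for a in gene_assoc}
    cov_genes = set(gene_cov.genes)
    out: list[ComponentAssociation] = []
    for module_id in eg_model.module_ids:
        mw = eg_model.modules[module_id]
        usable = [
            (g, w, s)
            for g, w, s in zip(mw.genes, mw.weights, mw.gene_sds)
            if g in assoc and g in cov_genes
        ]
        if not usable:
            logger.warning("module %s omitted: no gene with association", module_id)
            continue
        genes = [g for g, _, _ in usable]
        v = np.array([w for _, w, _ in usable], float)
        if gene_sds == "model":
            v = v / np.array([s for _, _, s in usable], float)
        gamma_g = gene_cov.submatrix(genes)
        var_l = float(v @ gamma_g @ v)
        if var_l <= DEGENERATE_VARIANCE:
            logger.info("module %s omitted: degenerate component variance", module_id)
            continue
        sigma_l = np.sqrt(var_l)
        sigma_g = np.array([assoc[g].sigma for g in genes])
        z_g = np.array([assoc[g].z for g in genes])
        z_l = float(np.sum(v * sigma_g * z_g) / sigma_l)
        out.append(ComponentAssociation(module_id, z_l, sigma_l, len(genes)))
    return out


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm–Sidak step-down familywise-error adjustment.

    Sorted ascending, the k-th smallest p becomes ``1 - (1 - p_(k))^(m-k+1)``,
    a running maximum enforces monotonicity, and values are returned in the
    input order, clipped at 1.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) at p = 1 is benign
        return multipletests(p, method="holm-sidak")[1]


def call_gwas_components(
    assoc: list[ComponentAssociation], alpha: float = 0.05
) -> list[ComponentAssociation]:
    """Flag components whose adjusted two-sided p falls below ``alpha``.

    Adjustment is Holm–Sidak over all components tested together (one family
    per tissue/run).  Returns new ComponentAssociation objects.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not assoc:
        raise ValueError("no component associations to call")
    p_raw = np.array([two_sided_p(a.z) for a in assoc])
    p_adj = np.maximum(holm_sidak_adjust(p_raw), p_raw)
    return [
        ComponentAssociation(
            a.module_id, a.z, a.sigma, a.n_genes_used,
            p_raw=float(pr), p_adjusted=float(pa),
            is_gwas_component=bool(pa < alpha),
        )
        for a, pr, pa in zip(assoc, p_raw, p_adj)
    ]
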