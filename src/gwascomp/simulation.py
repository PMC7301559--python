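"""Synthetic-data generation and the summary-vs-individual consistency harness.

The generator emulates the full input stack: LD-structured genotype dosages
(latent Gaussian AR(1) haplotypes thresholded at each SNP's minor-allele
frequency, so dosages are Hardy–Weinberg), a sparse SNP->gene weight model in
which module co-members share a core of SNPs (inducing within-module
predicted-expression correlation), eigengene loadings fitted on the planted
partition, and a quantitative trait driven by a single eigengene component,

    Y = L_1 + alpha * eps,   SNR = std(L_1) / (std(L_1) + alpha),

so the signal-to-noise ratio plays the role of broad-sense heritability.
``consistency_experiment`` closes the loop: run a per-SNP GWAS on the
simulated trait, propagate the summary statistics through the association
module, and compare against component z-scores computed directly from
individual-level eigengene activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kstest, norm

from . import association, coexpression
from .coexpression import EigengeneModel, ModuleAssignment
from .datatypes import ExpressionMatrix, GwasSummary, PredictionModel, SnpCovariance
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SyntheticSystem",
    "TraitSimulation",
    "ConsistencyReport",
    "SimulationConfig",
    "simulate_genotypes",
    "build_synthetic_system",
    "simulate_trait",
    "null_trait",
    "run_snp_gwas",
    "individual_component_assoc",
    "summary_component_assoc",
    "consistency_experiment",
    "null_calibration_experiment",
]

PANEL_KEY = "__PANEL__"
EFFECT_ALLELE = "A"
OTHER_ALLELE = "G"


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages (SNPs x samples) with generating parameters."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    mafs: np.ndarray
    ld_rho: float
    seed: int

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape mismatch")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if np.any(self.dosages.var(axis=1) == 0):
            raise ValueError("monomorphic SNP in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SyntheticSystem:
    """A complete planted system: genotypes, weights, expression, eigengenes."""

    genotypes: GenotypeMatrix
    model: PredictionModel
    expression: ExpressionMatrix  # predicted expression W @ dosages
    modules: ModuleAssignment
    eigengenes: EigengeneModel
    activities: np.ndarray  # modules x samples, rows follow module_order
    module_order: list[int]
    covariance: SnpCovariance  # per-gene blocks plus PANEL_KEY panel
    seed: int


@dataclass
class TraitSimulation:
    """A simulated quantitative trait; ``snr=None`` marks a null trait."""

    y: np.ndarray
    causal_module_id: int | None
    snr: float | None
    alpha_noise: float
    epsilon: np.ndarray
    seed: int


@dataclass
class ConsistencyReport:
    """Summary-vs-individual comparison for one simulated replicate."""

    snr: float
    seed: int
    module_ids: list[int]
    summary_z: np.ndarray
    individual_z: np.ndarray
    pearson_r: float
    slope: float
    causal_module_id: int
    causal_rank: int  # 1 = largest |summary z|
    ks_stat: float
    ks_p: float  # non-causal summary z vs standard normal


@dataclass
class SimulationConfig:
    """Study conditions for the consistency experiment (desk scale)."""

    n_samples: int = 2000
    n_snps: int = 300
    n_genes: int = 60
    n_modules: int = 12
    genes_per_module: int = 5
    snps_per_gene: int = 5
    shared_fraction: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.3
    snr_list: tuple = (0.10, 0.05, 0.02)
    n_replicates: int = 10


def simulate_genotypes(
    n_samples: int = 2000,
    n_snps: int = 300,
    maf_range: tuple = (0.05, 0.5),
    ld_rho: float = 0.3,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate HWE dosages with AR(1) linkage disequilibrium.

    Two latent Gaussian haplotype fields with lag-1 correlation ``ld_rho``
    along the SNP axis are thresholded at each SNP's MAF quantile and summed,
    giving dosages in {0, 1, 2} with the requested allele frequencies and a
    geometric LD decay.  Monomorphic SNPs are redrawn (without LD) and a
    warning logged.
    """
    if n_samples < 30:
        raise ValueError("n_samples must be >= 30")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    thresholds = norm.ppf(mafs)

    def latent() -> np.ndarray:
        e = rng.standard_normal((n_snps, n_samples))
        z = np.empty_like(e)
        z[0] = e[0]
        scale = np.sqrt(1 - ld_rho**2)
        for j in range(1, n_snps):
            z[j] = ld_rho * z[j - 1] + scale * e[j]
        return z

    dosage = (latent() < thresholds[:, None]).astype(float)
    dosage += latent() < thresholds[:, None]

    for _ in range(20):
        mono = np.flatnonzero(dosage.var(axis=1) == 0)
        if len(mono) == 0:
            break
        logger.warning("redrawing %d monomorphic SNP(s)", len(mono))
        redraw = (rng.standard_normal((len(mono), n_samples)) < thresholds[mono, None]).astype(float)
        redraw += rng.standard_normal((len(mono), n_samples)) < thresholds[mono, None]
        dosage[mono] = redraw
    samples = [f"ind{k:05d}" for k in range(n_samples)]
    snps = [f"rs{k:06d}" for k in range(n_snps)]
    return GenotypeMatrix(samples, snps, dosage, mafs, ld_rho, seed)


def build_synthetic_system(
    genotypes: GenotypeMatrix,
    n_genes: int = 60,
    snps_per_gene: int = 5,
    n_modules: int = 12,
    genes_per_module: int = 5,
    shared_fraction: float = 0.8,
    seed: int = 0,
) -> SyntheticSystem:
    """Plant a sparse weight model and fit eigengenes on predicted expression.

    SNPs are split into contiguous per-module pools.  Each module draws a
    core of ``round(shared_fraction * snps_per_gene)`` SNPs with shared
    weights; member genes add private SNPs from the same pool, so co-members
    have correlated predicted expression while modules stay near-independent.
    Eigengene loadings are fitted on the planted partition; the SNP
    covariance is the in-sample dosage covariance (per-gene blocks plus a
    full panel under ``PANEL_KEY``).
    """
    if n_genes < n_modules * genes_per_module:
        raise ValueError("n_genes must be >= n_modules * genes_per_module")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    n_core = int(round(shared_fraction * snps_per_gene))
    n_private = snps_per_gene - n_core
    n_snps = len(genotypes.snp_ids)
    pool_size = n_snps // n_modules
    if pool_size < snps_per_gene:
        raise ValueError(
            f"infeasible sharing: pool of {pool_size} SNPs per module cannot host "
            f"{snps_per_gene} SNPs per gene"
        )
    rng = np.random.default_rng(seed)
    snp_idx = np.arange(n_snps)

    gene_ids = [f"gene{k:04d}" for k in range(n_genes)]
    labels = np.zeros(n_genes, dtype=int)
    rows = []
    w_dense = np.zeros((n_genes, n_snps))
    gene_cursor = 0
    for m in range(n_modules):
        pool = snp_idx[m * pool_size : (m + 1) * pool_size]
        core = rng.choice(pool, size=n_core, replace=False)
        core_w = rng.normal(size=n_core)
        rest = np.setdiff1d(pool, core)
        for _ in range(genes_per_module):
            gene = gene_ids[gene_cursor]
            labels[gene_cursor] = m + 1
            private = rng.choice(rest, size=n_private, replace=False) if n_private else np.array([], int)
            private_w = rng.normal(size=n_private)
            for si, wv in zip(np.concatenate([core, private]).astype(int),
                              np.concatenate([core_w, private_w])):
                rows.append((gene, genotypes.snp_ids[si], float(wv)))
                w_dense[gene_cursor, si] = wv
            gene_cursor += 1
    # background genes (if any) draw private SNPs anywhere
    while gene_cursor < n_genes:
        gene = gene_ids[gene_cursor]
        chosen = rng.choice(snp_idx, size=snps_per_gene, replace=False)
        for si in chosen:
            wv = rng.normal()
            rows.append((gene, genotypes.snp_ids[si], float(wv)))
            w_dense[gene_cursor, si] = wv
        gene_cursor += 1

    model = PredictionModel(
        pd.DataFrame(rows, columns=["gene", "rsid", "weight"]).assign(
            ref_allele=OTHER_ALLELE, eff_allele=EFFECT_ALLELE
        )
    )
    expression = ExpressionMatrix(gene_ids, list(genotypes.sample_ids), w_dense @ genotypes.dosages)
    modules = ModuleAssignment(gene_ids, labels)
    eigengenes = coexpression.fit_eigengene_weights(expression, modules)
    activities, module_order = coexpression.eigengene_activity(eigengenes, expression)

    gamma = np.cov(genotypes.dosages, ddof=1)
    blocks: dict = {PANEL_KEY: (list(genotypes.snp_ids), gamma)}
    snp_index = {s: k for k, s in enumerate(genotypes.snp_ids)}
    for gene in gene_ids:
        snps = model.snps(gene)
        idx = [snp_index[s] for s in snps]
        blocks[gene] = (snps, gamma[np.ix_(idx, idx)])
    covariance = SnpCovariance(blocks)
    return SyntheticSystem(
        genotypes, model, expression, modules, eigengenes,
        activities, module_order, covariance, seed,
    )


def simulate_trait(system: SyntheticSystem, causal_module: int, snr: float, seed: int = 0) -> TraitSimulation:
    """Trait driven by one eigengene: Y = L_causal + alpha * eps.

    ``alpha`` solves SNR = std(L)/(std(L) + alpha), i.e.
    alpha = std(L) * (1 - snr) / snr; snr=1 gives the noiseless trait.
    """
    if not 0 < snr <= 1:
        raise ValueError("snr must be in (0, 1]; use null_trait for snr=0")
    if causal_module not in system.module_order:
        raise KeyError(f"module {causal_module} not in system")
    l1 = system.activities[system.module_order.index(causal_module)]
    sd = float(l1.std(ddof=1))
    alpha = sd * (1 - snr) / snr
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(l1))
    return TraitSimulation(l1 + alpha * eps, causal_module, snr, alpha, eps, seed)


def null_trait(n_samples: int, seed: int = 0) -> TraitSimulation:
    """Pure-noise trait, independent of all genotypes."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_samples)
    return TraitSimulation(eps.copy(), None, None, 1.0, eps, seed)


def _ols_z(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple-regression (beta, se, z) of y on each row of x."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = xc @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        resvar = np.maximum(syy - beta * sxy, 0.0) / (n - 2)
        se = np.sqrt(resvar / sxx)
        z = beta / se
    return beta, se, z


def run_snp_gwas(genotypes: GenotypeMatrix, trait: TraitSimulation) -> GwasSummary:
    """Per-SNP OLS of the trait on dosage; z = beta/se.

    Effect alleles are emitted in the genotype coding (dosage counts the
    effect allele).  Monomorphic SNPs are dropped with a warning.
    """
    if len(trait.y) != genotypes.n_samples:
        raise ValueError("trait and genotype sample counts differ")
    x = genotypes.dosages
    poly = x.var(axis=1) > 0
    if (~poly).any():
        logger.warning("dropping %d monomorphic SNP(s) from GWAS", int((~poly).sum()))
    beta, se, z = _ols_z(x[poly], trait.y)
    snps = [s for s, ok in zip(genotypes.snp_ids, poly) if ok]
    return GwasSummary(
        pd.DataFrame(
            dict(snp_id=snps, effect_allele=EFFECT_ALLELE,
                 non_effect_allele=OTHER_ALLELE, z=z)
        )
    )


def individual_component_assoc(system: SyntheticSystem, trait: TraitSimulation) -> dict[int, float]:
    """Individual-level benchmark: OLS z of the trait on each eigengene."""
    if len(trait.y) != system.activities.shape[1]:
        raise ValueError("trait and system sample counts differ")
    keep = system.activities.var(axis=1) > 0
    if (~keep).any():
        logger.warning("omitting %d constant component(s)", int((~keep).sum()))
    _, _, z = _ols_z(system.activities[keep], trait.y)
    kept_modules = [m for m, ok in zip(system.module_order, keep) if ok]
    return {m: float(zv) for m, zv in zip(kept_modules, z)}


def summary_component_assoc(
    system: SyntheticSystem, gwas: GwasSummary
) -> list[association.ComponentAssociation]:
    """Propagate a GWAS summary through both stages of the system's models."""
    harmonized = association.harmonize_alleles(gwas, system.model)
    gene_assoc = association.compute_gene_z(harmonized, system.model, system.covariance)
    gene_cov = association.predicted_gene_covariance(
        system.model, system.covariance, list(system.expression.gene_ids), panel=PANEL_KEY
    )
    return association.compute_component_z(gene_assoc, system.eigengenes, gene_cov)


def _replicate_seed(base_seed: int, *idx: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), *map(int, idx)]).generate_state(1)[0] % (2**31 - 1))


def _one_replicate(config: SimulationConfig, snr: float, seed: int) -> ConsistencyReport:
    genotypes = simulate_genotypes(
        config.n_samples, config.n_snps, config.maf_range, config.ld_rho, seed=seed
    )
    system = build_synthetic_system(
        genotypes, config.n_genes, config.snps_per_gene, config.n_modules,
        config.genes_per_module, config.shared_fraction, seed=seed + 1,
    )
    rng = np.random.default_rng(seed + 2)
    causal = int(rng.choice(system.module_order))
    trait = simulate_trait(system, causal, snr, seed=seed + 3)
    gwas = run_snp_gwas(genotypes, trait)
    comp = summary_component_assoc(system, gwas)
    indiv = individual_component_assoc(system, trait)
    ids = [c.module_id for c in comp]
    sz = np.array([c.z for c in comp])
    iz = np.array([indiv[m] for m in ids])
    r = float(np.corrcoef(sz, iz)[0, 1])
    slope = float(np.polyfit(sz, iz, 1)[0])
    order = np.argsort(-np.abs(sz), kind="stable")
    causal_rank = int(np.flatnonzero(np.array(ids)[order] == causal)[0]) + 1
    noncausal = sz[np.array(ids) != causal]
    ks = kstest(noncausal, "norm")
    return ConsistencyReport(
        snr, seed, ids, sz, iz, r, slope, causal, causal_rank,
        float(ks.statistic), float(ks.pvalue),
    )


def consistency_experiment(config: SimulationConfig, seed: int = 1) -> dict[float, list[ConsistencyReport]]:
    """Full summary-vs-individual loop over SNRs and replicates.

    For each SNR in ``config.snr_list`` and each of ``config.n_replicates``
    replicates: simulate genotypes and a planted system, pick a causal
    component at random, simulate the trait, run the per-SNP GWAS, propagate
    the summary statistics through both stages, and compare with
    individual-level eigengene regression z-scores.  Bit-reproducible given
    (config, seed).
    """
    out: dict[float, list[ConsistencyReport]] = {}
    for snr in config.snr_list:
        reports = []
        for rep in range(config.n_replicates):
            rep_seed = _replicate_seed(seed, int(round(snr * 1000)), rep)
            reports.append(_one_replicate(config, snr, rep_seed))
        out[snr] = reports
    return out


def null_calibration_experiment(
    config: SimulationConfig, n_replicates: int = 20, seed: int = 1
) -> tuple[np.ndarray, float, float]:
    """Pooled component z-scores under genotype-independent null traits.

    Returns (pooled z, KS statistic, KS p) against the standard normal;
    under the null the propagated component z-scores should be N(0, 1).
    """
    pooled = []
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, 999, rep)
        genotypes = simulate_genotypes(
            config.n_samples, config.n_snps, config.maf_range, config.ld_rho, seed=rep_seed
        )
        system = build_synthetic_system(
            genotypes, config.n_genes, config.snps_per_gene, config.n_modules,
            config.genes_per_module, config.shared_fraction, seed=rep_seed + 1,
        )
        trait = null_trait(config.n_samples, seed=rep_seed + 2)
        gwas = run_snp_gwas(genotypes, trait)
        comp = summary_component_assoc(system, gwas)
        pooled.extend(c.z for c in comp)
    pooled_arr = np.array(pooled)
    ks = kstest(pooled_arr, "norm")
    return pooled_arr, float(ks.statistic), float(ks.pvalue)
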