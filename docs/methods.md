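# Methods

## The two-stage propagation model

The package treats gene-level and component-level association inference as
the same operation applied twice. For any linear combination U = Σ_k c_k V_k
of variables V with known covariance C, the Wald z-score of U against a trait
can be approximated from the z-scores of the V_k:

    Z_U ≈ Σ_k c_k (σ_k / σ_U) Z_k,     σ_U² = cᵀ C c.

Stage one takes V = SNP dosages, c = the pre-trained expression-model weights
W_g, C = the LD reference covariance Γ (per-gene blocks assembled from
`GENE RSID1 RSID2 VALUE` records). Stage two takes V = predicted gene
expression, c = the eigengene loadings, C = the propagated covariance
Γ^G = W Γ Wᵀ. Because both stages are linear, composing them is exactly
equivalent to a single propagation with combined weights — a property the
test suite checks to 1e-8 ("stacking consistency") and that the simulation
harness verifies empirically against individual-level regression.

### Standardized vs raw loadings

Eigengene loadings R_l are fitted on *standardized* gene profiles (each gene
centered, unit variance), as is usual for module eigengenes. The eigengene is
therefore a combination of raw predicted expression with weights
v_lg = R_lg / sd_g, and stage two uses v, with the per-gene SDs recorded in
the eigengene model at fit time. With unit SDs this reduces to using R
directly, which is how the worked unit examples are phrased. The z-score is
invariant under positive rescaling of a whole loading row (σ_l absorbs the
scale), so the choice only matters when gene SDs differ within a module.
`compute_component_z(gene_sds="unit")` switches to treating R as raw-scale
weights; externally supplied (e.g. measured-expression) SDs can be injected
by editing the model's `gene_sds`. σ_g and σ_l always come from the
genotype-propagated covariance W Γ Wᵀ, keeping both stages on the same
reference; the per-gene SD enters only through the loading conversion.

### Missing genes, degenerate variances

Genes in a module without a prediction model, without GWAS SNPs, or without
covariance entries are dropped from the stage-two sum *and* from σ_l — no
imputation and no renormalization, so the tested component is exactly the
combination of the genes that contributed. Entities with propagated variance
≤ 1e-12 are omitted with a logged reason rather than producing NaNs.
Cross-gene SNP covariances that never co-occur in any covariance block
default to zero; a full-panel covariance block (the `panel=` argument)
overrides this with exact cross terms and is what the simulation uses.

### Allele harmonization

GWAS effect alleles are aligned to the prediction model's coding before
stage one: matching pairs keep z, swapped effect/non-effect pairs negate z,
and strand-ambiguous (A/T, C/G) or mismatched pairs are dropped with logged
counts. SNP identity is the rsid string throughout; no genomic coordinates
are used.

## Module detection

`detect_modules` follows the weighted-correlation-network recipe:
row-standardize, Pearson correlation, unsigned adjacency |cor|^β,
topological-overlap similarity, average-linkage clustering of (1 − TOM), and
a *static* cut of the dendrogram at a fixed height. Clusters below the
minimum size are left unassigned (module id 0). Defaults: β = 6 (the common
unsigned-network default), cut height 0.98, minimum module size 5 (chosen to
admit small modules). The static cut — rather than the dynamic hybrid tree
cut — keeps the stage fully deterministic and dependency-free; externally
computed module tables can always be supplied through the module-weight TSV
instead. Module ids are assigned by decreasing size with ties broken by the
first member's row index, making labels deterministic and
permutation-equivariant.

Eigengene loadings are the leading eigenvector of the module's gene
correlation matrix, unit-normalized, with the sign fixed so the eigengene
correlates non-negatively with the module's mean standardized profile (first
nonzero loading positive on exact ties). The eigengene's variance then
equals the leading eigenvalue, which the tests verify to 1e-8.

## Enrichment and target ranking

The 2×2 overrepresentation engine reports the contingency cells over an
explicit background, the enrichment odds ratio OR = (a/b)/(c/d), the
hypergeometric point probability of the observed table, and the one-sided
upper-tail p (the probability of an overlap ≥ a at fixed margins) — the tail
rather than the point probability is the reported significance since the
hypothesis is OR > 1. When b or c is zero the OR is reported as +infinity
rather than continuity-corrected: the exact test needs no correction and a
corrected OR would be an invented number. Driver ranking tests every network
node whose *descendant* set (all nodes reachable by directed paths; a
direct-children-only switch exists) intersects the background
B = model genes ∩ network nodes, Holm–Šidák-adjusts across all candidates
tested in the run, and requires adjusted p < α together with OR > 1.
Candidates need not belong to the component themselves.

## Signatures

The characteristic direction is v ∝ Σ̂⁻¹(μ₁ − μ₀) with the pooled
within-class covariance shrunk toward a scaled identity,
Σ̂ = (1 − s)·S + s·(tr S / p)·I. The default shrinkage s = 0.5 exists
because expression data have p ≫ n and the raw pooled covariance is
singular; s = 0 demands a nonsingular S and fails loudly otherwise. This is
a deliberate simplification of the original characteristic-direction
derivation (no PCA-subspace preprocessing). Cosine similarities are computed
on the intersected gene universe after re-normalization, and are
standardized against an empirical null of 10,000 cosine distances per target
signature. The null can be resampled from a user-supplied signature pool
(closer to an empirical biological null) or drawn as isotropic random unit
vectors, for which the cosine has mean 0 and SD ≈ 1/√p; both modes are
seeded. Hit calling standardizes |cosine|, converts to two-sided normal
p-values, Holm–Šidák-adjusts across each perturbation's (perturbation,
disease) pairs, and calls a hit when any pair survives at α = 0.05 — with
adjustment disabled this reduces to the bare |normalized| > 1.96 rule.

## The synthetic-data generator

`simulate_genotypes` draws two latent Gaussian haplotype fields with AR(1)
lag correlation ρ along the SNP axis, thresholds each at the SNP's MAF
quantile and sums them, giving Hardy–Weinberg dosages in {0, 1, 2} with
geometrically decaying LD. Defaults: MAF ~ Uniform(0.05, 0.5), ρ = 0.3 — a
moderate, common-variant regime. `build_synthetic_system` splits SNPs into
contiguous per-module pools; each module's genes share a core of 80% of
their SNPs (with shared weights), inducing within-module predicted-expression
correlation while modules stay near-independent. Eigengene loadings are
fitted on the planted partition and the SNP covariance handed to the
association stage is the in-sample dosage covariance, deliberately
eliminating reference-mismatch noise so the consistency experiment isolates
the propagation identity itself.

Traits are Y = L_causal + α·ε with α = std(L)·(1 − SNR)/SNR, so
SNR = std(L)/(std(L) + α) holds by construction and plays the role of
broad-sense heritability; the GWAS engine is per-SNP OLS with
normal-approximation z (quantitative traits only, no covariates).

The default experiment scale is 2,000 samples, 300 SNPs, 60 genes in 12
modules of 5, 10 replicates per SNR at SNR ∈ {0.10, 0.05, 0.02} — a
desk-scale configuration that keeps the full three-SNR experiment under a
minute while leaving ample power for the consistency and detection checks;
population-scale settings are reachable through `SimulationConfig`. All
randomness flows from explicit seeds (replicate streams are derived from the
base seed via `numpy.random.SeedSequence`), making every experiment
bit-reproducible.

### What the generator does not emulate

Real LD is block-structured and long-ranged, not AR(1); allele frequencies
are not uniform; expression prediction weights are estimated (noisy), not
known; real co-expression modules overlap, drift across tissues and contain
genes with no eQTL signal; and measured expression adds biological and
technical noise absent from the noiseless linear map T = W·X used here.
Passing the consistency checks therefore demonstrates the correctness of the
propagation mathematics and its implementation — not that the method's
real-data gene lists are biologically right, which depends on the quality of
the supplied weights, covariance, modules and network.

## Numerical conventions

- Variances and correlations use ddof = 1 throughout (matching the
  eigenvalue identities tested).
- Two-sided p-values from the standard normal tail, floored at the smallest
  positive double so they stay in (0, 1].
- Holm–Šidák: sorted ascending, adjusted_(k) = 1 − (1 − p_(k))^(m − k + 1),
  running maximum, input order restored, clipped at 1 (delegated to
  statsmodels; tested against the hand-computed step-down).
- Covariance blocks must be symmetric to 1e-10, PSD to −1e-8 on the smallest
  eigenvalue, with non-negative diagonals.
- Tie-breaks: module labels by (size desc, first row index); target ranks by
  (p asc, OR desc, candidate id); eigengene signs per the mean-profile rule.
- Degenerate inputs (constant genes, empty modules, monomorphic SNPs,
  singular covariances) raise typed errors or drop with logged counts —
  never silent NaNs.

## Known limitations

- The static dendrogram cut can merge adjacent modules that the dynamic
  hybrid cut would split; supply external module tables when that matters.
- Zero-filled cross-gene covariance understates σ_l when module genes share
  LD across covariance blocks; provide a panel block where possible.
- The characteristic direction omits the PCA-subspace step of the original
  derivation; directions in very high dimensions lean on the shrinkage
  parameter.
- Binary traits, covariate adjustment, and estimation of prediction weights
  from training data are out of scope; weights, covariance and networks are
  inputs.
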