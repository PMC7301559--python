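import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwascomp import association as assoc
from gwascomp.coexpression import EigengeneModel, ModuleWeights
from gwascomp.datatypes import GwasSummary, PredictionModel, SnpCovariance


def gwas_from(rows):
    return GwasSummary(pd.DataFrame(rows, columns=["snp_id", "effect_allele", "non_effect_allele", "z"]))


def model_from(rows):
    return PredictionModel(
        pd.DataFrame(rows, columns=["gene", "rsid", "weight", "ref_allele", "eff_allele"])
    )


class TestHarmonize:
    def test_alignment_swap_and_drops(self):
        gwas = gwas_from([
            ("rs1", "A", "G", 2.5),   # aligned
            ("rs2", "G", "A", 2.5),   # swapped -> negate
            ("rs3", "A", "T", 1.0),   # strand-ambiguous -> drop
            ("rs4", "C", "A", 1.0),   # allele mismatch -> drop
        ])
        model = model_from([
            ("G1", "rs1", 1.0, "G", "A"),
            ("G1", "rs2", 1.0, "G", "A"),
            ("G1", "rs3", 1.0, "G", "A"),
            ("G1", "rs4", 1.0, "G", "A"),
            ("G1", "rs5", 1.0, "G", "A"),  # absent from gwas -> drop
        ])
        out = assoc.harmonize_alleles(gwas, model)
        z = out.z_by_snp()
        assert set(z.index) == {"rs1", "rs2"}
        assert z["rs1"] == 2.5 and z["rs2"] == -2.5

    def test_output_uses_model_allele_coding(self):
        gwas = gwas_from([("rs2", "G", "A", 1.0)])
        model = model_from([("G1", "rs2", 1.0, "G", "A")])
        out = assoc.harmonize_alleles(gwas, model)
        row = out.table.iloc[0]
        assert row["effect_allele"] == "A" and row["non_effect_allele"] == "G"


class TestGeneZ:
    def test_single_snp_identity(self):
        gwas = gwas_from([("rs1", "A", "G", 2.0)])
        model = model_from([("G1", "rs1", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1"], np.array([[1.0]]))})
        (ga,) = assoc.compute_gene_z(gwas, model, cov)
        assert ga.z == pytest.approx(2.0) and ga.sigma == pytest.approx(1.0)
        assert ga.n_snps_used == 1

    def test_two_independent_snps(self):
        gwas = gwas_from([("rs1", "A", "G", 2.0), ("rs2", "A", "G", 2.0)])
        model = model_from([("G1", "rs1", 1.0, "G", "A"), ("G1", "rs2", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1", "rs2"], np.eye(2))})
        (ga,) = assoc.compute_gene_z(gwas, model, cov)
        assert ga.z == pytest.approx(4 / np.sqrt(2))
        assert ga.sigma == pytest.approx(np.sqrt(2))

    def test_zero_snp_z_gives_zero(self):
        gwas = gwas_from([("rs1", "A", "G", 0.0), ("rs2", "A", "G", 0.0)])
        model = model_from([("G1", "rs1", 0.7, "G", "A"), ("G1", "rs2", -0.3, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1", "rs2"], np.array([[1.0, 0.4], [0.4, 2.0]]))})
        (ga,) = assoc.compute_gene_z(gwas, model, cov)
        assert ga.z == 0.0

    def test_snp_missing_from_block_excluded(self, caplog):
        gwas = gwas_from([("rs1", "A", "G", 2.0), ("rs2", "A", "G", 5.0)])
        model = model_from([("G1", "rs1", 1.0, "G", "A"), ("G1", "rs2", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1"], np.array([[1.0]]))})
        with caplog.at_level("WARNING"):
            (ga,) = assoc.compute_gene_z(gwas, model, cov)
        assert ga.n_snps_used == 1 and ga.z == pytest.approx(2.0)
        assert "missing from covariance" in caplog.text

    def test_degenerate_variance_gene_omitted(self):
        gwas = gwas_from([("rs1", "A", "G", 2.0)])
        model = model_from([("G1", "rs1", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1"], np.array([[0.0]]))})
        assert assoc.compute_gene_z(gwas, model, cov) == []


class TestGeneCovariance:
    def test_disjoint_snps_zero_cross_term(self):
        model = model_from([("G1", "rs1", 1.0, "G", "A"), ("G2", "rs2", 1.0, "G", "A")])
        cov = SnpCovariance({
            "G1": (["rs1"], np.array([[1.0]])),
            "G2": (["rs2"], np.array([[1.0]])),
        })
        gc = assoc.predicted_gene_covariance(model, cov, ["G1", "G2"])
        assert np.allclose(gc.matrix, np.eye(2))

    def test_shared_variant_perfect_covariance(self):
        model = model_from([("G1", "rs1", 1.0, "G", "A"), ("G2", "rs1", 1.0, "G", "A")])
        cov = SnpCovariance({
            "G1": (["rs1"], np.array([[1.0]])),
            "G2": (["rs1"], np.array([[1.0]])),
        })
        gc = assoc.predicted_gene_covariance(model, cov, ["G1", "G2"])
        assert np.allclose(gc.matrix, np.ones((2, 2)))

    def test_shared_pair_cross_covariance(self):
        block = (["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        model = model_from([("G1", "rs1", 1.0, "G", "A"), ("G2", "rs2", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": block, "G2": block})
        gc = assoc.predicted_gene_covariance(model, cov, ["G1", "G2"])
        assert gc.matrix[0, 1] == pytest.approx(0.5)

    def test_panel_path_matches_blockwise_path(self):
        rng = np.random.default_rng(8)
        raw = rng.standard_normal((6, 4))
        gamma = raw @ raw.T / 4
        snps = [f"rs{i}" for i in range(6)]
        model = model_from(
            [("G1", s, w, "G", "A") for s, w in zip(snps[:3], [0.5, -1.0, 2.0])]
            + [("G2", s, w, "G", "A") for s, w in zip(snps[2:], [1.0, 0.3, -0.7, 0.2])]
        )
        shared = (snps, gamma)  # every pair co-occurs in one big block
        cov = SnpCovariance({"G1": shared, "G2": shared, "PANEL": shared})
        via_blocks = assoc.predicted_gene_covariance(model, cov, ["G1", "G2"])
        via_panel = assoc.predicted_gene_covariance(model, cov, ["G1", "G2"], panel="PANEL")
        assert np.allclose(via_blocks.matrix, via_panel.matrix, atol=1e-12)

    def test_empty_gene_list_rejected(self):
        model = model_from([("G1", "rs1", 1.0, "G", "A")])
        cov = SnpCovariance({"G1": (["rs1"], np.array([[1.0]]))})
        with pytest.raises(ValueError):
            assoc.predicted_gene_covariance(model, cov, [])


def make_component_inputs(weights, gene_cov, z_values, sigmas=None, sds=None):
    genes = [f"G{i}" for i in range(len(weights))]
    sigmas = sigmas if sigmas is not None else np.ones(len(genes))
    sds = sds if sds is not None else np.ones(len(genes))
    gene_assoc = [
        assoc.GeneAssociation(g, z, s, 1) for g, z, s in zip(genes, z_values, sigmas)
    ]
    model = EigengeneModel({1: ModuleWeights(genes, np.asarray(weights, float), np.asarray(sds, float))})
    gc = assoc.GeneCovariance(genes, np.asarray(gene_cov, float))
    return gene_assoc, model, gc


class TestComponentZ:
    def test_single_gene_identity(self):
        ga, model, gc = make_component_inputs([1.0], [[1.0]], [2.3])
        (ca,) = assoc.compute_component_z(ga, model, gc)
        assert ca.z == pytest.approx(2.3) and ca.sigma == pytest.approx(1.0)

    def test_two_independent_genes(self):
        w = np.array([1.0, 1.0]) / np.sqrt(2)
        ga, model, gc = make_component_inputs(w, np.eye(2), [1.7, 1.7])
        (ca,) = assoc.compute_component_z(ga, model, gc)
        assert ca.z == pytest.approx(1.7 * np.sqrt(2))

    def test_perfectly_correlated_genes(self):
        w = np.array([1.0, 1.0]) / np.sqrt(2)
        ga, model, gc = make_component_inputs(w, np.ones((2, 2)), [1.7, 1.7])
        (ca,) = assoc.compute_component_z(ga, model, gc)
        assert ca.z == pytest.approx(1.7)

    def test_scale_invariance_of_weight_row(self):
        rng = np.random.default_rng(9)
        raw = rng.standard_normal((3, 5))
        gamma = raw @ raw.T / 5
        w = rng.standard_normal(3)
        z = rng.standard_normal(3)
        sigmas = np.sqrt(np.diag(gamma))
        ga, model, gc = make_component_inputs(w, gamma, z, sigmas=sigmas)
        (base,) = assoc.compute_component_z(ga, model, gc)
        for c in (0.1, 3.0, 1e4):
            model_scaled = EigengeneModel(
                {1: ModuleWeights(model.modules[1].genes, w * c, model.modules[1].gene_sds)}
            )
            (scaled,) = assoc.compute_component_z(ga, model_scaled, gc)
            assert scaled.z == pytest.approx(base.z, abs=1e-10)
            assert scaled.sigma == pytest.approx(base.sigma * c)

    def test_missing_genes_dropped_from_sum(self):
        w = np.array([1.0, 1.0]) / np.sqrt(2)
        genes = ["G0", "G1"]
        ga = [assoc.GeneAssociation("G0", 2.0, 1.0, 1)]  # G1 has no association
        model = EigengeneModel({1: ModuleWeights(genes, w, np.ones(2))})
        gc = assoc.GeneCovariance(genes, np.eye(2))
        (ca,) = assoc.compute_component_z(ga, model, gc)
        assert ca.n_genes_used == 1 and ca.z == pytest.approx(2.0)

    def test_empty_module_omitted(self, caplog):
        ga = [assoc.GeneAssociation("GX", 1.0, 1.0, 1)]
        model = EigengeneModel({1: ModuleWeights(["G0"], np.array([1.0]), np.array([1.0]))})
        gc = assoc.GeneCovariance(["G0"], np.eye(1))
        with caplog.at_level("WARNING"):
            assert assoc.compute_component_z(ga, model, gc) == []
        assert "omitted" in caplog.text


class TestStackingConsistency:
    def test_two_stage_equals_single_step(self):
        """Composing SNP->gene and gene->component propagation equals direct
        SNP->component propagation with combined weights (R W) and SNP
        covariance, when every gene is available."""
        rng = np.random.default_rng(10)
        n_snps, n_genes = 8, 4
        raw = rng.standard_normal((n_snps, 20))
        gamma = raw @ raw.T / 20
        w = rng.standard_normal((n_genes, n_snps))
        r = rng.standard_normal(n_genes)
        z_snp = rng.standard_normal(n_snps)
        snps = [f"rs{i}" for i in range(n_snps)]
        genes = [f"G{i}" for i in range(n_genes)]

        gwas = gwas_from([(s, "A", "G", z) for s, z in zip(snps, z_snp)])
        model = model_from(
            [(g, s, w[gi, si], "G", "A") for gi, g in enumerate(genes) for si, s in enumerate(snps)]
        )
        shared = (snps, gamma)
        cov = SnpCovariance({**{g: shared for g in genes}, "PANEL": shared})

        gene_assoc = assoc.compute_gene_z(gwas, model, cov)
        gc = assoc.predicted_gene_covariance(model, cov, genes, panel="PANEL")
        sds = rng.uniform(0.5, 2.0, n_genes)
        eg = EigengeneModel({1: ModuleWeights(genes, r, sds)})
        (two_stage,) = assoc.compute_component_z(gene_assoc, eg, gc)

        combined = (r / sds) @ w  # raw-scale component weights over SNPs
        sigma_l = np.sqrt(combined @ gamma @ combined)
        sigma_i = np.sqrt(np.diag(gamma))
        direct = float(np.sum(combined * sigma_i * z_snp) / sigma_l)
        assert two_stage.z == pytest.approx(direct, abs=1e-8)


class TestHolmSidak:
    def test_hand_computed_stepdown(self):
        adjusted = assoc.holm_sidak_adjust([0.01, 0.04])
        assert adjusted[0] == pytest.approx(1 - 0.99**2, abs=1e-12)
        assert adjusted[1] == pytest.approx(0.04, abs=1e-12)

    def test_single_test_unchanged(self):
        assert assoc.holm_sidak_adjust([0.03])[0] == pytest.approx(0.03)

    def test_ties_equal_and_monotone(self):
        adjusted = assoc.holm_sidak_adjust([0.5, 0.5, 0.5])
        assert np.all(adjusted == adjusted[0]) and np.all(adjusted >= 0.5)

    def test_domain_validation(self):
        for bad in ([0.0], [1.5], [-0.1], [np.nan]):
            with pytest.raises(ValueError):
                assoc.holm_sidak_adjust(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_and_order_free(self, p):
        adjusted = assoc.holm_sidak_adjust(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-15)
        assert np.all(adjusted <= 1.0)
        # adjustment commutes with permutation
        perm = np.argsort(p, kind="stable")[::-1]
        again = assoc.holm_sidak_adjust(np.asarray(p)[perm])
        assert np.allclose(again, adjusted[perm])


class TestCallComponents:
    def comp(self, z_list):
        return [assoc.ComponentAssociation(i + 1, z, 1.0, 1) for i, z in enumerate(z_list)]

    def test_zero_z_never_significant(self):
        (c,) = assoc.call_gwas_components(self.comp([0.0]))
        assert c.p_raw == pytest.approx(1.0) and not c.is_gwas_component

    def test_boundary_z(self):
        # the two-sided 5% critical value is z = Phi^-1(0.975) = 1.959964
        (below,) = assoc.call_gwas_components(self.comp([1.9599]), alpha=0.05)
        assert below.p_raw == pytest.approx(0.05, abs=1e-4)
        assert not below.is_gwas_component
        (above,) = assoc.call_gwas_components(self.comp([1.9601]), alpha=0.05)
        assert above.is_gwas_component

    def test_strong_signals_all_significant_after_correction(self):
        out = assoc.call_gwas_components(self.comp([5.0] * 100), alpha=0.05)
        assert all(c.is_gwas_component for c in out)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(11)
        out = assoc.call_gwas_components(self.comp(rng.standard_normal(30)))
        assert all(c.p_adjusted >= c.p_raw for c in out)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            assoc.call_gwas_components(self.comp([1.0]), alpha=1.5)
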