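import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapblocks import (
    PanelError,
    enumerate_haplotypes,
    haplotype_gwas,
    loiselle_kinship,
    marker_r2,
    mlm_fit,
    p3d_null,
    pca_covariates,
    significance_rule,
    simulate_panel,
    simulate_phenotypes,
    snp_gwas,
    wheat_like_scenario,
)
from hapblocks.association import _weighted_rss
from hapblocks.simulate import planted_blocks

from conftest import make_panel


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "n, threshold, neglog",
        [
            (4434, 2.3e-4, 3.65),
            (847, 1.2e-3, 2.93),
            (100, 1.0e-2, 2.0),
        ],
    )
    def test_printed_threshold_pairs(self, n, threshold, neglog):
        rule = significance_rule(n)
        assert rule.threshold == pytest.approx(threshold, rel=1e-9)
        assert rule.neglog10 == pytest.approx(neglog)

    def test_rule_membership(self):
        rule = significance_rule(847)
        assert rule.passes(1e-4) and not rule.passes(5e-3)


class TestMarkerR2:
    def test_identical_group_means_give_zero(self):
        assert marker_r2([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"]) == 0.0

    def test_hand_worked_anova(self):
        # groups means 0 and 1, grand mean 0.5: SSA = 1, SST = 5 -> 0.2
        y = [-1.0, 1.0, 0.0, 2.0]
        assert marker_r2(y, ["a", "a", "b", "b"]) == pytest.approx(0.2)

    def test_bounded_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.normal(size=30)
            g = rng.integers(0, 3, size=30)
            assert 0.0 <= marker_r2(y, g) <= 1.0


def _full_reml_pvalue(y, x0, marker, kinship):
    """Independent slow route: re-estimate the variance ratio per marker
    (full REML with the marker in the model), then F-test at that ratio."""
    m = marker[:, None]
    x_full = np.column_stack([x0, m])
    ctx = p3d_null(y, x_full[:, 1:], kinship, [str(i) for i in range(len(y))])
    w = ctx.weights
    u = ctx.eigvecs
    rss1, _ = _weighted_rss(u.T @ x_full, u.T @ y, w)
    rss0, _ = _weighted_rss(u.T @ x0, u.T @ y, w)
    df2 = len(y) - x_full.shape[1]
    f = (rss0 - rss1) / (rss1 / df2)
    return float(stats.f.sf(f, 1, df2))


class TestMlmFit:
    def _structured_data(self, seed=0, n=80, m=40):
        rng = np.random.default_rng(seed)
        config = wheat_like_scenario(seed, snps_per_chrom=m, n_landrace=n // 2, n_modern=n // 2)
        panel, _, truth = simulate_panel(config)
        pheno, _ = simulate_phenotypes(panel, truth, config)
        y = (
            pheno[pheno["environment"] == "02LY"]
            .set_index("line")["value"]
            .reindex(list(panel.line_ids))
            .to_numpy()
        )
        return panel, y

    def test_identity_kinship_reduces_to_ols_f_test(self):
        rng = np.random.default_rng(1)
        n = 60
        y = rng.normal(size=n)
        marker = rng.integers(0, 2, size=n).astype(float)
        ctx = p3d_null(y, None, np.eye(n), [str(i) for i in range(n)])
        fit = mlm_fit(ctx, marker)
        # independent route: ordinary least squares F-test via linregress
        lr = stats.linregress(marker, y)
        assert fit.p_value == pytest.approx(lr.pvalue, rel=1e-6)
        assert fit.f_stat == pytest.approx(lr.rvalue**2 / (1 - lr.rvalue**2) * (n - 2), rel=1e-6)

    def test_zero_variance_phenotype_rejected(self):
        with pytest.raises(PanelError):
            p3d_null(np.ones(10), None, np.eye(10), [str(i) for i in range(10)])

    def test_marker_missing_lines_handled_by_omission(self):
        rng = np.random.default_rng(2)
        n = 50
        y = rng.normal(size=n)
        marker = rng.integers(0, 2, size=n).astype(float)
        marker[:5] = np.nan
        ctx = p3d_null(y, None, np.eye(n), [str(i) for i in range(n)])
        fit = mlm_fit(ctx, marker)
        lr = stats.linregress(marker[5:], y[5:])
        assert fit.p_value == pytest.approx(lr.pvalue, rel=1e-6)

    def test_p3d_close_to_per_marker_reml(self):
        panel, y = self._structured_data(seed=3)
        kin = loiselle_kinship(panel).values
        ctx = p3d_null(y, None, kin, list(panel.line_ids))
        x0 = np.ones((len(y), 1))
        dosages = panel.haploid_calls()
        tested = 0
        for j in range(panel.n_snps):
            d = dosages[:, j]
            if np.isnan(d).any() or d.std() == 0 or min(d.mean(), 1 - d.mean()) < 0.1:
                continue
            p_fast = mlm_fit(ctx, d).p_value
            p_full = _full_reml_pvalue(y, x0, d, kin)
            assert abs(math.log10(p_fast) - math.log10(p_full)) <= 0.2
            tested += 1
            if tested == 50:
                break
        assert tested >= 30


class TestSnpGwas:
    @pytest.fixture(scope="class")
    def gwas_inputs(self):
        config = wheat_like_scenario(19, snps_per_chrom=30, n_landrace=70, n_modern=50)
        panel, _, truth = simulate_panel(config)
        pheno, _ = simulate_phenotypes(panel, truth, config)
        y = pheno[pheno["environment"] == "02LY"].set_index("line")["value"]
        kin = loiselle_kinship(panel)
        q = pca_covariates(panel, 1)
        return panel, y, q, kin

    def test_monomorphic_and_rare_markers_excluded_from_n(self, gwas_inputs):
        panel, y, q, kin = gwas_inputs
        result, rule = snp_gwas(panel, y, q, kin, maf=0.05)
        assert rule.n_markers == len(result)
        mafs = panel.minor_allele_frequency()
        eligible = np.sum(np.nan_to_num(mafs, nan=-1) >= 0.05)
        assert len(result) <= eligible

    def test_allele_swap_flips_effect_sign_not_p(self, gwas_inputs):
        panel, y, q, kin = gwas_inputs
        result, _ = snp_gwas(panel, y, q, kin)
        snp = result.iloc[0]["marker"]
        j = panel.snp_index(snp)
        flipped = panel.calls.copy()
        col = flipped[:, j]
        homo = (col == 0) | (col == 1)
        col[homo] = 1 - col[homo]
        from hapblocks import GenotypePanel

        panel2 = GenotypePanel(panel.line_ids, panel.snp_ids, flipped, panel.genetic_map)
        result2, _ = snp_gwas(panel2, y, q, kin)
        row1 = result[result["marker"] == snp].iloc[0]
        row2 = result2[result2["marker"] == snp].iloc[0]
        assert row2["effect"] == pytest.approx(-row1["effect"], rel=1e-6)
        assert row2["p_value"] == pytest.approx(row1["p_value"], rel=1e-6)


class TestHaplotypeGwas:
    def test_two_haplotype_block_equals_tag_snp_test(self):
        # block with exactly two haplotypes differing at one SNP: the block
        # F-test must equal the tag-SNP test (F = t^2 equivalence)
        rng = np.random.default_rng(6)
        n = 80
        tag = rng.integers(0, 2, n).astype(np.int8)
        other = np.zeros(n, np.int8)
        noise_snp = rng.integers(0, 2, n).astype(np.int8)
        panel = make_panel(np.column_stack([tag, other, noise_snp]))
        y = pd.Series(rng.normal(size=n) + 0.8 * tag, index=[f"L{i+1}" for i in range(n)])
        from hapblocks.blocks import Block

        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        haps = enumerate_haplotypes(panel, [block])
        hres, _ = haplotype_gwas(haps, [block], y, panel)
        sres, _ = snp_gwas(panel, y, maf=0.0)
        p_block = hres.iloc[0]["p_value"]
        p_snp = sres[sres["marker"] == "s1"].iloc[0]["p_value"]
        assert p_block == pytest.approx(p_snp, rel=1e-6)

    def test_rare_haplotypes_pooled_into_other(self):
        rng = np.random.default_rng(9)
        n = 100
        # three classes: common 00 and 11, rare 01 (2 lines -> pooled)
        rows = [[0, 0]] * 58 + [[1, 1]] * 40 + [[0, 1]] * 2
        panel = make_panel(np.array(rows, np.int8))
        from hapblocks.blocks import Block

        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        haps = enumerate_haplotypes(panel, [block])
        y = pd.Series(rng.normal(size=n), index=[f"L{i+1}" for i in range(n)])
        hres, _ = haplotype_gwas(haps, [block], y, panel, rare_freq=0.05)
        assert hres.iloc[0]["n_classes"] == 3  # 2 common + pooled 'other'
        assert "other:" in hres.iloc[0]["effects"]

    def test_block_with_single_class_skipped(self):
        rng = np.random.default_rng(10)
        rows = [[0, 0]] * 97 + [[1, 1]] * 3  # second class below block MAF
        panel = make_panel(np.array(rows, np.int8))
        from hapblocks.blocks import Block

        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        haps = enumerate_haplotypes(panel, [block])
        y = pd.Series(rng.normal(size=100), index=[f"L{i+1}" for i in range(100)])
        with pytest.raises(PanelError, match="MAF"):
            haplotype_gwas(haps, [block], y, panel, maf=0.05)

    def test_favorable_haplotype_follows_trait_orientation(self):
        rng = np.random.default_rng(12)
        n = 120
        classes = rng.integers(0, 2, n).astype(np.int8)
        panel = make_panel(np.column_stack([classes, classes]))
        y = pd.Series(
            rng.normal(size=n) + 2.0 * classes, index=[f"L{i+1}" for i in range(n)]
        )
        from hapblocks.blocks import Block

        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        haps = enumerate_haplotypes(panel, [block])
        up, _ = haplotype_gwas(haps, [block], y, panel, higher_is_favorable=True)
        down, _ = haplotype_gwas(haps, [block], y, panel, higher_is_favorable=False)
        assert up.iloc[0]["favorable"] != down.iloc[0]["favorable"]

    def test_permuted_phenotypes_break_planted_association(self):
        config = wheat_like_scenario(
            24,
            snps_per_chrom=40,
            n_landrace=80,
            n_modern=70,
            qtls=(__import__("hapblocks").QtlPlan("block", "1A", 0, 1, None, 5.0),),
        )
        panel, _, truth = simulate_panel(config)
        pheno, _ = simulate_phenotypes(panel, truth, config)
        y = pheno[pheno["environment"] == "02LY"].set_index("line")["value"]
        blocks = planted_blocks(truth, panel)
        haps = enumerate_haplotypes(panel, blocks)
        causal = blocks[0].block_id
        hres, rule = haplotype_gwas(haps, blocks, y, panel)
        p_real = hres.set_index("marker").loc[causal, "p_value"]
        assert p_real < rule.threshold
        rng = np.random.default_rng(1)
        p_perm = []
        for _ in range(8):
            perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            pres, _ = haplotype_gwas(haps, blocks, perm, panel)
            p_perm.append(pres.set_index("marker").loc[causal, "p_value"])
        assert all(p > p_real for p in p_perm)
        assert np.median(p_perm) > 0.05
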