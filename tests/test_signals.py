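import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import annofine as af
from annofine.signals import CollinearityError, locus_variants


def _leads(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "pvalue"]
    )


class TestDefineLoci:
    def test_overlapping_windows_merge(self):
        leads = _leads([("a", "1", 1_000_000, 1e-9), ("b", "1", 1_600_000, 1e-9)])
        loci = af.define_loci(leads)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (500_000, 2_100_000)
        assert loci[0].lead_ids == ["a", "b"]

    def test_distant_leads_stay_separate(self):
        leads = _leads([("a", "1", 1_000_000, 1e-9), ("b", "1", 2_200_000, 1e-9)])
        loci = af.define_loci(leads)
        assert len(loci) == 2

    def test_start_clipped_at_one(self):
        loci = af.define_loci(_leads([("a", "1", 200_000, 1e-9)]))
        assert loci[0].start == 1 and loci[0].end == 700_000

    def test_empty_leads_empty_list(self):
        assert af.define_loci(_leads([])) == []

    def test_non_significant_lead_rejected(self):
        with pytest.raises(ValueError, match="not genome-wide significant"):
            af.define_loci(_leads([("a", "1", 100, 1e-7)]))

    def test_chromosomes_partition_merging(self):
        leads = _leads([("a", "1", 1_000_000, 1e-9), ("b", "2", 1_000_000, 1e-9)])
        loci = af.define_loci(leads)
        assert len(loci) == 2
        assert [l.locus_id for l in loci] == [1, 2]


class TestJointModel:
    def test_single_variant_reduces_to_marginal(self, geno_study):
        panel, truth, stats_df, _ = geno_study
        vid = truth.causal_ids[0]
        jm = af.joint_model(stats_df, panel, [vid])
        row = stats_df.set_index("variant_id").loc[vid]
        assert jm["joint_beta"].iloc[0] == pytest.approx(row["beta"], rel=1e-9)
        assert jm["joint_se"].iloc[0] == pytest.approx(row["se"], rel=1e-9)
        assert jm["joint_p"].iloc[0] == pytest.approx(row["pvalue"], rel=1e-6)

    def test_matches_full_data_ols(self, geno_study):
        panel, truth, stats_df, y = geno_study
        ids = [truth.causal_ids[0], "rs0_3", truth.causal_ids[1], "rs2_5", truth.causal_ids[2]]
        jm = af.joint_model(stats_df, panel, ids)
        X = sm.add_constant(panel.genotypes[:, panel.indices(ids)].astype(float))
        fit = sm.OLS(y, X).fit()
        np.testing.assert_allclose(jm["joint_beta"], fit.params[1:], rtol=1e-6)
        np.testing.assert_allclose(jm["joint_se"], fit.bse[1:], rtol=1e-6)

    def test_independent_causals_joint_equals_marginal(self, geno_study):
        panel, truth, stats_df, _ = geno_study
        ids = truth.causal_ids[:2]  # different blocks: r = 0 in the panel model
        jm = af.joint_model(stats_df, panel, ids)
        marg = stats_df.set_index("variant_id").loc[ids, "beta"].to_numpy()
        # empirical cross-block correlation is O(1/sqrt(n)), not exactly 0
        np.testing.assert_allclose(jm["joint_beta"], marg, atol=0.02)

    def test_exactly_independent_causals_joint_equals_marginal(self):
        # analytic panel: cross-block r is exactly 0, so the joint model
        # decouples and reproduces the marginal estimates to within rounding
        cfg = af.SimConfig(seed=19, n_blocks=2, n_variants=5, rho=0.7, block_prior=1.0,
                           gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        truth = af.SimTruth(["rs0_2", "rs1_2"], np.array([0.1, -0.1]), block_of)
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=20)
        jm = af.joint_model(stats_df, panel, ["rs0_2", "rs1_2"])
        marg = stats_df.set_index("variant_id").loc[["rs0_2", "rs1_2"], "beta"].to_numpy()
        np.testing.assert_allclose(jm["joint_beta"], marg, rtol=1e-6)

    def test_collinear_later_variant_rejected(self, single_block_panel):
        cfg, panel = single_block_panel
        truth = af.SimTruth([], np.array([]), pd.Series(panel.variants["block"].to_numpy(),
                                                        index=panel.variants["variant_id"]))
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=3)
        # adjacent variants at rho = 0.9: r^2 = 0.81 < cap, two apart 0.9^4... use cap 0.5
        with pytest.raises(CollinearityError):
            af.joint_model(stats_df, panel, ["rs0_0", "rs0_1"], collinearity_r2=0.5)


class TestConditional:
    def test_conditioning_on_independent_variant_is_identity(self, geno_study):
        panel, truth, stats_df, _ = geno_study
        cond = af.conditional_sumstats(stats_df, panel, [truth.causal_ids[0]], ["rs2_5"])
        marg = stats_df.set_index("variant_id").loc["rs2_5", "beta"]
        assert cond["beta"].iloc[0] == pytest.approx(marg, abs=0.02)

    def test_matches_ols_oracle(self, geno_study):
        panel, truth, stats_df, y = geno_study
        conditioning = [truth.causal_ids[0]]
        cond = af.conditional_sumstats(stats_df, panel, conditioning, ["rs0_7"])
        X = sm.add_constant(
            panel.genotypes[:, panel.indices(conditioning + ["rs0_7"])].astype(float)
        )
        fit = sm.OLS(y, X).fit()
        assert cond["beta"].iloc[0] == pytest.approx(fit.params[-1], rel=1e-6)
        assert cond["se"].iloc[0] == pytest.approx(fit.bse[-1], rel=1e-6)

    def test_conditioning_on_perfect_proxy_kills_block_signal(self):
        cfg = af.SimConfig(seed=21, n_blocks=1, n_variants=10, rho=0.95, block_prior=1.0,
                           gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        zmax = []
        for rep in range(40):
            truth = af.SimTruth(["rs0_4"], np.array([0.1]), block_of)
            stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=rep)
            cond = af.conditional_sumstats(stats_df, panel, ["rs0_4"])
            zmax.append((cond["beta"] / cond["se"]).abs().mean())
        # conditioned on the causal itself, residual associations are null
        assert np.mean(zmax) < 2

    def test_conditioning_variants_absent_from_output(self, geno_study):
        panel, truth, stats_df, _ = geno_study
        cond = af.conditional_sumstats(stats_df, panel, [truth.causal_ids[0]])
        assert truth.causal_ids[0] not in set(cond["variant_id"])


class TestStepwise:
    def _direct_locus(self, seed, n_variants=20, effect=0.06, causal_slot=10):
        cfg = af.SimConfig(seed=seed, n_blocks=1, n_variants=n_variants, rho=0.9,
                           block_prior=1.0, gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        vid = f"rs0_{causal_slot}"
        sd_x = np.sqrt(panel.dosage_var([vid])[0])
        truth = af.SimTruth([vid], np.array([effect / sd_x]), block_of)
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=seed + 7)
        locus = af.Locus(1, "1", 1, 10_000_000, [vid])
        return panel, truth, stats_df, locus

    def test_single_causal_recovered_across_loci(self):
        hits = 0
        for rep in range(60):
            panel, truth, stats_df, locus = self._direct_locus(1000 + rep)
            sigs = af.stepwise_select(stats_df, panel, locus)
            if len(sigs) != 1:
                continue
            r = panel.corr([sigs[0].index_variant_id, truth.causal_ids[0]])[0, 1]
            if r**2 > 0.8:
                hits += 1
        assert hits >= 57  # >= 95% of loci

    def test_signals_are_jointly_significant_fixed_point(self):
        panel, truth, stats_df, locus = self._direct_locus(77)
        sigs = af.stepwise_select(stats_df, panel, locus)
        assert sigs, "expected at least one signal"
        for s in sigs:
            assert s.joint_p < 5e-8
        ids = [s.index_variant_id for s in sigs]
        refit = af.joint_model(stats_df, panel, ids)
        assert (refit["joint_p"] < 5e-8).all()
        assert sigs[0].signal_id == "1_1"

    def test_two_independent_causals_in_merged_locus(self):
        cfg = af.SimConfig(seed=31, n_blocks=2, n_variants=15, rho=0.9, block_prior=1.0,
                           gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        # pull the second block within locus reach of the first
        panel.variants.loc[panel.variants["block"] == 1, "pos"] -= 1_400_000
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        sd = np.sqrt(panel.dosage_var(["rs0_7", "rs1_7"]))
        truth = af.SimTruth(["rs0_7", "rs1_7"], np.array([0.06 / sd[0], 0.06 / sd[1]]), block_of)
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=32)
        leads = stats_df.nsmallest(2, "pvalue")[["variant_id", "chrom", "pos", "pvalue"]]
        loci = af.define_loci(leads)
        assert len(loci) == 1
        sigs = af.stepwise_select(stats_df, panel, loci[0])
        assert len(sigs) == 2
        found_blocks = {block_of[s.index_variant_id] for s in sigs}
        assert found_blocks == {0, 1}

    def test_null_locus_yields_no_signals(self, single_block_panel):
        cfg, panel = single_block_panel
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        truth = af.SimTruth([], np.array([]), block_of)
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=5)
        locus = af.Locus(1, "1", 1, 10_000_000, [])
        assert af.stepwise_select(stats_df, panel, locus) == []

    def test_type_one_error_controlled_over_null_loci(self):
        cfg = af.SimConfig(seed=41, n_blocks=500, n_variants=20, rho=0.9, block_prior=0.0,
                           gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        block_of = pd.Series(panel.variants["block"].to_numpy(),
                             index=panel.variants["variant_id"])
        truth = af.SimTruth([], np.array([]), block_of)
        stats_df = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=42)
        n_hit = 0
        for b in range(cfg.n_blocks):
            locus = af.Locus(b + 1, "1", b * 2_000_000 + 1, b * 2_000_000 + 1_000_000, [])
            if af.stepwise_select(stats_df, panel, locus):
                n_hit += 1
        # ~20 tests/locus at alpha = 5e-8: expected false loci << 1 of 500
        assert n_hit / cfg.n_blocks <= 0.01

    def test_locus_variants_respects_bounds(self, geno_study):
        panel, _, stats_df, _ = geno_study
        locus = af.Locus(1, "1", 1, 5_000, [])
        sub = locus_variants(stats_df, locus)
        assert (sub["pos"] <= 5_000).all() and len(sub) == 5
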