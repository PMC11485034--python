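import numpy as np
import pandas as pd
import pytest
from scipy import stats

import annofine as af


def _adjacent_corr(panel):
    """Mean correlation of adjacent dosage pairs within blocks."""
    G = panel.genotypes.astype(float)
    blocks = panel.variants["block"].to_numpy()
    cors = []
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        for j, k in zip(idx[:-1], idx[1:]):
            cors.append(np.corrcoef(G[:, j], G[:, k])[0, 1])
    return float(np.mean(cors))


class TestReferencePanel:
    def test_seed_determinism(self):
        cfg = af.SimConfig(seed=1, n_blocks=2, n_variants=8, n_samples=200)
        p1 = af.simulate_reference_panel(cfg)
        p2 = af.simulate_reference_panel(cfg)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
        pd.testing.assert_frame_equal(p1.variants, p2.variants)

    def test_dosages_are_biallelic_counts(self):
        cfg = af.SimConfig(seed=2, n_blocks=2, n_variants=6, n_samples=150)
        panel = af.simulate_reference_panel(cfg)
        assert set(np.unique(panel.genotypes)) <= {0, 1, 2}

    def test_adjacent_correlation_tracks_rho(self):
        cfg = af.SimConfig(seed=3, rho=0.9, n_samples=2000, n_blocks=10, n_variants=10)
        assert 0.85 <= _adjacent_corr(af.simulate_reference_panel(cfg)) <= 0.95

    def test_zero_rho_gives_independence(self):
        cfg = af.SimConfig(seed=4, rho=0.0, n_samples=2000, n_blocks=10, n_variants=10)
        assert -0.05 <= _adjacent_corr(af.simulate_reference_panel(cfg)) <= 0.05

    def test_empirical_frequencies_within_binomial_tolerance(self):
        cfg = af.SimConfig(seed=5, n_blocks=6, n_variants=5, n_samples=2000, rho=0.0)
        panel = af.simulate_reference_panel(cfg)
        freq = panel.variants["freq"].to_numpy()
        # one frequency per block, drawn from maf_range; 5 sd binomial slack
        tol = 5 * np.sqrt(0.5 * 0.5 / (2 * cfg.n_samples))
        lo, hi = cfg.maf_range
        assert ((freq > lo - tol) & (freq < hi + tol)).all()


class TestCausalArchitecture:
    def test_uniform_within_blocks_when_beta_zero(self):
        cfg = af.SimConfig(seed=6, n_blocks=2000, n_variants=5, rho=0.0, block_prior=1.0,
                           true_beta=(0.0,))
        panel = af.analytic_panel(cfg)
        ann = af.simulate_annotations(cfg, panel)
        truth = af.simulate_causal_architecture(cfg, ann, panel, seed=7)
        # position of the causal within its block should be uniform over 5 slots
        slots = [int(v.split("_")[1]) for v in truth.causal_ids]
        counts = np.bincount(slots, minlength=5)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_enrichment_identity_single_annotation(self):
        # large-block limit: causal share of the annotation -> e^b q / (e^b q + 1 - q) = 0.5;
        # the exact finite-block expectation averages 4m/(3m+M) over m ~ Bin(M, q)
        M, q = 50, 0.2
        cfg = af.SimConfig(seed=8, n_blocks=2000, n_variants=M, rho=0.0, block_prior=1.0,
                           n_annotations=1, annotation_coverage=q, true_beta=(np.log(4),))
        panel = af.analytic_panel(cfg)
        ann = af.simulate_annotations(cfg, panel, seed=9)
        truth = af.simulate_causal_architecture(cfg, ann, panel, seed=10)
        z = ann.subset(truth.causal_ids)[:, 0]
        share = z.mean()
        m = np.arange(M + 1)
        exact = float(np.sum(stats.binom.pmf(m, M, q) * 4 * m / (3 * m + M)))
        assert abs(exact - 0.5) < 0.02  # finite-block correction is small
        assert abs(share - exact) < 3 * np.sqrt(0.25 / len(truth.causal_ids))

    def test_zero_block_prior_gives_no_causals(self):
        cfg = af.SimConfig(seed=11, n_blocks=50, n_variants=5, block_prior=0.0)
        panel = af.analytic_panel(cfg)
        ann = af.simulate_annotations(cfg, panel)
        truth = af.simulate_causal_architecture(cfg, ann, panel)
        assert truth.causal_ids == []

    def test_at_most_one_causal_per_block_enforced(self):
        block_of = pd.Series([0, 0], index=["a", "b"])
        with pytest.raises(ValueError, match="more than one causal"):
            af.SimTruth(["a", "b"], np.array([0.1, 0.2]), block_of)


class TestDirectModeSumstats:
    def test_null_z_scores_standard_normal(self):
        # one variant per block so the 10,000 draws are independent (the
        # Kolmogorov-Smirnov test assumes iid data); marginal normality under
        # LD is covered by the cross-mode comparison below
        cfg = af.SimConfig(seed=12, n_blocks=10_000, n_variants=1, rho=0.0, block_prior=0.0)
        panel = af.analytic_panel(cfg)
        truth = af.SimTruth([], np.array([]), pd.Series(panel.variants["block"].to_numpy(),
                                                        index=panel.variants["variant_id"]))
        ss = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=13)
        z = (ss["beta"] / ss["se"]).to_numpy()
        assert len(z) == 10_000
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_causal_z_mean_matches_ncp(self):
        # standardised effect 0.05 at n = 40,000 gives mean z = 10
        cfg = af.SimConfig(seed=14, n_blocks=1, n_variants=5, rho=0.5, gwas_n=40_000)
        panel = af.analytic_panel(cfg)
        sd_x = np.sqrt(panel.dosage_var(["rs0_2"])[0])
        truth = af.SimTruth(["rs0_2"], np.array([0.05 / sd_x]),
                            pd.Series(panel.variants["block"].to_numpy(),
                                      index=panel.variants["variant_id"]))
        zs = []
        for rep in range(300):
            ss = af.simulate_gwas_sumstats(panel, truth, cfg, mode="direct", seed=100 + rep)
            row = ss.set_index("variant_id").loc["rs0_2"]
            zs.append(row["beta"] / row["se"])
        assert abs(np.mean(zs) - 10.0) < 3 / np.sqrt(300) * 1.5

    def test_modes_agree_on_causal_z_mean(self, geno_cfg, geno_panel):
        vid = "rs1_4"
        sd_x = np.sqrt(geno_panel.dosage_var([vid])[0])
        b = 0.08 / sd_x  # standardised effect 0.08
        truth = af.SimTruth([vid], np.array([b]),
                            pd.Series(geno_panel.variants["block"].to_numpy(),
                                      index=geno_panel.variants["variant_id"]))
        cfg = af.SimConfig(seed=1, n_blocks=3, n_variants=10, n_samples=600, rho=0.6,
                           gwas_n=600)  # matched sample sizes
        zg, zd = [], []
        for rep in range(150):
            sg = af.simulate_gwas_sumstats(geno_panel, truth, cfg, mode="genotype", seed=rep)
            sd = af.simulate_gwas_sumstats(geno_panel, truth, cfg, mode="direct", seed=rep)
            rowg = sg.set_index("variant_id").loc[vid]
            rowd = sd.set_index("variant_id").loc[vid]
            zg.append(rowg["beta"] / rowg["se"])
            zd.append(rowd["beta"] / rowd["se"])
        # both means estimate sqrt(n) * 0.08 ~ 1.96; MC se ~ 0.08
        assert abs(np.mean(zg) - np.mean(zd)) < 0.35


class TestQtlSumstats:
    def _setup(self, seed=15):
        cfg = af.SimConfig(seed=seed, n_blocks=1, n_variants=10, rho=0.8, block_prior=1.0)
        panel = af.analytic_panel(cfg)
        ann = af.simulate_annotations(cfg, panel)
        truth = af.simulate_causal_architecture(cfg, ann, panel)
        return cfg, panel, truth

    def test_shared_reuses_gwas_causal(self):
        cfg, panel, truth = self._setup()
        qtl = af.simulate_qtl_sumstats(panel, truth, "shared", cfg, block=0, effect=0.3, seed=1)
        z = (qtl["beta"] / qtl["se"]).abs()
        assert qtl.loc[z.idxmax(), "variant_id"] == truth.causal_ids[0]
        assert set(qtl["gene"]) == {"GENE1"}

    def test_distinct_uses_other_variant(self):
        cfg, panel, truth = self._setup()
        qtl = af.simulate_qtl_sumstats(panel, truth, "distinct", cfg, block=0, effect=0.3, seed=1)
        z = (qtl["beta"] / qtl["se"]).abs()
        assert qtl.loc[z.idxmax(), "variant_id"] != truth.causal_ids[0]

    def test_null_pvalues_uniform_across_replicates(self):
        cfg, panel, truth = self._setup()
        pvals = []
        for rep in range(300):
            qtl = af.simulate_qtl_sumstats(panel, truth, "null", cfg, block=0, seed=rep)
            pvals.append(qtl["pvalue"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_variant_block_cannot_host_distinct(self):
        cfg = af.SimConfig(seed=16, n_blocks=1, n_variants=1, block_prior=1.0)
        panel = af.analytic_panel(cfg)
        ann = af.simulate_annotations(cfg, panel)
        truth = af.simulate_causal_architecture(cfg, ann, panel)
        with pytest.raises(ValueError, match="single-variant block"):
            af.simulate_qtl_sumstats(panel, truth, "distinct", cfg, block=0)


class TestHicFixture:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene": ["G1", "G2", "G3"],
                "chrom": ["1", "1", "2"],
                "promoter_start": [100_000, 900_000, 500_000],
                "promoter_end": [102_000, 902_000, 502_000],
            }
        )

    def test_three_genes_two_tissues_give_six_interactions(self):
        inter, prom = af.simulate_hic_fixture(self._genes(), tissues=["heart", "brain"])
        assert len(inter) == 6
        assert len(prom) == 3
        # anchors within a tissue do not overlap each other
        for _, grp in inter.groupby("tissue"):
            spans = sorted(
                [(r["chrom1"], r["start1"], r["end1"]) for _, r in grp.iterrows()]
                + [(r["chrom2"], r["start2"], r["end2"]) for _, r in grp.iterrows()]
            )
            for (c1, s1, e1), (c2, s2, e2) in zip(spans[:-1], spans[1:]):
                assert c1 != c2 or e1 <= s2

    def test_anchor_widths_equal_bin_size(self):
        inter, _ = af.simulate_hic_fixture(self._genes(), tissues=["heart"], bin_size=5_000)
        assert ((inter["end1"] - inter["start1"]) == 5_000).all()
        assert ((inter["end2"] - inter["start2"]) == 5_000).all()

    def test_roundtrip_preserves_rows(self, tmp_path):
        from annofine.hic import read_interactions, write_interactions

        inter, _ = af.simulate_hic_fixture(self._genes(), tissues=["heart", "brain"])
        path = tmp_path / "inter.tsv"
        write_interactions(inter, path)
        back = read_interactions(path)
        pd.testing.assert_frame_equal(back, inter)

    def test_promoterless_anchor_rejected(self):
        genes = self._genes()
        genes.loc[0, "promoter_start"] = 10_000  # distal anchor would start below 0
        with pytest.warns(UserWarning, match="rejected"):
            inter, _ = af.simulate_hic_fixture(genes, tissues=["heart"], distal_offset=50_000)
        assert "G1" not in set(inter["target_gene"])


def test_config_validation():
    with pytest.raises(ValueError):
        af.SimConfig(rho=1.0)
    with pytest.raises(ValueError):
        af.SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        af.SimConfig(block_prior=1.5)
    with pytest.raises(ValueError):
        af.SimConfig(effect_sd=0.0)
    with pytest.raises(ValueError):
        af.SimConfig(n_annotations=2, true_beta=(0.1,))
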