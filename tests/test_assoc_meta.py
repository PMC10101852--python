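"""GWAS, QC, meta-analysis, loci, clumping and conditional selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from matfet import assoc_meta, simdata
from matfet.ld import LDReference

from .conftest import make_sumstats


class TestRunGwas:
    def test_null_trait_p_value_calibration(self, small_world):
        g = small_world["trios"].mother_dosage().astype(float)
        rng = np.random.default_rng(10)
        y = rng.standard_normal(g.shape[0])
        out = assoc_meta.run_gwas(g, y)
        frac = (out["P"] < 0.05).mean()
        lo, hi = stats.binom.interval(0.999, len(out), 0.05)
        assert lo / len(out) <= frac <= hi / len(out)

    def test_matches_statsmodels_oracle(self, small_world):
        import statsmodels.api as sm

        g = small_world["trios"].mother_dosage().astype(float)
        y = small_world["phenos"]["gestational_duration"].to_numpy()
        covs = small_world["phenos"][["PC1", "PC2"]].to_numpy()
        out = assoc_meta.run_gwas(g, y, covs, small_world["trios"].variants)
        for j in (0, 17, 42):
            x = sm.add_constant(np.column_stack([g[:, j], covs]))
            fit = sm.OLS(y, x).fit()
            assert out["BETA"][j] == pytest.approx(fit.params[1], abs=1e-8)
            assert out["SE"][j] == pytest.approx(fit.bse[1], abs=1e-8)
            # normal-approximation p vs statsmodels' t reference
            assert out["P"][j] == pytest.approx(fit.pvalues[1], rel=1e-2)

    def test_causal_snp_recovery(self):
        cfg = simdata.ArchitectureConfig(n_snps=5, n_blocks=5, seed=11, gd_sd=3.0)
        pool = simdata.simulate_haplotype_panel(cfg, 50000)
        trios = simdata.simulate_trios(pool, 20000, seed=12)
        g = trios.mother_dosage().astype(float)
        rng = np.random.default_rng(13)
        y = g[:, 2] * 1.0 + rng.normal(0, 3, g.shape[0])
        out = assoc_meta.run_gwas(g, y)
        assert abs(out["BETA"][2] - 1.0) < 3 * out["SE"][2]

    def test_logistic_gwas_runs_and_flags(self, small_world):
        g = small_world["trios"].mother_dosage().astype(float)
        rng = np.random.default_rng(14)
        y = (rng.random(g.shape[0]) < 0.3).astype(float)
        out = assoc_meta.run_gwas(g[:, :10], y, binary=True)
        assert out["BETA"].notna().sum() >= 8
        frac = (out["P"].dropna() < 0.05).mean()
        assert frac < 0.4  # null trait


class TestQc:
    def test_low_maf_removed(self):
        df = make_sumstats([0.1, 0.1], 0.05, eaf=0.3)
        df.loc[1, "EAF"] = 0.005
        out, counts = assoc_meta.qc_cohort(df)
        assert len(out) == 1 and counts["maf"] == 1

    def test_hwe_and_info_filters(self):
        df = make_sumstats([0.1] * 3, 0.05)
        df["HWE_P"] = [0.5, 1e-7, 0.5]
        df["INFO"] = [1.0, 1.0, 0.3]
        out, counts = assoc_meta.qc_cohort(df)
        assert len(out) == 1
        assert counts["hwe"] == 1 and counts["info"] == 1

    def test_all_passing_identity(self):
        df = make_sumstats([0.1] * 5, 0.05)
        out, counts = assoc_meta.qc_cohort(df)
        pd.testing.assert_frame_equal(out, df)
        assert counts.sum() == 0

    def test_hwe_exact_p_against_enumeration_oracle(self):
        # independent oracle: direct enumeration of the conditional
        # distribution of het counts given allele counts
        from math import comb

        def oracle(n_ab, n_aa, n_bb):
            n = n_ab + n_aa + n_bb
            n_a = 2 * n_aa + n_ab
            probs = {}
            for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
                aa = (n_a - het) // 2
                bb = n - aa - het
                if aa < 0 or bb < 0:
                    continue
                # multinomial count of genotype configurations
                import math

                logp = (
                    math.lgamma(n + 1) - math.lgamma(aa + 1) - math.lgamma(het + 1)
                    - math.lgamma(bb + 1) + het * math.log(2)
                )
                probs[het] = math.exp(logp)
            z = sum(probs.values())
            obs = probs[n_ab] / z
            return sum(p / z for p in probs.values() if p / z <= obs * (1 + 1e-12))

        for n_ab, n_aa, n_bb in [(10, 5, 85), (3, 20, 77), (50, 25, 25), (0, 10, 90)]:
            assert assoc_meta.hwe_exact_p(n_ab, n_aa, n_bb) == pytest.approx(
                oracle(n_ab, n_aa, n_bb), rel=1e-9
            )


class TestMetaFixed:
    def test_two_identical_cohorts_closed_form(self):
        a = make_sumstats([0.2], [0.1])
        out = assoc_meta.meta_fixed([a, a.copy()])
        assert out["BETA"][0] == pytest.approx(0.2)
        assert out["SE"][0] == pytest.approx(0.1 / np.sqrt(2))
        assert out["N"][0] == 20000

    def test_opposite_effects_heterogeneity(self):
        a = make_sumstats([1.0], [1.0])
        b = make_sumstats([-1.0], [1.0])
        out = assoc_meta.meta_fixed([a, b])
        assert out["BETA"][0] == pytest.approx(0.0)
        assert out["Q"][0] == pytest.approx(2.0)
        assert out["I2"][0] == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        cohorts = [
            make_sumstats(rng.normal(0, 0.3, 20), rng.uniform(0.05, 0.2, 20))
            for _ in range(4)
        ]
        out = assoc_meta.meta_fixed(cohorts).set_index("SNP")
        for snp in out.index:
            bs = np.array([c.set_index("SNP").loc[snp, "BETA"] for c in cohorts])
            ses = np.array([c.set_index("SNP").loc[snp, "SE"] for c in cohorts])
            w = 1 / ses**2
            assert out.loc[snp, "BETA"] == pytest.approx(np.sum(w * bs) / np.sum(w), abs=1e-12)
            assert out.loc[snp, "SE"] == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-12)

    def test_allele_flip_involution(self):
        a = make_sumstats([0.2, -0.1], [0.1, 0.1], eaf=0.3)
        b = make_sumstats([0.15, -0.05], [0.1, 0.1], eaf=0.32)
        flipped = b.copy()
        flipped["EA"], flipped["NEA"] = b["NEA"], b["EA"]
        flipped["BETA"] = -b["BETA"]
        flipped["EAF"] = 1 - b["EAF"]
        out1 = assoc_meta.meta_fixed([a, b])
        out2 = assoc_meta.meta_fixed([a, flipped])
        pd.testing.assert_frame_equal(out1, out2)

    @settings(max_examples=25, deadline=None)
    @given(
        betas=st.lists(st.floats(-1, 1), min_size=2, max_size=5),
        ses=st.lists(st.floats(0.01, 1), min_size=5, max_size=5),
    )
    def test_pooled_beta_within_cohort_range(self, betas, ses):
        cohorts = [make_sumstats([b], [s]) for b, s in zip(betas, ses)]
        out = assoc_meta.meta_fixed(cohorts)
        assert min(betas) - 1e-9 <= out["BETA"][0] <= max(betas) + 1e-9
        assert out["SE"][0] <= min(ses[: len(betas)]) + 1e-12


class TestFilters:
    def test_half_max_n_paper_boundary(self):
        df = make_sumstats([0.1] * 3, 0.05)
        df["N"] = [195555, 97777, 97778]
        out = assoc_meta.filter_half_max_n(df)
        assert set(out["N"]) == {195555, 97778}

    def test_half_max_n_toy_and_identity(self):
        df = make_sumstats([0.1] * 3, 0.05)
        df["N"] = [100, 60, 49]
        assert set(assoc_meta.filter_half_max_n(df)["N"]) == {100, 60}
        same = make_sumstats([0.1] * 3, 0.05)
        assert len(assoc_meta.filter_half_max_n(same)) == 3

    @pytest.mark.parametrize(
        "cases,controls,included",
        [(50, 50, False), (1000, 1000, True), (26, 10000, True), (0, 100, False)],
    )
    def test_effective_n_gate(self, cases, controls, included):
        assert assoc_meta.effective_n_gate(cases, controls) is included

    def test_effective_n_derived_value(self):
        # 26 cases / 10,000 controls: n_eff = 4/(1/26 + 1/10000) = 103.73
        n_eff = 4 / (1 / 26 + 1 / 10000)
        assert n_eff == pytest.approx(103.73, abs=0.01)


class TestGenomicLambda:
    def test_all_half_p_gives_unity(self):
        df = make_sumstats([0.0] * 10, 0.1)
        df["P"] = 0.5
        assert assoc_meta.genomic_lambda(df) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_p_near_unity(self):
        rng = np.random.default_rng(16)
        df = make_sumstats(np.zeros(100000), 0.1)
        df["P"] = rng.uniform(0, 1, 100000)
        assert assoc_meta.genomic_lambda(df) == pytest.approx(1.0, abs=0.02)

    def test_inflated_chi2_by_construction(self):
        rng = np.random.default_rng(17)
        chi2 = rng.chisquare(1, 200000) * 1.1
        df = make_sumstats(np.zeros(200000), 0.1)
        df["P"] = stats.chi2.sf(chi2, 1)
        assert assoc_meta.genomic_lambda(df) == pytest.approx(1.1, abs=0.02)

    def test_empty_raises(self):
        df = make_sumstats([], [])
        with pytest.raises(ValueError):
            assoc_meta.genomic_lambda(df)


class TestLoci:
    def test_no_signal_empty(self):
        df = make_sumstats([0.01] * 5, 0.1)
        assert assoc_meta.define_loci(df).empty

    def test_near_hits_merge_far_hits_split(self):
        df = make_sumstats([1.0, 0.9, 0.8], 0.1, pos=[1_000_000, 1_100_000, 1_700_000])
        loci = assoc_meta.define_loci(df)
        assert len(loci) == 2  # 100 kb apart merge; 600 kb apart split

    def test_overlapping_loci_merged(self):
        df = make_sumstats([1.0, 0.9], 0.1, pos=[1_000_000, 1_400_000])
        loci = assoc_meta.define_loci(df)
        assert len(loci) == 1
        assert loci["start"].iloc[0] == 750_000 and loci["end"].iloc[0] == 1_650_000


class TestClump:
    def test_unlinked_variants_all_index(self, ldsc_world):
        rng = np.random.default_rng(18)
        variants = ldsc_world["ld"].variants
        # one variant per block -> mutually unlinked
        picks = variants.groupby("block").head(1).head(10)
        df = make_sumstats(
            np.full(10, 1.0), 0.1, snps=picks["SNP"].tolist(), pos=picks["POS"].tolist()
        )
        out = assoc_meta.clump(df, ldsc_world["ld"])
        assert len(out) == 10

    def test_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(19)
        cfg = simdata.ArchitectureConfig(n_snps=2, n_blocks=1, block_ld_rho=0.95, seed=20)
        pool = simdata.simulate_haplotype_panel(cfg, 5000)
        ld = simdata.ld_reference_from_pool(pool)
        df = make_sumstats([1.0, 0.9], [0.1, 0.1], snps=["rs1", "rs2"], pos=[10000, 15000])
        out = assoc_meta.clump(df, ld, r2=0.5)
        assert out["SNP"].tolist() == ["rs1"]
        assert out["clump_members"].iloc[0] == "rs2"

    def test_matches_brute_force_oracle(self, small_world):
        pool = small_world["pool"]
        ld = simdata.ld_reference_from_pool(pool)
        rng = np.random.default_rng(21)
        z = rng.normal(0, 3, pool.n_snps)
        df = make_sumstats(
            z * 0.1, 0.1, snps=pool.variants["SNP"].tolist(), pos=pool.variants["POS"].tolist()
        )
        p1, p2, r2, kb = 1e-3, 0.05, 0.2, 1000
        got = assoc_meta.clump(df, ld, r2=r2, kb=kb, p1=p1, p2=p2)["SNP"].tolist()

        # brute-force greedy oracle
        cand = df.sort_values(["P", "POS"]).reset_index(drop=True)
        alive = {s: p for s, p in zip(cand["SNP"], cand["P"]) if p < p2}
        pos = dict(zip(cand["SNP"], cand["POS"]))
        expected = []
        for snp, p in zip(cand["SNP"], cand["P"]):
            if snp not in alive or p >= p1:
                continue
            expected.append(snp)
            del alive[snp]
            for other in list(alive):
                if abs(pos[other] - pos[snp]) <= kb * 1000 and ld.r(snp, other) ** 2 > r2:
                    del alive[other]
        assert got == expected


class TestCojoSelect:
    @pytest.fixture(scope="class")
    def cojo_world(self):
        cfg = simdata.ArchitectureConfig(
            n_snps=40, n_blocks=4, block_ld_rho=0.7, maf_range=(0.2, 0.5), seed=22
        )
        pool = simdata.simulate_haplotype_panel(cfg, 20000)
        trios = simdata.simulate_trios(pool, 5000, seed=23)
        g = trios.mother_dosage().astype(float)
        return cfg, pool, g

    def test_single_causal_snp_selected(self, cojo_world):
        cfg, pool, g = cojo_world
        rng = np.random.default_rng(24)
        y = g[:, 15] * 0.6 + rng.normal(0, 2, g.shape[0])
        stats_df = assoc_meta.run_gwas(g, y, None, pool.variants)
        ld = LDReference.from_genotypes(g, pool.variants, pool.variants["block"].to_numpy())
        sel = assoc_meta.cojo_select(stats_df, ld, p_threshold=1e-5)
        assert sel["SNP"].tolist() == ["rs16"]

    def test_two_unlinked_causal_snps_both_selected(self, cojo_world):
        cfg, pool, g = cojo_world
        rng = np.random.default_rng(25)
        true = {5: 0.6, 25: -0.5}  # different blocks -> r2 = 0
        y = g[:, 5] * 0.6 + g[:, 25] * -0.5 + rng.normal(0, 2, g.shape[0])
        stats_df = assoc_meta.run_gwas(g, y, None, pool.variants)
        ld = LDReference.from_genotypes(g, pool.variants, pool.variants["block"].to_numpy())
        sel = assoc_meta.cojo_select(stats_df, ld, p_threshold=1e-5)
        assert set(sel["SNP"]) == {"rs6", "rs26"}
        for _, row in sel.iterrows():
            assert abs(row["BETA_JOINT"] - true[int(row["SNP"][2:]) - 1]) < 3 * row["SE_JOINT"]

    def test_joint_betas_equal_multiple_regression_oracle(self, cojo_world):
        cfg, pool, g = cojo_world
        rng = np.random.default_rng(26)
        y = g[:, 3] * 0.5 + g[:, 7] * 0.45 + rng.normal(0, 2, g.shape[0])
        stats_df = assoc_meta.run_gwas(g, y, None, pool.variants)
        ld = LDReference.from_genotypes(g, pool.variants, pool.variants["block"].to_numpy())
        sel = assoc_meta.cojo_select(stats_df, ld, p_threshold=1e-4)
        idx = [int(s[2:]) - 1 for s in sel["SNP"]]
        x = np.column_stack([g[:, idx], np.ones(g.shape[0])])
        b = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.abs(sel["BETA_JOINT"].to_numpy() - b[:-1]).max() < 1e-6

    def test_invariant_to_variant_order(self, cojo_world):
        cfg, pool, g = cojo_world
        rng = np.random.default_rng(27)
        y = g[:, 5] * 0.6 + g[:, 25] * -0.5 + rng.normal(0, 2, g.shape[0])
        stats_df = assoc_meta.run_gwas(g, y, None, pool.variants)
        ld = LDReference.from_genotypes(g, pool.variants, pool.variants["block"].to_numpy())
        a = assoc_meta.cojo_select(stats_df, ld, p_threshold=1e-5)
        shuffled = stats_df.sample(frac=1, random_state=1).reset_index(drop=True)
        b = assoc_meta.cojo_select(shuffled, ld, p_threshold=1e-5)
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
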