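"""Trio regression, pooling, sign alignment and effect-origin clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from matfet import effect_origin, simdata
from matfet.effect_origin import (
    CLUSTERS,
    _phi2,
    align_signs,
    classify,
    cluster_effect_origin,
    fit_trio_regression,
    meta_trio_effects,
)
from matfet.trio_alleles import resolve_trioset


def synth_estimates(seed=0, n_per=40, se=0.05, mag=(0.3, 0.6)):
    """Noisy MnT/MT/PT triplets with known class, one row per SNP."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_per):
        m = rng.uniform(*mag) * rng.choice([-1, 1])
        f = rng.uniform(*mag) * rng.choice([-1, 1])
        noisy = lambda v: v + rng.normal(0, se)
        fs = np.sign(m) * abs(f)
        fo = -np.sign(m) * abs(f)
        rows += [
            ("maternal_only", noisy(m), noisy(m), noisy(0)),
            ("fetal_only", noisy(0), noisy(f), noisy(f)),
            ("fetal_poe_mt", noisy(0), noisy(f), noisy(0)),
            ("both_same", noisy(m), noisy(m + fs), noisy(fs)),
            ("both_opposite", noisy(m), noisy(m + fo), noisy(fo)),
        ]
    est = pd.DataFrame(rows, columns=["true", "beta_mnt", "beta_mt", "beta_pt"])
    est["SNP"] = [f"s{i}" for i in range(len(est))]
    est["se_mnt"] = est["se_mt"] = est["se_pt"] = se
    est["estimable"] = True
    return est


@pytest.fixture(scope="module")
def recovery_world():
    """2,000 trios with one strong maternal-only and one fetal-only SNP."""
    cfg = simdata.ArchitectureConfig(
        n_snps=2, n_blocks=2, gd_sd=3.0, maf_range=(0.3, 0.5), seed=30,
        effect_class_mix={"null": 1.0},
    )
    pool = simdata.simulate_haplotype_panel(cfg, 50000)
    trios = simdata.simulate_trios(pool, 20000, seed=31)
    truth = simdata.simulate_truth(cfg, pool.variants)
    truth["true_class"] = ["maternal_only", "fetal_only"]
    truth["m"] = [1.0, 0.0]
    truth["f"] = [0.0, 0.8]
    ph = simdata.simulate_phenotypes(trios, truth, cfg)
    dos = resolve_trioset(trios)
    est = fit_trio_regression(dos, ph["gestational_duration"].to_numpy())
    return trios, ph, dos, est


class TestFitTrioRegression:
    def test_maternal_only_pattern_recovery(self, recovery_world):
        *_, est = recovery_world
        r = est.iloc[0]
        assert abs(r["beta_mnt"] - 1.0) < 3 * r["se_mnt"]
        assert abs(r["beta_mt"] - 1.0) < 3 * r["se_mt"]
        assert abs(r["beta_pt"]) < 3 * r["se_pt"]

    def test_fetal_only_pattern_recovery(self, recovery_world):
        *_, est = recovery_world
        r = est.iloc[1]
        assert abs(r["beta_mnt"]) < 3 * r["se_mnt"]
        assert abs(r["beta_mt"] - 0.8) < 3 * r["se_mt"]
        assert abs(r["beta_pt"] - 0.8) < 3 * r["se_pt"]

    def test_matches_normal_equations_oracle(self, recovery_world):
        trios, ph, dos, est = recovery_world
        y = ph["gestational_duration"].to_numpy()
        x = np.column_stack([dos.mnt[:, 0], dos.mt[:, 0], dos.pt[:, 0], np.ones(len(y))])
        b = np.linalg.solve(x.T @ x, x.T @ y)
        assert est["beta_mnt"][0] == pytest.approx(b[0], abs=1e-8)
        assert est["beta_mt"][0] == pytest.approx(b[1], abs=1e-8)
        assert est["beta_pt"][0] == pytest.approx(b[2], abs=1e-8)

    def test_non_estimable_snp_flagged(self, small_world):
        dos = resolve_trioset(small_world["trios"])
        dos.mt[:, 0] = 0.0
        dos.mnt[:, 0] = 0.0
        dos.pt[:, 0] = 0.0
        est = fit_trio_regression(dos, small_world["phenos"]["gestational_duration"].to_numpy())
        assert not est["estimable"].iloc[0]
        assert np.isnan(est["beta_mnt"].iloc[0])


class TestMetaTrioEffects:
    def test_single_cohort_identity(self):
        est = synth_estimates(seed=1, n_per=5)
        est["n"] = 100
        out = meta_trio_effects([est])
        for c in ("beta_mnt", "beta_mt", "beta_pt"):
            np.testing.assert_allclose(out[c], est[c], atol=1e-12)

    def test_two_identical_cohorts_shrink_se_sqrt2(self):
        est = synth_estimates(seed=2, n_per=5)
        est["n"] = 100
        out = meta_trio_effects([est, est.copy()])
        np.testing.assert_allclose(out["se_mnt"], est["se_mnt"] / np.sqrt(2), atol=1e-12)
        assert (out["n"] == 200).all()

    def test_matches_componentwise_weighted_mean(self):
        rng = np.random.default_rng(3)
        cohorts = []
        for k in range(3):
            est = synth_estimates(seed=10 + k, n_per=4)
            est[["se_mnt", "se_mt", "se_pt"]] = rng.uniform(0.02, 0.1, (len(est), 3))
            est["n"] = 100
            cohorts.append(est)
        out = meta_trio_effects(cohorts).set_index("SNP")
        snp = cohorts[0]["SNP"].iloc[2]
        for comp in ("mnt", "mt", "pt"):
            b = np.array([c.set_index("SNP").loc[snp, f"beta_{comp}"] for c in cohorts])
            s = np.array([c.set_index("SNP").loc[snp, f"se_{comp}"] for c in cohorts])
            w = 1 / s**2
            assert out.loc[snp, f"beta_{comp}"] == pytest.approx(np.sum(w * b) / np.sum(w), abs=1e-12)


class TestAlignSigns:
    def test_negative_mt_flipped(self):
        est = pd.DataFrame(
            {"SNP": ["a"], "beta_mnt": [0.2], "beta_mt": [-0.5], "beta_pt": [0.1],
             "se_mnt": [0.1], "se_mt": [0.1], "se_pt": [0.1], "estimable": [True]}
        )
        out = align_signs(est)
        assert out["beta_mt"].iloc[0] == 0.5
        assert out["beta_mnt"].iloc[0] == -0.2
        assert out["beta_pt"].iloc[0] == -0.1

    def test_idempotent_and_nonnegative(self):
        est = synth_estimates(seed=4, n_per=10)
        once = align_signs(est)
        twice = align_signs(once)
        assert (once["beta_mt"] >= 0).all()
        for c in ("beta_mnt", "beta_mt", "beta_pt"):
            np.testing.assert_allclose(once[c], twice[c])


class TestBivariateCdf:
    @pytest.mark.parametrize(
        "h,k,rho",
        [(0.5, -0.3, 0.4), (-1.0, 2.0, -0.7), (0.2, 0.1, 0.0), (3.0, -3.0, 0.2),
         (-0.8, -0.9, 0.85), (1.5, 1.5, -0.95)],
    )
    def test_matches_scipy_oracle(self, h, k, rho):
        got = float(_phi2(np.array([h]), np.array([k]), np.array([rho]))[0])
        want = multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([h, k])
        assert got == pytest.approx(want, abs=1e-8)


class TestClustering:
    def test_clean_mean_patterns_confident(self):
        # exact mean patterns at tiny noise: (0.5, 0.5, 0) is maternal-only,
        # (0, 0.5, 0.5) fetal-only, with near-certain posteriors
        rng = np.random.default_rng(5)
        n = 40
        rows = []
        for i in range(n):
            m = rng.uniform(0.3, 0.6)
            f = rng.uniform(0.3, 0.6)
            rows.append((f"m{i}", m, m, 0.0, "maternal_only"))
            rows.append((f"f{i}", 0.0, f, f, "fetal_only"))
        est = pd.DataFrame(
            rows, columns=["SNP", "beta_mnt", "beta_mt", "beta_pt", "true"]
        )
        est[["beta_mnt", "beta_mt", "beta_pt"]] += rng.normal(0, 0.01, (len(est), 3))
        est["se_mnt"] = est["se_mt"] = est["se_pt"] = 0.01
        est["estimable"] = True
        fit = cluster_effect_origin(est, n_restarts=20)
        post = fit.posteriors.set_index("SNP")
        assert post.loc["m0", "maternal_only"] > 0.99
        assert post.loc["f0", "fetal_only"] > 0.99
        lab = classify(fit)
        assert (lab["top_class"].to_numpy() == est["true"].to_numpy()).mean() == 1.0

    def test_simulation_accuracy_at_moderate_noise(self):
        est = synth_estimates(seed=6, n_per=40, se=0.05)
        fit = cluster_effect_origin(est, n_restarts=30, fix_uniform_weights=True)
        lab = classify(fit)
        acc = (lab["top_class"].to_numpy() == est["true"].to_numpy()).mean()
        assert acc >= 0.9

    def test_posteriors_sum_to_one(self):
        est = synth_estimates(seed=7, n_per=10)
        fit = cluster_effect_origin(est, n_restarts=5)
        totals = fit.posteriors[list(CLUSTERS)].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_invariant_to_joint_rescaling(self):
        est = synth_estimates(seed=8, n_per=10)
        scaled = est.copy()
        for c in ("beta_mnt", "beta_mt", "beta_pt", "se_mnt", "se_mt", "se_pt"):
            scaled[c] = est[c] * 7.3
        a = cluster_effect_origin(est, n_restarts=10)
        b = cluster_effect_origin(scaled, n_restarts=10)
        # equivariance is structural; float round-off accumulates over EM
        # iterations, so only near-equality is asserted
        np.testing.assert_allclose(
            a.posteriors[list(CLUSTERS)].to_numpy(),
            b.posteriors[list(CLUSTERS)].to_numpy(),
            atol=1e-3,
        )

    def test_maternal_only_world_concentrates(self):
        est = synth_estimates(seed=9, n_per=40, se=0.02)
        mat = est[est["true"] == "maternal_only"].reset_index(drop=True)
        fit = cluster_effect_origin(mat, n_restarts=20)
        lab = classify(fit)
        assert (lab["top_class"] == "maternal_only").mean() >= 0.95

    def test_too_few_snps_raises(self):
        est = synth_estimates(seed=10, n_per=1).head(1)
        with pytest.raises(ValueError):
            cluster_effect_origin(est)


class TestClassify:
    def test_confident_and_low_confidence_labels(self):
        fit = effect_origin.MixtureFit(
            posteriors=pd.DataFrame(
                {"SNP": ["a", "b", "c"],
                 "maternal_only": [0.9, 0.47, 0.2],
                 "fetal_only": [0.05, 0.46, 0.2],
                 "fetal_poe_mt": [0.03, 0.04, 0.2],
                 "both_same": [0.01, 0.02, 0.2],
                 "both_opposite": [0.01, 0.01, 0.2]}
            ),
            weights={}, tau2={}, log_likelihood=0.0, converged=True,
        )
        out = classify(fit, min_prob=0.5)
        assert out.loc[0, "top_class"] == "maternal_only" and not out.loc[0, "low_confidence"]
        # the 0.47 case is labelled but flagged for caution
        assert out.loc[1, "top_class"] == "maternal_only" and out.loc[1, "low_confidence"]
        assert out.loc[2, "low_confidence"]
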