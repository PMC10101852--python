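"""Summary-statistic models: LD-score regression, ABF colocalization,
multitrait conditioning and effect-attenuation summaries.

The LD-score machinery is a lightweight reimplementation of the canonical
estimator: association chi-square regressed on N * l_j / M with a free
intercept, heteroskedasticity weights 1 / max(l_j, 1), and block-jackknife
standard errors; the cross-trait version regresses z_a * z_b on
sqrt(N_a N_b) * l_j / M to estimate the genetic covariance, and
r_g = gencov / sqrt(h2_a h2_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MHC_REGION = (6, 28477797, 33448354)  # chr6:28477797-33448354, excluded from LDSC


@dataclass
class LdscResult:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    rg: float | None = None
    rg_se: float | None = None
    n_blocks: int = 0

    def h2_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.isf((1 - level) / 2)
        return self.h2 - z * self.h2_se, self.h2 + z * self.h2_se

    def rg_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.isf((1 - level) / 2)
        return self.rg - z * self.rg_se, self.rg + z * self.rg_se


def exclude_mhc(stats_df: pd.DataFrame) -> pd.DataFrame:
    chrom, start, end = MHC_REGION
    mask = (stats_df["CHR"] == chrom) & stats_df["POS"].between(start, end)
    return stats_df[~mask]


def _merge_ld(stats_df: pd.DataFrame, ld_scores: pd.DataFrame) -> pd.DataFrame:
    merged = stats_df.merge(ld_scores[["SNP", "L2"]], on="SNP", how="inner")
    return merged.dropna(subset=["BETA", "SE", "L2"])


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Weighted regression of y on (x, 1) with delete-one-block jackknife.

    Returns ((slope, intercept), (slope_se, intercept_se), per-block
    delete-one estimates, n_blocks actually used).
    """
    m = len(x)
    n_blocks = int(min(n_blocks, max(2, m // 2)))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    design = np.column_stack([x, np.ones(m)])
    wx = design * w[:, None]
    xtx_tot = wx.T @ design
    xty_tot = wx.T @ y
    full = np.linalg.solve(xtx_tot, xty_tot)
    deletes = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        xtx_b = wx[sl].T @ design[sl]
        xty_b = wx[sl].T @ y[sl]
        deletes[b] = np.linalg.solve(xtx_tot - xtx_b, xty_tot - xty_b)
    mean_del = deletes.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((deletes - mean_del) ** 2).sum(axis=0))
    return full, se, deletes, n_blocks


def ldsc_h2(
    stats_df: pd.DataFrame,
    ld_scores: pd.DataFrame,
    n: float | None = None,
    n_blocks: int = 200,
    drop_mhc: bool = True,
) -> LdscResult:
    """Observed-scale SNP heritability by LD-score regression."""
    df = exclude_mhc(stats_df) if drop_mhc and "CHR" in stats_df else stats_df
    merged = _merge_ld(df, ld_scores)
    if len(merged) < 4:
        raise ValueError("too few variants with LD scores")
    z2 = (merged["BETA"] / merged["SE"]) ** 2
    n_vec = merged["N"].to_numpy(dtype=float) if n is None else np.full(len(merged), float(n))
    m = len(merged)
    x = n_vec * merged["L2"].to_numpy() / m
    w = 1.0 / np.maximum(merged["L2"].to_numpy(), 1.0)
    (slope, intercept), (s_se, i_se), _, used = _wls_jackknife(x, z2.to_numpy(), w, n_blocks)
    if used < 2:
        raise ValueError("need at least 2 jackknife blocks")
    return LdscResult(h2=slope, h2_se=s_se, intercept=intercept, intercept_se=i_se, n_blocks=used)


def ldsc_rg(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    ld_scores: pd.DataFrame,
    n_blocks: int = 200,
    drop_mhc: bool = True,
) -> LdscResult:
    """Bivariate LD-score regression: genetic correlation with jackknife SE.

    The jackknife recomputes the full ratio rg = gencov / sqrt(h2_a h2_b)
    on every delete-one-block sample, so the SE propagates the uncertainty
    of all three regressions.
    """
    if drop_mhc and "CHR" in stats_a:
        stats_a, stats_b = exclude_mhc(stats_a), exclude_mhc(stats_b)
    a = _merge_ld(stats_a, ld_scores)
    b = _merge_ld(stats_b, ld_scores)
    merged = a.merge(b, on="SNP", suffixes=("_a", "_b"))
    if len(merged) < 4:
        raise ValueError("too few shared variants")
    za = (merged["BETA_a"] / merged["SE_a"]).to_numpy()
    zb = (merged["BETA_b"] / merged["SE_b"]).to_numpy()
    na = merged["N_a"].to_numpy(dtype=float)
    nb = merged["N_b"].to_numpy(dtype=float)
    ell = merged["L2_a"].to_numpy()
    m = len(merged)
    w = 1.0 / np.maximum(ell, 1.0)

    x_a = na * ell / m
    x_b = nb * ell / m
    x_ab = np.sqrt(na * nb) * ell / m

    (h2a, int_a), _, del_a, used = _wls_jackknife(x_a, za**2, w, n_blocks)
    (h2b, int_b), _, del_b, _ = _wls_jackknife(x_b, zb**2, w, used)
    (gcov, int_ab), gcov_se, del_ab, _ = _wls_jackknife(x_ab, za * zb, w, used)

    if h2a <= 0 or h2b <= 0:
        return LdscResult(
            h2=h2a, h2_se=np.nan, intercept=int_a, intercept_se=np.nan,
            rg=np.nan, rg_se=np.nan, n_blocks=used,
        )
    rg = gcov / np.sqrt(h2a * h2b)
    with np.errstate(invalid="ignore"):
        rg_del = del_ab[:, 0] / np.sqrt(np.clip(del_a[:, 0] * del_b[:, 0], 1e-12, None))
    rg_mean = rg_del.mean()
    rg_se = float(np.sqrt((used - 1) / used * ((rg_del - rg_mean) ** 2).sum()))
    return LdscResult(
        h2=h2a, h2_se=np.nan, intercept=int_a, intercept_se=np.nan,
        rg=float(rg), rg_se=rg_se, n_blocks=used,
    )


# ---------------------------------------------------------------------------
# colocalization


@dataclass
class ColocResult:
    pp: dict[str, float]  # PP0..PP4
    n_variants: int
    priors: tuple[float, float, float]

    @property
    def pp4(self) -> float:
        return self.pp["PP4"]

    @property
    def strong_colocalization(self) -> bool:
        return self.pp["PP4"] > 0.9


def _log_abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """Wakefield approximate Bayes factor (log scale) per variant."""
    v = se**2
    z2 = (beta / se) ** 2
    r = w / (w + v)
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(
    region_a: pd.DataFrame,
    region_b: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 5e-6,
    prior_sd: float = 0.15,
) -> ColocResult:
    """Approximate-Bayes-factor colocalization of one region for two traits.

    Evaluates the five hypotheses (no association; trait A only; trait B
    only; two distinct causal variants; one shared causal variant) with
    priors p1, p2, p12 for a random variant being associated with A, B or
    both.  ``prior_sd`` is the prior effect SD on the standardized scale.
    """
    merged = region_a.merge(region_b, on="SNP", suffixes=("_a", "_b"))
    if len(merged) < 2:
        raise ValueError("need at least 2 shared variants in the region")
    la = _log_abf(merged["BETA_a"].to_numpy(), merged["SE_a"].to_numpy(), prior_sd**2)
    lb = _log_abf(merged["BETA_b"].to_numpy(), merged["SE_b"].to_numpy(), prior_sd**2)

    from scipy.special import logsumexp

    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    # sum over ordered distinct pairs: sum_a sum_b - sum_shared
    l_h3_total = logsumexp([lsum_a + lsum_b, lsum_ab], b=[1.0, -1.0])

    lh = np.array(
        [
            0.0,
            np.log(p1) + lsum_a,
            np.log(p2) + lsum_b,
            np.log(p1) + np.log(p2) + l_h3_total,
            np.log(p12) + lsum_ab,
        ]
    )
    lh -= logsumexp(lh)
    pp = np.exp(lh)
    return ColocResult(
        pp={f"PP{i}": float(pp[i]) for i in range(5)},
        n_variants=len(merged),
        priors=(p1, p2, p12),
    )


# ---------------------------------------------------------------------------
# multitrait conditioning


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def _b_xy_with_outlier_screen(
    b_exp: np.ndarray, b_out: np.ndarray, se_out: np.ndarray, z_cut: float = 3.29
) -> float:
    """Causal-effect estimate robust to pleiotropic instruments.

    A weighted-median preliminary slope anchors the majority of instruments;
    instruments whose residual from that line exceeds ``z_cut`` outcome SEs
    are dropped (they affect the target through a path other than the
    exposure, e.g. reverse mediation), and IVW is run on the remainder.
    This mirrors the outlier screening the published multitrait-conditioning
    method applies before estimating b_xy.
    """
    ratios = b_out / b_exp
    w_med = (b_exp / se_out) ** 2
    slope0 = _weighted_median(ratios, w_med)
    resid_z = (b_out - slope0 * b_exp) / se_out
    keep = np.abs(resid_z) <= z_cut
    if keep.sum() < 3:
        keep = np.ones(len(b_exp), dtype=bool)
    w = 1.0 / se_out[keep] ** 2
    return float(np.sum(w * b_exp[keep] * b_out[keep]) / np.sum(w * b_exp[keep] ** 2))


def mtcojo_condition(
    target_stats: pd.DataFrame,
    covariate_stats: pd.DataFrame,
    instruments: list[str],
    b_xy: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Condition one trait's summary statistics on another.

    The causal effect b_xy of the covariate trait on the target is estimated
    by IVW MR over the instrument SNPs (unless supplied); conditioned
    effects are b_c = b_target - b_xy * b_covariate with
    se_c^2 = se_target^2 + b_xy^2 * se_covariate^2.  Returns the
    conditioned summary statistics and b_xy.  Valid for non-overlapping
    samples (no sampling-covariance term is subtracted).
    """
    merged = target_stats.merge(
        covariate_stats[["SNP", "BETA", "SE"]], on="SNP", suffixes=("", "_cov")
    )
    if b_xy is None:
        if len(instruments) < 3:
            raise ValueError("need at least 3 instruments to estimate b_xy")
        inst = merged[merged["SNP"].isin(instruments)]
        if len(inst) < 3:
            raise ValueError("fewer than 3 instruments found in both traits")
        b_xy = _b_xy_with_outlier_screen(
            inst["BETA_cov"].to_numpy(), inst["BETA"].to_numpy(), inst["SE"].to_numpy()
        )
    out = merged.copy()
    out["BETA"] = merged["BETA"] - b_xy * merged["BETA_cov"]
    out["SE"] = np.sqrt(merged["SE"] ** 2 + b_xy**2 * merged["SE_cov"] ** 2)
    out["P"] = 2 * stats.norm.sf(np.abs(out["BETA"] / out["SE"]))
    out = out.drop(columns=["BETA_cov", "SE_cov"])
    return out, float(b_xy)


def effect_attenuation(
    before: pd.DataFrame, after: pd.DataFrame, snp_set: list[str]
) -> dict:
    """Per-SNP relative change in effect magnitude after conditioning.

    relative difference = (|beta_after| - |beta_before|) / |beta_before|;
    reports the median and a Wilcoxon signed-rank test of the differences.
    """
    if len(snp_set) == 0:
        raise ValueError("empty SNP set")
    b = before[before["SNP"].isin(snp_set)].set_index("SNP")["BETA"]
    a = after[after["SNP"].isin(snp_set)].set_index("SNP")["BETA"]
    common = b.index.intersection(a.index)
    if len(common) == 0:
        raise ValueError("no shared SNPs between before/after")
    rel = (a.loc[common].abs() - b.loc[common].abs()) / b.loc[common].abs()
    diffs = rel.to_numpy()
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return {
        "relative_differences": rel,
        "median": float(np.median(diffs)),
        "wilcoxon_p": p,
        "n_snps": len(common),
    }


def select_region_lead_snps(
    stats_df: pd.DataFrame, p_threshold: float = 5e-6, region_size: int = 1_000_000
) -> list[str]:
    """Lowest-p SNP below ``p_threshold`` from each fixed-size region
    (a stand-in for approximately LD-independent regions)."""
    df = stats_df.dropna(subset=["P"]).copy()
    df["_region"] = df["POS"] // region_size
    df = df[df["P"] < p_threshold]
    if df.empty:
        return []
    idx = df.groupby(["CHR", "_region"])["P"].idxmin()
    return df.loc[idx, "SNP"].tolist()
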