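"""Per-cohort GWAS, QC, fixed-effect IVW meta-analysis, loci, clumping, COJO.

Summary statistics live in pandas DataFrames with the column convention
{SNP, CHR, POS, EA, NEA, EAF, BETA, SE, P, N, INFO} (+ heterogeneity
columns Q, I2, HET_P, N_STUDIES after meta-analysis).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDReference

GWS_P = 5e-8  # genome-wide significance

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N", "INFO"]


# ---------------------------------------------------------------------------
# association


def run_gwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Additive single-variant association scan.

    Quantitative traits: per-variant OLS with covariates, computed by
    Frisch-Waugh residualization (exactly equivalent to fitting each
    ``y ~ g + covariates`` model).  Binary traits: per-variant logistic
    regression (statsmodels MLE); variants with separation or failed
    convergence are flagged and excluded (P = NaN).
    """
    g = np.asarray(dosages, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = g.shape
    c = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=np.float64)]
    )
    p_cov = c.shape[1]

    eaf = g.mean(axis=0) / 2.0
    if variants is None:
        variants = pd.DataFrame(
            {"SNP": [f"v{i}" for i in range(m)], "CHR": 1, "POS": np.arange(m) + 1,
             "EA": "A", "NEA": "G"}
        )
    out = variants[[c_ for c_ in ("SNP", "CHR", "POS", "EA", "NEA") if c_ in variants]].copy()

    if not binary:
        # residualize y and every genotype column on the covariates
        q, _ = np.linalg.qr(c)
        y_r = y - q @ (q.T @ y)
        g_r = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", g_r, g_r)
        gy = g_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(gg > 0, gy / gg, np.nan)
        dof = n - p_cov - 1
        rss = (y_r @ y_r) - beta**2 * gg
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.where(gg > 0, sigma2 / gg, np.nan))
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        import statsmodels.api as sm

        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            if g[:, j].std() == 0:
                continue
            x = np.column_stack([g[:, j], c])
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True) or fit.bse[0] > 100:
                    continue
                beta[j], se[j], p[j] = fit.params[0], fit.bse[0], fit.pvalues[0]
            except Exception:
                continue

    out["EAF"] = eaf
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = p
    out["N"] = n
    out["INFO"] = 1.0
    return out


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value (two-sided, mid-p off).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on allele counts.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # ensure "rare" counts the minor allele
        n_rare = 2 * n - n_rare
    if n == 0:
        return 1.0
    # log-probability of each possible het count with same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array(
        [
            _hwe_logprob(h, (n_rare - h) // 2, n - (n_rare + h) // 2, n, n_rare)
            for h in hets
        ]
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _hwe_logprob(n_ab: int, n_aa: int, n_bb: int, n: int, n_a: int) -> float:
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_aa + 1)
        - math.lgamma(n_ab + 1)
        - math.lgamma(n_bb + 1)
        + n_ab * math.log(2)
        - (math.lgamma(2 * n + 1) - math.lgamma(n_a + 1) - math.lgamma(2 * n - n_a + 1))
    )


def qc_cohort(
    stats_df: pd.DataFrame,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    info_min: float = 0.4,
    call_rate_min: float = 0.98,
) -> tuple[pd.DataFrame, pd.Series]:
    """Variant QC: drop MAF < 1%, HWE exact P < 1e-6, imputation INFO < 0.4
    and call rate < 98% (columns HWE_P / CALL_RATE are optional).  Returns
    (passing variants, removal counts by reason)."""
    reasons = pd.Series(pd.NA, index=stats_df.index, dtype="string")

    def flag(mask, reason):
        nonlocal reasons
        reasons = reasons.mask(reasons.isna() & mask.fillna(False), reason)

    if "EAF" in stats_df:
        maf = np.minimum(stats_df["EAF"], 1 - stats_df["EAF"])
        flag(maf < maf_min, "maf")
    if "HWE_P" in stats_df:
        flag(stats_df["HWE_P"] < hwe_p_min, "hwe")
    if "INFO" in stats_df:
        flag(stats_df["INFO"] < info_min, "info")
    if "CALL_RATE" in stats_df:
        flag(stats_df["CALL_RATE"] < call_rate_min, "call_rate")
    counts = reasons.value_counts()
    return stats_df[reasons.isna()].copy(), counts


# ---------------------------------------------------------------------------
# meta-analysis

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, nea: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == nea.upper()


def harmonize(
    reference: pd.DataFrame, other: pd.DataFrame, eaf_ambiguity: float = 0.08
) -> pd.DataFrame:
    """Align ``other`` to the reference effect/other allele orientation.

    Swapped alleles flip BETA and EAF; strand flips are resolved through
    allele complements; palindromic (A/T, C/G) variants are aligned by
    allele frequency when |EAF - 0.5| > ``eaf_ambiguity`` on both sides and
    dropped otherwise; irreconcilable variants are dropped.
    """
    ref = reference.set_index("SNP")
    rows = []
    for _, row in other.iterrows():
        snp = row["SNP"]
        if snp not in ref.index:
            continue
        r = ref.loc[snp]
        ea, nea = str(row["EA"]).upper(), str(row["NEA"]).upper()
        rea, rnea = str(r["EA"]).upper(), str(r["NEA"]).upper()
        row = row.copy()
        if _is_palindromic(ea, nea):
            if {ea, nea} != {rea, rnea}:
                continue
            if abs(row["EAF"] - 0.5) <= eaf_ambiguity or abs(r["EAF"] - 0.5) <= eaf_ambiguity:
                continue
            same = (ea == rea) == ((row["EAF"] > 0.5) == (r["EAF"] > 0.5))
            if not same:
                row["BETA"] = -row["BETA"]
                row["EAF"] = 1 - row["EAF"]
                row["EA"], row["NEA"] = rea, rnea
        elif (ea, nea) == (rea, rnea):
            pass
        elif (ea, nea) == (rnea, rea):
            row["BETA"] = -row["BETA"]
            row["EAF"] = 1 - row["EAF"]
            row["EA"], row["NEA"] = rea, rnea
        else:
            flip = (_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(nea, "?"))
            if flip == (rea, rnea):
                row["EA"], row["NEA"] = rea, rnea
            elif flip == (rnea, rea):
                row["BETA"] = -row["BETA"]
                row["EAF"] = 1 - row["EAF"]
                row["EA"], row["NEA"] = rea, rnea
            else:
                continue
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def meta_fixed(stats_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance weighted meta-analysis across cohorts.

    beta = sum(w_k b_k) / sum(w_k), w_k = se_k^-2; se = sum(w_k)^-1/2.
    Attaches Cochran's Q, I2 = max(0, (Q - df)/Q) * 100 and the
    heterogeneity p-value; N is summed over contributing cohorts and EAF is
    N-weighted.  Cohorts after the first are allele-harmonized to the first.
    """
    if not stats_list:
        raise ValueError("need at least one cohort")
    ref = stats_list[0]
    aligned = [ref] + [harmonize(ref, s) for s in stats_list[1:]]
    stacked = pd.concat(aligned, keys=range(len(aligned)), names=["cohort"])
    stacked = stacked.dropna(subset=["BETA", "SE"])
    g = stacked.groupby("SNP", sort=False)

    w = 1.0 / stacked["SE"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["BETA"], _wn=stacked["N"] * stacked["EAF"])
    agg = stacked.groupby("SNP", sort=False).agg(
        sw=("_w", "sum"),
        swb=("_wb", "sum"),
        n=("N", "sum"),
        wn=("_wn", "sum"),
        k=("BETA", "size"),
    )
    beta = agg["swb"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    # Cochran's Q = sum w_k (b_k - beta)^2
    stacked["_dev"] = stacked["_w"] * (stacked["BETA"] - beta.reindex(stacked["SNP"]).to_numpy()) ** 2
    q = stacked.groupby("SNP", sort=False)["_dev"].sum()
    df_ = agg["k"] - 1
    i2 = np.where(q > 0, np.maximum(0.0, (q - df_) / q) * 100.0, 0.0)
    het_p = np.where(df_ > 0, stats.chi2.sf(q, np.maximum(df_, 1)), np.nan)

    first = g.first()
    out = pd.DataFrame(
        {
            "SNP": agg.index,
            "CHR": first["CHR"].reindex(agg.index),
            "POS": first["POS"].reindex(agg.index),
            "EA": first["EA"].reindex(agg.index),
            "NEA": first["NEA"].reindex(agg.index),
            "EAF": agg["wn"] / agg["n"],
            "BETA": beta,
            "SE": se,
            "P": 2 * stats.norm.sf(np.abs(beta / se)),
            "N": agg["n"],
            "INFO": first["INFO"].reindex(agg.index) if "INFO" in first else 1.0,
            "Q": q,
            "I2": i2,
            "HET_P": het_p,
            "N_STUDIES": agg["k"],
        }
    ).reset_index(drop=True)
    return out


def filter_half_max_n(meta_stats: pd.DataFrame) -> pd.DataFrame:
    """Keep variants reported in at least half the maximum per-variant N."""
    cutoff = meta_stats["N"].max() / 2.0
    return meta_stats[meta_stats["N"] >= cutoff].copy()


def effective_n_gate(n_cases: int, n_controls: int, threshold: float = 100.0) -> bool:
    """Cohort inclusion gate for binary traits: effective sample size
    4 / (1/cases + 1/controls) must exceed ``threshold``."""
    if n_cases <= 0 or n_controls <= 0:
        return False
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return bool(n_eff > threshold)


def genomic_lambda(stats_df: pd.DataFrame) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549364
    (the null median of a 1-df chi-square)."""
    p = stats_df["P"].dropna().to_numpy()
    if len(p) == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


# ---------------------------------------------------------------------------
# loci, clumping, conditional selection


def define_loci(
    meta_stats: pd.DataFrame, window: int = 250_000, p_threshold: float = GWS_P
) -> pd.DataFrame:
    """Greedy locus definition: repeatedly take the smallest-p genome-wide
    significant variant, absorb everything within ``window`` bp on the same
    chromosome, and merge overlapping loci."""
    sig = meta_stats[meta_stats["P"] < p_threshold].copy()
    if sig.empty:
        return pd.DataFrame(columns=["locus", "CHR", "start", "end", "index_snp", "index_p"])
    sig = sig.sort_values(["P", "POS"], kind="mergesort")
    taken = np.zeros(len(sig), dtype=bool)
    loci = []
    chrom = sig["CHR"].to_numpy()
    pos = sig["POS"].to_numpy()
    for i in range(len(sig)):
        if taken[i]:
            continue
        absorb = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window) & ~taken
        taken |= absorb
        loci.append(
            {
                "CHR": chrom[i],
                "start": int(pos[i] - window),
                "end": int(pos[i] + window),
                "index_snp": sig["SNP"].iloc[i],
                "index_p": float(sig["P"].iloc[i]),
            }
        )
    # merge overlapping intervals on the same chromosome
    loci.sort(key=lambda d: (d["CHR"], d["start"]))
    merged = []
    for loc in loci:
        if merged and loc["CHR"] == merged[-1]["CHR"] and loc["start"] <= merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], loc["end"])
            if loc["index_p"] < prev["index_p"]:
                prev["index_snp"], prev["index_p"] = loc["index_snp"], loc["index_p"]
        else:
            merged.append(dict(loc))
    out = pd.DataFrame(merged)
    out.insert(0, "locus", np.arange(1, len(out) + 1))
    return out


def clump(
    stats_df: pd.DataFrame,
    ld: LDReference,
    r2: float = 0.001,
    kb: float = 1000,
    p1: float = GWS_P,
    p2: float = 1e-5,
) -> pd.DataFrame:
    """Greedy LD clumping with plink semantics.

    Index SNPs are chosen by ascending p among variants with P < p1;
    variants with P < p2 within ``kb`` kilobases and r^2 > ``r2`` of an
    index are assigned to that clump and removed from index candidacy.
    Variants absent from the LD reference are treated as unlinked.
    Ties on p are broken by smaller position.
    """
    cand = stats_df.dropna(subset=["P"]).copy()
    cand = cand.sort_values(["P", "POS"], kind="mergesort")
    in_play = cand[cand["P"] < p2].reset_index(drop=True)
    removed = np.zeros(len(in_play), dtype=bool)
    chrom = in_play["CHR"].to_numpy()
    pos = in_play["POS"].to_numpy()
    snps = in_play["SNP"].to_numpy()
    pvals = in_play["P"].to_numpy()
    index_rows = []
    for i in range(len(in_play)):
        if removed[i] or pvals[i] >= p1:
            continue
        removed[i] = True
        members = []
        near = np.flatnonzero(
            (~removed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= kb * 1000)
        )
        for j in near:
            if ld.r(snps[i], snps[j]) ** 2 > r2:
                removed[j] = True
                members.append(snps[j])
        row = in_play.iloc[i].to_dict()
        row["clump_members"] = ";".join(members)
        index_rows.append(row)
    return pd.DataFrame(index_rows).reset_index(drop=True)


def cojo_select(
    meta_stats: pd.DataFrame,
    ld: LDReference,
    p_threshold: float = GWS_P,
    collinearity_r2: float = 0.9,
    le_distance: float = 10e6,
    var_y: float | None = None,
    max_selected: int = 50,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Approximate stepwise conditional-and-joint selection from summary data.

    Forward selection: start from the smallest-p variant; at each step,
    compute every remaining candidate's effect conditional on the selected
    set through the joint model b_J = (V^1/2 R V^1/2 + ridge I)^-1 V b,
    where R is the reference LD matrix (variants more than ``le_distance``
    bp apart are taken as unlinked) and V the per-variant genotype
    variances; add the candidate with the smallest conditional p while it
    stays below ``p_threshold``.  Candidates with r^2 > ``collinearity_r2``
    to any selected variant are skipped.  Returns the selected variants
    with joint effects and conditional p-values.
    """
    dfc = meta_stats.dropna(subset=["BETA", "SE", "P"]).copy()
    dfc = dfc.sort_values(["P", "POS"], kind="mergesort").reset_index(drop=True)
    if dfc.empty or dfc["P"].iloc[0] >= p_threshold:
        return pd.DataFrame(columns=list(dfc.columns) + ["BETA_JOINT", "SE_JOINT", "P_JOINT"])

    snps = dfc["SNP"].to_numpy()
    betas = dfc["BETA"].to_numpy()
    ses = dfc["SE"].to_numpy()
    ns = dfc["N"].to_numpy().astype(float)
    pos = dfc["POS"].to_numpy().astype(float)
    chrom = dfc["CHR"].to_numpy()
    v = ld.variance_of(list(snps))
    eaf = dfc["EAF"].to_numpy()
    v = np.where(np.isnan(v), 2 * eaf * (1 - eaf), v)

    # phenotypic variance: median over variants of v_j (b_j^2 + n_j se_j^2)
    if var_y is None:
        var_y = float(np.median(v * (betas**2 + ns * ses**2)))
    n_med = float(np.median(ns))

    def _joint(sel: list[int]) -> tuple[np.ndarray, np.ndarray]:
        k = len(sel)
        r_mat = ld.submatrix([snps[i] for i in sel])
        # distance rule: unlinked beyond le_distance or across chromosomes
        for a in range(k):
            for b_ in range(a + 1, k):
                if chrom[sel[a]] != chrom[sel[b_]] or abs(pos[sel[a]] - pos[sel[b_]]) > le_distance:
                    r_mat[a, b_] = r_mat[b_, a] = 0.0
        sd = np.sqrt(v[sel])
        xtx = sd[:, None] * r_mat * sd[None, :] + ridge * np.eye(k)
        xty = v[sel] * betas[sel]
        try:
            bj = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"non-invertible LD matrix for selected set {[snps[i] for i in sel]}"
            ) from exc
        # residual variance: var(y)*(n-1) - b_J'X'y, on the covariance scale
        sigma2 = max(var_y - bj @ xty, var_y * 1e-6) * (n_med - 1)
        dof = max(n_med - k - 1, 1.0)
        se_j = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2 / ((n_med - 1) * dof))
        return bj, se_j

    selected = [0]
    while len(selected) < max_selected:
        best_j, best_p, best_fit = None, np.inf, None
        sel_set = set(selected)
        for j in range(len(dfc)):
            if j in sel_set or dfc["P"].iloc[j] >= 0.05:  # cheap candidate screen
                continue
            # collinearity guard
            r2s = [ld.r(snps[j], snps[i]) ** 2 for i in selected]
            if any(r > collinearity_r2 for r in r2s):
                continue
            trial = selected + [j]
            try:
                bj, se_j = _joint(trial)
            except np.linalg.LinAlgError:
                continue
            z = bj[-1] / se_j[-1]
            p_cond = 2 * stats.norm.sf(abs(z))
            if p_cond < best_p - 1e-300 or (
                p_cond == best_p and best_j is not None and pos[j] < pos[best_j]
            ):
                best_j, best_p, best_fit = j, p_cond, (bj, se_j)
        if best_j is None or best_p >= p_threshold:
            break
        selected.append(best_j)

    bj, se_j = _joint(selected)
    out = dfc.iloc[selected].copy()
    out["BETA_JOINT"] = bj
    out["SE_JOINT"] = se_j
    out["P_JOINT"] = 2 * stats.norm.sf(np.abs(bj / se_j))
    return out.sort_values(["CHR", "POS"]).reset_index(drop=True)
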