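"""Effect-origin dissection: MnT/MT/PT regression and five-cluster classification.

Per index SNP the linear model

    gestational duration ~ MnT + MT + PT + covariates

yields a triplet (b_MnT, b_MT, b_PT).  A maternal-only effect m shows up as
(m, m, 0), a fetal-only effect f as (0, f, f), a fetal effect limited to the
maternally transmitted allele as (0, f, 0), and joint maternal+fetal effects
as (m, m+f, f) with concordant or discordant signs.  SNPs are classified by
a Gaussian mixture whose component means are constrained to these patterns:
the latent effect magnitudes carry zero-mean Gaussian priors with
cluster-level variances estimated by EM, the per-SNP observation noise is
the diagonal of squared standard errors, and the sign-constrained clusters
(both_same / both_opposite) restrict the (m, f) prior to the matching sign
quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

CLUSTERS = ("maternal_only", "fetal_only", "fetal_poe_mt", "both_same", "both_opposite")

_A_MATERNAL = np.array([1.0, 1.0, 0.0])
_A_FETAL = np.array([0.0, 1.0, 1.0])
_A_POE = np.array([0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# per-SNP regression and pooling


def fit_trio_regression(
    dosages, phenotype: np.ndarray, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """OLS fit of phenotype on (MnT, MT, PT, covariates) for every SNP.

    ``dosages`` is a :class:`~matfet.trio_alleles.TrioDosage`.  Non-estimable
    SNPs (zero variance in an allele column after complete-case filtering)
    get NaN estimates and ``estimable = False``.
    """
    from .trio_alleles import build_design

    y_all = np.asarray(phenotype, dtype=np.float64)
    rows = []
    for j in range(dosages.n_snps):
        x, keep, meta = build_design(dosages, j, covariates)
        rec = {
            "SNP": dosages.variants["SNP"].iloc[j],
            "beta_mnt": np.nan, "beta_mt": np.nan, "beta_pt": np.nan,
            "se_mnt": np.nan, "se_mt": np.nan, "se_pt": np.nan,
            "n": int(keep.sum()), "estimable": meta["estimable"],
        }
        if meta["estimable"] and keep.sum() > x.shape[1] + 1:
            y = y_all[keep]
            xtx = x.T @ x
            try:
                xtx_inv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                rec["estimable"] = False
                rows.append(rec)
                continue
            b = xtx_inv @ (x.T @ y)
            resid = y - x @ b
            sigma2 = resid @ resid / (len(y) - x.shape[1])
            se = np.sqrt(np.diag(xtx_inv) * sigma2)
            rec.update(
                beta_mnt=b[0], beta_mt=b[1], beta_pt=b[2],
                se_mnt=se[0], se_mt=se[1], se_pt=se[2],
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def meta_trio_effects(estimates_by_cohort: list[pd.DataFrame]) -> pd.DataFrame:
    """Component-wise fixed-effect IVW pooling of per-cohort MnT/MT/PT
    estimates (delegates to :func:`matfet.assoc_meta.meta_fixed`)."""
    from .assoc_meta import meta_fixed

    parts = {}
    for comp in ("mnt", "mt", "pt"):
        cohort_frames = []
        for est in estimates_by_cohort:
            ok = est[est["estimable"]]
            cohort_frames.append(
                pd.DataFrame(
                    {
                        "SNP": ok["SNP"], "CHR": 0, "POS": 0, "EA": "A", "NEA": "G",
                        "EAF": 0.5, "BETA": ok[f"beta_{comp}"], "SE": ok[f"se_{comp}"],
                        "P": 1.0, "N": ok["n"], "INFO": 1.0,
                    }
                )
            )
        parts[comp] = meta_fixed(cohort_frames).set_index("SNP")
    snps = parts["mnt"].index
    out = pd.DataFrame({"SNP": snps})
    for comp in ("mnt", "mt", "pt"):
        out[f"beta_{comp}"] = parts[comp]["BETA"].reindex(snps).to_numpy()
        out[f"se_{comp}"] = parts[comp]["SE"].reindex(snps).to_numpy()
    out["n"] = parts["mnt"]["N"].reindex(snps).to_numpy()
    out["estimable"] = True
    return out


def align_signs(estimates: pd.DataFrame, reference: str = "beta_mt") -> pd.DataFrame:
    """Flip each SNP's effect alleles so the maternal-side reference effect
    (default: the maternally transmitted allele, present in both genomes)
    is non-negative.  Involution: applying twice equals applying once."""
    out = estimates.copy()
    flip = out[reference].to_numpy() < 0
    for col in ("beta_mnt", "beta_mt", "beta_pt"):
        out[col] = np.where(flip, -out[col], out[col])
    out["sign_flipped"] = flip
    return out


# ---------------------------------------------------------------------------
# constrained-mean Gaussian mixture


def _phi2(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k) at correlation rho,
    via Owen's T (vectorized)."""
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    denom = np.sqrt(1.0 - rho**2)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    delta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    out = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - delta
    )
    return np.clip(out, 0.0, 1.0)


def _orthant_same_sign(mu1, mu2, s1, s2, rho):
    """P(X > 0, Y > 0) + P(X < 0, Y < 0) for bivariate normal with means
    mu, standard deviations s and correlation rho."""
    h1, h2 = mu1 / s1, mu2 / s2
    return _phi2(h1, h2, rho) + _phi2(-h1, -h2, rho)


@dataclass
class MixtureFit:
    """Fitted mixture: per-SNP cluster posteriors plus hyperparameters."""

    posteriors: pd.DataFrame  # SNP + one probability column per cluster
    weights: dict[str, float]
    tau2: dict[str, tuple]
    log_likelihood: float
    converged: bool

    def assignments(self) -> pd.DataFrame:
        probs = self.posteriors[list(CLUSTERS)].to_numpy()
        top = probs.argmax(axis=1)
        out = self.posteriors.copy()
        out["top_class"] = [CLUSTERS[i] for i in top]
        out["top_prob"] = probs.max(axis=1)
        return out


def _single_loglik_and_moments(y, s2, a, tau2):
    """Marginal log-density of y ~ N(0, tau2 a a' + diag(s2)) and posterior
    (mean, var) of the latent magnitude, vectorized over SNPs."""
    u = (y * a / s2).sum(axis=1)
    q = (a**2 / s2).sum(axis=1)
    yy = (y**2 / s2).sum(axis=1)
    logdet = np.log(s2).sum(axis=1) + np.log1p(tau2 * q)
    quad = yy - tau2 * u**2 / (1.0 + tau2 * q)
    ll = -0.5 * (3 * np.log(2 * np.pi) + logdet + quad)
    post_var = 1.0 / (q + 1.0 / tau2)
    post_mean = post_var * u
    return ll, post_mean, post_var


def _double_loglik_and_moments(y, s2, tau2_m, tau2_f, same_sign: bool):
    """Marginal log-density for the two-effect clusters with the (m, f)
    prior truncated to same-sign or opposite-sign quadrants, plus the
    untruncated posterior moments used in the M-step."""
    a1, a2 = _A_MATERNAL, _A_FETAL
    b1 = (y * a1 / s2).sum(axis=1)
    b2 = (y * a2 / s2).sum(axis=1)
    q11 = (a1**2 / s2).sum(axis=1) + 1.0 / tau2_m
    q22 = (a2**2 / s2).sum(axis=1) + 1.0 / tau2_f
    q12 = (a1 * a2 / s2).sum(axis=1)
    det_m = q11 * q22 - q12**2
    yy = (y**2 / s2).sum(axis=1)
    # posterior cov = M^-1, mean = M^-1 b
    c11 = q22 / det_m
    c22 = q11 / det_m
    c12 = -q12 / det_m
    mu1 = c11 * b1 + c12 * b2
    mu2 = c12 * b1 + c22 * b2
    quad = yy - (b1 * mu1 + b2 * mu2)
    logdet = np.log(s2).sum(axis=1) + np.log(tau2_m) + np.log(tau2_f) + np.log(det_m)
    ll_full = -0.5 * (3 * np.log(2 * np.pi) + logdet + quad)
    s1 = np.sqrt(c11)
    s2_ = np.sqrt(c22)
    rho = c12 / (s1 * s2_)
    p_same = _orthant_same_sign(mu1, mu2, s1, s2_, rho)
    p_region = p_same if same_sign else 1.0 - p_same
    # prior mass of the region is 1/2 by symmetry of the zero-mean prior
    ll = ll_full + np.log(np.clip(p_region, 1e-300, 1.0)) - np.log(0.5)
    return ll, (mu1, mu2, c11, c22)


def cluster_effect_origin(
    estimates: pd.DataFrame,
    n_restarts: int = 50,
    max_iter: int = 200,
    tol: float = 1e-8,
    fix_uniform_weights: bool = False,
    weight_prior_count: float = 1.0,
    seed: int = 7,
) -> MixtureFit:
    """Classify SNPs into the five effect-origin clusters.

    EM over mixture weights and the cluster-level prior variances of the
    latent maternal/fetal magnitudes, with ``n_restarts`` deterministic
    random restarts; posterior cluster probabilities are returned per SNP.
    Estimates should be sign-aligned first (:func:`align_signs`) for
    plotting parity, though classification itself is sign-symmetric.
    """
    est = estimates[estimates["estimable"]] if "estimable" in estimates else estimates
    if len(est) < 2:
        raise ValueError("need at least 2 SNPs to share mixture hyperparameters")
    y = est[["beta_mnt", "beta_mt", "beta_pt"]].to_numpy(dtype=np.float64)
    s2 = est[["se_mnt", "se_mt", "se_pt"]].to_numpy(dtype=np.float64) ** 2
    scale = max(float(np.median(y**2)), float(np.median(s2)))
    # weak inverse-gamma hyperprior on every tau^2 (one pseudo-SNP at the
    # data scale).  This is the standard guard against variance collapse in
    # EM and, here, breaks the ridge where a two-effect cluster with its
    # fetal variance driven to zero becomes indistinguishable from the
    # maternal-only cluster: the collapsed solution pays the Occam factor.
    prior_a = 1.0
    prior_b = scale
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        tau = {
            "maternal_only": scale * rng.uniform(0.2, 5.0),
            "fetal_only": scale * rng.uniform(0.2, 5.0),
            "fetal_poe_mt": scale * rng.uniform(0.2, 5.0),
            "both_same": (scale * rng.uniform(0.2, 5.0), scale * rng.uniform(0.2, 5.0)),
            "both_opposite": (scale * rng.uniform(0.2, 5.0), scale * rng.uniform(0.2, 5.0)),
        }
        w = np.full(5, 0.2)
        prev_ll = -np.inf
        converged = False
        for _it in range(max_iter):
            lls = np.empty((len(est), 5))
            moments = {}
            lls[:, 0], m_mean, m_var = _single_loglik_and_moments(
                y, s2, _A_MATERNAL, tau["maternal_only"]
            )
            moments["maternal_only"] = (m_mean, m_var)
            lls[:, 1], f_mean, f_var = _single_loglik_and_moments(
                y, s2, _A_FETAL, tau["fetal_only"]
            )
            moments["fetal_only"] = (f_mean, f_var)
            lls[:, 2], p_mean, p_var = _single_loglik_and_moments(
                y, s2, _A_POE, tau["fetal_poe_mt"]
            )
            moments["fetal_poe_mt"] = (p_mean, p_var)
            lls[:, 3], mom_s = _double_loglik_and_moments(
                y, s2, tau["both_same"][0], tau["both_same"][1], True
            )
            moments["both_same"] = mom_s
            lls[:, 4], mom_o = _double_loglik_and_moments(
                y, s2, tau["both_opposite"][0], tau["both_opposite"][1], False
            )
            moments["both_opposite"] = mom_o

            logw = np.log(np.clip(w, 1e-300, 1.0))
            joint = lls + logw[None, :]
            norm = special.logsumexp(joint, axis=1)
            gamma = np.exp(joint - norm[:, None])
            ll_total = float(norm.sum())

            if not fix_uniform_weights:
                # Dirichlet-MAP with a small pseudo-count per cluster keeps
                # components from dying of weight feedback
                w = (gamma.sum(axis=0) + weight_prior_count) / (
                    len(est) + 5 * weight_prior_count
                )
            gsum = gamma.sum(axis=0)

            def _tau_map(ss: float, g: float) -> float:
                # MAP update under inverse-gamma(prior_a, prior_b)
                return (ss + 2 * prior_b) / (g + 2 * (prior_a + 1))

            for i, name in enumerate(("maternal_only", "fetal_only", "fetal_poe_mt")):
                mean, var = moments[name]
                tau[name] = _tau_map(
                    float((gamma[:, i] * (mean**2 + var)).sum()), gsum[i]
                )
            for i, name in ((3, "both_same"), (4, "both_opposite")):
                mu1, mu2, c11, c22 = moments[name]
                tau[name] = (
                    _tau_map(float((gamma[:, i] * (mu1**2 + c11)).sum()), gsum[i]),
                    _tau_map(float((gamma[:, i] * (mu2**2 + c22)).sum()), gsum[i]),
                )

            if abs(ll_total - prev_ll) < tol * (1 + abs(ll_total)):
                converged = True
                break
            prev_ll = ll_total

        def _log_ig(t2: float) -> float:
            return -(prior_a + 1) * np.log(t2) - prior_b / t2

        penalized = ll_total + sum(
            _log_ig(t) for v in tau.values() for t in (v if isinstance(v, tuple) else (v,))
        )
        if best is None or penalized > best[0]:
            best = (penalized, gamma, dict(w=w.copy()), dict(tau), converged, ll_total)

    _, gamma, wdict, tau, converged, ll_total = best
    posteriors = pd.DataFrame({"SNP": est["SNP"].to_numpy()})
    for i, name in enumerate(CLUSTERS):
        posteriors[name] = gamma[:, i]
    return MixtureFit(
        posteriors=posteriors,
        weights={name: float(wdict["w"][i]) for i, name in enumerate(CLUSTERS)},
        tau2=tau,
        log_likelihood=ll_total,
        converged=converged,
    )


def classify(fit: MixtureFit, min_prob: float = 0.5) -> pd.DataFrame:
    """Label each SNP by its highest-probability cluster; labels whose top
    probability falls below ``min_prob`` are flagged low-confidence."""
    out = fit.assignments()
    out["low_confidence"] = out["top_prob"] < min_prob
    return out


def export_heatmap_matrix(estimates: pd.DataFrame) -> pd.DataFrame:
    """SNP x (MnT, MT, PT) effect matrix, sign-aligned, for heatmap plotting."""
    aligned = align_signs(estimates)
    return aligned.set_index("SNP")[["beta_mnt", "beta_mt", "beta_pt"]].rename(
        columns={"beta_mnt": "MnT", "beta_mt": "MT", "beta_pt": "PT"}
    )
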