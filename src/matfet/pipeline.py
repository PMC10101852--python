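"""End-to-end pipeline: simulate -> phenotype -> GWAS/meta -> loci/COJO ->
trio effect origin -> LDSC/coloc/conditioning -> MR -> PGS.

`run_pipeline` chains the stages on synthetic data with a single seed, writes
tab-delimited artifacts plus a JSON manifest (per-stage row counts, config
echo, seed) into an output directory, and returns the in-memory results.
Stages can be toggled off; later stages that need a disabled stage's output
are skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc_meta, effect_origin, mr, pgs, pheno, simdata, sumstat_models
from .trio_alleles import resolve_trioset

ALL_STAGES = (
    "simulate", "pheno", "gwas_meta", "loci_cojo", "effect_origin",
    "ldsc", "coloc", "condition", "mr", "pgs",
)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults give the 5,000-trio demo."""

    n_trios: int = 5000
    n_snps: int = 2000
    n_cohorts: int = 3
    seed: int = 1
    out_dir: str = "matfet_run"
    stages: tuple[str, ...] = ALL_STAGES
    architecture: dict = field(default_factory=dict)  # ArchitectureConfig overrides
    gws_p: float = 5e-8
    index_p: float = 1e-4  # demo-scale index-SNP threshold for trio follow-up

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a dict of per-stage results."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    results: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
    }

    def _log(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2), **counts}

    arch = simdata.ArchitectureConfig(
        n_snps=config.n_snps, seed=config.seed, **config.architecture
    )

    if "simulate" in stages:
        pool = simdata.simulate_haplotype_panel(arch, n_haplotypes=4000)
        trios = simdata.simulate_trios(pool, config.n_trios, seed=config.seed + 1)
        truth = simdata.simulate_truth(arch, pool.variants)
        phenos = simdata.simulate_phenotypes(trios, truth, arch)
        ld = simdata.ld_reference_from_pool(pool)
        results.update(pool=pool, trios=trios, truth=truth, phenos=phenos, ld=ld)
        truth.to_csv(out_dir / "truth_manifest.tsv", sep="\t", index=False)
        phenos.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
        _log("simulate", n_trios=trios.n_trios, n_snps=trios.n_snps)

    if "pheno" in stages and "phenos" in results:
        rec = results["phenos"].copy()
        eligible, excl = pheno.filter_eligible(rec)
        labels = pheno.label_preterm(eligible)
        results["eligible"] = eligible
        results["preterm_labels"] = labels
        excl.rename("count").to_csv(out_dir / "exclusions.tsv", sep="\t")
        _log("pheno", n_in=len(rec), n_eligible=len(eligible),
             n_preterm_cases=int((labels == 1).sum()))

    if "gwas_meta" in stages and "trios" in results:
        trios, phenos_df, truth = results["trios"], results["phenos"], results["truth"]
        cohorts = simdata.split_cohorts(trios, phenos_df, config.n_cohorts, seed=config.seed + 2)
        covs = ["PC1", "PC2"]
        cohort_stats = []
        for ctrios, cphen in cohorts:
            stats_c = assoc_meta.run_gwas(
                ctrios.mother_dosage().astype(float),
                cphen["gestational_duration"].to_numpy(),
                covariates=cphen[covs].to_numpy(),
                variants=ctrios.variants,
            )
            stats_c, _ = assoc_meta.qc_cohort(stats_c)
            cohort_stats.append(stats_c)
        meta = assoc_meta.meta_fixed(cohort_stats)
        meta = assoc_meta.filter_half_max_n(meta)
        lam = assoc_meta.genomic_lambda(meta)
        meta = meta.sort_values(["CHR", "POS"]).reset_index(drop=True)
        results.update(cohort_stats=cohort_stats, meta=meta, genomic_lambda=lam)
        meta.to_csv(out_dir / "meta_gd.tsv", sep="\t", index=False)
        _log("gwas_meta", n_cohorts=len(cohorts), n_variants=len(meta),
             genomic_lambda=round(lam, 4))

    if "loci_cojo" in stages and "meta" in results:
        meta, ld = results["meta"], results["ld"]
        loci = assoc_meta.define_loci(meta, p_threshold=config.gws_p)
        sig = meta[meta["P"] < config.index_p]
        cojo = (
            assoc_meta.cojo_select(sig, ld, p_threshold=config.index_p)
            if not sig.empty
            else sig.assign(BETA_JOINT=[], SE_JOINT=[], P_JOINT=[])
        )
        index_snps = cojo["SNP"].tolist()
        results.update(loci=loci, cojo=cojo, index_snps=index_snps)
        loci.to_csv(out_dir / "loci.tsv", sep="\t", index=False)
        cojo.to_csv(out_dir / "cojo.tsv", sep="\t", index=False)
        _log("loci_cojo", n_loci=len(loci), n_index_snps=len(index_snps))

    if "effect_origin" in stages and "trios" in results:
        trios, phenos_df = results["trios"], results["phenos"]
        # follow up index SNPs when available, else all truly causal SNPs
        truth = results["truth"]
        snps = results.get("index_snps") or truth.loc[
            truth["true_class"] != "null", "SNP"
        ].tolist()
        if len(snps) >= 2:
            keep = trios.variants["SNP"].isin(snps).to_numpy()
            dos = resolve_trioset(trios)
            sub = type(dos)(
                mnt=dos.mnt[:, keep], mt=dos.mt[:, keep], pt=dos.pt[:, keep],
                variants=trios.variants[keep].reset_index(drop=True),
                flagged=dos.flagged[:, keep],
            )
            est = effect_origin.fit_trio_regression(
                sub, phenos_df["gestational_duration"].to_numpy(),
                covariates=phenos_df[["PC1", "PC2"]].to_numpy(),
            )
            est = effect_origin.align_signs(est)
            fit = effect_origin.cluster_effect_origin(est, n_restarts=10)
            labels = effect_origin.classify(fit)
            results.update(trio_estimates=est, cluster_fit=fit, cluster_labels=labels)
            est.to_csv(out_dir / "trio_effects.tsv", sep="\t", index=False)
            labels.to_csv(out_dir / "effect_origin.tsv", sep="\t", index=False)
            _log("effect_origin", n_snps=len(est),
                 n_confident=int((~labels["low_confidence"]).sum()))

    if "ldsc" in stages and "ld" in results:
        ld = results["ld"]
        ld_scores = pd.DataFrame({"SNP": ld.variants["SNP"], "L2": ld.ld_scores()})
        stats_a, stats_b = simdata.simulate_sumstats_pair(
            ld, h2_a=0.3, h2_b=0.3, rg=0.5, n_a=20000, n_b=20000, seed=config.seed + 3
        )
        h2 = sumstat_models.ldsc_h2(stats_a, ld_scores, n_blocks=50)
        rg = sumstat_models.ldsc_rg(stats_a, stats_b, ld_scores, n_blocks=50)
        results.update(ldsc_h2=h2, ldsc_rg=rg, ld_scores=ld_scores)
        _log("ldsc", h2=round(h2.h2, 4), rg=round(rg.rg, 4) if rg.rg == rg.rg else None)

    if "coloc" in stages and "meta" in results:
        meta, ld = results["meta"], results["ld"]
        top = meta.nsmallest(1, "P")
        if not top.empty:
            block = ld.variants.loc[
                ld.variants["SNP"] == top["SNP"].iloc[0], "block"
            ].iloc[0]
            region_snps = ld.variants.loc[ld.variants["block"] == block, "SNP"]
            region = meta[meta["SNP"].isin(region_snps)]
            if len(region) >= 2:
                coloc = sumstat_models.coloc_abf(
                    region.rename(columns={"BETA": "BETA", "SE": "SE"}),
                    region,  # self-colocalization demo: shared signal
                )
                results["coloc"] = coloc
                _log("coloc", n_variants=coloc.n_variants, pp4=round(coloc.pp4, 4))

    if "condition" in stages and "trios" in results:
        # GD and BW maternal GWAS; condition BW on GD
        trios, phenos_df = results["trios"], results["phenos"]
        g = trios.mother_dosage().astype(float)
        covs = phenos_df[["PC1", "PC2"]].to_numpy()
        gd_stats = assoc_meta.run_gwas(
            g, phenos_df["gestational_duration"].to_numpy(), covs, trios.variants
        )
        bw_stats = assoc_meta.run_gwas(
            g, phenos_df["birth_weight"].to_numpy(), covs, trios.variants
        )
        instruments = sumstat_models.select_region_lead_snps(gd_stats, p_threshold=1e-4)
        if len(instruments) >= 3:
            conditioned, b_xy = sumstat_models.mtcojo_condition(
                bw_stats, gd_stats, instruments
            )
            lead_bw = sumstat_models.select_region_lead_snps(bw_stats, p_threshold=1e-4)
            att = (
                sumstat_models.effect_attenuation(bw_stats, conditioned, lead_bw)
                if lead_bw
                else None
            )
            results.update(bw_conditioned=conditioned, b_xy_gd_bw=b_xy, attenuation=att)
            _log("condition", b_xy=round(b_xy, 4),
                 median_attenuation=round(att["median"], 4) if att else None)

    if "mr" in stages and "trio_estimates" in results:
        trios, phenos_df = results["trios"], results["phenos"]
        est_gd = results["trio_estimates"]
        keep = trios.variants["SNP"].isin(est_gd["SNP"]).to_numpy()
        dos = resolve_trioset(trios)
        sub = type(dos)(
            mnt=dos.mnt[:, keep], mt=dos.mt[:, keep], pt=dos.pt[:, keep],
            variants=trios.variants[keep].reset_index(drop=True),
            flagged=dos.flagged[:, keep],
        )
        est_bw = effect_origin.fit_trio_regression(
            sub, phenos_df["birth_weight"].to_numpy(),
            covariates=phenos_df[["PC1", "PC2"]].to_numpy(),
        )
        bw_fetal = pd.DataFrame(
            {"SNP": est_bw["SNP"], "beta": est_bw["beta_pt"], "se": est_bw["se_pt"]}
        )
        if len(est_gd) >= 2:
            xg = {
                ch: mr.crossgenome_ivw(est_gd, bw_fetal, channel=ch)
                for ch in mr.CHANNELS
            }
            results["crossgenome"] = xg
            _log("mr", **{ch: round(r.slope, 3) for ch, r in xg.items()})

    if "pgs" in stages and "meta" in results:
        trios, phenos_df, ld = results["trios"], results["phenos"], results["ld"]
        n = trios.n_trios
        train_idx, valid_idx = pgs.train_validation_split(n, seed=config.seed + 4)
        g = trios.mother_dosage().astype(float)
        y = phenos_df["gestational_duration"].to_numpy()
        try:
            weights = pgs.build_ct(
                results["meta"], ld, g[train_idx], trios.variants, y[train_idx],
                p_grid=(config.gws_p, 1e-5, 1e-3, 0.05),
            )
            s = pgs.score(weights, g[valid_idx], trios.variants)
            quant = pgs.validate_quantitative(
                s, y[valid_idx], covariates=phenos_df[["PC1", "PC2"]].to_numpy()[valid_idx]
            )
            labels = pheno.dichotomize_for_validation(phenos_df.iloc[valid_idx]).to_numpy(dtype=float)
            binary = None
            if np.nansum(labels == 1) >= 10 and np.nansum(labels == 0) >= 10:
                # a GD-increasing score protects against preterm delivery:
                # match direction so the score points toward preterm risk
                binary = pgs.validate_binary(-s, labels, n_boot=500, seed=config.seed)
            results.update(pgs_weights=weights, pgs_quant=quant, pgs_binary=binary)
            weights.table.to_csv(out_dir / "pgs_weights.tsv", sep="\t", index=False)
            _log("pgs", n_weights=len(weights.table), r2=round(quant["r2"], 4),
                 auc=round(binary["auc"], 4) if binary else None)
        except ValueError as exc:
            _log("pgs", skipped=str(exc))

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
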