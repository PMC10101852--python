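"""Resolve phased trio/duo genotypes into MnT / MT / PT allele dosages.

For a phased mother-father-child trio, each bi-allelic SNP contributes three
resolvable allele slots: the maternal transmitted allele (MT, present in
both maternal and fetal genomes), the maternal nontransmitted allele (MnT,
maternal genome only) and the paternal transmitted allele (PT, fetal genome
only).  By construction MnT + MT equals the maternal genotype dosage and
MT + PT the child's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import PhasedTrioSet


@dataclass
class TrioDosage:
    """Per-sample, per-SNP effect-allele counts on the three resolvable
    slots; NaN marks sites flagged as Mendelian-inconsistent or missing."""

    mnt: np.ndarray
    mt: np.ndarray
    pt: np.ndarray
    variants: pd.DataFrame
    flagged: np.ndarray  # boolean (n_samples, n_snps)

    @property
    def n_samples(self) -> int:
        return self.mnt.shape[0]

    @property
    def n_snps(self) -> int:
        return self.mnt.shape[1]


def resolve_trio(
    mother_haps: tuple[np.ndarray, np.ndarray],
    father_haps: tuple[np.ndarray, np.ndarray],
    child_haps: tuple[np.ndarray, np.ndarray],
    transmission: dict | None = None,
    variants: pd.DataFrame | None = None,
) -> TrioDosage:
    """Resolve MnT/MT/PT from phased haplotypes.

    ``child_haps`` is (maternal-origin hap, paternal-origin hap).  When
    ``transmission`` provides ``mat_transmitted`` (index 0/1 of the
    transmitted maternal haplotype) MnT is read off directly; otherwise it
    is inferred by matching the child's maternal-origin haplotype against
    the mother's two haplotypes, flagging Mendelian-inconsistent sites
    (child allele matching neither maternal haplotype) as missing.
    """
    m1, m2 = (np.asarray(h, dtype=np.float64) for h in mother_haps)
    f1, f2 = (np.asarray(h, dtype=np.float64) for h in father_haps)
    c_mat, c_pat = (np.asarray(h, dtype=np.float64) for h in child_haps)

    mt = c_mat.copy()
    pt = c_pat.copy()
    flagged = np.zeros(mt.shape, dtype=bool)

    if transmission is not None and "mat_transmitted" in transmission:
        t = np.asarray(transmission["mat_transmitted"]).reshape(-1, 1)
        mnt = np.where(t == 0, m2, m1)
        flagged |= np.where(t == 0, m1, m2) != c_mat
    else:
        # per-site inference: the transmitted maternal hap is whichever
        # matches the child's maternal-origin allele (either at heterozygous
        # consistent sites).
        match1 = m1 == c_mat
        match2 = m2 == c_mat
        mnt = np.where(match1, m2, m1)
        flagged |= ~(match1 | match2)

    # paternal-side Mendelian check
    flagged |= (f1 != c_pat) & (f2 != c_pat)

    mnt = np.where(flagged, np.nan, mnt)
    mt = np.where(flagged, np.nan, mt)
    pt = np.where(flagged, np.nan, pt)
    if variants is None:
        variants = pd.DataFrame({"SNP": [f"v{i}" for i in range(mt.shape[1])]})
    return TrioDosage(mnt=mnt, mt=mt, pt=pt, variants=variants, flagged=flagged)


def resolve_duo(
    mother_haps: tuple[np.ndarray, np.ndarray],
    child_haps: tuple[np.ndarray, np.ndarray],
    child_maternal_hap_index: np.ndarray | int | None = None,
    variants: pd.DataFrame | None = None,
) -> TrioDosage:
    """Mother-child duo: the child's non-maternal haplotype is taken as the
    paternal transmitted allele.  The maternal-origin annotation must come
    from upstream phasing; no statistical re-inference is attempted."""
    if child_maternal_hap_index is None:
        raise ValueError(
            "duo resolution requires the child's maternal-origin haplotype index"
        )
    c1, c2 = (np.asarray(h, dtype=np.float64) for h in child_haps)
    idx = np.asarray(child_maternal_hap_index).reshape(-1, 1)
    c_mat = np.where(idx == 0, c1, c2)
    c_pat = np.where(idx == 0, c2, c1)
    m1, m2 = (np.asarray(h, dtype=np.float64) for h in mother_haps)

    match1 = m1 == c_mat
    match2 = m2 == c_mat
    mnt = np.where(match1, m2, m1)
    flagged = ~(match1 | match2)
    mnt = np.where(flagged, np.nan, mnt)
    mt = np.where(flagged, np.nan, c_mat)
    pt = np.where(flagged, np.nan, c_pat)
    if variants is None:
        variants = pd.DataFrame({"SNP": [f"v{i}" for i in range(mt.shape[1])]})
    return TrioDosage(mnt=mnt, mt=mt, pt=pt, variants=variants, flagged=flagged)


def resolve_trioset(trios: PhasedTrioSet) -> TrioDosage:
    """Convenience: resolve a simulated :class:`PhasedTrioSet` (which carries
    its transmission record) into MnT/MT/PT dosages."""
    return resolve_trio(
        (trios.mother_h1, trios.mother_h2),
        (trios.father_h1, trios.father_h2),
        (trios.child_maternal_hap(), trios.child_paternal_hap()),
        transmission={"mat_transmitted": trios.mat_transmitted},
        variants=trios.variants,
    )


def build_design(
    dosages: TrioDosage, snp_index: int, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Design matrix for one SNP: columns (MnT, MT, PT, covariates..., 1).

    Flagged/missing samples are dropped site-wise (complete cases).  Returns
    (X, keep_mask, meta); ``meta['estimable']`` is False when any allele
    column has zero variance (e.g. monomorphic SNP).
    """
    cols = np.column_stack(
        [dosages.mnt[:, snp_index], dosages.mt[:, snp_index], dosages.pt[:, snp_index]]
    )
    keep = ~np.isnan(cols).any(axis=1)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep &= ~np.isnan(covariates).any(axis=1)
        x = np.column_stack(
            [cols[keep], covariates[keep], np.ones(int(keep.sum()))]
        )
    else:
        x = np.column_stack([cols[keep], np.ones(int(keep.sum()))])
    estimable = bool(np.all(cols[keep].std(axis=0) > 0)) if keep.any() else False
    names = ["MnT", "MT", "PT"]
    if covariates is not None:
        names += [f"cov{i}" for i in range(covariates.shape[1])]
    names += ["intercept"]
    return x, keep, {"estimable": estimable, "columns": names}
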