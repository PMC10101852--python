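"""File formats: summary statistics (tab-delimited), phased VCF, phenotypes.

Coordinates are 1-based inclusive everywhere (VCF convention).  Summary
statistics use the header set {SNP, CHR, POS, EA, NEA, EAF, BETA, SE, P, N,
INFO}; common synonyms are mapped on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import PhasedTrioSet

_SYNONYMS = {
    "SNP": ["SNP", "RSID", "ID", "MARKERNAME", "VARIANT_ID"],
    "CHR": ["CHR", "CHROM", "CHROMOSOME"],
    "POS": ["POS", "BP", "POSITION", "BASE_PAIR_LOCATION"],
    "EA": ["EA", "ALT", "A1", "EFFECT_ALLELE"],
    "NEA": ["NEA", "REF", "A2", "OTHER_ALLELE", "NON_EFFECT_ALLELE"],
    "EAF": ["EAF", "AF", "FREQ", "EFFECT_ALLELE_FREQUENCY", "MAF"],
    "BETA": ["BETA", "B", "EFFECT", "EFFECT_SIZE"],
    "SE": ["SE", "STDERR", "STANDARD_ERROR"],
    "P": ["P", "PVAL", "PVALUE", "P_VALUE"],
    "N": ["N", "NSAMPLES", "SAMPLE_SIZE"],
    "INFO": ["INFO", "IMPINFO", "IMPUTATION_INFO", "R2HAT"],
}
_MANDATORY = ("SNP", "CHR", "POS", "EA", "NEA", "BETA", "SE", "P")


def read_sumstats(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a tab-delimited (optionally gzipped) summary-statistic table,
    mapping column synonyms onto the canonical header set and checking that
    p-values are consistent with beta/se under the normal approximation."""
    df = pd.read_csv(path, sep="\t", comment="#")
    upper = {c.upper(): c for c in df.columns}
    rename = {}
    for canon, names in _SYNONYMS.items():
        for cand in names:
            if cand in upper:
                rename[upper[cand]] = canon
                break
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if "N" not in df:
        df["N"] = np.nan
    if "INFO" not in df:
        df["INFO"] = 1.0
    if "EAF" not in df:
        df["EAF"] = np.nan
    if validate:
        from scipy import stats as st

        with np.errstate(divide="ignore", invalid="ignore"):
            p_expect = 2 * st.norm.sf(np.abs(df["BETA"] / df["SE"]))
        ok = np.isfinite(p_expect) & np.isfinite(df["P"])
        rel = np.abs(df["P"][ok] - p_expect[ok]) / np.maximum(p_expect[ok], 1e-300)
        n_bad = int((rel > 1e-3).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} variants with P inconsistent with BETA/SE (>1e-3 relative)"
            )
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phased VCF


def write_phased_vcf(trios: PhasedTrioSet, path: str | Path) -> None:
    """Write trio genotypes as VCF v4.2 with '|'-phased GT fields.

    Samples are named FID_M / FID_F / FID_C per family.  The child's first
    GT allele is the maternal-origin haplotype, recorded by the header
    metadata line ``childHaplotypeOrder=maternal,paternal`` (MO=1
    convention).
    """
    path = Path(path)
    v = trios.variants
    c_mat = trios.child_maternal_hap()
    c_pat = trios.child_paternal_hap()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=matfet.simdata\n")
        fh.write("##MO=1\n")
        fh.write("##childHaplotypeOrder=maternal,paternal\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={int(v['CHR'].iloc[0])}>\n")
        samples = []
        for fid in trios.family_ids:
            samples += [f"{fid}_M", f"{fid}_F", f"{fid}_C"]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(trios.n_snps):
            # EA is written as ALT; haplotype value 1 = effect allele
            fields = [
                str(int(v["CHR"].iloc[j])), str(int(v["POS"].iloc[j])), str(v["SNP"].iloc[j]),
                str(v["NEA"].iloc[j]), str(v["EA"].iloc[j]), ".", "PASS", ".", "GT",
            ]
            gts = np.empty(3 * trios.n_trios, dtype=object)
            gts[0::3] = [
                f"{a}|{b}" for a, b in zip(trios.mother_h1[:, j], trios.mother_h2[:, j])
            ]
            gts[1::3] = [
                f"{a}|{b}" for a, b in zip(trios.father_h1[:, j], trios.father_h2[:, j])
            ]
            gts[2::3] = [f"{a}|{b}" for a, b in zip(c_mat[:, j], c_pat[:, j])]
            fh.write("\t".join(fields) + "\t" + "\t".join(gts) + "\n")


def read_phased_vcf(path: str | Path, trio_map: pd.DataFrame | None = None) -> PhasedTrioSet:
    """Read a phased VCF back into a :class:`PhasedTrioSet`.

    ``trio_map`` (columns family, mother, father, child) defaults to the
    FID_M / FID_F / FID_C naming convention.  The child's first GT allele
    is taken as maternal-origin (MO=1 convention).  Unphased sites and
    multi-allelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if trio_map is None:
        fids = sorted({s[:-2] for s in samples if s.endswith("_M")})
        trio_map = pd.DataFrame(
            {"family": fids, "mother": [f + "_M" for f in fids],
             "father": [f + "_F" for f in fids], "child": [f + "_C" for f in fids]}
        )
    sample_idx = {s: i for i, s in enumerate(samples)}
    for col in ("mother", "father", "child"):
        missing = [s for s in trio_map[col] if s not in sample_idx]
        if missing:
            raise KeyError(f"samples in trio map absent from VCF: {missing[:5]}")
    mi = [sample_idx[s] for s in trio_map["mother"]]
    fi = [sample_idx[s] for s in trio_map["father"]]
    ci = [sample_idx[s] for s in trio_map["child"]]

    rows = []
    m1l, m2l, f1l, f2l, cml, cpl = [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        ph = rec.genotypes  # list of [a, b, phased]
        arr = np.array(ph, dtype=int)
        if not np.all(arr[:, 2] == 1):
            n_skipped += 1
            continue
        rows.append(
            {"SNP": rec.ID, "CHR": int(rec.CHROM), "POS": rec.POS,
             "EA": rec.ALT[0], "NEA": rec.REF}
        )
        m1l.append(arr[mi, 0]); m2l.append(arr[mi, 1])
        f1l.append(arr[fi, 0]); f2l.append(arr[fi, 1])
        cml.append(arr[ci, 0]); cpl.append(arr[ci, 1])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic or unphased records")
    variants = pd.DataFrame(rows)
    m1 = np.array(m1l, dtype=np.int8).T
    m2 = np.array(m2l, dtype=np.int8).T
    f1 = np.array(f1l, dtype=np.int8).T
    f2 = np.array(f2l, dtype=np.int8).T
    c_mat = np.array(cml, dtype=np.int8).T
    c_pat = np.array(cpl, dtype=np.int8).T
    # the transmitted maternal haplotype index is recoverable where the
    # mother is heterozygous; elsewhere it is irrelevant (set 0 when h1
    # matches).
    mat_t = np.zeros(m1.shape[0], dtype=np.int8)
    het = m1 != m2
    for i in range(m1.shape[0]):
        j = np.flatnonzero(het[i])
        if len(j):
            mat_t[i] = 0 if m1[i, j[0]] == c_mat[i, j[0]] else 1
    pat_t = np.zeros(f1.shape[0], dtype=np.int8)
    het_f = f1 != f2
    for i in range(f1.shape[0]):
        j = np.flatnonzero(het_f[i])
        if len(j):
            pat_t[i] = 0 if f1[i, j[0]] == c_pat[i, j[0]] else 1
    ts = PhasedTrioSet(
        mother_h1=m1, mother_h2=m2, father_h1=f1, father_h2=f2,
        mat_transmitted=mat_t, pat_transmitted=pat_t,
        variants=variants, family_ids=trio_map["family"].to_numpy(), seed=-1,
    )
    return ts


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
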