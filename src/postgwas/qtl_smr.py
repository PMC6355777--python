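"""cis-QTL mapping, SMR/HEIDI integration and conditional analyses.

QTL mapping is simple per-pair linear regression of a molecular phenotype
on additive allele dosage with exact t-based p-values and BH correction
within each (analysis, tissue) family. SMR tests whether a trait
association is mediated by a molecular feature using the top cis SNP's
GWAS and QTL z-scores: b_xy = b_GWAS/b_QTL and
T_SMR = z_GWAS^2 z_QTL^2 / (z_GWAS^2 + z_QTL^2) ~ chi^2(1). HEIDI tests
heterogeneity of b_xy across cis instruments against the single-shared-
causal-variant model: d_i = b_xy(i) - b_xy(top), the statistic is
sum_i d_i^2 / Var(d_i), and its null distribution — a sum of correlated
1-df chi-squares — is approximated by a moment-matched scaled chi-square
using the full delta-method covariance of the d_i (which reduces to the
plain chi-square with m-1 df when instruments are independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from postgwas.stats import bh_adjust

CIS_WINDOW = 1_000_000
HEIDI_P_ELIGIBLE = 1.6e-3
HEIDI_MAX_SNPS = 20
HEIDI_PRUNE_R2 = 0.9
HEIDI_MIN_INSTRUMENTS = 3


# --------------------------------------------------------------------------- cis pairs


def cis_pairs(func_snps: pd.DataFrame, features: pd.DataFrame,
              window: int = CIS_WINDOW) -> pd.DataFrame:
    """Candidate (SNP, feature) pairs.

    Enhancer SNPs (``is_enhancer`` truthy) are paired with every feature
    whose TSS lies within ``window`` bp (inclusive at the boundary); other
    functional SNPs are paired only with features of their host gene.

    ``func_snps`` needs columns id, chrom, pos, is_enhancer, gene (host
    gene, may be empty); ``features`` needs feature_id, gene, chrom, tss.
    """
    rows = []
    for _, s in func_snps.iterrows():
        if bool(s["is_enhancer"]):
            f = features[(features["chrom"] == s["chrom"])
                         & ((features["tss"] - int(s["pos"])).abs() <= window)]
        else:
            f = features[features["gene"] == s.get("gene", "")]
        for _, r in f.iterrows():
            rows.append({"id": s["id"], "feature_id": r["feature_id"], "gene": r["gene"]})
    return pd.DataFrame(rows, columns=["id", "feature_id", "gene"]).drop_duplicates(
        ignore_index=True)


# --------------------------------------------------------------------------- QTL fit


def _ols_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """(beta, se, p, degenerate) for y ~ intercept + x."""
    n = len(x)
    sxx = float(((x - x.mean()) ** 2).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    if n < 3 or sxx == 0.0 or syy == 0.0:
        return 0.0, np.nan, 1.0, True
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    b = sxy / sxx
    sse = syy - b * sxy
    sigma2 = max(sse, 0.0) / (n - 2)
    if sigma2 == 0.0:
        return b, 0.0, 0.0, False
    se = float(np.sqrt(sigma2 / sxx))
    t = b / se
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return b, se, p, False


def fit_qtl(pairs: pd.DataFrame, dosages: pd.DataFrame, phenotypes: pd.DataFrame,
            analysis: str, tissue: str) -> pd.DataFrame:
    """Per-pair linear QTL regression with BH within this (analysis, tissue).

    ``dosages``: SNPs x samples; ``phenotypes``: features x samples (same
    sample order). Constant phenotypes or genotypes are flagged with p = 1.
    """
    rows = []
    for _, pr in pairs.iterrows():
        sid, fid = pr["id"], pr["feature_id"]
        if sid not in dosages.index or fid not in phenotypes.index:
            continue
        x = dosages.loc[sid].to_numpy(float)
        y = phenotypes.loc[fid].to_numpy(float)
        b, se, p, degen = _ols_assoc(x, y)
        rows.append({"id": sid, "feature_id": fid, "gene": pr.get("gene", ""),
                     "analysis": analysis, "tissue": tissue,
                     "beta": b, "se": se, "p": p, "degenerate": degen})
    out = pd.DataFrame(rows, columns=["id", "feature_id", "gene", "analysis", "tissue",
                                      "beta", "se", "p", "degenerate"])
    out["q"] = bh_adjust(out["p"]) if len(out) else None
    return out


# --------------------------------------------------------------------------- SMR


def smr_test(b_gwas: float, se_gwas: float, b_eqtl: float, se_eqtl: float) -> dict:
    """SMR Wald-ratio test from the top cis SNP's summary statistics."""
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValueError("standard errors must be positive")
    zg = b_gwas / se_gwas
    ze = b_eqtl / se_eqtl
    if ze == 0:
        raise ValueError("eQTL z-score must be nonzero")
    b_xy = b_gwas / b_eqtl
    denom = zg * zg + ze * ze
    t_smr = (zg * zg * ze * ze) / denom if denom > 0 else 0.0
    p_smr = float(sps.chi2.sf(t_smr, df=1))
    return {"b_xy": float(b_xy), "t_smr": float(t_smr), "p_smr": p_smr}


def heidi_test(b_gwas, se_gwas, b_eqtl, se_eqtl, ld: np.ndarray, top: int,
               p_eligible: float = HEIDI_P_ELIGIBLE, max_snps: int = HEIDI_MAX_SNPS,
               prune_r2: float = HEIDI_PRUNE_R2,
               min_instruments: int = HEIDI_MIN_INSTRUMENTS) -> dict:
    """Heterogeneity-in-dependent-instruments test.

    Arrays cover the cis SNP set (top included); ``ld`` is the signed
    allele-correlation matrix among them. Instruments besides the top SNP
    need QTL p < ``p_eligible`` and r^2 <= ``prune_r2`` with the top SNP;
    at most ``max_snps`` strongest are used. With fewer than
    ``min_instruments`` eligible SNPs p is reported absent (NaN) and the
    caller decides the pass without it.
    """
    b_g = np.asarray(b_gwas, float)
    se_g = np.asarray(se_gwas, float)
    b_e = np.asarray(b_eqtl, float)
    se_e = np.asarray(se_eqtl, float)
    R = np.asarray(ld, float)
    z_e = b_e / se_e
    p_e = 2.0 * sps.norm.sf(np.abs(z_e))
    cand = [i for i in range(len(b_g)) if i != top and p_e[i] < p_eligible
            and R[i, top] ** 2 <= prune_r2]
    cand.sort(key=lambda i: p_e[i])
    cand = cand[:max_snps]
    if len(cand) < min_instruments:
        return {"p_heidi": float("nan"), "n_instruments": len(cand)}
    sel = [top] + cand
    bg, sg, be, se_ = b_g[sel], se_g[sel], b_e[sel], se_e[sel]
    Rs = R[np.ix_(sel, sel)]
    # delta-method covariance of b_xy = b_gwas / b_eqtl (GWAS and QTL
    # samples independent)
    cov_g = Rs * np.outer(sg, sg)
    cov_e = Rs * np.outer(se_, se_)
    inv_be = 1.0 / be
    bxy = bg * inv_be
    C = cov_g * np.outer(inv_be, inv_be) + np.outer(bxy, bxy) * cov_e * np.outer(inv_be, inv_be)
    k = len(cand)
    d = bxy[1:] - bxy[0]
    V = C[1:, 1:] - C[1:, [0]] - C[[0], 1:] + C[0, 0]
    var_d = np.clip(np.diag(V), 1e-300, None)
    z_d = d / np.sqrt(var_d)
    t_heidi = float((z_d ** 2).sum())
    corr = V / np.sqrt(np.outer(var_d, var_d))
    var_t = 2.0 * float((corr ** 2).sum())
    # moment-matched scaled chi-square (Satterthwaite); reduces to
    # chi^2(k) for independent instruments
    scale = var_t / (2.0 * k)
    df = 2.0 * k * k / var_t
    p = float(sps.chi2.sf(t_heidi / scale, df))
    return {"p_heidi": p, "t_heidi": t_heidi, "n_instruments": k}


def run_smr(gwas: pd.DataFrame, eqtl: pd.DataFrame, ld_lookup, tissue_class: str,
            heidi_absent_fails: bool = False) -> pd.DataFrame:
    """Per-gene SMR + HEIDI from summary tables.

    ``gwas``: id, b, se. ``eqtl``: id, gene (or feature gene), beta, se, p
    (one tissue). ``ld_lookup(snp_ids)`` returns the signed correlation
    matrix among the given SNPs. The SMR q-value is BH across genes; the
    pass flag is p_HEIDI > 0.05 (or HEIDI absent, unless
    ``heidi_absent_fails``) AND top-SNP QTL p < 0.05 AND q_SMR < 0.05.
    """
    gw = gwas.set_index("id")
    rows = []
    for gene, sub in eqtl.groupby("gene"):
        sub = sub[sub["id"].isin(gw.index)]
        sub = sub[~sub.get("degenerate", pd.Series(False, index=sub.index)).astype(bool)]
        if not len(sub):
            continue
        sub = sub.reset_index(drop=True)
        top = int(sub["p"].idxmin())
        t = sub.loc[top]
        res = smr_test(float(gw.loc[t["id"], "b"]), float(gw.loc[t["id"], "se"]),
                       float(t["beta"]), float(t["se"]))
        ids = list(sub["id"])
        R = np.asarray(ld_lookup(ids), float)
        hres = heidi_test(
            gw.loc[ids, "b"].to_numpy(float), gw.loc[ids, "se"].to_numpy(float),
            sub["beta"].to_numpy(float), sub["se"].to_numpy(float), R, top)
        rows.append({"gene": gene, "tissue_class": tissue_class, "top_snp": t["id"],
                     "b_xy": res["b_xy"], "t_smr": res["t_smr"], "p_smr": res["p_smr"],
                     "p_eqtl_top": float(t["p"]), "p_heidi": hres["p_heidi"],
                     "n_instruments": hres.get("n_instruments", 0)})
    out = pd.DataFrame(rows, columns=["gene", "tissue_class", "top_snp", "b_xy", "t_smr",
                                      "p_smr", "p_eqtl_top", "p_heidi", "n_instruments"])
    if not len(out):
        out["q_smr"] = None
        out["pass_smr"] = None
        return out
    out["q_smr"] = bh_adjust(out["p_smr"])
    heidi_ok = np.where(np.isnan(out["p_heidi"]),
                        not heidi_absent_fails,
                        out["p_heidi"] > 0.05)
    out["pass_smr"] = heidi_ok & (out["p_eqtl_top"] < 0.05) & (out["q_smr"] < 0.05)
    return out


def intersect_rule(eqtl_genes: dict, smr_pass_genes: dict) -> dict:
    """Per-tissue-class intersection of eQTL-significant and SMR-passing genes.

    Returns {'per_class': {cls: set}, 'union': set}.
    """
    per_class = {}
    for cls in sorted(set(eqtl_genes) | set(smr_pass_genes)):
        per_class[cls] = set(eqtl_genes.get(cls, set())) & set(smr_pass_genes.get(cls, set()))
    return {"per_class": per_class, "union": set().union(*per_class.values()) if per_class else set()}


# --------------------------------------------------------------------------- extras


def gene_correlation(expr: pd.DataFrame, pairs) -> pd.DataFrame:
    """Pearson correlation between gene pairs across samples."""
    rows = []
    for a, b in pairs:
        x = expr.loc[a].to_numpy(float)
        y = expr.loc[b].to_numpy(float)
        if a == b:
            rows.append({"gene_a": a, "gene_b": b, "r": 1.0, "p": 0.0})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"gene_a": a, "gene_b": b, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])


def conditional_eqtl(dosage: np.ndarray, target_expr: np.ndarray,
                     covariate_exprs: np.ndarray | None,
                     alpha: float = 0.05) -> dict:
    """SNP association before and after regressing out covariate genes.

    ``covariate_exprs`` is (n_covariates, n_samples) or None. The target is
    residualized on the covariates (with intercept) and the SNP association
    re-fitted on the residuals; with no covariates the result equals the
    unadjusted fit.
    """
    x = np.asarray(dosage, float)
    y = np.asarray(target_expr, float)
    _, _, p_un, _ = _ols_assoc(x, y)
    if covariate_exprs is None or len(covariate_exprs) == 0:
        p_cond = p_un
    else:
        Z = np.column_stack([np.ones_like(y)] + [np.asarray(c, float) for c in covariate_exprs])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        _, _, p_cond, _ = _ols_assoc(x, resid)
    return {"p_unadjusted": float(p_un), "p_conditional": float(p_cond),
            "still_significant": bool(p_cond < alpha)}
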