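"""Molecular phenotypes, case/control studies, summary stats and resources.

Planted structure (ground truth in ``PhenotypeBundle.causal_map``):

* signal genes: expression (brain + blood) driven by the block's enhancer
  SNP, methylation (brain) by the promoter SNP, protein (blood, subset) by
  the enhancer SNP, each as ``beta * dosage + N(0, noise_sd)``; consistent-
  direction case/control shift in all three expression studies; entries in
  the mouse nervous-system, disease-pathway and known-gene tables.
* partial genes: differential expression + mouse phenotype only (two
  validation hits, never prioritized).
* null genes: no planted effects; a sprinkling of non-nervous mouse terms
  and PPI edges to disease genes keeps the validation logic non-trivial.

GWAS summary z-scores are drawn per block from MVN(lambda * r_causal, R)
using the realized haplotype correlation matrix R, so LD partners of a
causal SNP inherit proportional signal, as association theory predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from postgwas.synthio.genotypes import GenotypePanel, gen_genotypes
from postgwas.synthio.layout import Layout, build_layout

GWAS_LAMBDA = 9.0
GWAS_N = 50_000
DE_STUDY_SIZES = (("study_pfc", 48, 55), ("study_dlpfc", 102, 106), ("study_blood", 106, 96))
TF_DE_SHIFT_SD = 2.0
TF_DE_N = 20  # per condition

NERVOUS_TERMS = frozenset({
    "nervous system phenotype",
    "abnormal nervous system physiology",
    "abnormal somatic nervous system morphology",
})


@dataclass
class DEStudy:
    name: str
    expr: pd.DataFrame  # genes x samples
    labels: np.ndarray  # 1 = case
    n_cases: int
    n_controls: int


@dataclass
class Resources:
    mouse: pd.DataFrame        # gene, phenotype
    pathways: pd.DataFrame     # pathway, gene  (disease pathways)
    known_genes: list
    ppi: pd.DataFrame          # gene_a, gene_b
    drugs: pd.DataFrame        # drug, gene


@dataclass
class PhenotypeBundle:
    expression: dict                  # tissue -> genes x samples DataFrame
    methylation: pd.DataFrame         # cpgs x samples (brain)
    cpg_gene_map: pd.DataFrame        # cpg, gene, pos
    protein: pd.DataFrame             # proteins x samples (blood)
    protein_gene_map: pd.DataFrame    # protein, gene
    de_studies: list
    tf_expression: pd.DataFrame       # genes x samples
    tf_labels: np.ndarray
    predictor_scores: pd.DataFrame
    resources: Resources
    gwas: pd.DataFrame                # id, chrom, pos, ref, alt, b, se, z, p
    index_snps: pd.DataFrame
    summary_snps: pd.DataFrame
    causal_map: pd.DataFrame          # gene, snp_id, analysis
    mirnas: pd.DataFrame = field(default=None)


def _block_snp(layout: Layout, block: int, role: str) -> str | None:
    sub = layout.snps[(layout.snps["block"] == block) & (layout.snps["role"] == role)]
    return sub["id"].iloc[0] if len(sub) else None


def gen_phenotypes(cfg, panel: GenotypePanel | None = None,
                   layout: Layout | None = None) -> PhenotypeBundle:
    if layout is None:
        layout = build_layout(cfg)
    if panel is None:
        panel = gen_genotypes(cfg, layout)
    rng = np.random.default_rng([int(cfg.seed), 4])
    samples = panel.samples
    genes = [g.gene_id for g in layout.genes]
    dosage = {sid: panel.dosage(sid) for sid in panel.variants["id"]}

    causal_rows = []

    # ---- QTL phenotype matrices ------------------------------------------
    expression = {}
    for tissue in ("brain", "blood"):
        mat = rng.normal(0.0, cfg.noise_sd, size=(len(genes), len(samples)))
        for g in layout.genes:
            if not g.signal:
                continue
            snp = _block_snp(layout, g.block, "enhancer")
            if snp is None:
                continue
            mat[genes.index(g.gene_id)] += cfg.qtl_effect * dosage[snp]
            if tissue == "brain":
                causal_rows.append({"gene": g.gene_id, "snp_id": snp, "analysis": "eQTL"})
        expression[tissue] = pd.DataFrame(mat, index=genes, columns=samples)

    cpgs = [f"cg{g.block:03d}" for g in layout.genes]
    meth = rng.normal(0.0, cfg.noise_sd, size=(len(cpgs), len(samples)))
    cpg_map = []
    for i, g in enumerate(layout.genes):
        cpg_map.append({"cpg": cpgs[i], "gene": g.gene_id, "pos": g.tss})
        if g.signal:
            snp = _block_snp(layout, g.block, "promoter")
            if snp is not None:
                meth[i] += cfg.qtl_effect * dosage[snp]
                causal_rows.append({"gene": g.gene_id, "snp_id": snp, "analysis": "meQTL"})
    methylation = pd.DataFrame(meth, index=cpgs, columns=samples)

    prot_genes = [g for g in layout.genes if g.cds and g.block % 2 == 0]
    prot_ids = [f"P{g.block:03d}" for g in prot_genes]
    prot = rng.normal(0.0, cfg.noise_sd, size=(len(prot_ids), len(samples)))
    for i, g in enumerate(prot_genes):
        if g.signal:
            snp = _block_snp(layout, g.block, "enhancer")
            if snp is not None:
                prot[i] += cfg.qtl_effect * dosage[snp]
                causal_rows.append({"gene": g.gene_id, "snp_id": snp, "analysis": "pQTL"})
    protein = pd.DataFrame(prot, index=prot_ids, columns=samples)
    protein_gene_map = pd.DataFrame(
        {"protein": prot_ids, "gene": [g.gene_id for g in prot_genes]}
    )

    # ---- case/control differential-expression studies --------------------
    de_studies = []
    shifted = {g.gene_id: (1.0 if g.block % 2 == 0 else -1.0)
               for g in layout.genes if g.signal or g.partial}
    for name, n_cases, n_controls in DE_STUDY_SIZES:
        n = n_cases + n_controls
        labels = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
        mat = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
        for gid, sign in shifted.items():
            mat[genes.index(gid), labels == 1] += sign * cfg.de_effect * cfg.noise_sd
        cols = [f"{name}_s{i}" for i in range(n)]
        de_studies.append(DEStudy(name, pd.DataFrame(mat, index=genes, columns=cols),
                                  labels, n_cases, n_controls))

    # ---- TF differential expression (neuronal differentiation model) -----
    tf_labels = np.r_[np.zeros(TF_DE_N, dtype=int), np.ones(TF_DE_N, dtype=int)]
    tf_rows = layout.tf_genes if layout.tf_genes else []
    tf_mat = rng.normal(0.0, cfg.noise_sd, size=(len(tf_rows), 2 * TF_DE_N))
    planted_tfs = set(layout.motif_assignment.values())
    for i, tf in enumerate(tf_rows):
        if tf in planted_tfs:
            tf_mat[i, tf_labels == 1] += TF_DE_SHIFT_SD * cfg.noise_sd
    tf_expression = pd.DataFrame(
        tf_mat, index=tf_rows, columns=[f"sh_{i}" for i in range(2 * TF_DE_N)]
    )

    # ---- predictor-score table for missense SNPs -------------------------
    score_rows = []
    for _, r in panel.variants[panel.variants["role"] == "cds_missense"].iterrows():
        b = int(r["block"])
        signal = b in set(layout.signal_blocks)
        if signal:
            calls = ["damaging"] * 4
        elif b % 3 == 2:
            calls = ["damaging", "tolerated", "tolerated", "tolerated"]
        else:
            calls = ["tolerated"] * 4
        if not signal and b % 5 == 4:
            calls[3] = "missing"
        score_rows.append({"id": r["id"], "PROVEAN": calls[0], "SIFT": calls[1],
                           "PolyPhen2": calls[2], "CADD": calls[3]})
    predictor_scores = pd.DataFrame(score_rows,
                                    columns=["id", "PROVEAN", "SIFT", "PolyPhen2", "CADD"])

    # ---- resource tables --------------------------------------------------
    mouse_rows = []
    for g in layout.genes:
        if g.signal or g.partial:
            mouse_rows.append({"gene": g.gene_id, "phenotype": "nervous system phenotype"})
        elif g.block % 4 == 1:
            mouse_rows.append({"gene": g.gene_id, "phenotype": "abnormal coat color"})
    signal_genes = [g.gene_id for g in layout.genes if g.signal]
    null_genes = [g.gene_id for g in layout.genes if not (g.signal or g.partial)]
    pathway_rows = []
    for i, gid in enumerate(signal_genes):
        pathway_rows.append({"pathway": f"disease_pathway_{i % 2 + 1}", "gene": gid})
    known = signal_genes[:1]
    ppi_rows = []
    for i, gid in enumerate(null_genes):
        if signal_genes and i % 2 == 0:
            ppi_rows.append({"gene_a": gid, "gene_b": signal_genes[i % len(signal_genes)]})
    drug_rows = []
    if signal_genes:
        drug_rows.append({"drug": "drug_A", "gene": signal_genes[0]})
    if ppi_rows:
        drug_rows.append({"drug": "drug_B", "gene": ppi_rows[0]["gene_a"]})
    resources = Resources(
        mouse=pd.DataFrame(mouse_rows, columns=["gene", "phenotype"]),
        pathways=pd.DataFrame(pathway_rows, columns=["pathway", "gene"]),
        known_genes=known,
        ppi=pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"]),
        drugs=pd.DataFrame(drug_rows, columns=["drug", "gene"]),
    )

    # ---- GWAS summary statistics -----------------------------------------
    gwas = _gen_gwas_summary(cfg, panel, layout, rng)
    signal_set = set(layout.signal_blocks)
    idx_ids = [
        _block_snp(layout, b, "enhancer") for b in sorted(signal_set)
    ]
    index_snps = gwas[gwas["id"].isin([i for i in idx_ids if i]) & (gwas["p"] < 5e-8)].copy()
    summary_snps = gwas.copy()

    return PhenotypeBundle(
        expression=expression,
        methylation=methylation,
        cpg_gene_map=pd.DataFrame(cpg_map),
        protein=protein,
        protein_gene_map=protein_gene_map,
        de_studies=de_studies,
        tf_expression=tf_expression,
        tf_labels=tf_labels,
        predictor_scores=predictor_scores,
        resources=resources,
        gwas=gwas,
        index_snps=index_snps,
        summary_snps=summary_snps,
        causal_map=pd.DataFrame(causal_rows, columns=["gene", "snp_id", "analysis"]),
        mirnas=layout.mirnas,
    )


def _gen_gwas_summary(cfg, panel: GenotypePanel, layout: Layout,
                      rng: np.random.Generator) -> pd.DataFrame:
    v = panel.variants
    z = np.empty(len(v))
    signal = set(layout.signal_blocks)
    for b in range(cfg.n_blocks):
        idx = v.index[v["block"] == b].to_numpy()
        H = panel.haplotypes[:, idx].astype(float)
        R = np.corrcoef(H, rowvar=False)
        R = np.atleast_2d(R)
        mu = np.zeros(len(idx))
        if b in signal:
            causal = _block_snp(layout, b, "enhancer")
            if causal is not None:
                c = int(np.where(v.loc[idx, "id"] == causal)[0][0])
                mu = GWAS_LAMBDA * R[:, c]
        L = np.linalg.cholesky(R + 1e-6 * np.eye(len(idx)))
        z[idx] = mu + L @ rng.standard_normal(len(idx))
    maf = v["maf"].to_numpy(float)
    se = 1.0 / np.sqrt(2.0 * GWAS_N * maf * (1.0 - maf))
    out = v[["id", "chrom", "pos", "ref", "alt"]].copy()
    out["b"] = z * se
    out["se"] = se
    out["z"] = z
    out["p"] = 2.0 * sps.norm.sf(np.abs(z))
    return out
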