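"""End-to-end driver: variants -> annotate -> tfbs -> enrich_hist -> qtl_smr -> integrate.

``run(cfg)`` generates a full synthetic study from one configuration and
pushes it through every stage, returning all intermediate tables and the
final prioritization report. Stage logic lives in the per-stage modules;
this driver only wires their interfaces together (and optionally writes
each stage's tables to disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from postgwas import annotate, enrich_hist, integrate, qtl_smr, tfbs, variants as variants_mod
from postgwas.genemodels import GeneModels, TranscriptModel
from postgwas.synthio import (build_layout, gen_gene_models, gen_genotypes, gen_motifs,
                              gen_phenotypes, gen_tracks, reference_sequence)

ENRICH_Q = 0.05
QTL_Q = 0.05


@dataclass
class PipelineResult:
    cfg: object
    susceptibility: pd.DataFrame
    ld_blocks: list
    region_calls: pd.DataFrame
    functional: annotate.FunctionalSets
    disruptions: pd.DataFrame
    tf_enrichment: dict
    enriched_tfs: set
    tf_de: pd.DataFrame
    hist_enrichment: pd.DataFrame | None
    qtl: dict                    # (analysis, tissue) -> records
    smr: dict                    # tissue_class -> records
    target_sources: dict
    evidence: pd.DataFrame
    meta_de: pd.DataFrame
    bridges: pd.DataFrame
    pathway_enrichment: pd.DataFrame
    drugs: pd.DataFrame
    report: dict
    table1: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _utr3_context(pos: int, ref: str, alt: str, t: TranscriptModel, refseq: str):
    """Transcript-sense 3'UTR sequence, variant offset and alleles."""
    parts, offset, found = [], 0, None
    for s, e in t.utr3:  # transcript order
        chunk = refseq[s - 1 : e]
        if t.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        if s <= pos <= e:
            found = offset + (pos - s if t.strand == "+" else e - pos)
        parts.append(chunk)
        offset += e - s + 1
    if found is None:
        return None
    seq = "".join(parts)
    if t.strand == "-":
        ref, alt = str(Seq(ref).complement()), str(Seq(alt).complement())
    return seq, found, ref, alt


def _background_pool(panel, r2_min: float = 0.8) -> dict:
    """Every panel SNP with its own strong-LD members (itself included)."""
    pool: dict[str, set] = {}
    v = panel.variants
    for b in sorted(v["block"].unique()):
        idx = v.index[v["block"] == b].to_numpy()
        H = panel.haplotypes[:, idx].astype(float)
        R = np.corrcoef(H, rowvar=False)
        R = np.atleast_2d(R)
        ids = v.loc[idx, "id"].to_numpy()
        r2 = R ** 2
        for i, sid in enumerate(ids):
            pool[sid] = set(ids[r2[i] >= r2_min - 1e-12])
    return pool


def run(cfg, n_perm: int = 200, run_enrichment: bool = True,
        outdir: str | Path | None = None) -> PipelineResult:
    """Execute the whole pipeline on a synthetic study."""
    layout = build_layout(cfg)
    refseq = reference_sequence(cfg, layout)
    panel = gen_genotypes(cfg, layout, refseq)
    models = gen_gene_models(cfg, layout)
    tracks = gen_tracks(cfg, layout)
    pwms = gen_motifs(cfg, layout)
    pheno = gen_phenotypes(cfg, panel, layout)

    # ---- susceptibility set ----------------------------------------------
    index_df = pheno.index_snps[["id", "chrom", "pos", "ref", "alt", "p"]]
    ld_df, blocks = variants_mod.ld_expand(index_df, panel)
    merged = variants_mod.merge_sources(index_df, ld_df, pheno.summary_snps)

    # ---- region + consequence annotation ---------------------------------
    calls = annotate.classify_regions(merged, models, refseq)
    calls = calls.merge(merged[["id", "pos", "chrom", "ref", "alt"]], on="id")

    splicing_set = set(calls[calls["region"] == "splicing"]["id"])
    missense = calls[(calls["region"] == "CDS") & (calls["consequence"] == "missense")]
    damaging = annotate.consensus_damaging_table(
        pheno.predictor_scores[pheno.predictor_scores["id"].isin(missense["id"])])
    damaging_set = set(damaging[damaging["damaging_any"]]["id"])

    utr_set = set()
    for _, v in calls[calls["region"] == "UTR3"].iterrows():
        t = models.by_gene[v["gene"]][0]
        ctx = _utr3_context(int(v["pos"]), v["ref"], v["alt"], t, refseq)
        if ctx is None:
            continue
        scan = annotate.mirna_seed_scan(ctx[0], ctx[1], ctx[2], ctx[3], pheno.mirnas)
        if (scan["effect"] != "unchanged").any():
            utr_set.add(v["id"])

    # ---- TF-binding disruption -------------------------------------------
    disruptions = tfbs.scan_variants(calls, refseq, pwms)
    disrupted_ids = set(disruptions["id"]) if len(disruptions) else set()
    promoter_ids = set(calls[calls["region"] == "promoter"]["id"])
    promoter_tf = promoter_ids & disrupted_ids

    enh_candidates = calls[calls["region"].isin(["intronic", "intergenic"])]
    enh_overlap = annotate.enhancer_overlap(enh_candidates, tracks.chromatin)
    enhancer_tf, enhancer_all = {}, {}
    for tissue in ("brain", "blood"):
        in_enh = set(enh_overlap[enh_overlap[tissue]]["id"]) if tissue in enh_overlap else set()
        enhancer_all[tissue] = in_enh
        enhancer_tf[tissue] = in_enh & disrupted_ids

    functional = annotate.assemble_functional_sets(
        {"splicing": splicing_set, "damaging_missense": damaging_set,
         "utr_mirna": utr_set, "promoter_tf": promoter_tf},
        enhancer_tf,
    )

    all_ids = set(calls["id"])
    tf_enr = {
        "promoter": tfbs.tf_enrichment(disruptions, promoter_ids, all_ids - promoter_ids),
        "enhancer_brain": tfbs.tf_enrichment(disruptions, enhancer_all["brain"],
                                             all_ids - enhancer_all["brain"]),
        "enhancer_blood": tfbs.tf_enrichment(disruptions, enhancer_all["blood"],
                                             all_ids - enhancer_all["blood"]),
    }
    enriched_tfs = set()
    for df in tf_enr.values():
        if len(df):
            enriched_tfs |= set(df[(df["q"] < ENRICH_Q) & (df["odds_ratio"] > 1)]["tf"])
    tf_de = tfbs.tf_expression_check(pheno.tf_expression, pheno.tf_labels,
                                     sorted(pheno.tf_expression.index))

    # ---- histone-mark enrichment -----------------------------------------
    hist = None
    if run_enrichment and blocks:
        avs = enrich_hist.build_avs(blocks)
        pool = _background_pool(panel)
        nulls = enrich_hist.sample_null_avs(avs, pool, n_perm,
                                            seed=int(cfg.seed) % (2 ** 31 - 1) + 7)
        hist = enrich_hist.enrichment_matrix(avs, tracks.marks, nulls, panel.variants)

    # ---- QTL + SMR --------------------------------------------------------
    dosages = pd.DataFrame(panel.dosages.T, index=panel.variants["id"].to_numpy(),
                           columns=panel.samples)
    host = calls.set_index("id")["gene"]
    tss = {g.gene_id: g.tss for g in layout.genes}

    def func_table(tissue: str) -> pd.DataFrame:
        ids = sorted(functional.per_tissue.get(tissue, set()))
        sub = calls[calls["id"].isin(ids)]
        return pd.DataFrame({
            "id": sub["id"], "chrom": sub["chrom"], "pos": sub["pos"],
            "is_enhancer": sub["id"].isin(enhancer_tf[tissue]),
            "gene": sub["gene"],
        })

    gene_features = pd.DataFrame(
        [{"feature_id": g.gene_id, "gene": g.gene_id, "chrom": layout.chrom, "tss": g.tss}
         for g in layout.genes])
    cpg_features = pheno.cpg_gene_map.rename(columns={"cpg": "feature_id"}).assign(
        chrom=layout.chrom).rename(columns={"pos": "tss"})
    prot_features = pheno.protein_gene_map.rename(columns={"protein": "feature_id"}).assign(
        chrom=layout.chrom)
    prot_features["tss"] = prot_features["gene"].map(tss)

    qtl = {}
    for tissue in ("brain", "blood"):
        pairs = qtl_smr.cis_pairs(func_table(tissue), gene_features)
        qtl[("eQTL", tissue)] = qtl_smr.fit_qtl(pairs, dosages, pheno.expression[tissue],
                                                "eQTL", tissue)
    pairs_m = qtl_smr.cis_pairs(func_table("brain"), cpg_features)
    qtl[("meQTL", "brain")] = qtl_smr.fit_qtl(pairs_m, dosages, pheno.methylation,
                                              "meQTL", "brain")
    pairs_p = qtl_smr.cis_pairs(func_table("blood"), prot_features)
    qtl[("pQTL", "blood")] = qtl_smr.fit_qtl(pairs_p, dosages, pheno.protein,
                                             "pQTL", "blood")

    def ld_lookup(ids):
        cols = [int(panel.variants.index[panel.variants["id"] == i][0]) for i in ids]
        H = panel.haplotypes[:, cols].astype(float)
        return np.atleast_2d(np.corrcoef(H, rowvar=False))

    smr, eqtl_sets, smr_sets = {}, {}, {}
    for tissue in ("brain", "blood"):
        rec = qtl[("eQTL", tissue)]
        eqtl_sets[tissue] = set(rec[rec["q"] < QTL_Q]["gene"])
        smr[tissue] = qtl_smr.run_smr(pheno.gwas, rec, ld_lookup, tissue)
        s = smr[tissue]
        smr_sets[tissue] = set(s[s["pass_smr"].fillna(False)]["gene"]) if len(s) else set()
    eqtl_rule = qtl_smr.intersect_rule(eqtl_sets, smr_sets)

    me = qtl[("meQTL", "brain")]
    meqtl_genes = set(me[me["q"] < QTL_Q]["gene"])
    pq = qtl[("pQTL", "blood")]
    pqtl_genes = set(pq[pq["q"] < QTL_Q]["gene"])

    # ---- integration ------------------------------------------------------
    sources = {"enriched_TF": enriched_tfs, "meQTL": meqtl_genes,
               "eQTL": eqtl_rule["union"], "pQTL": pqtl_genes}
    evidence = integrate.build_evidence(sources, set(models.coding_genes()))
    meta_de = integrate.meta_de_from_studies(pheno.de_studies)
    tallied = integrate.tally_validations(evidence, meta_de, pheno.resources.mouse,
                                          pheno.resources.pathways,
                                          pheno.resources.known_genes)
    coding = tallied[tallied["protein_coding"]]
    unexplained = sorted(coding[~coding["malacards_direct"]]["gene"])
    bridges = integrate.ppi_bridge(unexplained, pheno.resources.ppi,
                                   set(pheno.resources.pathways["gene"]),
                                   pheno.resources.known_genes)
    pathway_sets = {p: set(sub["gene"]) for p, sub in pheno.resources.pathways.groupby("pathway")}
    two_hit = sorted(coding[coding["n_hits"] >= integrate.N_HITS_PATHWAY]["gene"])
    pw = integrate.pathway_enrichment(two_hit, pathway_sets, models.gene_ids())
    drugs = integrate.drug_join(set(tallied["gene"]), bridges, pheno.resources.drugs)
    report = integrate.summarize(tallied, bridges, meta_de)
    report["functional_tally"] = functional.tally.to_dict("records")
    report["consequence_tally"] = annotate.consequence_tally(calls).to_dict()
    report["n_susceptibility"] = len(merged)
    tab1 = integrate.table1(tallied, meta_de, pheno.resources.mouse, pheno.resources.pathways)

    result = PipelineResult(
        cfg=cfg, susceptibility=merged, ld_blocks=blocks, region_calls=calls,
        functional=functional, disruptions=disruptions, tf_enrichment=tf_enr,
        enriched_tfs=enriched_tfs, tf_de=tf_de, hist_enrichment=hist, qtl=qtl,
        smr=smr, target_sources=sources, evidence=tallied, meta_de=meta_de,
        bridges=bridges, pathway_enrichment=pw, drugs=drugs, report=report,
        table1=tab1,
        extras={"panel": panel, "layout": layout, "pheno": pheno, "models": models,
                "eqtl_rule": eqtl_rule},
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    import json

    from postgwas import io

    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(res.susceptibility, outdir / "susceptibility_set.tsv")
    io.write_tsv(res.region_calls, outdir / "region_calls.tsv")
    io.write_tsv(res.functional.tally, outdir / "functional_tally.tsv")
    io.write_tsv(res.disruptions, outdir / "tfbs_disruptions.tsv")
    if res.hist_enrichment is not None:
        io.write_tsv(res.hist_enrichment, outdir / "histone_enrichment.tsv")
    for key, df in res.qtl.items():
        io.write_tsv(df, outdir / f"qtl_{key[0]}_{key[1]}.tsv")
    for tissue, df in res.smr.items():
        io.write_tsv(df, outdir / f"smr_{tissue}.tsv")
    io.write_tsv(res.evidence, outdir / "evidence.tsv")
    io.write_tsv(res.meta_de, outdir / "meta_de.tsv")
    io.write_tsv(res.table1, outdir / "prioritized_genes.tsv")
    (outdir / "report.json").write_text(json.dumps(res.report, indent=2, default=str))
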