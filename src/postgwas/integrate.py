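"""Evidence integration: meta-DE, validation tally, prioritization, report.

Target genes come from four sources (enriched TFs, meQTL, eQTL-and-SMR,
pQTL). Protein-coding targets are validated on three tracks: differential
expression (sample-size-weighted Stouffer meta-analysis with effect
direction, BH q < 0.05), mouse nervous-system phenotype, and direct
disease-pathway/known-gene membership. Genes with all three hits are
prioritized; genes with at least two feed pathway over-representation.
Unexplained genes may be bridged to disease pathways or known genes
through one-hop protein-protein interactions, and approved drugs are
joined on direct targets and PPI neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from postgwas.stats import (bh_adjust, hypergeom_enrichment, p_to_signed_z,
                            percent, stouffer_weighted, z_to_p_two_sided)

TARGET_SOURCES = ("enriched_TF", "meQTL", "eQTL", "pQTL")
VALIDATIONS = ("DE", "mouse", "malacards_direct")
N_HITS_PRIORITIZED = 3
N_HITS_PATHWAY = 2

DEFAULT_NERVOUS_TERMS = frozenset({
    "nervous system phenotype",
    "abnormal nervous system physiology",
    "abnormal somatic nervous system morphology",
    "abnormal sciatic nerve morphology",
    "abnormal nervous system electrophysiology",
})


# --------------------------------------------------------------------------- meta-DE


def de_test(expr: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-gene case/control two-sample t-test with effect direction."""
    labels = np.asarray(labels)
    case = expr.loc[:, labels == 1].to_numpy(float)
    ctrl = expr.loc[:, labels == 0].to_numpy(float)
    res = sps.ttest_ind(case, ctrl, axis=1)
    direction = np.sign(case.mean(axis=1) - ctrl.mean(axis=1))
    return pd.DataFrame({"gene": expr.index, "p": res.pvalue,
                         "direction": direction, "n": expr.shape[1]})


def meta_stouffer(per_study: pd.DataFrame) -> pd.DataFrame:
    """Sample-size-weighted, direction-aware meta-analysis across studies.

    ``per_study`` has columns gene, study, p, n, direction. Per gene:
    z_i = Phi^-1(1 - p_i/2) * sign(direction_i), combined as
    sum(sqrt(N_i) z_i) / sqrt(sum N_i), two-sided p, BH across genes.
    Single-study genes pass through (combined z equals the study z) with a
    ``singleton`` flag.
    """
    rows = []
    for gene, sub in per_study.groupby("gene"):
        z = p_to_signed_z(sub["p"].to_numpy(float), sub["direction"].to_numpy(float))
        combined = stouffer_weighted(z, sub["n"].to_numpy(float))
        dirs = set(np.sign(sub["direction"]).astype(int)) - {0}
        rows.append({"gene": gene, "n_studies": len(sub), "z": combined,
                     "p": float(z_to_p_two_sided(combined)),
                     "consistent_direction": len(dirs) <= 1,
                     "singleton": len(sub) == 1})
    out = pd.DataFrame(rows, columns=["gene", "n_studies", "z", "p",
                                      "consistent_direction", "singleton"])
    out["q"] = bh_adjust(out["p"]) if len(out) else None
    return out


def meta_de_from_studies(studies) -> pd.DataFrame:
    """Convenience: t-test each study then meta-combine (studies are
    objects with ``expr``, ``labels``, ``name``)."""
    frames = []
    for s in studies:
        d = de_test(s.expr, s.labels)
        d["study"] = s.name
        frames.append(d)
    return meta_stouffer(pd.concat(frames, ignore_index=True))


# --------------------------------------------------------------------------- evidence


def build_evidence(sources: dict, coding_genes: set) -> pd.DataFrame:
    """Union the per-source target-gene sets into one evidence table.

    ``sources`` maps 'enriched_TF' / 'meQTL' / 'eQTL' / 'pQTL' to gene
    sets. Every union member gets one row with per-source membership flags
    and a protein-coding flag; non-coding targets stay in the union but are
    excluded from the validation tally downstream.
    """
    sets = {k: set(sources.get(k, set())) for k in TARGET_SOURCES}
    union = sorted(set().union(*sets.values()))
    rows = []
    for g in union:
        row = {"gene": g, "protein_coding": g in coding_genes}
        for k in TARGET_SOURCES:
            row[k] = g in sets[k]
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "protein_coding", *TARGET_SOURCES])


def venn_counts(evidence: pd.DataFrame) -> dict:
    out = {k: int(evidence[k].sum()) for k in TARGET_SOURCES if k in evidence}
    out["total"] = len(evidence)
    out["protein_coding"] = int(evidence["protein_coding"].sum()) if len(evidence) else 0
    return out


def tally_validations(evidence: pd.DataFrame, meta_de: pd.DataFrame,
                      mouse: pd.DataFrame, pathways: pd.DataFrame,
                      known_genes, q_max: float = 0.05,
                      nervous_terms: frozenset = DEFAULT_NERVOUS_TERMS) -> pd.DataFrame:
    """Add the three validation hits, n_hits and the prioritized flag.

    DE hit: meta-analysis q < ``q_max``. Mouse hit: the gene maps to a
    nervous-system phenotype term (exact term-set membership). Direct
    disease hit: membership in the disease-pathway table or the known-gene
    list. Only protein-coding genes are tallied; prioritized means all
    three hits.
    """
    de_q = meta_de.set_index("gene")["q"] if len(meta_de) else pd.Series(dtype=float)
    mouse_hits = set(mouse[mouse["phenotype"].isin(nervous_terms)]["gene"]) if len(mouse) else set()
    direct = (set(pathways["gene"]) if len(pathways) else set()) | set(known_genes)
    out = evidence.copy()
    hit_de, hit_mouse, hit_direct = [], [], []
    for _, r in out.iterrows():
        coding = bool(r["protein_coding"])
        q = de_q.get(r["gene"], np.nan)
        hit_de.append(bool(coding and np.isfinite(q) and q < q_max))
        hit_mouse.append(bool(coding and r["gene"] in mouse_hits))
        hit_direct.append(bool(coding and r["gene"] in direct))
    out["DE"] = hit_de
    out["mouse"] = hit_mouse
    out["malacards_direct"] = hit_direct
    out["n_hits"] = out[list(VALIDATIONS)].sum(axis=1).astype(int)
    out["prioritized"] = out["n_hits"] == N_HITS_PRIORITIZED
    return out


# --------------------------------------------------------------------------- PPI, pathways, drugs


def ppi_bridge(unexplained, ppi: pd.DataFrame, pathway_genes: set, known_genes) -> pd.DataFrame:
    """One-hop bridge class per unexplained gene.

    'pathway' if any direct PPI neighbor is in a disease pathway,
    else 'known_gene' if any neighbor is a known disease gene, else 'none'.
    """
    neighbors: dict[str, set] = {}
    for _, e in ppi.iterrows():
        neighbors.setdefault(e["gene_a"], set()).add(e["gene_b"])
        neighbors.setdefault(e["gene_b"], set()).add(e["gene_a"])
    pathway_genes, known = set(pathway_genes), set(known_genes)
    rows = []
    for g in unexplained:
        nb = neighbors.get(g, set())
        if nb & pathway_genes:
            cls = "pathway"
        elif nb & known:
            cls = "known_gene"
        else:
            cls = "none"
        rows.append({"gene": g, "bridge": cls})
    return pd.DataFrame(rows, columns=["gene", "bridge"])


def pathway_enrichment(genes, pathway_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation per pathway, BH across pathways."""
    universe = set(universe)
    query = set(genes) & universe
    rows = []
    for name, members in sorted(pathway_sets.items()):
        members = set(members) & universe
        k = len(query & members)
        p = hypergeom_enrichment(k, len(universe), len(members), len(query))
        rows.append({"pathway": name, "overlap": k, "set_size": len(members),
                     "query_size": len(query), "p": p})
    out = pd.DataFrame(rows, columns=["pathway", "overlap", "set_size", "query_size", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else None
    return out


def drug_join(target_genes, bridges: pd.DataFrame, drugs: pd.DataFrame) -> pd.DataFrame:
    """Drug-gene connections: direct targets and one-hop PPI-linked genes."""
    targets = set(target_genes)
    bridged = set(bridges[bridges["bridge"] != "none"]["gene"]) if len(bridges) else set()
    rows = []
    for _, d in drugs.iterrows():
        if d["gene"] in targets:
            rows.append({"drug": d["drug"], "gene": d["gene"], "link": "direct"})
        elif d["gene"] in bridged:
            rows.append({"drug": d["drug"], "gene": d["gene"], "link": "bridge"})
    return pd.DataFrame(rows, columns=["drug", "gene", "link"])


# --------------------------------------------------------------------------- report


def summarize(tallied: pd.DataFrame, bridges: pd.DataFrame | None = None,
              meta_de: pd.DataFrame | None = None) -> dict:
    """Headline counts and half-up two-decimal percentages over coding targets."""
    coding = tallied[tallied["protein_coding"]] if len(tallied) else tallied
    n_coding = len(coding)
    n_de = int(coding["DE"].sum()) if n_coding else 0
    n_mouse = int(coding["mouse"].sum()) if n_coding else 0
    n_direct = int(coding["malacards_direct"].sum()) if n_coding else 0
    rep = {
        "n_targets": len(tallied),
        "n_protein_coding": n_coding,
        "n_de": n_de,
        "pct_de": percent(n_de, n_coding),
        "n_mouse": n_mouse,
        "pct_mouse": percent(n_mouse, n_coding),
        "n_direct": n_direct,
        "n_two_hits": int((coding["n_hits"] >= N_HITS_PATHWAY).sum()) if n_coding else 0,
        "n_prioritized": int(coding["prioritized"].sum()) if n_coding else 0,
        "prioritized_genes": sorted(coding[coding["prioritized"]]["gene"]) if n_coding else [],
    }
    if bridges is not None and len(bridges):
        n_unexplained = len(bridges)
        n_bridged_pathway = int((bridges["bridge"] == "pathway").sum())
        rep["n_unexplained"] = n_unexplained
        rep["n_bridged_pathway"] = n_bridged_pathway
        rep["pct_bridged_pathway"] = percent(n_bridged_pathway, n_unexplained)
        rep["n_bridged_known"] = int((bridges["bridge"] == "known_gene").sum())
    return rep


def table1(tallied: pd.DataFrame, meta_de: pd.DataFrame, mouse: pd.DataFrame,
           pathways: pd.DataFrame) -> pd.DataFrame:
    """Per-prioritized-gene report: DE q, pathways, mouse terms, QTL sources."""
    de_q = meta_de.set_index("gene")["q"] if len(meta_de) else pd.Series(dtype=float)
    rows = []
    for _, r in tallied[tallied["prioritized"]].iterrows():
        g = r["gene"]
        rows.append({
            "gene": g,
            "fdr_de": float(de_q.get(g, np.nan)),
            "pathways": ";".join(sorted(pathways[pathways["gene"] == g]["pathway"])) if len(pathways) else "",
            "mouse_phenotypes": ";".join(sorted(mouse[mouse["gene"] == g]["phenotype"])) if len(mouse) else "",
            "qtl_sources": ";".join(s for s in TARGET_SOURCES if r.get(s, False)),
        })
    return pd.DataFrame(rows, columns=["gene", "fdr_de", "pathways", "mouse_phenotypes", "qtl_sources"])
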