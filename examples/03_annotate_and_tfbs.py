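"""Annotate the susceptibility SNPs and call TF-binding disruption.

Each SNP gets exactly one primary region (CDS > splicing > UTR > ncRNA >
promoter > intronic > intergenic); CDS SNPs get a strand-aware coding
consequence; missense SNPs are checked against the four-predictor damaging
consensus; promoter and enhancer SNPs are scanned allele-aware against the
TF position-weight matrices.
"""

from postgwas.annotate import (classify_regions, consensus_damaging_table,
                               consequence_tally, enhancer_overlap)
from postgwas.config import SimConfig
from postgwas.synthio import (build_layout, gen_gene_models, gen_genotypes, gen_motifs,
                              gen_phenotypes, gen_tracks, reference_sequence)
from postgwas.tfbs import scan_variants
from postgwas.variants import ld_expand, merge_sources

cfg = SimConfig(seed=1)
layout = build_layout(cfg)
refseq = reference_sequence(cfg, layout)
panel = gen_genotypes(cfg, layout, refseq)
models = gen_gene_models(cfg, layout)
tracks = gen_tracks(cfg, layout)
pwms = gen_motifs(cfg, layout)
pheno = gen_phenotypes(cfg, panel, layout)

ld, _ = ld_expand(pheno.index_snps, panel)
snps = merge_sources(pheno.index_snps, ld, pheno.summary_snps)

calls = classify_regions(snps, models, refseq)
print("primary region of each susceptibility SNP:")
print(calls["region"].value_counts().to_string())
print("\ncoding consequences:")
print(consequence_tally(calls).to_string())

missense = calls[calls["consequence"] == "missense"]["id"]
damaging = consensus_damaging_table(
    pheno.predictor_scores[pheno.predictor_scores["id"].isin(missense)])
print(f"\nmissense SNPs damaging by >= 1 predictor: {int(damaging['damaging_any'].sum())}"
      f" (all 4: {int(damaging['damaging_all'].sum())})")

merged = calls.merge(snps[["id", "pos", "chrom", "ref", "alt"]], on="id")
disruptions = scan_variants(merged, refseq, pwms)
print(f"\nTF-binding disruptions ({len(disruptions)} SNP x TF calls):")
print(disruptions.to_string(index=False))

enh = enhancer_overlap(merged, tracks.chromatin)
print(f"\nSNPs in enhancer chromatin states: brain {int(enh['brain'].sum())}, "
      f"blood {int(enh['blood'].sum())}")
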