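"""Generate a complete synthetic study and export it in standard formats.

The synthetic genome is one chromosome tiled by 50 kb LD blocks; each block
carries one gene (strands alternate) and eight SNPs with designated
functional roles. Planted "disease" genes get a genome-wide-significant
GWAS signal at their enhancer SNP, cis-QTL effects, motif-breaking alleles
and consistent differential expression.
"""

from pathlib import Path

from postgwas import io
from postgwas.config import SimConfig
from postgwas.synthio import (build_layout, gen_gene_models, gen_genotypes, gen_motifs,
                              gen_phenotypes, gen_tracks, reference_sequence)

out = Path("example_output/study")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=1)
layout = build_layout(cfg)
refseq = reference_sequence(cfg, layout)
panel = gen_genotypes(cfg, layout, refseq)
models = gen_gene_models(cfg, layout)
tracks = gen_tracks(cfg, layout)
pwms = gen_motifs(cfg, layout)
pheno = gen_phenotypes(cfg, panel, layout)

print(f"genome: {layout.genome_length:,} bp, {len(layout.genes)} genes, "
      f"{len(panel.variants)} SNPs in {cfg.n_blocks} LD blocks")
print(f"planted disease genes: {[g.gene_id for g in layout.genes if g.signal]}")
print(f"index SNPs at genome-wide significance: {list(pheno.index_snps['id'])}")

io.write_vcf(panel, out / "panel.vcf")
io.write_fasta(refseq, layout.chrom, out / "genome.fa")
models.to_gtf(out / "genes.gtf")
io.write_jaspar(pwms, out / "motifs.jaspar")
tracks.write_beds(out / "tracks")
cfg.to_yaml(out / "config.yaml")
io.write_tsv(pheno.gwas, out / "gwas_summary.tsv")
print(f"wrote VCF / FASTA / GTF / JASPAR / BED / TSV artifacts to {out}/")
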