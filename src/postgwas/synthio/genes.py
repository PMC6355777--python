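"""Gene-model generation: one strand-alternating gene per block."""

from __future__ import annotations

from postgwas.genemodels import GeneModels, TranscriptModel
from postgwas.synthio.layout import Layout, build_layout


def gen_gene_models(cfg, layout: Layout | None = None) -> GeneModels:
    """Non-overlapping genes on both strands with valid CDS and UTRs.

    Protein-coding genes carry a 300-nt CDS (ATG ... TAA, length divisible
    by 3, no internal stop in the reference), a 60-nt 5'UTR and a 120-nt
    3'UTR split over two exons; a 15% tail of null genes is non-coding
    (exons only). ``n_genes=0`` yields an empty, still-valid model set.
    """
    if layout is None:
        layout = build_layout(cfg)
    transcripts = []
    for g in layout.genes:
        transcripts.append(
            TranscriptModel(
                gene_id=g.gene_id,
                transcript_id=f"{g.gene_id}.t1",
                chrom=layout.chrom,
                strand=g.strand,
                start=g.tx_start,
                end=g.tx_end,
                exons=list(g.exons if g.strand == "+" else g.exons[::-1]),
                cds=list(g.cds),
                utr5=list(g.utr5),
                utr3=list(g.utr3),
                gene_type=g.gene_type,
            )
        )
    return GeneModels(transcripts)
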