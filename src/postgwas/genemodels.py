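"""Strand-aware gene/transcript models with GTF round-trip.

All coordinates are 1-based inclusive (GTF convention). Interval lists
(exons, CDS, UTRs) are stored in transcript order (5' to 3'), so for
minus-strand transcripts the first interval has the highest genomic
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

PROMOTER_SIZE = 1_000


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    gene_type: str = "protein_coding"

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on '+', interval end on '-'."""
        return self.start if self.strand == "+" else self.end

    def promoter(self, size: int = PROMOTER_SIZE) -> tuple[int, int]:
        """Strand-aware upstream promoter window [TSS-size, TSS-1] (coding strand)."""
        if self.strand == "+":
            return (self.tss - size, self.tss - 1)
        return (self.tss + 1, self.tss + size)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


class GeneModels:
    """A set of transcripts grouped by gene."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = list(transcripts)
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)

    def __len__(self) -> int:
        return len(self.by_gene)

    def gene_ids(self) -> list[str]:
        return list(self.by_gene)

    def gene_type(self, gene_id: str) -> str:
        return self.by_gene[gene_id][0].gene_type

    def coding_genes(self) -> list[str]:
        return [g for g, ts in self.by_gene.items() if any(t.is_coding for t in ts)]

    def tss_table(self):
        import pandas as pd

        rows = [
            {"gene_id": t.gene_id, "transcript_id": t.transcript_id,
             "chrom": t.chrom, "tss": t.tss, "strand": t.strand,
             "gene_type": t.gene_type}
            for t in self.transcripts
        ]
        return pd.DataFrame(rows)

    # ---------------------------------------------------------------- GTF IO
    def to_gtf(self, path: str | Path) -> None:
        lines = []
        for t in sorted(self.transcripts, key=lambda t: (t.chrom, min(t.start, t.end))):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{t.gene_type}";'
            )

            def row(feature: str, s: int, e: int) -> str:
                return "\t".join(
                    [t.chrom, "postgwas", feature, str(s), str(e), ".", t.strand, ".", attrs]
                )

            lines.append(row("gene", t.start, t.end))
            lines.append(row("transcript", t.start, t.end))
            for s, e in sorted(t.exons):
                lines.append(row("exon", s, e))
            for s, e in sorted(t.cds):
                lines.append(row("CDS", s, e))
            for s, e in sorted(t.utr5):
                lines.append(row("five_prime_utr", s, e))
            for s, e in sorted(t.utr3):
                lines.append(row("three_prime_utr", s, e))
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneModels":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        transcripts: dict[str, TranscriptModel] = {}
        for f in db.features_of_type("transcript"):
            tid = f.attributes["transcript_id"][0]
            transcripts[tid] = TranscriptModel(
                gene_id=f.attributes["gene_id"][0],
                transcript_id=tid,
                chrom=f.seqid,
                strand=f.strand,
                start=f.start,
                end=f.end,
                gene_type=f.attributes.get("gene_type", ["protein_coding"])[0],
            )
        kind_map = {"exon": "exons", "CDS": "cds",
                    "five_prime_utr": "utr5", "three_prime_utr": "utr3"}
        for feature, attr in kind_map.items():
            for f in db.features_of_type(feature):
                t = transcripts[f.attributes["transcript_id"][0]]
                getattr(t, attr).append((f.start, f.end))
        for t in transcripts.values():
            for attr in ("exons", "cds", "utr5", "utr3"):
                ivs = sorted(getattr(t, attr))
                if t.strand == "-":
                    ivs = ivs[::-1]
                setattr(t, attr, ivs)
        return cls(list(transcripts.values()))
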