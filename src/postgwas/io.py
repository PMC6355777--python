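"""File-format round-trips: VCF 4.2, FASTA, JASPAR PFM, TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_vcf(panel, path: str | Path) -> None:
    """Write a phased panel as uncompressed VCF 4.2 (GT only)."""
    v = panel.variants
    lines = [
        "##fileformat=VCFv4.2",
        "##source=postgwas-synthio",
        f"##contig=<ID={v['chrom'].iloc[0]},length={int(v['pos'].max()) + 10_000}>"
        if len(v) else "##contig=<ID=chr1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples),
    ]
    H = panel.haplotypes
    for j, r in v.iterrows():
        gts = "\t".join(f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(len(panel.samples)))
        lines.append(
            f"{r['chrom']}\t{int(r['pos'])}\t{r['id']}\t{r['ref']}\t{r['alt']}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path):
    """Read a phased VCF back into a GenotypePanel (biallelic SNVs only)."""
    from cyvcf2 import VCF

    from postgwas.synthio.genotypes import GenotypePanel

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, hap_cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rows.append({"id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0]})
        g = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        hap_cols.append(g[:, :2].reshape(-1))
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    haps = (np.column_stack(hap_cols).astype(np.int8)
            if hap_cols else np.zeros((2 * len(samples), 0), np.int8))
    return GenotypePanel(variants=variants, haplotypes=haps, samples=samples)


def write_fasta(refseq: str, chrom: str, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(refseq), id=chrom, description="")], str(path), "fasta")


def write_jaspar(pwms, path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR PFM blocks (probabilities scaled to counts)."""
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.name}\t{pwm.name}")
        mat = np.rint(pwm.probs * scale).astype(int)
        for bi, base in enumerate("ACGT"):
            vals = " ".join(str(x) for x in mat[:, bi])
            lines.append(f"{base}  [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jaspar(path: str | Path, pseudocount: float = 0.25):
    """Read JASPAR PFM motifs into PWM objects (via Biopython)."""
    from Bio import motifs as bio_motifs

    from postgwas.tfbs import PWM

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack([np.asarray(m.counts[b], float) for b in "ACGT"])
            out.append(PWM.from_counts(m.name or m.matrix_id, counts, pseudocount))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
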