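"""Deterministic genome layout shared by all generators.

The synthetic genome is a single chromosome tiled by ``n_blocks`` LD blocks
of 50 kb. Each of the first ``n_genes`` blocks carries one gene (alternating
strand); every block carries ``snps_per_block`` SNPs whose first eight
positions play designated functional roles (enhancer, promoter, missense,
3'UTR, intron, intergenic, synonymous, splice site). Planted disease genes
("signal" blocks) additionally carry a TF motif around their promoter and
enhancer SNPs and a microRNA seed-match site around their 3'UTR SNP, with
the reference allele completing the site and the alternate allele breaking
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

BLOCK_SPAN = 50_000
CHROM = "chr1"
PROMOTER_SIZE = 1_000

# gene geometry (offsets within a block, 1-based)
_TX_OFFSET = 30_001
_EXON1_LEN = 210  # 60 nt 5'UTR + 150 nt CDS
_INTRON_LEN = 500
_EXON2_LEN = 270  # 150 nt CDS + 120 nt 3'UTR
_UTR5_LEN = 60
_UTR3_LEN = 120
_CDS_LEN = 300
TX_LEN = _EXON1_LEN + _INTRON_LEN + _EXON2_LEN

# planted-site geometry
_SEED_SITE_UTR3_START = 48  # 1-based transcript position within the 3'UTR
_SEED_SITE_LEN = 7
_UTR3_SNP_OFFSET = 51       # transcript position of the 3'UTR SNP within the UTR

# transcription-factor motif consensi (8-mers); the variant sits at motif
# position 4 (0-based offset 3)
TF_CONSENSUS = ("TGACTCAA", "CACGTGAC", "GGGACTTT", "TTGCGCAA")
MOTIF_SNP_OFFSET = 3

_STOP = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))

ROLE_ORDER = (
    "enhancer",
    "promoter",
    "cds_missense",
    "utr3",
    "intron",
    "intergenic",
    "cds_synonymous",
    "splicing",
)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _comp(b: str) -> str:
    return str(Seq(b).complement())


@dataclass
class GeneLayout:
    gene_id: str
    block: int
    strand: str
    tx_start: int  # 1-based inclusive, genomic
    tx_end: int
    tss: int
    exons: list = field(default_factory=list)  # [(start, end)] 1-based inclusive
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    gene_type: str = "protein_coding"
    signal: bool = False
    partial: bool = False
    is_tf: bool = False

    @property
    def promoter(self) -> tuple[int, int]:
        """Strand-aware upstream promoter interval, 1-based inclusive."""
        if self.strand == "+":
            return (self.tss - PROMOTER_SIZE, self.tss - 1)
        return (self.tss + 1, self.tss + PROMOTER_SIZE)


@dataclass
class Layout:
    cfg: object
    chrom: str
    genome_length: int
    genes: list
    snps: pd.DataFrame  # id, block, pos, role, gene_id
    signal_blocks: list
    partial_blocks: list
    tf_genes: list
    motif_assignment: dict  # snp_id -> tf name (signal promoter/enhancer SNPs)
    mirna_assignment: dict  # snp_id -> miRNA name (signal 3'UTR SNPs)
    mirnas: pd.DataFrame  # name, seed, sequence

    def gene_by_block(self, block: int):
        for g in self.genes:
            if g.block == block:
                return g
        return None

    def gene(self, gene_id: str):
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _gene_layout(block: int, gene_id: str) -> GeneLayout:
    origin = block * BLOCK_SPAN
    if block % 2 == 0:  # plus strand
        s = origin + _TX_OFFSET
        e = s + TX_LEN - 1
        g = GeneLayout(gene_id, block, "+", s, e, tss=s)
        g.exons = [(s, s + _EXON1_LEN - 1), (s + _EXON1_LEN + _INTRON_LEN, e)]
        g.utr5 = [(s, s + _UTR5_LEN - 1)]
        g.cds = [
            (s + _UTR5_LEN, s + _EXON1_LEN - 1),
            (s + _EXON1_LEN + _INTRON_LEN, s + _EXON1_LEN + _INTRON_LEN + 149),
        ]
        g.utr3 = [(s + _EXON1_LEN + _INTRON_LEN + 150, e)]
    else:  # minus strand: mirror image, TSS at the interval end
        e = origin + _TX_OFFSET + TX_LEN - 1
        s = e - TX_LEN + 1
        g = GeneLayout(gene_id, block, "-", s, e, tss=e)
        g.exons = [(s, s + _EXON2_LEN - 1), (e - _EXON1_LEN + 1, e)]
        g.utr5 = [(e - _UTR5_LEN + 1, e)]
        g.cds = [
            (e - _EXON1_LEN + 1, e - _UTR5_LEN),
            (s + _UTR3_LEN, s + _EXON2_LEN - 1),
        ]
        g.utr3 = [(s, s + _UTR3_LEN - 1)]
    return g


def _snp_positions(block: int, gene: GeneLayout | None, n_snps: int) -> list[tuple[int, str]]:
    """(pos, role) pairs for one block."""
    origin = block * BLOCK_SPAN
    out = []
    for k in range(n_snps):
        role = ROLE_ORDER[k] if k < len(ROLE_ORDER) else "intergenic"
        if gene is None and role not in ("enhancer", "intergenic"):
            role = "intergenic"
        if gene is not None and not gene.cds and role in ("cds_missense", "cds_synonymous", "utr3"):
            role = "ncRNA"
        if role == "ncRNA":
            # distinct exonic positions inside the noncoding transcript
            if gene.strand == "+":
                pos = gene.tx_start + 70 + k * 20
            else:
                pos = gene.tx_end - 70 - k * 20
        elif role == "enhancer":
            pos = origin + 10_000
        elif role == "intergenic":
            pos = origin + 5_000 + k * 150
        elif role == "promoter":
            pos = gene.tss - 500 if gene.strand == "+" else gene.tss + 500
        elif role == "cds_missense":
            # codon 10, position 2 of the codon
            cds_pos = 9 * 3 + 2
            pos = _cds_to_genomic(gene, cds_pos)
        elif role == "cds_synonymous":
            # codon 20, position 3 (wobble)
            cds_pos = 19 * 3 + 3
            pos = _cds_to_genomic(gene, cds_pos)
        elif role == "utr3":
            pos = _utr3_to_genomic(gene, _UTR3_SNP_OFFSET)
        elif role == "intron":
            if gene.strand == "+":
                pos = gene.tx_start + _EXON1_LEN + _INTRON_LEN // 2
            else:
                pos = gene.tx_end - _EXON1_LEN - _INTRON_LEN // 2
        elif role == "splicing":
            # 2nd intron base from the donor (5') exon-intron boundary
            if gene.strand == "+":
                pos = gene.tx_start + _EXON1_LEN + 1
            else:
                pos = gene.tx_end - _EXON1_LEN - 1
        else:  # pragma: no cover
            raise AssertionError(role)
        out.append((pos, role))
    return out


def _cds_to_genomic(gene: GeneLayout, cds_pos: int) -> int:
    """Map 1-based CDS (transcript-sense) position to genomic coordinate."""
    remaining = cds_pos
    if gene.strand == "+":
        for s, e in gene.cds:
            n = e - s + 1
            if remaining <= n:
                return s + remaining - 1
            remaining -= n
    else:
        for s, e in gene.cds:  # cds list is transcript-ordered
            n = e - s + 1
            if remaining <= n:
                return e - remaining + 1
            remaining -= n
    raise ValueError(f"CDS position {cds_pos} beyond CDS of {gene.gene_id}")


def _utr3_to_genomic(gene: GeneLayout, utr3_pos: int) -> int:
    s, e = gene.utr3[0]
    if gene.strand == "+":
        return s + utr3_pos - 1
    return e - utr3_pos + 1


def _mirna_library(rng: np.random.Generator, n: int = 6) -> pd.DataFrame:
    rows = []
    seen = set()
    while len(rows) < n:
        seq = "".join(rng.choice(_BASES, size=22))
        seed = seq[1:8]
        if seed in seen:
            continue
        seen.add(seed)
        rows.append({"name": f"miR-sim-{len(rows) + 1}", "seed": seed, "sequence": seq})
    return pd.DataFrame(rows)


def build_layout(cfg) -> Layout:
    """Deterministic structural layout for a configuration.

    Gene roles: the first ``round(causal_fraction * n_genes)`` genes are
    planted disease ("signal") genes; the next two are "partial" genes
    (differential expression + mouse phenotype only); the last four eligible
    null genes double as transcription factors whose motifs are planted at
    signal promoter/enhancer SNPs; a 15% tail of the remaining null genes is
    flagged non-coding.
    """
    rng = np.random.default_rng([int(cfg.seed), 0])
    n_signal = int(round(cfg.causal_fraction * cfg.n_genes))
    genes = []
    for i in range(cfg.n_genes):
        g = _gene_layout(i, f"G{i:03d}")
        g.signal = i < n_signal
        genes.append(g)
    partial_idx = [i for i in range(n_signal, min(n_signal + 2, cfg.n_genes))]
    for i in partial_idx:
        genes[i].partial = True
    eligible = [i for i in range(cfg.n_genes) if not genes[i].signal and not genes[i].partial]
    tf_idx = eligible[-4:] if len(eligible) >= 1 else []
    for i in tf_idx:
        genes[i].is_tf = True
    noncoding_pool = [i for i in eligible if i not in tf_idx]
    n_noncoding = int(0.15 * cfg.n_genes)
    for i in noncoding_pool[-n_noncoding:] if n_noncoding else []:
        genes[i].gene_type = "lincRNA"
        genes[i].cds = []
        genes[i].utr5 = []
        genes[i].utr3 = []

    snp_rows = []
    for b in range(cfg.n_blocks):
        gene = genes[b] if b < cfg.n_genes else None
        for j, (pos, role) in enumerate(_snp_positions(b, gene, cfg.snps_per_block)):
            snp_rows.append(
                {
                    "id": f"rs{b:03d}{j:02d}",
                    "block": b,
                    "pos": pos,
                    "role": role,
                    "gene_id": gene.gene_id if gene is not None else "",
                }
            )
    snps = pd.DataFrame(snp_rows).sort_values(["block", "pos"], kind="stable").reset_index(drop=True)
    if snps["pos"].duplicated().any():
        raise ValueError("layout produced colliding SNP positions")

    signal_blocks = [g.block for g in genes if g.signal]
    tf_names = [genes[i].gene_id for i in tf_idx]
    motif_assignment: dict[str, str] = {}
    mirnas = _mirna_library(rng)
    mirna_assignment: dict[str, str] = {}
    if tf_names:
        for b in signal_blocks:
            sub = snps[snps["block"] == b]
            prom = sub[sub["role"] == "promoter"]
            enh = sub[sub["role"] == "enhancer"]
            if len(prom):
                motif_assignment[prom["id"].iloc[0]] = tf_names[b % len(tf_names)]
            if len(enh):
                motif_assignment[enh["id"].iloc[0]] = tf_names[(b + 1) % len(tf_names)]
    for b in signal_blocks:
        sub = snps[(snps["block"] == b) & (snps["role"] == "utr3")]
        if len(sub):
            mirna_assignment[sub["id"].iloc[0]] = mirnas["name"].iloc[b % len(mirnas)]

    return Layout(
        cfg=cfg,
        chrom=CHROM,
        genome_length=cfg.n_blocks * BLOCK_SPAN,
        genes=genes,
        snps=snps,
        signal_blocks=signal_blocks,
        partial_blocks=partial_idx,
        tf_genes=tf_names,
        motif_assignment=motif_assignment,
        mirna_assignment=mirna_assignment,
        mirnas=mirnas,
    )


def _consensus_for_tf(tf_name: str, tf_genes: list) -> str:
    return TF_CONSENSUS[tf_genes.index(tf_name) % len(TF_CONSENSUS)]


def reference_sequence(cfg, layout: Layout | None = None) -> str:
    """Reference genome: random background, valid CDS codons, planted sites.

    CDS regions encode ATG + non-stop internal codons + TAA (transcript
    sense); signal-block promoter/enhancer SNPs sit at position 4 of their
    assigned TF's consensus 8-mer; signal-block 3'UTR SNPs complete a
    perfect 7-nt microRNA seed-match site.
    """
    if layout is None:
        layout = build_layout(cfg)
    rng = np.random.default_rng([int(cfg.seed), 1])
    seq = rng.choice(_BASES, size=layout.genome_length)

    codon_pool = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOP]
    for g in layout.genes:
        if not g.cds:
            continue
        internal = rng.choice(codon_pool, size=_CDS_LEN // 3 - 2)
        cds_seq = "ATG" + "".join(internal) + "TAA"
        # force the planted codons: codon 10 = GAT (Asp), codon 20 = GAT
        cds_seq = cds_seq[:27] + "GAT" + cds_seq[30:57] + "GAT" + cds_seq[60:]
        _write_transcript_sense(seq, g, g.cds, cds_seq)

    mirna_by_name = layout.mirnas.set_index("name")
    snps = layout.snps.set_index("id")
    for snp_id, tf in layout.motif_assignment.items():
        pos = int(snps.loc[snp_id, "pos"])
        consensus = _consensus_for_tf(tf, layout.tf_genes)
        start0 = pos - 1 - MOTIF_SNP_OFFSET
        seq[start0 : start0 + len(consensus)] = list(consensus)
    for snp_id, name in layout.mirna_assignment.items():
        g = layout.gene(str(snps.loc[snp_id, "gene_id"]))
        if not g.utr3:
            continue
        seed = mirna_by_name.loc[name, "seed"]
        site = _revcomp(seed)  # perfect 7mer-m8 site on the mRNA
        lo = _utr3_to_genomic(g, _SEED_SITE_UTR3_START)
        hi = _utr3_to_genomic(g, _SEED_SITE_UTR3_START + _SEED_SITE_LEN - 1)
        if g.strand == "+":
            seq[lo - 1 : lo - 1 + _SEED_SITE_LEN] = list(site)
        else:
            seq[hi - 1 : hi - 1 + _SEED_SITE_LEN] = list(_revcomp(site))
    return "".join(seq)


def _write_transcript_sense(seq: np.ndarray, gene: GeneLayout, intervals: list, tx_seq: str) -> None:
    """Write a transcript-sense string into genomic sequence across intervals.

    ``intervals`` are transcript-ordered; for minus-strand genes each
    genomic segment receives the reverse complement of its transcript chunk.
    """
    offset = 0
    for s, e in intervals:
        n = e - s + 1
        chunk = tx_seq[offset : offset + n]
        offset += n
        if gene.strand == "+":
            seq[s - 1 : e] = list(chunk)
        else:
            seq[s - 1 : e] = list(_revcomp(chunk))


def planted_alleles(cfg, layout: Layout, refseq: str, rng: np.random.Generator) -> pd.DataFrame:
    """Assign ref/alt alleles to every SNP (genomic strand).

    ref always matches the reference sequence. For planted functional SNPs
    the alt allele is chosen to break the planted feature (motif position,
    seed-site pairing, or the Asp codon); elsewhere alt is a random
    non-reference base.
    """
    rows = []
    snps = layout.snps
    for _, r in snps.iterrows():
        pos, role, snp_id = int(r["pos"]), r["role"], r["id"]
        ref = refseq[pos - 1]
        gene = layout.gene(r["gene_id"]) if r["gene_id"] else None
        alt = None
        if snp_id in layout.motif_assignment:
            alt = _breaking_base(ref)
        elif snp_id in layout.mirna_assignment:
            alt = _breaking_base(ref)
        elif role == "cds_missense" and gene is not None and gene.cds:
            # codon GAT, SNP at codon position 2 (transcript base 'A');
            # transcript alt 'C' makes GCT (Ala) -> missense
            alt = "C" if gene.strand == "+" else _comp("C")
        elif role == "cds_synonymous" and gene is not None and gene.cds:
            # codon GAT, position 3 (transcript 'T'); alt 'C' -> GAC, still Asp
            alt = "C" if gene.strand == "+" else _comp("C")
        if alt is None or alt == ref:
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(rng.integers(len(choices)))]
        rows.append({"id": snp_id, "chrom": layout.chrom, "pos": pos, "ref": ref, "alt": alt,
                     "block": int(r["block"]), "role": role, "gene_id": r["gene_id"]})
    return pd.DataFrame(rows)


def _breaking_base(ref: str) -> str:
    """A deterministic non-reference base (first in ACGT order)."""
    for b in "ACGT":
        if b != ref:
            return b
    raise ValueError(ref)
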