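"""Genomic-region and consequence annotation of susceptibility SNPs.

Classifies each SNP into exactly one primary region (precedence
CDS > splicing > UTR > ncRNA-exonic > promoter > intronic > intergenic),
calls strand-aware coding consequences, applies the four-predictor
damaging-consensus rule, scans 3'UTR variants for gained/lost microRNA
seed matches (8mer / 7mer-m8 / 7mer-A1), tags enhancer membership per
tissue from chromatin 15-state tracks, and assembles the per-tissue
functional SNP sets with deduplicated tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from postgwas.genemodels import GeneModels, TranscriptModel

SPLICE_WINDOW = 2
REGIONS = ("CDS", "splicing", "UTR5", "UTR3", "ncRNA", "promoter", "intronic", "intergenic")
_REGION_RANK = {r: i for i, r in enumerate(REGIONS)}

FUNCTIONAL_CATEGORIES = ("splicing", "damaging_missense", "utr_mirna", "promoter_tf", "enhancer_tf")

DEFAULT_ENHANCER_STATES = frozenset({"6_EnhG", "7_Enh", "12_EnhBiv"})

PREDICTORS = ("PROVEAN", "SIFT", "PolyPhen2", "CADD")


@dataclass
class RegionCall:
    variant_id: str
    region: str
    gene: str = ""
    consequence: str = "none"  # synonymous | missense | frameshift | unknown | none

    def __post_init__(self):
        if self.consequence != "none" and self.region != "CDS":
            raise ValueError("consequence only applies to CDS region calls")


class ReferenceMismatchError(ValueError):
    """Variant ref allele disagrees with the reference sequence."""


# --------------------------------------------------------------------------- region


def _in(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _transcript_region(pos: int, t: TranscriptModel) -> str | None:
    if _in(pos, t.cds):
        return "CDS"
    # splice sites: within SPLICE_WINDOW bases of an exon-intron boundary,
    # inside the intron
    exons = sorted(t.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        istart, iend = e1 + 1, s2 - 1
        if istart <= pos <= iend and (
            pos - istart < SPLICE_WINDOW or iend - pos < SPLICE_WINDOW
        ):
            return "splicing"
    if _in(pos, t.utr5):
        return "UTR5"
    if _in(pos, t.utr3):
        return "UTR3"
    if not t.is_coding and any(s <= pos <= e for s, e in t.exons):
        return "ncRNA"
    ps, pe = t.promoter()
    if ps <= pos <= pe:
        return "promoter"
    if min(t.start, t.end) <= pos <= max(t.start, t.end):
        return "intronic"
    return None


def classify_region(variant: dict, models: GeneModels, refseq: str | None = None) -> RegionCall:
    """Primary region for one variant (dict with id, chrom, pos, ref, alt).

    When ``refseq`` is given, the variant's ref allele is checked against it.
    Across transcripts the highest-precedence region wins; ties keep the
    first transcript. CDS calls carry a coding consequence.
    """
    pos = int(variant["pos"])
    if refseq is not None:
        have = refseq[pos - 1 : pos - 1 + len(variant["ref"])]
        if have.upper() != str(variant["ref"]).upper():
            raise ReferenceMismatchError(
                f"{variant['id']}: ref {variant['ref']} != reference {have} at {pos}"
            )
    best: tuple[int, str, TranscriptModel] | None = None
    for t in models.transcripts:
        if t.chrom != variant["chrom"]:
            continue
        region = _transcript_region(pos, t)
        if region is None:
            continue
        key = _REGION_RANK[region]
        if best is None or key < best[0]:
            best = (key, region, t)
    if best is None:
        return RegionCall(variant["id"], "intergenic")
    _, region, t = best
    if region == "CDS":
        cons = call_coding_consequence(variant, t, refseq) if refseq is not None else "unknown"
        return RegionCall(variant["id"], "CDS", t.gene_id, cons)
    return RegionCall(variant["id"], region, t.gene_id)


def classify_regions(variants: pd.DataFrame, models: GeneModels,
                     refseq: str | None = None) -> pd.DataFrame:
    calls = [classify_region(v, models, refseq) for v in variants.to_dict("records")]
    return pd.DataFrame(
        [{"id": c.variant_id, "region": c.region, "gene": c.gene, "consequence": c.consequence}
         for c in calls]
    )


# --------------------------------------------------------------------------- coding


def _cds_sequence(t: TranscriptModel, refseq: str) -> str:
    parts = []
    for s, e in t.cds:  # transcript order
        chunk = refseq[s - 1 : e]
        parts.append(chunk if t.strand == "+" else str(Seq(chunk).reverse_complement()))
    return "".join(parts)


def _genomic_to_cds(t: TranscriptModel, pos: int) -> int | None:
    """1-based CDS coordinate of a genomic position, or None if outside."""
    offset = 0
    for s, e in t.cds:
        n = e - s + 1
        if s <= pos <= e:
            return offset + (pos - s + 1 if t.strand == "+" else e - pos + 1)
        offset += n
    return None


def call_coding_consequence(variant: dict, transcript: TranscriptModel,
                            refseq: str) -> str:
    """synonymous / missense / frameshift / unknown for a CDS variant.

    Codons are translated strand-aware with the standard genetic code;
    indels whose length difference is not a multiple of 3 are frameshifts;
    anything untranslatable (partial codon context, CDS length not a
    multiple of 3, in-frame indels) falls back to ``unknown``.
    """
    ref, alt = str(variant["ref"]), str(variant["alt"])
    if len(ref) != len(alt):
        return "frameshift" if abs(len(ref) - len(alt)) % 3 else "unknown"
    if len(ref) != 1:
        return "unknown"
    cds_pos = _genomic_to_cds(transcript, int(variant["pos"]))
    cds_seq = _cds_sequence(transcript, refseq)
    if cds_pos is None or len(cds_seq) % 3 or cds_pos > len(cds_seq):
        return "unknown"
    alt_tx = alt if transcript.strand == "+" else str(Seq(alt).complement())
    codon_i = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "missense"


def consequence_tally(region_calls: pd.DataFrame) -> pd.Series:
    """Counts of coding consequences among CDS SNPs (plus total)."""
    cds = region_calls[region_calls["region"] == "CDS"]
    out = cds["consequence"].value_counts().to_dict()
    out["total_cds"] = len(cds)
    return pd.Series(out, dtype=int)


# --------------------------------------------------------------------------- predictors


def consensus_damaging(calls: dict) -> dict:
    """Consensus over {PROVEAN, SIFT, PolyPhen2, CADD} binary calls.

    Calls are 'damaging' / 'tolerated' / 'missing'; missing never counts.
    damaging_any means at least one algorithm calls damaging; damaging_all
    means all four do.
    """
    n = sum(1 for a in PREDICTORS if calls.get(a) == "damaging")
    return {"n_damaging": n, "damaging_any": n >= 1, "damaging_all": n == 4}


def consensus_damaging_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`consensus_damaging` to a SNP x predictor call table."""
    rows = []
    for _, r in scores.iterrows():
        d = consensus_damaging({a: r.get(a, "missing") for a in PREDICTORS})
        d["id"] = r["id"]
        rows.append(d)
    return pd.DataFrame(rows, columns=["id", "n_damaging", "damaging_any", "damaging_all"])


# --------------------------------------------------------------------------- miRNA


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _site_patterns(mature: str) -> list[tuple[str, str]]:
    """(match_type, site string) in decreasing stringency.

    Target sites, written 5'->3' on the mRNA, pair Watson-Crick with the
    miRNA seed: 8mer = complement of positions 2-8 plus an A opposite
    position 1; 7mer-m8 = complement of positions 2-8; 7mer-A1 = complement
    of positions 2-7 plus the A.
    """
    seed28 = mature[1:8]
    seed27 = mature[1:7]
    return [
        ("8mer", _revcomp(seed28) + "A"),
        ("7mer-m8", _revcomp(seed28)),
        ("7mer-A1", _revcomp(seed27) + "A"),
    ]


def _matches_over(seq: str, offset: int, patterns) -> list[tuple[str, int]]:
    """(match_type, start) of the best-class site at each start overlapping offset."""
    hits = []
    starts_seen = set()
    for mtype, site in patterns:
        k = len(site)
        for i in range(max(0, offset - k + 1), min(len(seq) - k, offset) + 1):
            if i in starts_seen:
                continue
            if seq[i : i + k] == site:
                hits.append((mtype, i))
                starts_seen.add(i)
    return hits


def mirna_seed_scan(utr_seq: str, var_offset: int, ref: str, alt: str,
                    mirnas: pd.DataFrame) -> pd.DataFrame:
    """Effect of a 3'UTR SNV on seed matches of each library miRNA.

    ``utr_seq`` is the reference 3'UTR in transcript sense, ``var_offset``
    the 0-based variant position within it, ``ref``/``alt`` transcript-sense
    alleles. Effect is 'destroyed' if a seed site overlapping the variant
    exists with ref but not alt, 'created' for the reverse, else
    'unchanged'.
    """
    if utr_seq[var_offset] != ref:
        raise ValueError(f"UTR sequence has {utr_seq[var_offset]} at offset {var_offset}, not {ref}")
    alt_seq = utr_seq[:var_offset] + alt + utr_seq[var_offset + 1 :]
    rows = []
    for _, m in mirnas.iterrows():
        patterns = _site_patterns(m["sequence"])
        ref_hits = _matches_over(utr_seq, var_offset, patterns)
        alt_hits = _matches_over(alt_seq, var_offset, patterns)
        if ref_hits and not alt_hits:
            effect, mtype = "destroyed", ref_hits[0][0]
        elif alt_hits and not ref_hits:
            effect, mtype = "created", alt_hits[0][0]
        else:
            effect = "unchanged"
            mtype = ref_hits[0][0] if ref_hits else ""
        rows.append({"mirna": m["name"], "effect": effect, "match_type": mtype})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- enhancers


def enhancer_overlap(variants: pd.DataFrame, chromatin: dict,
                     enhancer_states: frozenset = DEFAULT_ENHANCER_STATES) -> pd.DataFrame:
    """Per-tissue enhancer membership from chromatin-state tracks.

    ``chromatin`` maps (tissue, cell_line) to BED-like DataFrames (0-based
    half-open). A SNP counts for a tissue if at least one cell line of that
    tissue carries an enhancer state at its position.
    """
    tissues = sorted({t for t, _ in chromatin})
    trees: dict[str, IntervalTree] = {t: IntervalTree() for t in tissues}
    for (tissue, _cell), df in chromatin.items():
        sub = df[df["state"].isin(enhancer_states)]
        for _, r in sub.iterrows():
            if r["end"] > r["start"]:
                trees[tissue].addi(int(r["start"]), int(r["end"]))
    out = {"id": variants["id"].to_numpy()}
    pos0 = variants["pos"].to_numpy() - 1  # BED half-open: end coordinate excluded
    for tissue in tissues:
        out[tissue] = np.array([bool(trees[tissue][int(p)]) for p in pos0])
    return pd.DataFrame(out)


# --------------------------------------------------------------------------- assembly


@dataclass
class FunctionalSets:
    per_tissue: dict = field(default_factory=dict)  # tissue -> set of SNP ids
    tally: pd.DataFrame | None = None


def assemble_functional_sets(categories: dict, enhancer_by_tissue: dict) -> FunctionalSets:
    """Union the five functional categories per tissue, counting SNPs once.

    ``categories`` maps the tissue-shared categories (splicing,
    damaging_missense, utr_mirna, promoter_tf) to SNP-id sets;
    ``enhancer_by_tissue`` maps tissue name to the enhancer_tf SNP set of
    that tissue. The tally reports per-category sizes, the raw sum, the
    overlap removed by deduplication, and the union.
    """
    shared = {k: set(categories.get(k, set())) for k in
              ("splicing", "damaging_missense", "utr_mirna", "promoter_tf")}
    rows = []
    per_tissue = {}
    for tissue, enh in enhancer_by_tissue.items():
        cats = dict(shared)
        cats["enhancer_tf"] = set(enh)
        union = set().union(*cats.values())
        per_tissue[tissue] = union
        raw = sum(len(v) for v in cats.values())
        row = {"tissue": tissue, **{k: len(v) for k, v in cats.items()},
               "raw_sum": raw, "n_multi_category": raw - len(union), "union": len(union)}
        rows.append(row)
    return FunctionalSets(per_tissue=per_tissue, tally=pd.DataFrame(rows))
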