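"""Region classification, coding consequences, predictors, miRNA, enhancers."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from postgwas.annotate import (ReferenceMismatchError, assemble_functional_sets,
                               call_coding_consequence, classify_region, classify_regions,
                               consensus_damaging, consensus_damaging_table,
                               consequence_tally, enhancer_overlap, mirna_seed_scan)
from postgwas.genemodels import GeneModels, TranscriptModel


def _toy_transcript(strand="+"):
    # + strand: 5'UTR 101-110, CDS 111-140 & 241-270 (intron 141-240), 3'UTR 271-300
    if strand == "+":
        return TranscriptModel(
            gene_id="T", transcript_id="T.t1", chrom="chr1", strand="+",
            start=101, end=300,
            exons=[(101, 140), (241, 300)],
            cds=[(111, 140), (241, 270)],
            utr5=[(101, 110)], utr3=[(271, 300)],
        )
    return TranscriptModel(
        gene_id="T", transcript_id="T.t1", chrom="chr1", strand="-",
        start=101, end=300,
        exons=[(241, 300), (101, 140)],
        cds=[(241, 290), (131, 140)],
        utr5=[(291, 300)], utr3=[(101, 130)],
    )


def _models(strand="+"):
    return GeneModels([_toy_transcript(strand)])


def _variant(pos, ref="A", alt="C", vid="v"):
    return {"id": vid, "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt}


class TestRegionPrecedence:
    @pytest.mark.parametrize("pos,region", [
        (120, "CDS"),
        (141, "splicing"),   # 1st intron base after donor exon
        (142, "splicing"),   # 2nd intron base
        (143, "intronic"),
        (239, "splicing"),   # 2nd-from-acceptor intron base
        (240, "splicing"),
        (238, "intronic"),
        (105, "UTR5"),
        (280, "UTR3"),
        (100, "promoter"),   # TSS-1
    ])
    def test_plus_strand(self, pos, region):
        assert classify_region(_variant(pos), _models("+")).region == region

    def test_promoter_boundaries(self):
        m = _models("+")
        assert classify_region(_variant(100), m).region == "promoter"
        # upstream limit: TSS-1000 = -899 -> everything down to pos 1 is promoter
        t = _toy_transcript("+")
        t.start, t.end = 2101, 2300
        t.exons = [(2101, 2140), (2241, 2300)]
        t.cds = [(2111, 2140), (2241, 2270)]
        t.utr5, t.utr3 = [(2101, 2110)], [(2271, 2300)]
        m2 = GeneModels([t])
        assert classify_region(_variant(1101), m2).region == "promoter"  # TSS-1000
        assert classify_region(_variant(1100), m2).region == "intergenic"  # TSS-1001

    def test_minus_strand_promoter_downstream(self):
        m = _models("-")
        assert classify_region(_variant(301), m).region == "promoter"  # TSS+1
        assert classify_region(_variant(1300), m).region == "promoter"  # TSS+1000
        assert classify_region(_variant(1301), m).region == "intergenic"

    def test_ncrna_exonic(self):
        t = _toy_transcript("+")
        t.cds, t.utr5, t.utr3 = [], [], []
        t.gene_type = "lincRNA"
        call = classify_region(_variant(120), GeneModels([t]))
        assert call.region == "ncRNA"

    def test_reference_mismatch_raises(self):
        refseq = "G" * 400
        with pytest.raises(ReferenceMismatchError):
            classify_region(_variant(120, ref="A"), _models("+"), refseq)


class TestConsequence:
    def _refseq(self, strand="+"):
        seq = list("G" * 320)
        t = _toy_transcript(strand)
        cds = "ATG" + "GAT" * 18 + "TAA"  # 60 nt, Asp repeats
        offset = 0
        for s, e in t.cds:
            n = e - s + 1
            chunk = cds[offset : offset + n]
            offset += n
            if strand == "-":
                chunk = str(Seq(chunk).reverse_complement())
            seq[s - 1 : e] = list(chunk)
        return "".join(seq)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_synonymous_wobble(self, strand):
        # codon 2 = GAT; position 3 (wobble) T->C keeps Asp
        t = _toy_transcript(strand)
        refseq = self._refseq(strand)
        from postgwas.annotate import _genomic_to_cds
        pos = next(p for p in range(1, 320) if _genomic_to_cds(t, p) == 6)
        ref = refseq[pos - 1]
        alt = "C" if strand == "+" else "G"
        assert call_coding_consequence(_variant(pos, ref, alt), t, refseq) == "synonymous"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_missense(self, strand):
        # codon 2 position 2: A->C gives GCT = Ala
        t = _toy_transcript(strand)
        refseq = self._refseq(strand)
        from postgwas.annotate import _genomic_to_cds
        pos = next(p for p in range(1, 320) if _genomic_to_cds(t, p) == 5)
        ref = refseq[pos - 1]
        alt = "C" if strand == "+" else "G"
        assert call_coding_consequence(_variant(pos, ref, alt), t, refseq) == "missense"

    def test_frameshift_indel(self):
        t = _toy_transcript("+")
        refseq = self._refseq("+")
        assert call_coding_consequence(_variant(120, "GA", "G"), t, refseq) == "frameshift"
        assert call_coding_consequence(_variant(120, "GATA", "G"), t, refseq) == "unknown"

    def test_planted_pipeline_snps(self, layout, refseq, models, panel):
        v = panel.variants
        sub = v[v["role"].isin(["cds_missense", "cds_synonymous"])]
        calls = classify_regions(sub, models, refseq)
        merged = calls.merge(v[["id", "role"]], on="id")
        assert (merged["region"] == "CDS").all()
        expect = merged["role"].map({"cds_missense": "missense",
                                     "cds_synonymous": "synonymous"})
        assert (merged["consequence"] == expect).all()

    def test_tally(self):
        calls = pd.DataFrame({
            "region": ["CDS", "CDS", "CDS", "UTR3"],
            "consequence": ["missense", "missense", "synonymous", "none"],
        })
        t = consequence_tally(calls)
        assert t["missense"] == 2 and t["synonymous"] == 1 and t["total_cds"] == 3


class TestDamagingConsensus:
    def test_rules(self):
        assert consensus_damaging({"PROVEAN": "damaging", "SIFT": "tolerated",
                                   "PolyPhen2": "tolerated", "CADD": "tolerated"}) == \
            {"n_damaging": 1, "damaging_any": True, "damaging_all": False}
        assert consensus_damaging({a: "damaging" for a in
                                   ("PROVEAN", "SIFT", "PolyPhen2", "CADD")})["damaging_all"]

    def test_missing_never_counts(self):
        res = consensus_damaging({"PROVEAN": "missing", "SIFT": "missing",
                                  "PolyPhen2": "missing", "CADD": "missing"})
        assert res["n_damaging"] == 0 and not res["damaging_any"]

    def test_table(self):
        df = pd.DataFrame([
            {"id": "a", "PROVEAN": "damaging", "SIFT": "damaging",
             "PolyPhen2": "damaging", "CADD": "damaging"},
            {"id": "b", "PROVEAN": "tolerated", "SIFT": "tolerated",
             "PolyPhen2": "tolerated", "CADD": "missing"},
        ])
        out = consensus_damaging_table(df).set_index("id")
        assert bool(out.loc["a", "damaging_all"]) and not bool(out.loc["b", "damaging_any"])


class TestMirnaScan:
    def _mirnas(self, seqs):
        return pd.DataFrame([{"name": f"m{i}", "seed": s[1:8], "sequence": s}
                             for i, s in enumerate(seqs)])

    def test_destroyed_site(self):
        mature = "UAAGGCACGCGGUGAAUGCCA".replace("U", "T")
        site8 = str(Seq(mature[1:8]).reverse_complement()) + "A"
        utr = "CCCCC" + site8 + "CCCCC"
        off = 5 + 3  # inside the site
        ref = utr[off]
        alt = next(b for b in "ACGT" if b != ref)
        out = mirna_seed_scan(utr, off, ref, alt, self._mirnas([mature]))
        assert out["effect"].iloc[0] == "destroyed"
        assert out["match_type"].iloc[0] == "8mer"

    def test_created_site(self):
        mature = "UAAGGCACGCGGUGAAUGCCA".replace("U", "T")
        site = str(Seq(mature[1:8]).reverse_complement())
        broken = "G" + site[1:] if site[0] != "G" else "T" + site[1:]
        utr = "CCCCC" + broken + "CCCCCC"
        out = mirna_seed_scan(utr, 5, broken[0], site[0], self._mirnas([mature]))
        assert out["effect"].iloc[0] == "created"

    def test_unchanged_without_site(self):
        mature = "UAAGGCACGCGGUGAAUGCCA".replace("U", "T")
        utr = "C" * 20
        out = mirna_seed_scan(utr, 10, "C", "A", self._mirnas([mature]))
        assert out["effect"].iloc[0] == "unchanged"

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError):
            mirna_seed_scan("ACGT", 1, "A", "G", self._mirnas(["A" * 22]))

    def test_brute_force_oracle(self):
        """Effect calls agree with exhaustive site search on random 50-mers."""
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))

        def all_sites(seq, patterns, off):
            found = []
            for mtype, site in patterns:
                k = len(site)
                for i in range(len(seq) - k):  # last start excluded: site may need +A room
                    if i <= off <= i + k - 1 and seq[i : i + k] == site:
                        found.append((mtype, i))
            return found

        from postgwas.annotate import _site_patterns
        for _ in range(30):
            mature = "".join(rng.choice(bases, 22))
            seq = list(rng.choice(bases, 50))
            # plant the 7mer-m8 site half the time so hits actually occur
            site = str(Seq(mature[1:8]).reverse_complement())
            if rng.random() < 0.5:
                seq[20:27] = list(site)
            seq = "".join(seq)
            off = int(rng.integers(8, 40))
            ref = seq[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out = mirna_seed_scan(seq, off, ref, alt,
                                  self._mirnas([mature]))
            patterns = _site_patterns(mature)
            alt_seq = seq[:off] + alt + seq[off + 1:]
            ref_hits = all_sites(seq, patterns, off)
            alt_hits = all_sites(alt_seq, patterns, off)
            expect = ("destroyed" if ref_hits and not alt_hits
                      else "created" if alt_hits and not ref_hits else "unchanged")
            assert out["effect"].iloc[0] == expect


class TestEnhancerOverlap:
    def _chromatin(self):
        brain = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [200],
                              "state": ["7_Enh"]})
        blood = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [200],
                              "state": ["15_Quies"]})
        return {("brain", "c1"): brain, ("blood", "c1"): blood}

    def test_half_open_boundaries(self):
        # BED [100, 200) covers 1-based positions 101..200
        v = pd.DataFrame({"id": ["a", "b", "c", "d"], "chrom": "chr1",
                          "pos": [100, 101, 200, 201]})
        out = enhancer_overlap(v, self._chromatin()).set_index("id")
        assert not out.loc["a", "brain"]
        assert out.loc["b", "brain"] and out.loc["c", "brain"]
        assert not out.loc["d", "brain"]
        assert not out["blood"].any()  # quiescent state is not an enhancer

    def test_any_cell_line_counts(self):
        chromatin = self._chromatin()
        chromatin[("blood", "c2")] = pd.DataFrame(
            {"chrom": "chr1", "start": [150], "end": [160], "state": ["6_EnhG"]})
        v = pd.DataFrame({"id": ["x"], "chrom": "chr1", "pos": [155]})
        out = enhancer_overlap(v, chromatin)
        assert out["blood"].iloc[0]


class TestAssembly:
    def test_disjoint_sets_sum(self):
        cats = {"splicing": {"a"}, "damaging_missense": {"b"},
                "utr_mirna": {"c"}, "promoter_tf": {"d"}}
        fs = assemble_functional_sets(cats, {"brain": {"e", "f"}})
        row = fs.tally.iloc[0]
        assert row["union"] == 6 and row["n_multi_category"] == 0

    def test_overlap_counted_once(self):
        cats = {"splicing": set(), "damaging_missense": set(),
                "utr_mirna": set(), "promoter_tf": {"p1", "p2", "p3"}}
        fs = assemble_functional_sets(cats, {"blood": {"p1", "p2", "p3", "e1"}})
        row = fs.tally.iloc[0]
        assert row["raw_sum"] == 7 and row["n_multi_category"] == 3 and row["union"] == 4
        assert fs.per_tissue["blood"] == {"p1", "p2", "p3", "e1"}
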