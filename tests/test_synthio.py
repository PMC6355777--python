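"""Synthetic-data engine: determinism, LD structure, planted features."""

import numpy as np
import pytest
from Bio.Seq import Seq

from postgwas.config import SimConfig
from postgwas.synthio import (build_layout, gen_genotypes, gen_phenotypes, gen_tracks,
                              reference_sequence)
from postgwas.synthio.layout import (BLOCK_SPAN, MOTIF_SNP_OFFSET, TF_CONSENSUS,
                                     _consensus_for_tf)


class TestDeterminism:
    def test_refseq_byte_identical(self, cfg, refseq):
        assert reference_sequence(cfg) == refseq

    def test_panel_identical(self, cfg, panel):
        again = gen_genotypes(cfg)
        assert np.array_equal(again.haplotypes, panel.haplotypes)
        assert again.variants.equals(panel.variants)

    def test_phenotypes_identical(self, cfg, panel, layout, pheno):
        again = gen_phenotypes(cfg, panel, layout)
        assert again.expression["brain"].equals(pheno.expression["brain"])
        assert again.gwas.equals(pheno.gwas)

    def test_seed_changes_output(self, cfg, refseq, panel):
        other = cfg.with_(seed=cfg.seed + 1)
        assert reference_sequence(other) != refseq
        assert not np.array_equal(gen_genotypes(other).haplotypes, panel.haplotypes)


class TestLDStructure:
    def _adjacent_r2(self, panel, block):
        v = panel.variants
        idx = v.index[v["block"] == block].to_numpy()
        H = panel.haplotypes[:, idx].astype(float)
        R = np.corrcoef(H, rowvar=False)
        return np.array([R[j, j + 1] ** 2 for j in range(len(idx) - 1)])

    def test_block_r2_one_gives_perfect_ld(self):
        cfg = SimConfig(n_samples=100, n_blocks=3, n_genes=3, block_r2=1.0, seed=5)
        panel = gen_genotypes(cfg)
        for b in range(3):
            assert np.allclose(self._adjacent_r2(panel, b), 1.0)

    def test_block_r2_zero_gives_independence(self):
        cfg = SimConfig(n_samples=2000, n_blocks=3, n_genes=3, block_r2=0.0, seed=5)
        panel = gen_genotypes(cfg)
        r2 = np.concatenate([self._adjacent_r2(panel, b) for b in range(3)])
        # E[r^2] for independent loci is 1/n_hap
        assert r2.mean() < 5.0 / (2 * cfg.n_samples)

    def test_adjacent_r2_near_target(self):
        cfg = SimConfig(n_samples=4000, n_blocks=4, n_genes=4, block_r2=0.8, seed=9)
        panel = gen_genotypes(cfg)
        r2 = np.concatenate([self._adjacent_r2(panel, b) for b in range(4)])
        assert abs(r2.mean() - 0.8) < 0.05

    def test_blocks_independent(self, panel):
        a = panel.haplotypes[:, panel.variants.index[panel.variants["block"] == 0][0]]
        b = panel.haplotypes[:, panel.variants.index[panel.variants["block"] == 1][0]]
        r = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
        assert abs(r) < 0.2

    def test_polymorphic_and_maf_range(self, panel):
        freqs = panel.haplotypes.mean(axis=0)
        assert np.all((freqs > 0) & (freqs < 1))
        assert panel.variants["maf"].between(0.1, 0.5).all()

    def test_dosages_sum_haplotypes(self, panel):
        assert np.array_equal(panel.dosages, panel.haplotypes[0::2] + panel.haplotypes[1::2])


class TestReferenceSequence:
    def test_cds_translates_cleanly(self, layout, refseq):
        for g in layout.genes:
            if not g.cds:
                continue
            parts = []
            for s, e in g.cds:
                chunk = refseq[s - 1 : e]
                parts.append(chunk if g.strand == "+" else str(Seq(chunk).reverse_complement()))
            cds = "".join(parts)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds[-3:] in {"TAA", "TAG", "TGA"}
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in {"TAA", "TAG", "TGA"} for c in internal)

    def test_minus_strand_tss_at_interval_end(self, layout):
        minus = [g for g in layout.genes if g.strand == "-"]
        assert minus, "layout should place genes on both strands"
        for g in minus:
            assert g.tss == g.tx_end
            ps, pe = g.promoter
            assert ps == g.tss + 1 and pe == g.tss + 1000

    def test_motifs_planted_at_snp(self, layout, refseq):
        assert layout.motif_assignment
        snps = layout.snps.set_index("id")
        for snp_id, tf in layout.motif_assignment.items():
            pos = int(snps.loc[snp_id, "pos"])
            consensus = _consensus_for_tf(tf, layout.tf_genes)
            start0 = pos - 1 - MOTIF_SNP_OFFSET
            assert refseq[start0 : start0 + len(consensus)] == consensus

    def test_mirna_seed_sites_planted(self, layout, refseq):
        assert layout.mirna_assignment
        seeds = layout.mirnas.set_index("name")["seed"]
        snps = layout.snps.set_index("id")
        for snp_id, name in layout.mirna_assignment.items():
            g = layout.gene(str(snps.loc[snp_id, "gene_id"]))
            s, e = g.utr3[0]
            utr = refseq[s - 1 : e]
            if g.strand == "-":
                utr = str(Seq(utr).reverse_complement())
            site = str(Seq(seeds[name]).reverse_complement())
            assert site in utr

    def test_planted_alleles_match_reference(self, panel, refseq):
        for _, r in panel.variants.iterrows():
            assert refseq[int(r["pos"]) - 1] == r["ref"]
            assert r["alt"] != r["ref"]


class TestTracks:
    def test_chromatin_partitions_genome(self, cfg, tracks, layout):
        for (_, _), df in tracks.chromatin.items():
            d = df.sort_values("start")
            assert d["start"].iloc[0] == 0
            assert d["end"].iloc[-1] == layout.genome_length
            assert np.array_equal(d["end"].to_numpy()[:-1], d["start"].to_numpy()[1:])

    def test_signal_blocks_enhancer_covered_both_tissues(self, cfg, tracks, layout):
        from postgwas.annotate import enhancer_overlap

        enh_snps = layout.snps[layout.snps["role"] == "enhancer"].copy()
        enh_snps["chrom"] = layout.chrom
        enh_snps = enh_snps.rename(columns={"id": "id"})
        hits = enhancer_overlap(enh_snps[["id", "chrom", "pos"]].assign(), tracks.chromatin)
        sig_ids = set(
            layout.snps[(layout.snps["role"] == "enhancer")
                        & layout.snps["block"].isin(layout.signal_blocks)]["id"])
        sub = hits[hits["id"].isin(sig_ids)]
        assert sub["brain"].all() and sub["blood"].all()

    def test_null_multiplier_mark_rate(self, cfg, layout):
        null_tracks = gen_tracks(cfg, layout, multiplier=1.0)
        present = [len(df) for df in null_tracks.marks.values()]
        rate = sum(present) / (len(present) * cfg.n_blocks)
        assert abs(rate - 0.25) < 0.05


class TestPhenotypes:
    def test_planted_qtl_detectable(self, panel, layout, pheno):
        from postgwas.qtl_smr import _ols_assoc

        row = pheno.causal_map[pheno.causal_map["analysis"] == "eQTL"].iloc[0]
        x = panel.dosage(row["snp_id"]).astype(float)
        y = pheno.expression["brain"].loc[row["gene"]].to_numpy()
        _, _, p, _ = _ols_assoc(x, y)
        assert p < 1e-10

    def test_null_gwas_z_standard_normal(self, layout, pheno):
        null_blocks = set(range(layout.cfg.n_blocks)) - set(layout.signal_blocks)
        sub = pheno.gwas.merge(layout.snps[["id", "block"]], on="id")
        z = sub[sub["block"].isin(null_blocks)]["z"].to_numpy()
        assert abs(z.mean()) < 0.3 and abs(z.std() - 1.0) < 0.3

    def test_index_snps_are_signal_enhancers(self, layout, pheno):
        snps = layout.snps.set_index("id")
        for sid in pheno.index_snps["id"]:
            assert snps.loc[sid, "role"] == "enhancer"
            assert int(snps.loc[sid, "block"]) in layout.signal_blocks
        assert (pheno.index_snps["p"] < 5e-8).all()

    def test_de_shift_consistent_across_studies(self, layout, pheno):
        sig = [g.gene_id for g in layout.genes if g.signal]
        for gid in sig:
            signs = []
            for s in pheno.de_studies:
                diff = (s.expr.loc[gid, s.labels == 1].mean()
                        - s.expr.loc[gid, s.labels == 0].mean())
                signs.append(np.sign(diff))
            assert len(set(signs)) == 1

    def test_predictor_scores_signal_all_damaging(self, layout, pheno):
        scores = pheno.predictor_scores.set_index("id")
        sig_missense = layout.snps[(layout.snps["role"] == "cds_missense")
                                   & layout.snps["block"].isin(layout.signal_blocks)]
        for sid in sig_missense["id"]:
            assert (scores.loc[sid] == "damaging").all()


def test_small_config_runs():
    cfg = SimConfig(n_samples=50, n_blocks=4, n_genes=3, snps_per_block=8, seed=2)
    pheno = gen_phenotypes(cfg)
    assert len(pheno.gwas) == 32
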