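"""Phased genotype panel with block-LD haplotype structure.

Within a block, haplotype alleles are generated by copying: SNP j copies SNP
j-1's allele with probability sqrt(block_r2) and otherwise draws fresh from
Bernoulli(maf), which gives adjacent-SNP haplotype correlation of exactly
``block_r2`` in expectation (all SNPs of a block share the block's allele
frequency). Blocks are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from postgwas.synthio.layout import Layout, build_layout, planted_alleles, reference_sequence


class MonomorphicPanelError(ValueError):
    """The requested configuration produced a monomorphic SNP."""


@dataclass
class GenotypePanel:
    """Phased diploid panel: 2N haplotypes over M biallelic SNPs (alt coded 1)."""

    variants: pd.DataFrame  # id, chrom, pos, ref, alt, block, role, gene_id, maf
    haplotypes: np.ndarray  # (2N, M) int8, sample i owns rows 2i, 2i+1
    samples: list

    @property
    def dosages(self) -> np.ndarray:
        """(N, M) additive alt-allele dosage matrix (0/1/2)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def dosage(self, snp_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == snp_id]
        if not len(j):
            raise KeyError(snp_id)
        return self.dosages[:, int(j[0])]

    def haplotype(self, snp_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == snp_id]
        if not len(j):
            raise KeyError(snp_id)
        return self.haplotypes[:, int(j[0])]

    def to_vcf(self, path: str | Path) -> None:
        from postgwas import io

        io.write_vcf(self, path)


def _block_haplotypes(n_hap: int, n_snps: int, maf: float, copy_p: float,
                      rng: np.random.Generator) -> np.ndarray:
    fresh = (rng.random((n_hap, n_snps)) < maf).astype(np.int8)
    if n_snps == 1 or copy_p == 0.0:
        return fresh
    copy = rng.random((n_hap, n_snps)) < copy_p
    hap = fresh.copy()
    for j in range(1, n_snps):
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    return hap


def gen_genotypes(cfg, layout: Layout | None = None, refseq: str | None = None,
                  max_retries: int = 10) -> GenotypePanel:
    """Generate the phased panel for a configuration.

    Raises
    ------
    MonomorphicPanelError
        If a block repeatedly yields a monomorphic SNP (degenerate
        configurations: tiny ``n_samples`` with extreme allele frequency).
    """
    if layout is None:
        layout = build_layout(cfg)
    if refseq is None:
        refseq = reference_sequence(cfg, layout)
    rng = np.random.default_rng([int(cfg.seed), 2])
    n_hap = 2 * cfg.n_samples
    copy_p = float(np.sqrt(cfg.block_r2))

    variants = planted_alleles(cfg, layout, refseq, rng)
    variants = variants.sort_values("pos", kind="stable").reset_index(drop=True)

    mafs = rng.uniform(0.1, 0.5, size=cfg.n_blocks)
    cols = np.empty((n_hap, len(variants)), dtype=np.int8)
    maf_col = np.empty(len(variants))
    for b in range(cfg.n_blocks):
        idx = variants.index[variants["block"] == b].to_numpy()
        maf = float(mafs[b])
        for attempt in range(max_retries):
            hap = _block_haplotypes(n_hap, len(idx), maf, copy_p, rng)
            freqs = hap.mean(axis=0)
            if np.all((freqs > 0) & (freqs < 1)):
                break
        else:
            raise MonomorphicPanelError(
                f"block {b} produced a monomorphic SNP after {max_retries} draws "
                f"(n_samples={cfg.n_samples}, maf={maf:.3f})"
            )
        cols[:, idx] = hap
        maf_col[idx] = maf
    variants = variants.assign(maf=maf_col)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypePanel(variants=variants, haplotypes=cols, samples=samples)
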