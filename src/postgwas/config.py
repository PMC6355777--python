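"""Simulation configuration for the synthetic-data engine."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SimConfig:
    """Parameters controlling every synthetic input the pipeline consumes.

    Attributes
    ----------
    n_samples:
        Diploid individuals in the genotype panel.
    n_blocks:
        Number of independent LD blocks tiling the synthetic genome.
    snps_per_block:
        SNPs per block; the first eight carry designated functional roles
        (enhancer, promoter, missense, 3'UTR, intron, intergenic,
        synonymous, splice-site), the remainder are intergenic filler.
    block_r2:
        Target r^2 between adjacent SNPs of a block (haplotype copying).
    n_genes:
        Genes placed one per block (requires ``n_genes <= n_blocks``).
    causal_fraction:
        Fraction of genes planted as disease genes: their blocks carry the
        GWAS signal, motif-disrupting alleles, cis-QTL effects, consistent
        differential expression, and resource-table validation entries.
    qtl_effect:
        Standardized per-allele effect beta of each planted cis-QTL.
    de_effect:
        Standardized case-vs-control mean shift of planted disease genes,
        shared in direction across all simulated expression studies.
    noise_sd:
        Residual standard deviation of all molecular phenotypes.
    seed:
        Master seed; identical configs give bit-identical outputs.
    """

    n_samples: int = 300
    n_blocks: int = 20
    snps_per_block: int = 8
    block_r2: float = 0.8
    n_genes: int = 20
    causal_fraction: float = 0.3
    qtl_effect: float = 0.8
    de_effect: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_blocks", "snps_per_block", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, int) or (v < 1 and not (name == "n_genes" and v == 0)):
                raise ValueError(f"{name} must be a positive integer (got {v!r})")
        if not 0.0 <= self.block_r2 <= 1.0:
            raise ValueError(f"block_r2 must be in [0, 1] (got {self.block_r2})")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError(f"causal_fraction must be in [0, 1] (got {self.causal_fraction})")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive (got {self.noise_sd})")
        if self.n_genes > self.n_blocks:
            raise ValueError("n_genes must not exceed n_blocks (one gene per block)")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
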