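"""Chromatin 15-state tilings and histone-mark interval sets.

Two simulated tissues (brain, blood), two cell lines each. The state tiling
partitions the whole genome (BED, 0-based half-open, state label in the name
field). Histone marks are interval sets per (tissue, cell line, mark); a
configurable ``multiplier`` inflates the per-block presence probability of
the four "active" marks over planted signal blocks, which is what the
variant-set enrichment stage is meant to detect. ``multiplier=1`` is an
exchangeable null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from postgwas.synthio.layout import BLOCK_SPAN, Layout, build_layout

CHROMATIN_STATES = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv", "13_ReprPC",
    "14_ReprPCWk", "15_Quies",
)
DEFAULT_ENHANCER_STATES = frozenset({"6_EnhG", "7_Enh", "12_EnhBiv"})

HISTONE_MARKS = (
    "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1", "H3K4me2", "H3K4me3",
    "H3K79me2", "H3K9ac", "H3K9me", "H3K9me3", "H4K20me1",
)
SIGNAL_MARKS = frozenset({"H3K27ac", "H3K36me3", "H3K4me1", "H3K4me3"})

TISSUES = ("brain", "blood")
CELL_LINES = {"brain": ("brain_c1", "brain_c2"), "blood": ("blood_c1", "blood_c2")}

_ENH_HALF = 200  # enhancer state interval: +/-200 bp around the enhancer SNP
_BASE_MARK_P = 0.25


@dataclass
class TrackSet:
    """Interval tracks: DataFrames with 0-based half-open [start, end)."""

    chromatin: dict = field(default_factory=dict)  # (tissue, cell) -> DataFrame(chrom,start,end,state)
    marks: dict = field(default_factory=dict)      # (tissue, cell, mark) -> DataFrame(chrom,start,end)

    def write_beds(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (tissue, cell), df in self.chromatin.items():
            bed = df.assign(name=df["state"], score=0, strand=".")
            bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
                outdir / f"chromatin15_{tissue}_{cell}.bed", sep="\t", header=False, index=False
            )
        for (tissue, cell, mark), df in self.marks.items():
            bed = df.assign(name=mark, score=0, strand=".")
            bed[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
                outdir / f"mark_{tissue}_{cell}_{mark}.bed", sep="\t", header=False, index=False
            )


def _tissue_covers_enhancer(tissue: str, block: int, signal: bool) -> bool:
    """Which blocks' enhancer SNPs fall in an enhancer state, per tissue.

    Signal blocks are enhancer-active in both tissues; null blocks at 60%
    (brain) / 90% (blood) rates, so the blood functional set is the larger
    one, as in real brain-vs-blood segmentations.
    """
    if signal:
        return True
    return (block % 5) < 3 if tissue == "brain" else (block % 10) < 9


def gen_tracks(cfg, layout: Layout | None = None, multiplier: float = 5.0) -> TrackSet:
    """Generate the chromatin-state tiling and histone-mark tracks."""
    if layout is None:
        layout = build_layout(cfg)
    rng = np.random.default_rng([int(cfg.seed), 3])
    ts = TrackSet()
    signal = set(layout.signal_blocks)

    for tissue in TISSUES:
        for cell in CELL_LINES[tissue]:
            rows = []
            for b in range(cfg.n_blocks):
                origin0 = b * BLOCK_SPAN  # 0-based block start
                segments = []  # (start0, end0, state), half-open
                enh_pos0 = origin0 + 10_000 - 1
                if _tissue_covers_enhancer(tissue, b, b in signal):
                    segments.append((enh_pos0 - _ENH_HALF, enh_pos0 + _ENH_HALF, "7_Enh"))
                gene = layout.gene_by_block(b)
                if gene is not None:
                    ps, pe = gene.promoter
                    segments.append((ps - 1, pe, "1_TssA"))
                    segments.append((gene.tx_start - 1, gene.tx_end, "4_Tx"))
                segments.sort()
                cursor = origin0
                for s0, e0, state in segments:
                    if s0 > cursor:
                        rows.append((cursor, s0, "15_Quies"))
                    rows.append((s0, e0, state))
                    cursor = e0
                if cursor < origin0 + BLOCK_SPAN:
                    rows.append((cursor, origin0 + BLOCK_SPAN, "15_Quies"))
            ts.chromatin[(tissue, cell)] = pd.DataFrame(
                rows, columns=["start", "end", "state"]
            ).assign(chrom=layout.chrom)[["chrom", "start", "end", "state"]]

    for tissue in TISSUES:
        for cell in CELL_LINES[tissue]:
            for mark in HISTONE_MARKS:
                rows = []
                for b in range(cfg.n_blocks):
                    p = _BASE_MARK_P
                    if mark in SIGNAL_MARKS and b in signal:
                        p = min(1.0, _BASE_MARK_P * multiplier)
                    if rng.random() < p:
                        origin0 = b * BLOCK_SPAN
                        rows.append((layout.chrom, origin0 + 4_000, origin0 + 32_000))
                ts.marks[(tissue, cell, mark)] = pd.DataFrame(
                    rows, columns=["chrom", "start", "end"]
                )
    return ts
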