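"""TF motif generation: one strong 8-mer PWM per simulated TF gene."""

from __future__ import annotations

import numpy as np

from postgwas.synthio.layout import Layout, TF_CONSENSUS, build_layout
from postgwas.tfbs import PWM

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_from_consensus(name: str, consensus: str, strength: int = 91,
                       off: int = 3, pseudocount: float = 0.25) -> PWM:
    """Count matrix with ``strength`` observations of the consensus base and
    ``off`` of each alternative per column, pseudocount-normalized."""
    counts = np.full((len(consensus), 4), off, dtype=float)
    for i, b in enumerate(consensus):
        counts[i, _BASE_INDEX[b]] = strength
    return PWM.from_counts(name, counts, pseudocount)


def gen_motifs(cfg, layout: Layout | None = None) -> list[PWM]:
    """One PWM per TF gene, cycling through the fixed consensus set."""
    if layout is None:
        layout = build_layout(cfg)
    return [
        pwm_from_consensus(tf, TF_CONSENSUS[i % len(TF_CONSENSUS)])
        for i, tf in enumerate(layout.tf_genes)
    ]
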