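"""Allele-aware PWM scanning and TF-binding disruption calls.

Log-odds scores against a uniform 0.25/base background, maximized over both
strands and every motif offset that covers the variant. A TF's binding is
called disrupted when the allele score difference exceeds ``delta_min``
(default log 2, a two-fold affinity change) while the better allele still
scores at least ``binding_frac`` of the PWM maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from postgwas.stats import bh_adjust, fisher_one_sided

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP_INDEX = {"A": 3, "C": 2, "G": 1, "T": 0}

DEFAULT_DELTA_MIN = math.log(2.0)
DEFAULT_BINDING_FRAC = 0.8


@dataclass
class PWM:
    """Position probability matrix, rows = positions, columns = A,C,G,T."""

    name: str
    probs: np.ndarray  # (L, 4), each row sums to 1

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM needs an (L, 4) probability matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @classmethod
    def from_counts(cls, name: str, counts, pseudocount: float = 0.25) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True))

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def score_allele(window: str, pwm: PWM, center: int | None = None) -> float:
    """Best log-odds over both strands and all offsets covering ``center``.

    ``center`` defaults to the middle of the window (the variant base).
    The window must extend at least L-1 bases on each side of the center so
    every covering offset is scoreable.
    """
    window = window.upper()
    L = len(pwm)
    if center is None:
        center = len(window) // 2
    if center - (L - 1) < 0 or center + (L - 1) > len(window) - 1:
        raise ValueError(f"window too short: need >= {2 * L - 1} bases centered on the variant")
    lo = pwm.log_odds
    best = -np.inf
    fwd = np.array([_BASE_INDEX[b] for b in window])
    rev = np.array([_COMP_INDEX[b] for b in window])
    for start in range(center - L + 1, center + 1):
        seg_f = fwd[start : start + L]
        best = max(best, float(lo[np.arange(L), seg_f].sum()))
        # reverse strand: motif read 3'->5' on the forward sequence
        seg_r = rev[start : start + L][::-1]
        best = max(best, float(lo[np.arange(L), seg_r].sum()))
    return best


def call_disruption(variant_id: str, ref_window: str, alt_window: str, pwms,
                    delta_min: float = DEFAULT_DELTA_MIN,
                    binding_frac: float = DEFAULT_BINDING_FRAC,
                    center: int | None = None) -> pd.DataFrame:
    """One disruption record per TF whose criterion fires for this variant."""
    rows = []
    for pwm in pwms:
        ref_s = score_allele(ref_window, pwm, center)
        alt_s = score_allele(alt_window, pwm, center)
        delta = alt_s - ref_s
        if abs(delta) >= delta_min and max(ref_s, alt_s) >= binding_frac * pwm.max_score:
            rows.append({"id": variant_id, "tf": pwm.name, "ref_score": ref_s,
                         "alt_score": alt_s, "delta": delta})
    return pd.DataFrame(rows, columns=["id", "tf", "ref_score", "alt_score", "delta"])


def scan_variants(variants: pd.DataFrame, refseq: str, pwms, flank: int | None = None,
                  delta_min: float = DEFAULT_DELTA_MIN,
                  binding_frac: float = DEFAULT_BINDING_FRAC) -> pd.DataFrame:
    """Disruption calls for a table of SNVs against the reference sequence."""
    if not len(variants):
        return pd.DataFrame(columns=["id", "tf", "ref_score", "alt_score", "delta"])
    if flank is None:
        flank = max(len(p) for p in pwms) - 1
    out = []
    for _, v in variants.iterrows():
        pos0 = int(v["pos"]) - 1
        left = refseq[pos0 - flank : pos0]
        right = refseq[pos0 + 1 : pos0 + 1 + flank]
        ref_w = left + str(v["ref"]) + right
        alt_w = left + str(v["alt"]) + right
        out.append(call_disruption(v["id"], ref_w, alt_w, pwms, delta_min, binding_frac,
                                   center=flank))
    out = [df for df in out if len(df)]
    if not out:
        return pd.DataFrame(columns=["id", "tf", "ref_score", "alt_score", "delta"])
    return pd.concat(out, ignore_index=True)


def tf_enrichment(disruptions: pd.DataFrame, functional_ids: set,
                  background_ids: set) -> pd.DataFrame:
    """Per-TF enrichment of disruption in the functional set vs background.

    One-sided Fisher exact test on {disrupts TF, not} x {functional,
    background}, Benjamini-Hochberg across TFs. SNPs in neither set are
    ignored; an empty disruption table yields an empty result.
    """
    functional_ids, background_ids = set(functional_ids), set(background_ids)
    rows = []
    for tf, sub in disruptions.groupby("tf") if len(disruptions) else []:
        hit = set(sub["id"])
        a = len(hit & functional_ids)
        b = len(functional_ids) - a
        c = len(hit & background_ids)
        d = len(background_ids) - c
        odds, p = fisher_one_sided(a, b, c, d)
        rows.append({"tf": tf, "n_functional": a, "n_background": c,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows, columns=["tf", "n_functional", "n_background", "odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else out.get("p")
    return out


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def tf_expression_check(expr: pd.DataFrame, labels, tfs) -> pd.DataFrame:
    """Two-condition differential expression of candidate TFs.

    ``expr`` is a genes x samples matrix of log-scale expression, ``labels``
    a binary condition vector over samples. Per TF: Welch-free two-sample
    t-test, log-fold-change (condition 1 minus 0), BH adjustment, and
    significance stars at adjusted p < 0.05 / 0.01 / 0.001. Constant genes
    get p = 1 with a flag.
    """
    from scipy import stats as sps

    labels = np.asarray(labels)
    g1 = expr.loc[:, labels == 1]
    g0 = expr.loc[:, labels == 0]
    rows = []
    for tf in tfs:
        if tf not in expr.index:
            continue
        x1, x0 = g1.loc[tf].to_numpy(float), g0.loc[tf].to_numpy(float)
        lfc = float(x1.mean() - x0.mean())
        if np.ptp(np.concatenate([x1, x0])) == 0:
            rows.append({"tf": tf, "lfc": 0.0, "p": 1.0, "degenerate": True})
            continue
        p = float(sps.ttest_ind(x1, x0).pvalue)
        rows.append({"tf": tf, "lfc": lfc, "p": p, "degenerate": False})
    out = pd.DataFrame(rows, columns=["tf", "lfc", "p", "degenerate"])
    out["q"] = bh_adjust(out["p"]) if len(out) else None
    out["stars"] = [_stars(q) for q in out["q"]] if len(out) else None
    return out
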