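"""Shared statistical primitives: FDR, exact tests, Stouffer combination.

Thin wrappers around scipy/statsmodels so every module applies multiple-testing
correction and exact tests identically.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def fisher_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test on the 2x2 table [[a,b],[c,d]].

    Returns (odds_ratio, p). The alternative is 'greater': the first row is
    over-represented in the first column.
    """
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def hypergeom_enrichment(overlap: int, universe: int, set_size: int, query: int) -> float:
    """Upper-tail hypergeometric p for observing >= overlap hits.

    ``universe`` genes total, ``set_size`` in the annotation set, ``query``
    drawn; p = P(X >= overlap).
    """
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, query))


def stouffer_weighted(z: np.ndarray, n: np.ndarray) -> float:
    """Sample-size-weighted Stouffer combination: sum(sqrt(N_i) z_i)/sqrt(sum N_i)."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    return float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))


def p_to_signed_z(p: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Two-sided p plus effect direction -> signed z-score.

    z = Phi^-1(1 - p/2) * sign(direction); p is clipped away from 0/1 so the
    quantile stays finite.
    """
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1 - 1e-16)
    mag = sps.norm.isf(p / 2.0)
    return mag * np.sign(np.asarray(direction, dtype=float))


def z_to_p_two_sided(z) -> np.ndarray:
    return 2.0 * sps.norm.sf(np.abs(np.asarray(z, dtype=float)))


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage with half-up rounding to ``decimals`` places.

    ``percent(168, 447)`` is 37.58; ``percent(0, n)`` is 0.0.
    """
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(exp, rounding=ROUND_HALF_UP))
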