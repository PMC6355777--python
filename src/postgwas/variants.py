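"""Susceptibility-set assembly: index SNPs, LD expansion, summary SNPs.

Index SNPs are trait-associated variants at genome-wide significance;
LD SNPs are panel variants in strong LD (r^2 >= 0.8, inclusive) with an
index SNP; summary SNPs come from association summary statistics filtered
at P < 5e-8 (strict). The merged susceptibility set is deduplicated by
(chrom, pos, allele pair) with source precedence index > ld > summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

R2_DEFAULT = 0.8
P_GWS = 5e-8
_EPS = 1e-12

SOURCE_PRECEDENCE = {"index": 0, "ld": 1, "summary": 2}


@dataclass
class LDBlock:
    """An index SNP together with all its strong-LD partners."""

    index_id: str
    members: set = field(default_factory=set)

    def __post_init__(self):
        self.members = set(self.members) | {self.index_id}


class MonomorphicError(ValueError):
    """LD is undefined for a monomorphic locus."""


def compute_r2(hap_a, hap_b) -> float:
    """Squared LD correlation r^2 = D^2 / (pA pa pB pb) from phased haplotypes.

    ``hap_a`` / ``hap_b`` are equal-length 0/1 vectors over the same
    haplotypes; D = p_AB - p_A p_B. Symmetric in its arguments. Raises
    :class:`MonomorphicError` when either locus is monomorphic.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be equal-length 1-D arrays")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicError("r^2 undefined for a monomorphic locus")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_against(panel_haps: np.ndarray, col: int) -> np.ndarray:
    """Vectorized r^2 of one panel column against all columns."""
    H = panel_haps.astype(float)
    Hc = H - H.mean(axis=0)
    x = Hc[:, col]
    denom = (x @ x) * np.einsum("ij,ij->j", Hc, Hc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (x @ Hc) ** 2 / denom
    return r2


def ld_expand(index: pd.DataFrame, panel, r2_min: float = R2_DEFAULT):
    """Expand index SNPs to their strong-LD partners in the panel.

    Parameters
    ----------
    index:
        DataFrame with at least an ``id`` column; index SNPs absent from
        the panel are logged and skipped.
    panel:
        A :class:`~postgwas.synthio.genotypes.GenotypePanel` (phased).
    r2_min:
        Inclusive threshold; a partner at exactly r2_min is kept.

    Returns
    -------
    (ld_df, blocks): LD-SNP table (id, chrom, pos, ref, alt, source,
    ld_partner, r2) and one :class:`LDBlock` per usable index SNP.
    """
    if panel is None or not len(panel.variants):
        raise ValueError("empty genotype panel")
    pv = panel.variants.reset_index(drop=True)
    id_to_col = {sid: j for j, sid in enumerate(pv["id"])}
    ld_rows, blocks = [], []
    for iid in index["id"]:
        col = id_to_col.get(iid)
        if col is None:
            logger.warning("index SNP %s not in panel; skipped", iid)
            continue
        r2 = _r2_against(panel.haplotypes, col)
        partners = np.flatnonzero((r2 >= r2_min - _EPS) & np.isfinite(r2))
        members = set()
        for j in partners:
            sid = pv.at[j, "id"]
            members.add(sid)
            if sid == iid:
                continue
            ld_rows.append({
                "id": sid, "chrom": pv.at[j, "chrom"], "pos": int(pv.at[j, "pos"]),
                "ref": pv.at[j, "ref"], "alt": pv.at[j, "alt"],
                "source": "ld", "ld_partner": iid, "r2": float(r2[j]),
            })
        blocks.append(LDBlock(index_id=iid, members=members))
    cols = ["id", "chrom", "pos", "ref", "alt", "source", "ld_partner", "r2"]
    ld_df = pd.DataFrame(ld_rows, columns=cols)
    # stable, input-order-independent ordering
    ld_df = ld_df.sort_values(["chrom", "pos", "id", "ld_partner"], kind="stable").reset_index(drop=True)
    blocks.sort(key=lambda b: b.index_id)
    return ld_df, blocks


def merge_sources(index: pd.DataFrame, ld: pd.DataFrame, summary: pd.DataFrame,
                  p_max: float = P_GWS) -> pd.DataFrame:
    """Merged, deduplicated susceptibility set.

    Summary SNPs are filtered at p < p_max (strict). Duplicates share
    (chrom, pos, unordered allele pair); the record with the strongest
    source (index > ld > summary) is retained and the discarded sources are
    recorded in ``also_in``.
    """
    frames = []
    for df, source in ((index, "index"), (ld, "ld"), (summary, "summary")):
        if df is None or not len(df):
            continue
        d = df.copy()
        d["source"] = d.get("source", source) if "source" in d else source
        d["source"] = d["source"].fillna(source) if d["source"].isna().any() else d["source"]
        if source == "summary":
            d = d[d["p"].astype(float) < p_max]
        frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["id", "chrom", "pos", "ref", "alt", "source", "also_in"])
    allc = pd.concat(frames, ignore_index=True)
    allc["_key"] = [
        (c, int(p), tuple(sorted((str(r), str(a)))))
        for c, p, r, a in zip(allc["chrom"], allc["pos"], allc["ref"], allc["alt"])
    ]
    allc["_rank"] = allc["source"].map(SOURCE_PRECEDENCE)
    allc = allc.sort_values(["_key", "_rank"], kind="stable")
    keep = []
    for key, grp in allc.groupby("_key", sort=False):
        first = grp.iloc[0].copy()
        others = sorted(set(grp["source"].iloc[1:]))
        first["also_in"] = ",".join(others)
        ids = set(grp["id"])
        if len(ids) > 1:
            logger.warning("rsID mismatch at %s: %s", key, sorted(ids))
        keep.append(first)
    out = pd.DataFrame(keep).drop(columns=["_key", "_rank"])
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
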