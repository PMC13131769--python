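"""LD computation, greedy clumping, chunk assignment, and the pi1 statistic.

Clumping follows the classic greedy lead-SNP procedure: the unassigned
variant with the smallest p (<= p1) becomes a lead; every unassigned
variant with p <= p2, within ``kb`` kilobases of the lead, and r2 >= the
clump threshold with the lead joins it.  Ties on p break by position then
id, making the output independent of input order.  A clump (LD chunk) is
the unit treated as one independent signal: significant eQTLs from
different cell types landing on the same chunk are the same eQTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SummaryStatsTable

logger = logging.getLogger(__name__)

__all__ = ["LdMatrix", "Clump", "ld_r", "clump", "assign_to_chunks", "pi1"]


@dataclass
class LdMatrix:
    """Signed pairwise dosage correlation with an r2 view."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError("r must be square over the variant ids")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def submatrix(self, ids: list[str]) -> "LdMatrix":
        idx = [self.index(v) for v in ids]
        return LdMatrix(list(ids), self.r[np.ix_(idx, idx)])


def ld_r(genotypes: GenotypeMatrix, variant_ids: list[str] | None = None) -> LdMatrix:
    """Pairwise Pearson correlation of dosage columns over complete pairs."""
    ids = variant_ids if variant_ids is not None else genotypes.variant_ids
    sub = genotypes.subset_variants(ids)
    df = pd.DataFrame(sub.dosage, columns=ids)
    r = df.corr(min_periods=2).to_numpy()
    np.fill_diagonal(r, 1.0)
    return LdMatrix(list(ids), r)


@dataclass
class Clump:
    """A lead variant plus the correlated variants it absorbs."""

    chunk_id: str
    lead: str
    lead_p: float
    members: list[str] = field(default_factory=list)  # includes the lead
    member_p: dict[str, float] = field(default_factory=dict)
    span: tuple[int, int] = (0, 0)  # bp range covered by members

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.member_p


def clump(stats: SummaryStatsTable, ld: LdMatrix, p1: float, p2: float,
          r2_thresh: float = 0.1, kb: float = 500.0) -> list[Clump]:
    """Greedy LD clumping of a summary-statistics table."""
    t = stats.table[stats.table["snp"].isin(ld._index)]
    t = t.sort_values(["p", "pos", "snp"], kind="mergesort")
    order = list(t[["snp", "p", "pos"]].itertuples(index=False, name=None))
    pos = dict(zip(t["snp"], t["pos"].astype(int)))
    pvals = dict(zip(t["snp"], t["p"].astype(float)))
    assigned: set[str] = set()
    clumps: list[Clump] = []
    max_bp = kb * 1000.0
    for snp, p, snp_pos in order:
        if snp in assigned or p > p1:
            continue
        members = [snp]
        for other, op, opos in order:
            if other in assigned or other == snp or op > p2:
                continue
            if abs(opos - snp_pos) > max_bp:
                continue
            if ld.r2_between(snp, other) >= r2_thresh:
                members.append(other)
        assigned.update(members)
        spans = [pos[v] for v in members]
        clumps.append(Clump(
            chunk_id=f"chunk{len(clumps)}", lead=snp, lead_p=float(p),
            members=members, member_p={v: pvals[v] for v in members},
            span=(min(spans), max(spans))))
    return clumps


def assign_to_chunks(records: pd.DataFrame, clumps: list[Clump],
                     sig_threshold: float, p_col: str = "p_re2",
                     variant_col: str = "variant_id") -> pd.DataFrame:
    """Map eQTL records to LD chunks and flag per-chunk cell-type detection.

    Every record whose eSNP belongs to a clump receives that clump's
    ``chunk_id`` (clumps partition variants, so membership is unique);
    records on the same chunk share one eQTL identity across cell types.
    ``detected`` marks, per chunk and cell type, whether any member eSNP
    passes ``sig_threshold`` in that cell type.
    """
    membership: dict[str, str] = {}
    for c in clumps:
        for v in c.members:
            if v in membership:
                raise ValueError(f"variant {v} in two clumps")
            membership[v] = c.chunk_id
    out = records.copy()
    out["chunk_id"] = out[variant_col].map(membership)
    detected = (
        out.dropna(subset=["chunk_id"])
        .assign(sig=lambda d: d[p_col] <= sig_threshold)
        .groupby(["chunk_id", "cell_type"])["sig"].any()
        .rename("detected"))
    out = out.merge(detected, on=["chunk_id", "cell_type"], how="left")
    out["detected"] = out["detected"].fillna(False).astype(bool)
    return out


def pi1(pvalues: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimate of the fraction of non-null tests.

    pi0 = #{p > lambda} / (m (1 - lambda)), capped at 1; pi1 = 1 - pi0.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value set")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    pi0 = min(1.0, float((p > lam).sum()) / (len(p) * (1.0 - lam)))
    return 1.0 - pi0
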