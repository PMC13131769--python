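"""Summary-based Mendelian randomization and the HEIDI linkage test.

``smr_single`` tests whether expression mediates trait risk using the top
eSNP as an instrument: b_xy = b_GWAS / b_eQTL with the SMR chi-square
T = z_g^2 z_e^2 / (z_g^2 + z_e^2) on 1 df.  ``heidi`` (heterogeneity in
dependent instruments) asks whether b_xy is constant across cis SNPs in
LD with the top eSNP — constancy is what a single shared causal variant
implies, while linkage between two distinct causal variants makes b_xy
drift with r^2.  ``smr_multi`` sums per-SNP SMR statistics over the
HEIDI-selected SNPs with an LD-aware weighted-chi-square null.

Downstream pass rules: SMR p at the Bonferroni level for the forwarded
gene count, and HEIDI p >= 0.01 (non-significant heterogeneity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LdMatrix

logger = logging.getLogger(__name__)

__all__ = ["SmrResult", "smr_single", "heidi", "smr_multi", "run_smr",
           "SMR_COLUMNS", "InstrumentTooWeak"]

SMR_COLUMNS = ["gene_id", "cell_type", "top_esnp", "b_xy", "se_xy",
               "p_smr", "p_smr_multi", "p_heidi", "n_heidi_snps"]

#: default eQTL p-value gate for HEIDI candidate SNPs
HEIDI_PEQTL_GATE = 1.57e-3
#: minimum instrument strength |z_e|
MIN_INSTRUMENT_Z = 3.0


class InstrumentTooWeak(ValueError):
    """Top eSNP does not meet the instrument-strength threshold."""


@dataclass
class SmrResult:
    gene_id: str
    cell_type: str
    top_esnp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_smr_multi: float | None = None
    p_heidi: float | None = None
    n_heidi_snps: int = 0

    def row(self) -> tuple:
        return (self.gene_id, self.cell_type, self.top_esnp, self.b_xy,
                self.se_xy, self.p_smr, self.p_smr_multi, self.p_heidi,
                self.n_heidi_snps)


def _t_smr(z_g: float, z_e: float) -> float:
    zg2, ze2 = z_g ** 2, z_e ** 2
    if zg2 + ze2 == 0:
        return 0.0
    return zg2 * ze2 / (zg2 + ze2)


def smr_single(gwas: tuple[float, float], eqtl: tuple[float, float],
               min_instrument_z: float = MIN_INSTRUMENT_Z,
               ) -> tuple[float, float, float]:
    """Single-instrument SMR: returns (b_xy, se_xy, p_smr)."""
    b_g, se_g = gwas
    b_e, se_e = eqtl
    if se_g <= 0 or se_e <= 0:
        raise ValueError("standard errors must be positive")
    z_e = b_e / se_e
    if abs(z_e) < min_instrument_z:
        raise InstrumentTooWeak(
            f"|z_eQTL| = {abs(z_e):.2f} < {min_instrument_z}")
    z_g = b_g / se_g
    t = _t_smr(z_g, z_e)
    b_xy = b_g / b_e
    p = float(stats.chi2.sf(t, 1)) if t > 0 else 1.0
    se_xy = abs(b_xy) / np.sqrt(t) if t > 0 else np.inf
    return float(b_xy), float(se_xy), p


def _select_heidi_snps(top: str, eqtl: pd.DataFrame, ld: LdMatrix,
                       p_eqtl_gate: float, r2_window: tuple[float, float],
                       prune_r2: float, max_snps: int) -> list[str]:
    lo, hi = r2_window
    cands = []
    for row in eqtl.itertuples():
        snp = row.Index
        if snp == top or row.p >= p_eqtl_gate:
            continue
        if snp not in ld._index:
            continue
        r2 = ld.r2_between(snp, top)
        if lo <= r2 <= hi:
            cands.append((abs(row.beta / row.se), snp))
    cands.sort(reverse=True)
    kept: list[str] = []
    for _, snp in cands:
        if all(ld.r2_between(snp, k) <= prune_r2 for k in kept):
            kept.append(snp)
        if len(kept) == max_snps:
            break
    return kept


def heidi(top_esnp: str, eqtl: pd.DataFrame, gwas: pd.DataFrame, ld: LdMatrix,
          p_eqtl_gate: float = HEIDI_PEQTL_GATE,
          r2_window: tuple[float, float] = (0.05, 0.9),
          max_snps: int = 20, min_snps: int = 3,
          ridge: float = 1e-6) -> tuple[float | None, int]:
    """HEIDI heterogeneity test around the top eSNP.

    ``eqtl`` and ``gwas`` are allele-harmonized frames indexed by snp with
    columns beta, se (eqtl additionally p).  Candidate SNPs pass the eQTL
    p gate, sit in the r2 window around the top eSNP, are pruned so no
    pair exceeds r2 0.9, and are truncated to the ``max_snps`` strongest
    eQTL z-scores; with fewer than ``min_snps`` candidates the test is
    absent: (None, 0).

    The statistic sums squared standardized differences
    d_i = b_xy(i) - b_xy(top); its null is a scaled chi-square matched to
    the first two moments of the correlated-d eigenstructure
    (delta-method covariance with cross-SNP correlations equal to LD r).
    """
    snps = _select_heidi_snps(top_esnp, eqtl, ld, p_eqtl_gate, r2_window,
                              0.9, max_snps)
    if len(snps) < min_snps:
        return None, 0
    order = [top_esnp] + snps
    b_g = gwas.loc[order, "beta"].to_numpy(float)
    se_g = gwas.loc[order, "se"].to_numpy(float)
    b_e = eqtl.loc[order, "beta"].to_numpy(float)
    se_e = eqtl.loc[order, "se"].to_numpy(float)
    r = ld.submatrix(order).r

    b_xy = b_g / b_e
    # delta-method covariance of b_xy across SNPs; GWAS and eQTL stats are
    # independent cohorts, within each the cross-SNP correlation is LD r
    cov_g = r * np.outer(se_g, se_g)
    cov_e = r * np.outer(se_e, se_e)
    inv_be = 1.0 / b_e
    grad_e = -b_g / b_e ** 2
    cov_xy = (np.outer(inv_be, inv_be) * cov_g
              + np.outer(grad_e, grad_e) * cov_e)
    m = len(snps)
    # d_i = b_xy[i] - b_xy[0], i = 1..m
    cov_d = (cov_xy[1:, 1:] - cov_xy[1:, [0]] - cov_xy[[0], 1:]
             + cov_xy[0, 0])
    d = b_xy[1:] - b_xy[0]
    var_d = np.diag(cov_d).copy()
    var_d[var_d <= 0] = np.nan
    z_d = d / np.sqrt(var_d)
    denom = np.sqrt(np.outer(var_d, var_d))
    corr_d = cov_d / denom
    corr_d = np.nan_to_num(corr_d, nan=0.0)
    np.fill_diagonal(corr_d, 1.0)
    w = np.linalg.eigvalsh(corr_d)
    if w.min() < 0:
        corr_d += (ridge - w.min()) * np.eye(m)
        w = np.linalg.eigvalsh(corr_d)
        logger.debug("HEIDI correlation ridge-regularized")
    s = float(np.nansum(z_d ** 2))
    e_s = float(w.sum())
    var_s = float(2.0 * (w ** 2).sum())
    if var_s <= 0:
        return 1.0, m
    scale = var_s / (2.0 * e_s)
    df = 2.0 * e_s ** 2 / var_s
    p = float(stats.chi2.sf(s / scale, df))
    return p, m


def smr_multi(snps: list[str], gwas: pd.DataFrame, eqtl: pd.DataFrame,
              ld: LdMatrix) -> float:
    """Multi-SNP SMR: sum of per-SNP SMR statistics with an LD-aware null.

    The null of S = sum_i T_SMR(i) is approximated as a weighted sum of
    chi-square(1) variables with weights the eigenvalues of the r^2
    matrix among the SNPs, evaluated by Satterthwaite two-moment matching.
    """
    if len(snps) == 0:
        raise ValueError("empty SNP set")
    z_g = (gwas.loc[snps, "beta"] / gwas.loc[snps, "se"]).to_numpy(float)
    z_e = (eqtl.loc[snps, "beta"] / eqtl.loc[snps, "se"]).to_numpy(float)
    t = np.array([_t_smr(g, e) for g, e in zip(z_g, z_e)])
    s = float(t.sum())
    c = ld.submatrix(list(snps)).r2
    w = np.linalg.eigvalsh(c)
    w = np.maximum(w, 0.0)
    e_s = float(w.sum())
    var_s = float(2.0 * (w ** 2).sum())
    if var_s <= 0 or e_s <= 0:
        return 1.0
    scale = var_s / (2.0 * e_s)
    df = 2.0 * e_s ** 2 / var_s
    return float(stats.chi2.sf(s / scale, df))


def run_smr(gene_id: str, cell_type: str, eqtl: pd.DataFrame,
            gwas: pd.DataFrame, ld: LdMatrix,
            p_eqtl_gate: float = HEIDI_PEQTL_GATE,
            heidi_min_snps: int = 3, heidi_max_snps: int = 20,
            min_instrument_z: float = MIN_INSTRUMENT_Z) -> SmrResult | None:
    """SMR + HEIDI + multi-SNP SMR for one gene in one cell type.

    ``eqtl``/``gwas``: allele-harmonized frames indexed by snp with
    columns beta, se, p.  The instrument is the smallest-eQTL-p SNP with
    |z_e| >= ``min_instrument_z``; returns None when no SNP qualifies.
    """
    shared = eqtl.index.intersection(gwas.index)
    shared = [s for s in shared if s in ld._index]
    if not shared:
        return None
    et = eqtl.loc[shared]
    gt = gwas.loc[shared]
    z_e = (et["beta"] / et["se"]).abs()
    strong = et[z_e >= min_instrument_z]
    if strong.empty:
        return None
    top = strong["p"].idxmin()
    b_xy, se_xy, p_smr = smr_single(
        (float(gt.loc[top, "beta"]), float(gt.loc[top, "se"])),
        (float(et.loc[top, "beta"]), float(et.loc[top, "se"])),
        min_instrument_z)
    p_heidi, n_used = heidi(top, et, gt, ld, p_eqtl_gate,
                            max_snps=heidi_max_snps, min_snps=heidi_min_snps)
    heidi_set = _select_heidi_snps(top, et, ld, p_eqtl_gate, (0.05, 0.9),
                                   0.9, heidi_max_snps) if n_used else []
    p_multi = smr_multi([top] + heidi_set, gt, et, ld)
    return SmrResult(gene_id, cell_type, str(top), b_xy, se_xy, p_smr,
                     p_multi, p_heidi, n_used)
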