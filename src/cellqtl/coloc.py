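"""Bayesian colocalization under the single-causal-variant assumption.

For each SNP shared between an eQTL signal and a GWAS LD chunk, Wakefield
approximate Bayes factors summarize the association evidence of each
trait; the five-hypothesis posterior (H0 none, H1 eQTL only, H2 GWAS
only, H3 two distinct causal variants, H4 one shared causal variant) is
assembled in log space from per-SNP lABF sums with the standard priors
p1 = p2 = 1e-4 (SNP associated with one trait) and p12 = 1e-5 (with
both).  PP4 >= 0.8 is the pass rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io import SummaryStatsTable, harmonize_alleles
from .ld import Clump

logger = logging.getLogger(__name__)

__all__ = ["ColocResult", "wakefield_labf", "labf_from_p", "coloc_posteriors",
           "pair_and_run", "COLOC_COLUMNS"]

#: Wakefield prior SD on the trait-effect scale
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2

COLOC_COLUMNS = ["gene_id", "cell_type", "chunk_id", "n_snps",
                 "pp0", "pp1", "pp2", "pp3", "pp4", "pass"]


@dataclass
class ColocResult:
    gene_id: str
    cell_type: str
    chunk_id: str
    n_snps: int
    pp: np.ndarray  # pp0..pp4

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, float)
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posteriors do not sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_labf(beta: np.ndarray, se: np.ndarray,
                   sd_prior: float = PRIOR_SD_QUANTITATIVE) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    With z = beta/se, V = se^2, W = sd_prior^2 and r = W/(V+W):
    lABF = 0.5 log(1 - r) + 0.5 r z^2.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if sd_prior <= 0:
        raise ValueError("sd_prior must be positive")
    z = beta / se
    v = se ** 2
    w = sd_prior ** 2
    r = w / (v + w)
    return 0.5 * np.log(1.0 - r) + 0.5 * r * z ** 2


def labf_from_p(p: np.ndarray, maf: np.ndarray, n: np.ndarray,
                sd_prior: float = PRIOR_SD_QUANTITATIVE) -> np.ndarray:
    """lABF reconstructed from p, MAF and sample size.

    Uses the standard variance approximation V ~ 1/(2 N maf (1-maf)) for a
    unit-variance quantitative phenotype, with |z| from the p-value.
    """
    from scipy import stats

    p = np.asarray(p, float)
    maf = np.asarray(maf, float)
    n = np.asarray(n, float)
    z = stats.norm.isf(p / 2.0)
    v = 1.0 / (2.0 * n * maf * (1.0 - maf))
    se = np.sqrt(v)
    return wakefield_labf(z * se, se, sd_prior)


def coloc_posteriors(labf1: np.ndarray, labf2: np.ndarray,
                     p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
                     ) -> np.ndarray:
    """Five-hypothesis posterior from per-SNP lABFs of the two traits.

    Computed in log space; the H3 mass (sum over ordered pairs of distinct
    SNPs) is e^(L1+L2) - e^L12 and is clipped at zero with a warning if
    numerically negative.
    """
    labf1 = np.asarray(labf1, float)
    labf2 = np.asarray(labf2, float)
    if labf1.shape != labf2.shape or labf1.size == 0:
        raise ValueError("traits must share a non-empty SNP list")
    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + l1
    lh[2] = np.log(p2) + l2
    # H3: log(e^(L1+L2) - e^L12), guarded against cancellation
    cross = l1 + l2
    if cross <= l12 + 1e-12:
        if cross < l12 - 1e-9:
            logger.warning("negative H3 mass clipped to zero")
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + cross + np.log1p(-np.exp(l12 - cross))
    lh[4] = np.log(p12) + l12
    pp = np.exp(lh - logsumexp(lh))
    return pp / pp.sum()


def pair_and_run(eqtl_stats: dict[tuple[str, str], SummaryStatsTable],
                 gwas: SummaryStatsTable,
                 gwas_chunks: list[Clump],
                 cis_ranges: dict[str, tuple[str, int, int]],
                 threshold: float = 0.8,
                 p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
                 sd_prior_eqtl: float = PRIOR_SD_QUANTITATIVE,
                 sd_prior_gwas: float = PRIOR_SD_BINARY,
                 span_kb: float = 500.0) -> pd.DataFrame:
    """Colocalize each significant gene x cell type against GWAS chunks.

    ``eqtl_stats`` maps (gene_id, cell_type) to that gene's cis-wide
    meta-eQTL summary statistics; ``cis_ranges`` maps gene_id to
    (chrom, lo, hi) of its cis window.  For every chunk whose span
    overlaps the cis window, the SNP set is every shared cis SNP within
    ``span_kb`` kilobases of the chunk lead (not just chunk members, so
    both association profiles are complete around the signal), alleles
    are harmonized to the GWAS table, and the posterior is computed;
    pass = PP4 >= ``threshold``.  Genes whose cis window overlaps no
    chunk produce no rows.
    """
    from .io import VariantRecord

    gwas_t = gwas.table.set_index("snp")
    gwas_ref = [VariantRecord(id=r.snp, chrom=r.chrom, pos=int(r.pos),
                              a1=str(r.a1), a2=str(r.a2), eaf=float(r.eaf))
                for r in gwas.table.itertuples(index=False)]
    rows = []
    for (gene_id, cell_type), stats in eqtl_stats.items():
        chrom, lo, hi = cis_ranges[gene_id]
        for chunk in gwas_chunks:
            span_lo, span_hi = chunk.span
            chunk_chrom = str(gwas_t.loc[chunk.lead, "chrom"])
            if chunk_chrom != str(chrom) or span_hi < lo or span_lo > hi:
                continue
            harm = harmonize_alleles(stats, gwas_ref)
            lead_pos = int(gwas_t.loc[chunk.lead, "pos"])
            max_bp = span_kb * 1000.0
            snps = [s for s in harm.table["snp"]
                    if s in gwas_t.index
                    and abs(int(gwas_t.loc[s, "pos"]) - lead_pos) <= max_bp
                    and lo <= int(gwas_t.loc[s, "pos"]) <= hi]
            if not snps:
                continue
            et = harm.table.set_index("snp").loc[snps]
            gt = gwas_t.loc[snps]
            labf_e = wakefield_labf(et["beta"].to_numpy(),
                                    et["se"].to_numpy(), sd_prior_eqtl)
            labf_g = wakefield_labf(gt["beta"].to_numpy(),
                                    gt["se"].to_numpy(), sd_prior_gwas)
            pp = coloc_posteriors(labf_e, labf_g, p1, p2, p12)
            rows.append((gene_id, cell_type, chunk.chunk_id, len(snps),
                         *pp, pp[4] >= threshold))
    return pd.DataFrame(rows, columns=COLOC_COLUMNS)
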