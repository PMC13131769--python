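"""Candidate-variant selection and per-cell-type cis-eQTL regression.

Expression enters already residualized and z-scaled, so the additive model
per gene-variant pair is a simple OLS of expression on dosage with an
intercept; betas read as SD of expression per effect allele and p-values
come from a two-sided t test at n - 2 degrees of freedom.

Dynamic (genotype x pathology) effects are tested by adding a
dosage * Lewy-score interaction term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateTable, GeneAnnotation, GenotypeMatrix, SummaryStatsTable
from .ld import ld_r
from .pseudobulk import PseudobulkExpression

logger = logging.getLogger(__name__)

__all__ = ["EQTL_COLUMNS", "select_candidate_variants", "map_cis",
           "dynamic_interaction", "VariantSelection"]

EQTL_COLUMNS = ["gene_id", "variant_id", "cell_type", "dataset",
                "beta", "se", "t_stat", "p", "n_subjects"]

DYNAMIC_COLUMNS = ["gene_id", "variant_id", "cell_type",
                   "beta_interaction", "se_interaction", "p_interaction"]


@dataclass
class VariantSelection:
    """Candidate variants with class labels and per-class counts.

    Classes: 1 = genome-wide significant GWAS variants; 2 = sub-threshold
    GWAS variants within the locus window of a lead; 3 = LD proxies
    (r2 >= threshold with a class-1/2 variant).
    """

    table: pd.DataFrame  # columns: variant_id, vclass

    @property
    def counts(self) -> dict[int, int]:
        c = self.table["vclass"].value_counts().to_dict()
        return {1: int(c.get(1, 0)), 2: int(c.get(2, 0)), 3: int(c.get(3, 0))}

    @property
    def total(self) -> int:
        return int(len(self.table))

    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])


def select_candidate_variants(gwas: SummaryStatsTable,
                              genotypes: GenotypeMatrix,
                              loci: list[tuple[str, int]],
                              p_significant: float = 5e-8,
                              p_subthreshold: float = 1e-6,
                              locus_window_bp: int = 2_000_000,
                              proxy_r2: float = 0.4,
                              min_maf: float = 0.05) -> VariantSelection:
    """Three-class candidate-variant selection around GWAS loci.

    Class 1: GWAS p <= ``p_significant``.  Class 2: GWAS p <=
    ``p_subthreshold`` within ``locus_window_bp`` of a locus lead.
    Class 3: r2 >= ``proxy_r2`` (on the supplied genotype panel) with any
    class-1/2 variant.  Variants with panel MAF < ``min_maf`` are removed
    before classification.
    """
    t = gwas.table
    eaf = genotypes.eaf()
    maf = np.minimum(eaf, 1.0 - eaf)
    maf_ok = {v.id for v, m in zip(genotypes.variants, maf) if m >= min_maf}
    t = t[t["snp"].isin(maf_ok)]

    class1 = set(t.loc[t["p"] <= p_significant, "snp"])
    near_lead = pd.Series(False, index=t.index)
    for chrom, pos in loci:
        near_lead |= (t["chrom"] == str(chrom)) & \
                     (t["pos"] - pos).abs().le(locus_window_bp)
    class2 = set(t.loc[(t["p"] <= p_subthreshold) & near_lead, "snp"]) - class1

    seeds = class1 | class2
    class3: set[str] = set()
    if seeds:
        panel_ids = genotypes.variant_ids
        candidates = [v for v in panel_ids
                      if v in maf_ok and v not in seeds]
        if candidates:
            seed_list = sorted(seeds & set(panel_ids))
            both = seed_list + candidates
            ld = ld_r(genotypes, both)
            r2 = ld.r2
            seed_idx = [ld.index(v) for v in seed_list]
            for v in candidates:
                if np.nanmax(r2[ld.index(v), seed_idx]) >= proxy_r2:
                    class3.add(v)
    rows = ([(v, 1) for v in sorted(class1)] + [(v, 2) for v in sorted(class2)]
            + [(v, 3) for v in sorted(class3)])
    sel = VariantSelection(pd.DataFrame(rows, columns=["variant_id", "vclass"]))
    if not rows:
        logger.warning("variant selection is empty (no GWAS variant passed)")
    else:
        logger.info("selected %d variants (class counts %s)", sel.total, sel.counts)
    return sel


# ---------------------------------------------------------------------------
# cis-eQTL OLS
# ---------------------------------------------------------------------------

def _ols_simple(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, int]:
    """OLS of y on [1, x]; returns (beta, se, t, p, n)."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ZeroDivisionError("zero dosage variance")
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        return beta, 0.0, np.inf if beta != 0 else 0.0, 0.0 if beta != 0 else 1.0, n
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(se), float(t), float(p), n


def cis_window_variants(gene: GeneAnnotation, genotypes: GenotypeMatrix,
                        window_bp: int = 1_000_000,
                        candidate_ids: set[str] | None = None) -> list[str]:
    """Variants inside [start - window, end + window] on the gene's chromosome."""
    lo, hi = gene.start - window_bp, gene.end + window_bp
    out = []
    for v in genotypes.variants:
        if v.chrom != gene.chrom or not lo <= v.pos <= hi:
            continue
        if candidate_ids is not None and v.id not in candidate_ids:
            continue
        out.append(v.id)
    return out


def map_cis(pb: PseudobulkExpression, genotypes: GenotypeMatrix,
            annotation: list[GeneAnnotation], window_bp: int = 1_000_000,
            candidate_ids: set[str] | None = None, min_n: int = 20,
            dataset: str = "d0") -> pd.DataFrame:
    """Additive cis-eQTL scan for one cell type.

    For every annotated gene present in ``pb`` and every (candidate)
    variant within the cis window, regress z-scaled expression on dosage.
    Pairs with fewer than ``min_n`` complete subjects, or zero dosage
    variance among them, are skipped (logged).
    """
    if pb.state != "zscaled":
        raise ValueError("map_cis expects z-scaled expression")
    common = [s for s in pb.subjects if s in set(genotypes.subjects)]
    geno = genotypes.subset_subjects(common)
    frame = pb.frame().loc[common]
    vid_index = {v: i for i, v in enumerate(geno.variant_ids)}
    ann = {g.gene_id: g for g in annotation}
    records = []
    n_skipped = 0
    for gene_id in pb.genes:
        gene = ann.get(gene_id)
        if gene is None:
            continue
        y_all = frame[gene_id].to_numpy(float)
        for vid in cis_window_variants(gene, geno, window_bp, candidate_ids):
            x_all = geno.dosage[:, vid_index[vid]]
            ok = ~(np.isnan(x_all) | np.isnan(y_all))
            n = int(ok.sum())
            if n < min_n:
                n_skipped += 1
                continue
            try:
                beta, se, t, p, n = _ols_simple(x_all[ok], y_all[ok])
            except ZeroDivisionError:
                n_skipped += 1
                continue
            records.append((gene_id, vid, pb.cell_type, dataset,
                            beta, se, t, p, n))
    if n_skipped:
        logger.info("map_cis(%s/%s): skipped %d pair(s)",
                    pb.cell_type, dataset, n_skipped)
    return pd.DataFrame(records, columns=EQTL_COLUMNS)


# ---------------------------------------------------------------------------
# dynamic (genotype x pathology) eQTLs
# ---------------------------------------------------------------------------

def dynamic_interaction(pb: PseudobulkExpression, genotypes: GenotypeMatrix,
                        cov: CovariateTable, pairs: pd.DataFrame,
                        min_n: int = 20, center: bool = False,
                        flag_p: float = 0.01) -> pd.DataFrame:
    """Genotype x pathology-score interaction test per eQTL pair.

    Fits expression ~ dosage + score + dosage*score and reports the
    two-sided t test on the interaction coefficient; records with
    p <= ``flag_p`` carry ``dynamic=True``.  Returns an empty frame with a
    warning when the score is constant.
    """
    if "pathology_score" not in cov.table.columns:
        raise ValueError("covariate table lacks pathology_score")
    common = [s for s in pb.subjects if s in set(genotypes.subjects)]
    geno = genotypes.subset_subjects(common)
    frame = pb.frame().loc[common]
    score_all = cov.aligned(common)["pathology_score"].to_numpy(float)
    if np.nanstd(score_all) == 0:
        logger.warning("pathology score is constant; no dynamic eQTLs testable")
        return pd.DataFrame(columns=DYNAMIC_COLUMNS + ["dynamic"])
    vid_index = {v: i for i, v in enumerate(geno.variant_ids)}
    records = []
    for row in pairs[["gene_id", "variant_id"]].drop_duplicates().itertuples(False):
        if row.gene_id not in frame.columns or row.variant_id not in vid_index:
            continue
        y = frame[row.gene_id].to_numpy(float)
        x = geno.dosage[:, vid_index[row.variant_id]]
        ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(score_all))
        if ok.sum() < min_n:
            continue
        xs, ss, ys = x[ok], score_all[ok], y[ok]
        if center:
            xs = xs - xs.mean()
            ss = ss - ss.mean()
        X = np.column_stack([np.ones(ok.sum()), xs, ss, xs * ss])
        df = ok.sum() - X.shape[1]
        if df < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
        resid = ys - X @ coef
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
        if se == 0:
            continue
        t = coef[3] / se
        p = 2.0 * stats.t.sf(abs(t), df)
        records.append((row.gene_id, row.variant_id, pb.cell_type,
                        float(coef[3]), se, float(p)))
    out = pd.DataFrame(records, columns=DYNAMIC_COLUMNS)
    out["dynamic"] = out["p_interaction"] <= flag_p
    return out
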