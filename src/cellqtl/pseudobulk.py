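"""Per-cell-type pseudobulking, covariate adjustment and z-scaling.

Single-cell UMI counts are normalized per cell to counts-per-10k
(UMI / cell total x 10,000), averaged over each subject's cells of a
given type, adjusted for batch and for known plus hidden covariates, and
finally z-scaled per gene so downstream regression betas are in units of
SD of expression per allele.

State transitions are enforced in the order
``normalized_mean -> batch_adjusted -> residualized -> zscaled``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellCountMatrix, CovariateTable

logger = logging.getLogger(__name__)

__all__ = ["PseudobulkExpression", "normalize_and_pseudobulk",
           "adjust_covariates", "zscale"]

_STATES = ["normalized_mean", "batch_adjusted", "residualized", "zscaled"]

KNOWN_COVARIATES = ["age", "sex", "rin", "pmi"]


@dataclass
class PseudobulkExpression:
    """Subjects x genes expression for one cell type, with a state tag."""

    cell_type: str
    subjects: list[str]
    genes: list[str]
    values: np.ndarray  # subjects x genes, NaN rows = subject missing
    state: str = "normalized_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.genes)):
            raise ValueError("values shape does not match subjects x genes")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")

    def _advance(self, new_state: str) -> None:
        if _STATES.index(new_state) <= _STATES.index(self.state):
            raise ValueError(f"cannot move from {self.state} to {new_state}")

    @property
    def complete_mask(self) -> np.ndarray:
        """Subjects with data for this cell type (non-missing rows)."""
        return ~np.isnan(self.values).all(axis=1)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.genes)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cell_type={self.cell_type} state={self.state}\n")
            self.frame().to_csv(fh, sep="\t", index_label="subject_id",
                                float_format="%.8g")

    @classmethod
    def read_tsv(cls, path) -> "PseudobulkExpression":
        with open(path) as fh:
            header = fh.readline().strip()
            tags = dict(item.split("=", 1) for item in header.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(cell_type=tags["cell_type"], subjects=[str(s) for s in df.index],
                   genes=[str(g) for g in df.columns], values=df.to_numpy(float),
                   state=tags["state"])


def normalize_and_pseudobulk(counts: CellCountMatrix, min_cells: int = 10,
                             scale: float = 1e4,
                             ) -> dict[str, PseudobulkExpression]:
    """CP10k-normalize per cell, then average per subject within cell type.

    Cells with zero total UMIs are excluded (logged).  Subjects with fewer
    than ``min_cells`` cells of a type get a missing (NaN) row for that
    type, so the subject axis is identical across cell types.
    """
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    keep = totals > 0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("excluded %d cell(s) with zero total UMIs", n_zero)
    mat = counts.counts[keep]
    meta = counts.cell_meta.loc[keep].reset_index(drop=True)
    norm = mat.multiply(scale / totals[keep][:, None]).tocsr()

    subjects = list(pd.unique(counts.cell_meta["subject_id"]))
    subj_idx = {s: i for i, s in enumerate(subjects)}
    out: dict[str, PseudobulkExpression] = {}
    for ctype, grp in meta.groupby("cell_type", sort=True):
        values = np.full((len(subjects), len(counts.gene_ids)), np.nan)
        for subj, cells in grp.groupby("subject_id", sort=False):
            if len(cells) < min_cells:
                continue
            block = norm[cells.index.to_numpy()]
            values[subj_idx[subj]] = np.asarray(block.mean(axis=0)).ravel()
        out[str(ctype)] = PseudobulkExpression(
            cell_type=str(ctype), subjects=subjects,
            genes=list(counts.gene_ids), values=values)
    return out


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def _batch_meanvar(x: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Per gene, recenter/rescale each batch to the pooled mean/SD."""
    out = x.copy()
    m_pool = x.mean(axis=0)
    s_pool = x.std(axis=0, ddof=1)
    for b in np.unique(batches):
        rows = batches == b
        if rows.sum() < 2:
            continue
        m_b = x[rows].mean(axis=0)
        s_b = x[rows].std(axis=0, ddof=1)
        scale = np.divide(s_pool, s_b, out=np.ones_like(s_b), where=s_b > 0)
        out[rows] = (x[rows] - m_b) * scale + m_pool
    return out


def _batch_eb(x: np.ndarray, batches: np.ndarray, n_iter: int = 30,
              tol: float = 1e-6) -> np.ndarray:
    """Parametric empirical-Bayes shrinkage of batch location/scale.

    Per gene the data are standardized, per-batch location (gamma) and
    scale (delta^2) estimates are shrunk toward across-gene priors
    (normal for gamma, inverse-gamma for delta^2, moment-matched), and the
    shrunk parameters are removed — the standard parametric batch-effect
    model for expression matrices.
    """
    grand = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - grand) / sd
    out = z.copy()
    for b in np.unique(batches):
        rows = batches == b
        n_b = int(rows.sum())
        if n_b < 2:
            continue
        g_hat = z[rows].mean(axis=0)
        d_hat = z[rows].var(axis=0, ddof=1)
        # priors across genes (method of moments)
        g_bar, t2 = g_hat.mean(), g_hat.var()
        d_bar, s2 = d_hat.mean(), d_hat.var()
        lam = (d_bar ** 2 + 2 * s2) / s2 if s2 > 0 else 2.0 + 1e6
        theta = (d_bar ** 3 + d_bar * s2) / s2 if s2 > 0 else d_bar * (lam - 1)
        g_star, d_star = g_hat.copy(), d_hat.copy()
        if t2 > 0:
            for _ in range(n_iter):
                g_new = (n_b * t2 * g_hat + d_star * g_bar) / (n_b * t2 + d_star)
                ssq = d_hat * (n_b - 1) + n_b * (g_hat - g_new) ** 2
                d_new = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
                if (np.max(np.abs(g_new - g_star)) < tol
                        and np.max(np.abs(d_new - d_star)) < tol):
                    g_star, d_star = g_new, d_new
                    break
                g_star, d_star = g_new, d_new
        out[rows] = (z[rows] - g_star) / np.sqrt(np.maximum(d_star, 1e-12))
    return out * sd + grand


def adjust_covariates(pb: PseudobulkExpression, cov: CovariateTable,
                      n_hidden: int = 30, batch_mode: str = "meanvar",
                      sv_gene_mask: np.ndarray | None = None,
                      ) -> PseudobulkExpression:
    """Remove batch effects, known covariates and hidden factors.

    Stage 1 removes batch location/scale differences (``meanvar``: exact
    recentering to the pooled moments; ``eb``: parametric empirical-Bayes
    shrinkage of the batch parameters first).  Stage 2 regresses each gene
    on age/sex/RIN/PMI, extracts the top ``n_hidden`` principal components
    of the residual matrix as surrogate variables, and returns residuals
    on known covariates plus surrogates.  ``n_hidden`` is capped at
    n_subjects - rank(known) - 1 with a warning.

    ``sv_gene_mask`` optionally restricts the genes used to *estimate*
    the surrogates (all genes are still adjusted).  On small gene panels,
    estimating factors from control genes that carry no effect of
    interest stops the surrogates from absorbing the signal itself —
    the control-gene strategy of RUV-style factor correction.
    """
    pb._advance("residualized")
    if batch_mode not in ("meanvar", "eb"):
        raise ValueError(f"unknown batch_mode {batch_mode!r}")
    mask = pb.complete_mask
    if not mask.any():
        logger.warning("adjust_covariates(%s): no subjects pass the cell "
                       "floor; returning all-missing matrix", pb.cell_type)
        return PseudobulkExpression(cell_type=pb.cell_type,
                                    subjects=pb.subjects, genes=pb.genes,
                                    values=np.full_like(pb.values, np.nan),
                                    state="residualized")
    subjects = [s for s, keep in zip(pb.subjects, mask) if keep]
    x = pb.values[mask]
    aligned = cov.aligned(subjects)
    batches = aligned["batch"].to_numpy()

    if len(np.unique(batches)) > 1:
        x = _batch_meanvar(x, batches) if batch_mode == "meanvar" \
            else _batch_eb(x, batches)

    known = aligned[KNOWN_COVARIATES].to_numpy(float)
    known = np.column_stack([np.ones(len(subjects)), known])
    rank = np.linalg.matrix_rank(known)
    cap = max(0, len(subjects) - rank - 1)
    if n_hidden > cap:
        logger.warning("n_hidden reduced from %d to %d (n=%d subjects)",
                       n_hidden, cap, len(subjects))
        n_hidden = cap
    # residuals on known covariates
    coef, *_ = np.linalg.lstsq(known, x, rcond=None)
    resid = x - known @ coef
    design = known
    if n_hidden > 0:
        # surrogate variables: top PCs of the column-standardized residual
        # matrix, so high-expression genes do not dominate the directions
        sv_resid = resid if sv_gene_mask is None else resid[:, sv_gene_mask]
        centered = sv_resid - sv_resid.mean(axis=0)
        col_sd = centered.std(axis=0, ddof=1)
        centered = centered / np.where(col_sd > 0, col_sd, 1.0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        k = min(n_hidden, (s > 1e-10).sum())
        if k > 0:
            design = np.column_stack([known, u[:, :k]])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef

    values = np.full_like(pb.values, np.nan)
    values[mask] = resid
    return PseudobulkExpression(cell_type=pb.cell_type, subjects=pb.subjects,
                                genes=pb.genes, values=values,
                                state="residualized")


def zscale(pb: PseudobulkExpression) -> PseudobulkExpression:
    """Per gene: (x - mean) / sample SD (ddof=1) over non-missing subjects.

    Genes with zero SD are dropped (logged).  After this step regression
    betas read as SD of expression per effect allele.
    """
    if pb.state != "residualized":
        raise ValueError(f"zscale requires residualized input (got {pb.state})")
    mask = pb.complete_mask
    if not mask.any():
        return PseudobulkExpression(cell_type=pb.cell_type,
                                    subjects=pb.subjects, genes=[],
                                    values=np.empty((len(pb.subjects), 0)),
                                    state="zscaled")
    x = pb.values[mask]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("zscale(%s): dropped %d constant gene(s)", pb.cell_type, n_drop)
    values = np.full((len(pb.subjects), int(keep.sum())), np.nan)
    values[mask] = (x[:, keep] - mean[keep]) / sd[keep]
    genes = [g for g, k in zip(pb.genes, keep) if k]
    return PseudobulkExpression(cell_type=pb.cell_type, subjects=pb.subjects,
                                genes=genes, values=values, state="zscaled")
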