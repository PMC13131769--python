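"""Pseudobulk beta-binomial allelic-imbalance testing and eQTL concordance.

Phased UMI counts from heterozygous subjects are aggregated to
(subject, cell type, variant) and tested for departure of the effect
allele fraction mu from 0.5 with a beta-binomial intercept model

    a1_i ~ BetaBinomial(total_i, mu, phi),

where ``phi`` is the intraclass-correlation overdispersion
(phi = 1/(alpha + beta + 1); phi -> 0 recovers the binomial).  The test
is a likelihood-ratio against the null with mu fixed at 0.5 and phi free
(overdispersion is a nuisance; the test is about the mean), referred to
chi-square(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import PhasedAlleleCounts

logger = logging.getLogger(__name__)

__all__ = ["AseResult", "BetaBinomialASE", "pseudobulk_ase", "betabin_test",
           "ase_scan", "concordance", "ASE_COLUMNS"]

ASE_COLUMNS = ["gene_id", "variant_id", "cell_type", "n_subjects",
               "total_umis", "mu_hat", "phi_hat", "log_odds", "p",
               "significant", "boundary"]

_MU_EPS = 1e-6
_PHI_MIN = 1e-8
_PHI_MAX = 1.0 - 1e-6


@dataclass
class AseResult:
    """Fitted allelic imbalance for one (gene, variant, cell type)."""

    gene_id: str
    variant_id: str
    cell_type: str
    n_subjects: int
    total_umis: int
    mu_hat: float
    phi_hat: float
    p: float
    boundary: bool = False

    @property
    def log_odds(self) -> float:
        return float(special.logit(self.mu_hat))

    def row(self, alpha: float = 0.05) -> tuple:
        return (self.gene_id, self.variant_id, self.cell_type,
                self.n_subjects, self.total_umis, self.mu_hat, self.phi_hat,
                self.log_odds, self.p, self.p <= alpha, self.boundary)


def pseudobulk_ase(raw: PhasedAlleleCounts, min_umis: int = 20) -> pd.DataFrame:
    """Sum counts to (subject, cell_type, variant); drop low-coverage variants.

    Within each (cell_type, variant_id, gene_id), the summed total over
    all retained subjects must reach ``min_umis`` phased UMIs; otherwise
    the variant is dropped for that cell type.
    """
    agg = (raw.table
           .groupby(["subject_id", "cell_type", "variant_id", "gene_id"],
                    as_index=False)[["a1_umis", "total_umis"]].sum())
    totals = agg.groupby(["cell_type", "variant_id", "gene_id"]
                         )["total_umis"].transform("sum")
    kept = agg[totals >= min_umis].reset_index(drop=True)
    n_drop = agg.loc[totals < min_umis, ["cell_type", "variant_id"]
                     ].drop_duplicates().shape[0]
    if n_drop:
        logger.info("pseudobulk_ase: dropped %d variant/cell-type group(s) "
                    "below %d UMIs", n_drop, min_umis)
    return kept


class BetaBinomialASE:
    """Beta-binomial intercept model for pseudobulked allele counts.

    Parameters are (logit mu, logit phi); the likelihood is maximized
    with Nelder-Mead from multiple starts (mu in {0.3, 0.5, 0.7}).
    ``fit`` returns an :class:`AseResult` carrying the estimates and the
    LRT p against mu = 0.5 (phi free).
    """

    def __init__(self, a1: np.ndarray, total: np.ndarray,
                 gene_id: str = "", variant_id: str = "", cell_type: str = ""):
        a1 = np.asarray(a1, dtype=float)
        total = np.asarray(total, dtype=float)
        keep = total > 0
        self.a1 = a1[keep]
        self.total = total[keep]
        if len(self.a1) < 3:
            raise ValueError("need >= 3 subjects with positive totals")
        if ((self.a1 < 0) | (self.a1 > self.total)).any():
            raise ValueError("a1 outside [0, total]")
        self.gene_id, self.variant_id, self.cell_type = \
            gene_id, variant_id, cell_type

    def loglik(self, mu: float, phi: float) -> float:
        mu = float(np.clip(mu, _MU_EPS, 1.0 - _MU_EPS))
        phi = float(np.clip(phi, 0.0, _PHI_MAX))
        if phi < _PHI_MIN:
            return float(stats.binom.logpmf(self.a1, self.total, mu).sum())
        theta = (1.0 - phi) / phi
        a, b = mu * theta, (1.0 - mu) * theta
        return float(stats.betabinom.logpmf(self.a1, self.total, a, b).sum())

    def _maximize(self, fix_mu: float | None = None,
                  fix_phi: float | None = None,
                  tol: float = 1e-8) -> tuple[float, float, float]:
        """Maximize the log-likelihood; returns (mu, phi, loglik)."""
        if fix_mu is not None and fix_phi is not None:
            return fix_mu, fix_phi, self.loglik(fix_mu, fix_phi)

        def unpack(params):
            i = 0
            if fix_mu is None:
                mu = special.expit(params[i])
                i += 1
            else:
                mu = fix_mu
            phi = fix_phi if fix_phi is not None else special.expit(params[i])
            return mu, phi

        def neg(params):
            return -self.loglik(*unpack(params))

        mu_starts = (0.3, 0.5, 0.7) if fix_mu is None else (None,)
        phi_starts = (0.05, 0.3) if fix_phi is None else (None,)
        starts = []
        for mu0 in mu_starts:
            for phi0 in phi_starts:
                x0 = []
                if mu0 is not None:
                    x0.append(special.logit(mu0))
                if phi0 is not None:
                    x0.append(special.logit(phi0))
                starts.append(x0)
        best = None
        for x0 in starts:
            res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                    options={"fatol": tol, "xatol": 1e-6,
                                             "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        mu, phi = unpack(best.x)
        ll = -best.fun
        if fix_phi is None:
            # the binomial boundary phi -> 0 is outside the expit range
            ll0 = self.loglik(mu, 0.0)
            if ll0 > ll:
                phi, ll = 0.0, ll0
        return mu, phi, ll

    def fit(self, null_mu: float = 0.5,
            fix_phi: float | None = None) -> AseResult:
        """Fit the model; ``fix_phi`` pins the overdispersion (0 gives the
        pure-binomial special case) in both the alternative and the null."""
        boundary = bool((self.a1 == 0).all() or (self.a1 == self.total).all())
        mu_hat, phi_hat, ll_alt = self._maximize(fix_phi=fix_phi)
        if boundary:
            mu_hat = _MU_EPS if (self.a1 == 0).all() else 1.0 - _MU_EPS
            ll_alt = max(ll_alt, self.loglik(mu_hat, phi_hat))
        _, _, ll_null = self._maximize(fix_mu=null_mu, fix_phi=fix_phi)
        lrt = max(0.0, 2.0 * (ll_alt - ll_null))
        p = float(stats.chi2.sf(lrt, 1))
        return AseResult(
            gene_id=self.gene_id, variant_id=self.variant_id,
            cell_type=self.cell_type, n_subjects=len(self.a1),
            total_umis=int(self.total.sum()),
            mu_hat=float(np.clip(mu_hat, _MU_EPS, 1.0 - _MU_EPS)),
            phi_hat=float(phi_hat), p=p, boundary=boundary)


def betabin_test(a1: np.ndarray, total: np.ndarray,
                 fix_phi: float | None = None, **labels) -> AseResult:
    """Functional wrapper: fit the beta-binomial model on one count set."""
    return BetaBinomialASE(a1, total, **labels).fit(fix_phi=fix_phi)


def ase_scan(pseudobulked: pd.DataFrame, alpha: float = 0.05,
             min_subjects: int = 3) -> pd.DataFrame:
    """Fit the beta-binomial test per (gene, variant, cell type)."""
    rows = []
    for (gene, var, ctype), grp in pseudobulked.groupby(
            ["gene_id", "variant_id", "cell_type"], sort=True):
        grp = grp[grp["total_umis"] > 0]
        if len(grp) < min_subjects:
            continue
        res = BetaBinomialASE(grp["a1_umis"].to_numpy(),
                              grp["total_umis"].to_numpy(),
                              gene_id=gene, variant_id=var,
                              cell_type=ctype).fit()
        rows.append(res.row(alpha))
    return pd.DataFrame(rows, columns=ASE_COLUMNS)


def concordance(ase: pd.DataFrame, eqtl: pd.DataFrame,
                ) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between ASE log-odds and eQTL betas.

    Pairs are matched on (gene_id, variant_id, cell_type); the ASE
    log-odds must already be aligned to the eQTL effect allele.  Returns
    (r, two-sided p, paired table).
    """
    keys = ["gene_id", "variant_id", "cell_type"]
    paired = ase.merge(eqtl, on=keys, suffixes=("_ase", "_eqtl"))
    beta_col = "beta_re" if "beta_re" in paired.columns else "beta"
    paired = paired.dropna(subset=["log_odds", beta_col])
    if len(paired) < 3:
        raise ValueError("fewer than 3 matched ASE/eQTL pairs")
    r, p = stats.pearsonr(paired["log_odds"], paired[beta_col])
    return float(r), float(p), paired
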