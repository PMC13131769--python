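"""Fixed-effects, random-effects and Han-Eskin RE2 meta-analysis.

Per variant-gene-cell-type triple, per-dataset eQTL estimates
(beta_i, se_i) are combined with:

* FE  — inverse-variance weighting, two-sided normal p, Cochran's Q;
* RE  — DerSimonian-Laird moment estimate of the between-study variance
  tau^2, then inverse-variance weighting with weights 1/(se_i^2 + tau^2);
* RE2 — the Han-Eskin likelihood-ratio statistic
  S = -2 [ l(beta=0, tau2=0) - max_{beta, tau2>=0} l(beta, tau2) ]
  under the marginal normal likelihood beta_i ~ N(beta, se_i^2 + tau^2).

The asymptotic RE2 null is the boundary mixture
p = 1/2 P(chi2_1 >= S) + 1/2 P(chi2_2 >= S), but with few studies the
mixture weight P(tau2hat > 0) is well below 1/2 and the asymptotic p is
conservative.  The default null therefore uses a finite-k mixture weight
estimated once per k by a seeded Monte Carlo (the role the original
software's tabulated small-sample null plays); ``null="asymptotic"``
selects the textbook 1/2-1/2 mixture.

Downstream stages follow the convention of taking p from RE2 and the
effect size / SE from RE.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["meta_fixed", "meta_random", "meta_re2", "meta_analyze",
           "META_COLUMNS"]

META_COLUMNS = ["gene_id", "variant_id", "cell_type", "k",
                "beta_fe", "se_fe", "p_fe", "beta_re", "se_re", "p_re",
                "tau2", "Q", "p_re2"]


def meta_fixed(studies: Sequence[tuple[float, float]],
               ) -> tuple[float, float, float, float]:
    """Inverse-variance fixed-effects combination: (beta, se, p, Q)."""
    if len(studies) == 0:
        raise ValueError("empty study list")
    beta = np.array([b for b, _ in studies], float)
    se = np.array([s for _, s in studies], float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se ** 2
    beta_fe = float((w * beta).sum() / w.sum())
    se_fe = float(w.sum() ** -0.5)
    z = beta_fe / se_fe
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (beta - beta_fe) ** 2).sum())
    return beta_fe, se_fe, p, q


def meta_random(studies: Sequence[tuple[float, float]],
                ) -> tuple[float, float, float, float]:
    """DerSimonian-Laird random-effects combination: (beta, se, p, tau2)."""
    k = len(studies)
    if k < 2:
        raise ValueError("random-effects meta requires k >= 2 studies")
    beta = np.array([b for b, _ in studies], float)
    se = np.array([s for _, s in studies], float)
    w = 1.0 / se ** 2
    beta_fe = (w * beta).sum() / w.sum()
    q = (w * (beta - beta_fe) ** 2).sum()
    c = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    beta_re = float((w_star * beta).sum() / w_star.sum())
    se_re = float(w_star.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta_re / se_re)))
    return beta_re, se_re, p, float(tau2)


def _profile_loglik(tau2: np.ndarray, beta: np.ndarray, se2: np.ndarray,
                    ) -> np.ndarray:
    """Log-likelihood profiled over beta; inputs broadcast over rows.

    beta, se2: (n, k); tau2: (n,).  Returns (n,).
    """
    v = se2 + tau2[:, None]
    w = 1.0 / v
    bhat = (w * beta).sum(axis=1) / w.sum(axis=1)
    return (-0.5 * np.log(2.0 * np.pi * v)
            - (beta - bhat[:, None]) ** 2 / (2.0 * v)).sum(axis=1)


def _re2_stat_batch(beta: np.ndarray, se2: np.ndarray, n_iter: int = 80,
                    ) -> np.ndarray:
    """Vectorized RE2 likelihood-ratio statistics S per row.

    tau^2 is maximized by golden-section search on the profile likelihood
    over [0, 100 * max se_i^2] per row (the tau2 = 0 boundary is checked
    explicitly).
    """
    n = beta.shape[0]
    lo = np.zeros(n)
    hi = 100.0 * se2.max(axis=1)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _profile_loglik(c, beta, se2)
    fd = _profile_loglik(d, beta, se2)
    for _ in range(n_iter):
        take_c = fc > fd  # keep the larger-likelihood side
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = _profile_loglik(c, beta, se2)
        fd = _profile_loglik(d, beta, se2)
    tau2_hat = (a + b) / 2.0
    ll_alt = np.maximum.reduce([
        _profile_loglik(tau2_hat, beta, se2),
        _profile_loglik(np.zeros(n), beta, se2),  # boundary tau2 = 0
    ])
    ll_null = (-0.5 * np.log(2.0 * np.pi * se2)
               - beta ** 2 / (2.0 * se2)).sum(axis=1)
    return np.maximum(0.0, 2.0 * (ll_alt - ll_null))


@lru_cache(maxsize=64)
def _re2_null_table(k: int, n_sim: int = 50_000) -> tuple[np.ndarray, float]:
    """Simulated null distribution of the RE2 statistic for k studies.

    A fixed-seed Monte Carlo with unit standard errors (the statistic's
    null law does not depend on a common se scale).  Returns the sorted
    null sample and the boundary-mixture weight P(tau2hat > 0), which
    approaches 1/2 from below as k grows.
    """
    rng = np.random.default_rng([20110819, k])
    beta = rng.standard_normal((n_sim, k))
    se2 = np.ones((n_sim, k))
    ll0 = _profile_loglik(np.zeros(n_sim), beta, se2)
    s0 = 2.0 * (ll0 - (-0.5 * np.log(2.0 * np.pi * se2)
                       - beta ** 2 / (2.0 * se2)).sum(axis=1))
    s = _re2_stat_batch(beta, se2)
    w = float((s > s0 + 1e-9).mean())
    return np.sort(s), w


def _re2_calibrated_p(s: np.ndarray, k: int, tail_count: int = 20,
                      ) -> np.ndarray:
    """Empirical-null p-values with a mixture-stitched extreme tail.

    Inside the simulated range p is the add-one empirical tail
    probability; beyond the ``tail_count`` largest null draws it follows
    the boundary-mixture analytic tail rescaled to match continuously at
    the stitch point.
    """
    null_s, w = _re2_null_table(k)
    n = len(null_s)
    s_star = null_s[n - tail_count]
    t0 = (tail_count + 1) / (n + 1)

    def sf_mix(x):
        return (1.0 - w) * stats.chi2.sf(x, 1) + w * stats.chi2.sf(x, 2)

    emp = 1.0 - np.searchsorted(null_s, s, side="right") / (n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = t0 * sf_mix(s) / sf_mix(s_star)
    return np.where(s <= s_star, emp, tail)


def _re2_batch(beta: np.ndarray, se: np.ndarray,
               null: str = "calibrated") -> np.ndarray:
    """Vectorized RE2 p-values for rows of (beta_i, se_i) across k studies."""
    beta = np.atleast_2d(np.asarray(beta, float))
    se = np.atleast_2d(np.asarray(se, float))
    s = _re2_stat_batch(beta, se ** 2)
    if null == "asymptotic":
        return 0.5 * stats.chi2.sf(s, 1) + 0.5 * stats.chi2.sf(s, 2)
    if null == "calibrated":
        return _re2_calibrated_p(s, beta.shape[1])
    raise ValueError(f"unknown null {null!r}")


def meta_re2(studies: Sequence[tuple[float, float]],
             null: str = "calibrated") -> float:
    """Han-Eskin RE2 likelihood-ratio p-value for one set of studies."""
    if len(studies) < 2:
        raise ValueError("RE2 requires k >= 2 studies")
    beta = np.array([[b for b, _ in studies]], float)
    se = np.array([[s for _, s in studies]], float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    return float(_re2_batch(beta, se, null=null)[0])


def meta_analyze(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyze per-dataset eQTL tables into MetaRecord rows.

    ``tables`` maps dataset label -> eQTL frame with columns
    gene_id, variant_id, cell_type, beta, se.  Triples present in a single
    dataset carry that dataset's estimate as FE == RE with tau2 = 0 and
    p_re2 equal to the FE p.
    """
    stacked = pd.concat(
        [t.assign(dataset=name) for name, t in tables.items()],
        ignore_index=True)
    keys = ["gene_id", "variant_id", "cell_type"]
    wide = stacked.pivot_table(index=keys, columns="dataset",
                               values=["beta", "se"], aggfunc="first")
    beta = wide["beta"].to_numpy(float)
    se = wide["se"].to_numpy(float)
    records = []
    multi_rows = []
    for i in range(len(wide)):
        ok = ~np.isnan(beta[i]) & ~np.isnan(se[i])
        b, s = beta[i, ok], se[i, ok]
        k = int(ok.sum())
        if k == 0:
            continue
        if k == 1:
            b0, s0 = float(b[0]), float(s[0])
            p0 = float(2.0 * stats.norm.sf(abs(b0 / s0)))
            records.append((*wide.index[i], 1, b0, s0, p0, b0, s0, p0,
                            0.0, 0.0, p0))
        else:
            bf, sf, pf, q = meta_fixed(list(zip(b, s)))
            br, sr, pr, tau2 = meta_random(list(zip(b, s)))
            records.append((*wide.index[i], k, bf, sf, pf, br, sr, pr,
                            tau2, q, np.nan))
            multi_rows.append((len(records) - 1, b, s))
    out = pd.DataFrame(records, columns=META_COLUMNS)
    # batch the RE2 optimization per study count k
    by_k: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for row in multi_rows:
        by_k.setdefault(len(row[1]), []).append(row)
    for rows in by_k.values():
        bm = np.vstack([b for _, b, _ in rows])
        sm = np.vstack([s for _, _, s in rows])
        p_re2 = _re2_batch(bm, sm)
        out.loc[[i for i, _, _ in rows], "p_re2"] = p_re2
    return out
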