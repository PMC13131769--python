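"""SMR chi-square, HEIDI heterogeneity test, and multi-SNP SMR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellqtl.ld import LdMatrix
from cellqtl.smr import (InstrumentTooWeak, heidi, run_smr, smr_multi,
                         smr_single)


def _ld(m, rho=0.9):
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LdMatrix([f"v{j}" for j in range(m)], r)


def _frames(b_e, se_e, b_g, se_g, ids=None):
    ids = ids or [f"v{j}" for j in range(len(b_e))]
    eqtl = pd.DataFrame({"beta": b_e, "se": se_e,
                         "p": 2 * stats.norm.sf(np.abs(
                             np.asarray(b_e) / np.asarray(se_e)))},
                        index=ids)
    gwas = pd.DataFrame({"beta": b_g, "se": se_g,
                         "p": 2 * stats.norm.sf(np.abs(
                             np.asarray(b_g) / np.asarray(se_g)))},
                        index=ids)
    return eqtl, gwas


class TestSmrSingle:
    def test_zero_gwas_effect(self):
        b_xy, se_xy, p = smr_single((0.0, 0.1), (1.0, 0.1))
        assert b_xy == 0.0 and p == 1.0

    def test_frozen_chi_square_example(self):
        """z_g = 5, z_e = 10: T = 2500/125 = 20, p = 7.744e-6."""
        b_xy, se_xy, p = smr_single((0.2, 0.04), (1.0, 0.1))
        assert b_xy == pytest.approx(0.2)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_equal_z4(self):
        _, _, p = smr_single((0.4, 0.1), (0.4, 0.1))
        assert p == pytest.approx(4.678e-3, rel=1e-3)

    def test_weak_instrument_rejected(self):
        with pytest.raises(InstrumentTooWeak):
            smr_single((0.2, 0.04), (0.2, 0.1))

    def test_sign_flip_invariance(self):
        a = smr_single((0.2, 0.04), (1.0, 0.1))
        b = smr_single((-0.2, 0.04), (-1.0, 0.1))
        assert a == pytest.approx(b)

    def test_t_bounded_by_component_chi_squares(self, rng):
        """T_SMR <= min(z_g^2, z_e^2): the harmonic-mean bound."""
        for _ in range(50):
            z_g = rng.normal(0, 3)
            z_e = rng.normal(0, 6)
            if abs(z_e) < 3:
                continue
            b_xy, se_xy, p = smr_single((z_g * 0.1, 0.1), (z_e * 0.1, 0.1))
            t = stats.chi2.isf(p, 1) if p > 0 else np.inf
            assert t <= min(z_g ** 2, z_e ** 2) + 1e-6


class TestHeidi:
    def test_no_candidates_absent(self):
        eqtl, gwas = _frames([1.0], [0.1], [0.2], [0.05])
        p, n = heidi("v0", eqtl, gwas, _ld(1))
        assert p is None and n == 0

    def test_identical_bxy_gives_p_one(self):
        """All candidate SNPs implying the same b_xy as the top SNP: no
        heterogeneity, S = 0, p = 1."""
        m = 6
        r = _ld(m, rho=0.7)
        z_e = np.array([10.0, 8, 7, 6, 5, 4])
        b_e = z_e * 0.1
        b_g = 0.3 * b_e  # exact proportionality: b_xy constant
        eqtl, gwas = _frames(b_e, [0.1] * m, b_g, [1e-9] * m)
        p, n = heidi("v0", eqtl, gwas, r)
        assert n >= 3
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_order_invariance(self, rng):
        m = 8
        ld = _ld(m)
        b_e = rng.uniform(0.5, 1.0, m)
        b_g = rng.normal(0.1, 0.05, m)
        eqtl, gwas = _frames(b_e, [0.05] * m, b_g, [0.02] * m)
        p1, n1 = heidi("v3", eqtl, gwas, ld)
        perm = rng.permutation(m)
        ids = [f"v{j}" for j in perm]
        p2, n2 = heidi("v3", eqtl.loc[ids], gwas.loc[ids], ld)
        assert n1 == n2
        assert p1 == pytest.approx(p2, rel=1e-9)


def _simulate_summary(rng, m=30, rho=0.9, shared=True, z_expr=10.0,
                      z_gwas=10.0, n_eqtl=1200, n_gwas=100_000,
                      gwas_null=False, linked_offset=6):
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    c_e = m // 2
    c_g = c_e if shared else c_e + linked_offset
    z1 = r[:, c_e] * z_expr + chol @ rng.standard_normal(m)
    z2 = chol @ rng.standard_normal(m)
    if not gwas_null:
        z2 = z2 + r[:, c_g] * z_gwas
    se_e = np.full(m, 1 / np.sqrt(0.42 * n_eqtl))
    se_g = np.full(m, 1 / np.sqrt(0.42 * n_gwas))
    eqtl, gwas = _frames(z1 * se_e, se_e, z2 * se_g, se_g)
    return eqtl, gwas, LdMatrix([f"v{j}" for j in range(m)], r)


class TestHeidiCalibrationAndPower:
    def test_shared_causal_rarely_rejected(self, rng):
        """Pleiotropy (one shared causal variant): HEIDI rejects at
        alpha = 0.01 in at most 3% of 500 replicates."""
        rej = used = 0
        for _ in range(500):
            eqtl, gwas, ld = _simulate_summary(rng, shared=True)
            top = (eqtl["beta"] / eqtl["se"]).abs().idxmax()
            p, n = heidi(top, eqtl, gwas, ld)
            if p is not None:
                used += 1
                rej += p < 0.01
        assert used >= 400
        assert rej / used <= 0.03

    def test_linkage_rejected_much_more_often(self, rng):
        """Two causal variants in LD (r2 ~ 0.27 at six steps of 0.9):
        rejection rate at least 5x the shared-causal rate."""
        shared_rej = linked_rej = 0
        n_rep = 250
        for _ in range(n_rep):
            eqtl, gwas, ld = _simulate_summary(rng, shared=True)
            top = (eqtl["beta"] / eqtl["se"]).abs().idxmax()
            p, _ = heidi(top, eqtl, gwas, ld)
            shared_rej += (p is not None and p < 0.01)
            eqtl, gwas, ld = _simulate_summary(rng, shared=False)
            top = (eqtl["beta"] / eqtl["se"]).abs().idxmax()
            p, _ = heidi(top, eqtl, gwas, ld)
            linked_rej += (p is not None and p < 0.01)
        assert linked_rej >= 5 * max(shared_rej, 1)


class TestSmrMulti:
    def test_single_snp_reduces_to_smr(self):
        eqtl, gwas = _frames([1.0], [0.1], [0.2], [0.04])
        _, _, p_single = smr_single((0.2, 0.04), (1.0, 0.1))
        p_multi = smr_multi(["v0"], gwas, eqtl, _ld(1))
        assert p_multi == pytest.approx(p_single, rel=1e-9)

    def test_perfect_ld_effective_df_one(self, rng):
        """All SNPs identical (r = 1): the weighted null collapses to
        ~1 df and the multi-SNP p tracks the single-SNP p."""
        m = 5
        ld = LdMatrix([f"v{j}" for j in range(m)], np.ones((m, m)))
        ratios = []
        for _ in range(50):
            z_e = rng.normal(8, 0.5)
            z_g = rng.normal(2.5, 0.5)
            b_e = np.full(m, z_e * 0.1)
            b_g = np.full(m, z_g * 0.05)
            eqtl, gwas = _frames(b_e, [0.1] * m, b_g, [0.05] * m)
            _, _, p_single = smr_single((b_g[0], 0.05), (b_e[0], 0.1))
            p_multi = smr_multi(list(eqtl.index), gwas, eqtl, ld)
            ratios.append(np.log10(p_multi) / np.log10(p_single))
        assert np.median(np.abs(np.array(ratios) - 1)) < 0.2

    def test_null_calibration(self, rng):
        """No GWAS effect anywhere: type-I error of the multi-SNP test at
        0.05 within [0.03, 0.08] over 1,000 replicates."""
        hits = total = 0
        for _ in range(1000):
            eqtl, gwas, ld = _simulate_summary(rng, gwas_null=True)
            et = eqtl[(eqtl["beta"] / eqtl["se"]).abs() >= 3]
            if et.empty:
                continue
            top = et["p"].idxmin()
            from cellqtl.smr import _select_heidi_snps
            snps = [top] + _select_heidi_snps(top, eqtl, ld, 1.57e-3,
                                              (0.05, 0.9), 0.9, 20)
            p = smr_multi(snps, gwas, eqtl, ld)
            total += 1
            hits += p <= 0.05
        assert total >= 900
        rate = hits / total
        assert 0.03 <= rate <= 0.08


class TestRunSmr:
    def test_full_record(self, rng):
        eqtl, gwas, ld = _simulate_summary(rng, shared=True)
        res = run_smr("g", "GLU", eqtl, gwas, ld)
        assert res is not None
        assert res.p_smr <= 1.0 and res.n_heidi_snps >= 3
        assert res.p_heidi is not None

    def test_weak_instruments_return_none(self):
        eqtl, gwas = _frames([0.1, 0.1], [0.1, 0.1], [0.2, 0.2],
                             [0.05, 0.05])
        assert run_smr("g", "GLU", eqtl, gwas, _ld(2)) is None
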