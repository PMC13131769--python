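"""Variant selection, cis-eQTL OLS, and dynamic interaction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellqtl.cis import (_ols_simple, cis_window_variants, dynamic_interaction,
                         map_cis, select_candidate_variants)
from cellqtl.io import (CovariateTable, GeneAnnotation, GenotypeMatrix,
                        SummaryStatsTable, VariantRecord)
from cellqtl.pseudobulk import PseudobulkExpression


def _geno(dosage, positions=None, chrom="1"):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    variants = [VariantRecord(f"v{j}", chrom,
                              (positions[j] if positions else 1000 + j),
                              "A", "G", eaf=0.3) for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosage)


def _pb(values, genes=None, subjects=None):
    values = np.asarray(values, float)
    n, g = values.shape
    return PseudobulkExpression(
        "GLU", subjects or [f"s{i}" for i in range(n)],
        genes or [f"g{j}" for j in range(g)], values, state="zscaled")


class TestOlsCore:
    def test_perfect_fit(self):
        beta, se, t, p, n = _ols_simple(np.array([0., 1., 2.]),
                                        np.array([0., 1., 2.]))
        assert beta == pytest.approx(1.0)
        assert se == 0.0 and p == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        """OLS slope/SE/t/p agree with the closed-form normal-equations
        solution to 1e-10 on random instances."""
        for _ in range(25):
            n = rng.integers(10, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            beta, se, t, p, _ = _ols_simple(x, y)
            X = np.column_stack([np.ones(n), x])
            coef = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ coef
            s2 = resid @ resid / (n - 2)
            cov = s2 * np.linalg.inv(X.T @ X)
            se_o = np.sqrt(cov[1, 1])
            t_o = coef[1] / se_o
            assert beta == pytest.approx(coef[1], abs=1e-10)
            assert se == pytest.approx(se_o, abs=1e-10)
            assert p == pytest.approx(2 * stats.t.sf(abs(t_o), n - 2),
                                      abs=1e-10)

    def test_p_is_t_tail_at_n_minus_2(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        _, _, t, p, n = _ols_simple(x, y)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-10)


class TestMapCis:
    ANN = [GeneAnnotation("g0", "1", 1_200_000, 1_210_000)]

    def test_allele_swap_flips_beta_exactly(self, rng):
        dos = rng.integers(0, 3, size=(50, 1)).astype(float)
        y = 0.4 * dos[:, 0] + rng.normal(size=50)
        pb = _pb((y - y.mean())[:, None] / y.std(ddof=1), genes=["g0"])
        g1 = _geno(dos, positions=[1_205_000])
        g2 = _geno(2 - dos, positions=[1_205_000])
        r1 = map_cis(pb, g1, self.ANN, min_n=10)
        r2 = map_cis(pb, g2, self.ANN, min_n=10)
        assert r1.loc[0, "beta"] == pytest.approx(-r2.loc[0, "beta"])
        assert r1.loc[0, "p"] == pytest.approx(r2.loc[0, "p"])

    def test_cis_window_boundary_inclusive(self):
        gene = GeneAnnotation("g0", "1", 2_000_000, 2_010_000)
        inside = 2_000_000 - 1_000_000
        geno = _geno(np.zeros((3, 2)), positions=[inside, inside - 1])
        ids = cis_window_variants(gene, geno, window_bp=1_000_000)
        assert ids == ["v0"]

    def test_null_calibration(self, rng):
        """Expression independent of dosage: empirical type-I error at
        0.05 within 3 binomial SEs over 1,000 pairs."""
        n, m = 200, 1000
        dos = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        y = rng.normal(size=(n, m))
        y = (y - y.mean(0)) / y.std(0, ddof=1)
        pb = _pb(y)
        ann = [GeneAnnotation(f"g{j}", "1", 1000, 2000) for j in range(m)]
        res = map_cis(pb, _geno(dos, positions=[1500]), ann, min_n=10)
        assert len(res) == m
        rate = (res["p"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) <= 3 * se

    def test_planted_beta_recovered(self, rng):
        """Planted 0.4 SD/allele at MAF 0.3, n = 200: mean estimate within
        0.05 over 200 replicates (allowing for the z-scale shrinkage)."""
        n, reps = 200, 200
        betas = []
        for _ in range(reps):
            x = rng.binomial(2, 0.3, size=n).astype(float)
            y = 0.4 * x + rng.normal(size=n) * np.sqrt(1 - 0.4 ** 2 * 0.42)
            y = (y - y.mean()) / y.std(ddof=1)
            pb = _pb(y[:, None], genes=["g0"])
            res = map_cis(pb, _geno(x[:, None], positions=[1500]),
                          [GeneAnnotation("g0", "1", 1000, 2000)], min_n=10)
            betas.append(res.loc[0, "beta"])
        assert abs(np.mean(betas) - 0.4) < 0.05

    def test_min_subjects_and_zero_variance_skipped(self):
        y = np.array([[0.1], [0.2], [np.nan], [0.3]])
        pb = _pb(y, genes=["g0"])
        geno = _geno(np.ones((4, 1)), positions=[1500])
        res = map_cis(pb, geno, [GeneAnnotation("g0", "1", 1000, 2000)],
                      min_n=3)
        assert len(res) == 0  # constant dosage skipped
        res2 = map_cis(pb, _geno(np.array([[0.], [1.], [2.], [1.]]),
                                 positions=[1500]),
                       [GeneAnnotation("g0", "1", 1000, 2000)], min_n=4)
        assert len(res2) == 0  # only 3 complete subjects < min_n


class TestSelectCandidates:
    def _stats(self, rows):
        return SummaryStatsTable("gwas", pd.DataFrame(
            rows, columns=["snp", "chrom", "pos", "a1", "a2", "eaf", "beta",
                           "se", "p", "n"]))

    def test_three_classes(self, rng):
        # v0 genome-wide significant; v1 sub-threshold near the locus;
        # v2 correlated proxy of v0; v3 unrelated
        base = rng.binomial(1, 0.5, size=(4000, 1)).astype(float)
        proxy = base.copy()
        flip = rng.random(size=base.shape) < 0.1
        proxy[flip] = 1 - proxy[flip]
        dosage = np.column_stack([
            base[:, 0] + base[:, 0],  # v0 (two identical haplotypes)
            rng.binomial(2, 0.4, size=4000),  # v1 independent
            proxy[:, 0] * 2,  # v2 proxy of v0
            rng.binomial(2, 0.4, size=4000)])  # v3
        positions = [100_000, 150_000, 200_000, 250_000]
        variants = [VariantRecord(f"v{j}", "1", positions[j], "A", "G")
                    for j in range(4)]
        geno = GenotypeMatrix([f"s{i}" for i in range(4000)], variants,
                              dosage)
        gwas = self._stats([
            ("v0", "1", 100_000, "A", "G", 0.5, 1, 0.1, 4e-8, 1000),
            ("v1", "1", 150_000, "A", "G", 0.4, 1, 0.1, 5e-7, 1000),
            ("v2", "1", 200_000, "A", "G", 0.5, 1, 0.1, 0.2, 1000),
            ("v3", "1", 250_000, "A", "G", 0.4, 1, 0.1, 0.2, 1000)])
        sel = select_candidate_variants(gwas, geno, loci=[("1", 100_000)])
        classes = dict(zip(sel.table["variant_id"], sel.table["vclass"]))
        assert classes == {"v0": 1, "v1": 2, "v2": 3}
        assert sel.counts == {1: 1, 2: 1, 3: 1}
        assert sel.total == 3

    def test_low_maf_removed(self):
        dosage = np.zeros((100, 1))
        dosage[:2] = 1.0  # MAF 0.01
        geno = GenotypeMatrix(["s%d" % i for i in range(100)],
                              [VariantRecord("v0", "1", 100, "A", "G")],
                              dosage)
        gwas = self._stats([("v0", "1", 100, "A", "G", 0.01, 1, 0.1,
                             1e-9, 1000)])
        sel = select_candidate_variants(gwas, geno, loci=[("1", 100)])
        assert sel.total == 0


class TestDynamic:
    def _fixture(self, rng, n=120):
        x = rng.binomial(2, 0.4, size=n).astype(float)
        score = rng.integers(0, 7, size=n).astype(float)
        cov = CovariateTable(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": 70.0, "sex": 0, "rin": 7.0, "pmi": 5.0, "batch": "b0",
            "pathology_score": score}))
        return x, score, cov

    def test_exact_interaction_recovered(self, rng):
        x, score, cov = self._fixture(rng)
        y = x * score
        pb = _pb(y[:, None], genes=["g0"])
        geno = _geno(x[:, None], positions=[1500])
        pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
        res = dynamic_interaction(pb, geno, cov, pairs, center=True)
        assert res.loc[0, "beta_interaction"] == pytest.approx(1.0)
        assert bool(res.loc[0, "dynamic"])

    def test_null_calibration(self, rng):
        """No planted interaction: flag rate at 0.01 within 3 binomial SEs
        over 1,000 pairs."""
        n, m = 150, 1000
        x = rng.binomial(2, 0.4, size=n).astype(float)
        score = rng.integers(0, 7, size=n).astype(float)
        cov = CovariateTable(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": 70.0, "sex": 0, "rin": 7.0, "pmi": 5.0, "batch": "b0",
            "pathology_score": score}))
        y = rng.normal(size=(n, m))
        pb = _pb(y)
        geno = _geno(x[:, None], positions=[1500])
        pairs = pd.DataFrame({"gene_id": [f"g{j}" for j in range(m)],
                              "variant_id": ["v0"] * m})
        res = dynamic_interaction(pb, geno, cov, pairs)
        rate = res["dynamic"].mean()
        se = np.sqrt(0.01 * 0.99 / m)
        assert abs(rate - 0.01) <= 3 * se

    def test_planted_interaction_sign_recovered(self, rng):
        """Interaction 0.3 at n = 300: sign recovered in >= 90% of reps."""
        hits, reps = 0, 60
        for _ in range(reps):
            n = 300
            x = rng.binomial(2, 0.4, size=n).astype(float)
            score = rng.integers(0, 7, size=n).astype(float)
            cov = CovariateTable(pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(n)],
                "age": 70.0, "sex": 0, "rin": 7.0, "pmi": 5.0,
                "batch": "b0", "pathology_score": score}))
            y = 0.3 * x * score + rng.normal(size=n)
            pb = _pb(y[:, None], genes=["g0"])
            geno = _geno(x[:, None], positions=[1500])
            pairs = pd.DataFrame({"gene_id": ["g0"], "variant_id": ["v0"]})
            res = dynamic_interaction(pb, geno, cov, pairs)
            hits += res.loc[0, "beta_interaction"] > 0
        assert hits / reps >= 0.9

    def test_constant_score_returns_empty(self, rng, caplog):
        x, _, _ = self._fixture(rng)
        cov = CovariateTable(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(x))],
            "age": 70.0, "sex": 0, "rin": 7.0, "pmi": 5.0, "batch": "b0",
            "pathology_score": 2.0}))
        pb = _pb(np.zeros((len(x), 1)), genes=["g0"])
        res = dynamic_interaction(pb, _geno(x[:, None], positions=[1500]),
                                  cov, pd.DataFrame({"gene_id": ["g0"],
                                                     "variant_id": ["v0"]}))
        assert len(res) == 0
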