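"""Ground-truth properties of the synthetic-cohort generator."""

import numpy as np
import pytest
from scipy import stats

from cellqtl.pseudobulk import adjust_covariates, normalize_and_pseudobulk, \
    zscale
from cellqtl.simulate import (LocusSpec, SimConfig, build_truth,
                              simulate_ase, simulate_cells,
                              simulate_covariates, simulate_genotypes,
                              simulate_gwas)


class TestGenotypes:
    def test_fixed_seed_reproducible(self, small_config):
        a = simulate_genotypes(small_config, stream=2)
        b = simulate_genotypes(small_config, stream=2)
        np.testing.assert_array_equal(a.dosage, b.dosage)

    def test_zero_ld_gives_independent_variants(self):
        cfg = SimConfig(n_subjects=2000, ld_decay=0.0, seed=3)
        g = simulate_genotypes(cfg, stream=1)
        m = cfg.variants_per_locus
        rs = []
        for l in range(cfg.n_loci):
            r = np.corrcoef(g.dosage[:, l * m:(l + 1) * m], rowvar=False)
            rs.extend(abs(r[j, j + 1]) for j in range(m - 1))
        assert np.mean(rs) < 3 * 2 / np.sqrt(cfg.n_subjects)

    def test_high_ld_realized_adjacent_r2(self):
        """ld_decay 0.9 at n = 2000: mean adjacent r2 in the Monte-Carlo
        band of the thresholded-Gaussian construction."""
        cfg = SimConfig(n_subjects=2000, ld_decay=0.9, seed=7)
        g = simulate_genotypes(cfg, stream=3)
        m = cfg.variants_per_locus
        r2s = []
        for l in range(cfg.n_loci):
            r = np.corrcoef(g.dosage[:, l * m:(l + 1) * m], rowvar=False)
            r2s.extend(r[j, j + 1] ** 2 for j in range(m - 1))
        assert 0.64 <= np.mean(r2s) <= 0.97
        # realized correlation within 0.1 of the requested level
        assert abs(np.sqrt(np.mean(r2s)) - 0.9) < 0.1

    def test_dosages_in_range_and_eaf_consistent(self, small_genotypes):
        assert np.nanmin(small_genotypes.dosage) >= 0
        assert np.nanmax(small_genotypes.dosage) <= 2


class TestGwas:
    def test_null_scenario_uniform_p(self):
        # independent variants so the binomial error band applies
        cfg = SimConfig(n_subjects=600, seed=5, ld_decay=0.0,
                        loci=tuple(LocusSpec("null") for _ in range(8)),
                        variants_per_locus=40)
        g = simulate_genotypes(cfg, stream=1)
        truth = build_truth(cfg, g)
        ps = []
        for rep in range(10):
            ss = simulate_gwas(cfg, g, truth, stream=200 + rep)
            ps.append(ss.table["p"].to_numpy())
        p = np.concatenate(ps)
        assert len(p) >= 2000
        frac = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(frac - 0.05) <= 3 * se + 1e-12

    def test_shared_causal_variant_usually_top(self):
        """With z* = 8 the causal variant attains the locus minimum p in
        most replicates (Monte-Carlo oracle of the MVN construction)."""
        cfg = SimConfig(n_subjects=1000, seed=5,
                        loci=(LocusSpec("shared_causal", gwas_z=8.0),),
                        variants_per_locus=20)
        g = simulate_genotypes(cfg, stream=1)
        truth = build_truth(cfg, g)
        causal = truth.trait_causal["gene0"]
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            ss = simulate_gwas(cfg, g, truth, stream=300 + rep)
            top = ss.table.loc[ss.table["p"].idxmin(), "snp"]
            hits += top == causal
        assert hits / n_rep >= 0.8

    def test_linked_scenario_distinct_causal_variants(self, small_genotypes):
        cfg = SimConfig(n_subjects=200, seed=11,
                        loci=(LocusSpec("linked_causal", r2_target=0.25),),
                        variants_per_locus=12)
        g = simulate_genotypes(cfg, stream=1)
        truth = build_truth(cfg, g)
        assert truth.trait_causal["gene0"] != truth.expr_causal["gene0"]
        r = np.corrcoef(g.column(truth.trait_causal["gene0"]),
                        g.column(truth.expr_causal["gene0"]))[0, 1]
        assert 0.05 < r ** 2 < 0.6  # near the 0.25 target

    def test_beta_se_scale(self, small_config, small_genotypes, small_truth):
        ss = simulate_gwas(small_config, small_genotypes, small_truth)
        t = ss.table
        np.testing.assert_allclose(
            t["se"], 1 / np.sqrt(2 * t["eaf"] * (1 - t["eaf"]) * t["n"]),
            rtol=1e-10)


class TestCells:
    def test_fixed_seed_reproducible(self, small_config, small_genotypes,
                                     small_truth):
        cov = simulate_covariates(small_config, small_genotypes, stream=1)
        a = simulate_cells(small_config, small_genotypes, cov, small_truth, 1)
        b = simulate_cells(small_config, small_genotypes, cov, small_truth, 1)
        assert (a.counts != b.counts).nnz == 0

    def test_planted_effect_recovered_in_planted_cell_type_only(
            self, small_config, small_genotypes, small_truth):
        """Pseudobulk regression recovers a positive beta in planted cell
        types; other cell types stay near zero."""
        cov = simulate_covariates(small_config, small_genotypes, stream=1)
        cells = simulate_cells(small_config, small_genotypes, cov,
                               small_truth, stream=1)
        pbs = normalize_and_pseudobulk(cells, min_cells=2)
        planted = small_truth.planted_eqtls[0]
        dos = small_genotypes.column(planted.variant_id)
        betas = {}
        for ctype, pb in pbs.items():
            z = zscale(adjust_covariates(pb, cov, n_hidden=0))
            y = z.frame()[planted.gene_id].to_numpy()
            betas[ctype] = np.polyfit(dos, y, 1)[0]
        for ctype in small_config.cell_types:
            if ctype in planted.cell_types:
                assert betas[ctype] > 0.5
            else:
                assert abs(betas[ctype]) < 0.3


class TestAse:
    def test_null_variants_balanced(self, small_config, small_genotypes,
                                    small_truth):
        pac = simulate_ase(small_config, small_genotypes, small_truth,
                           stream=1)
        t = pac.table
        planted = {(e.gene_id, ct) for e in small_truth.planted_eqtls
                   for ct in e.cell_types}
        null = t[[(g, c) not in planted
                  for g, c in zip(t["gene_id"], t["cell_type"])]]
        frac = null["a1_umis"].sum() / null["total_umis"].sum()
        se = np.sqrt(0.25 / null["total_umis"].sum())
        # overdispersion inflates the binomial SE; allow a wide factor
        assert abs(frac - 0.5) < 10 * se + 0.02

    def test_planted_effect_shifts_allele_fraction(self, small_config,
                                                   small_genotypes,
                                                   small_truth):
        pac = simulate_ase(small_config, small_genotypes, small_truth,
                           stream=1)
        t = pac.table
        e = small_truth.planted_eqtls[0]
        sub = t[(t["gene_id"] == e.gene_id)
                & (t["cell_type"].isin(e.cell_types))]
        frac = sub["a1_umis"].sum() / sub["total_umis"].sum()
        expected = 1 / (1 + np.exp(-small_config.ase_kappa * e.effect))
        assert abs(frac - expected) < 0.05
        assert np.sign(np.log(frac / (1 - frac))) == np.sign(e.effect)

    def test_only_heterozygotes_emit_rows(self, small_config,
                                          small_genotypes, small_truth):
        pac = simulate_ase(small_config, small_genotypes, small_truth,
                           stream=1)
        vid = {v.id: i for i, v in enumerate(small_genotypes.variants)}
        sid = {s: i for i, s in enumerate(small_genotypes.subjects)}
        for row in pac.table.itertuples(index=False):
            d = small_genotypes.dosage[sid[row.subject_id],
                                       vid[row.variant_id]]
            assert d == 1.0


class TestTruthValidation:
    def test_planted_references_must_exist(self, small_config,
                                           small_genotypes):
        from dataclasses import replace

        from cellqtl.simulate import PlantedEqtl
        bad = replace(small_config, planted_eqtls=(
            PlantedEqtl("nope", "v0_0", ("GLU",), 0.5),))
        with pytest.raises(ValueError, match="absent"):
            build_truth(bad, small_genotypes)
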