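"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the data shapes the pipeline consumes:

* LD-structured diploid genotypes — haplotypes are thresholded AR(1)
  Gaussians, so the adjacent-pair allelic correlation is controlled
  analytically (a tetrachoric inversion maps the requested allelic
  correlation to the latent Gaussian correlation).
* negative-binomial single-cell UMI counts across nine brain cell types,
  with cell-type-specific planted cis effects (log-mean scale), batch
  shifts, a hidden confounding factor, and optional genotype x pathology
  interactions,
* GWAS summary statistics drawn directly in z-space from
  ``z ~ MVN(R z*, R)`` under shared-causal, linked-causal, or null locus
  scenarios,
* beta-binomial phased allele counts at heterozygous subjects whose
  imbalance mirrors the planted cis effects through a coupling ``kappa``
  (logit of the effect-allele fraction = kappa * effect).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import special, stats
from scipy.optimize import brentq

from .io import (
    CellCountMatrix,
    CovariateTable,
    GeneAnnotation,
    GenotypeMatrix,
    PhasedAlleleCounts,
    SummaryStatsTable,
    VariantRecord,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedEqtl",
    "InteractionEffect",
    "LocusSpec",
    "DEFAULT_CELL_TYPES",
    "simulate_genotypes",
    "simulate_bulk",
    "build_truth",
    "simulate_covariates",
    "simulate_cells",
    "simulate_gwas",
    "simulate_ase",
    "gene_annotation",
]

#: the nine brain cell types profiled in the study design this emulates
DEFAULT_CELL_TYPES = ("DA", "GLU", "GABA", "Oli", "OPC", "Ast", "Mic", "End", "Per")

_LOCUS_SPACING_BP = 10_000_000
_VARIANT_SPACING_BP = 5_000


@dataclass(frozen=True)
class PlantedEqtl:
    gene_id: str
    variant_id: str
    cell_types: tuple[str, ...]
    effect: float  # log-mean scale per effect allele


@dataclass(frozen=True)
class InteractionEffect:
    gene_id: str
    variant_id: str
    cell_type: str
    size: float  # log-mean scale per allele per pathology-score unit


@dataclass(frozen=True)
class LocusSpec:
    """Per-locus trait/expression scenario."""

    scenario: str  # shared_causal | linked_causal | null
    r2_target: float = 0.25  # linked_causal only
    gwas_z: float = 8.0  # causal-variant non-centrality


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the simulated study design used throughout the test
    suite: three independent datasets of 400 subjects (the pipeline driver
    draws one cohort per dataset from the same config), eight loci of 40
    variants in strong local LD, one gene per locus, nine cell types with
    20 cells per subject and type, cell-type-specific planted effects of
    0.5 log-units per allele, and GWAS non-centrality z* = 8 at causal
    variants.
    """

    n_subjects: int = 400
    variants_per_locus: int = 40
    loci: tuple[LocusSpec, ...] = (
        LocusSpec("shared_causal"),
        LocusSpec("shared_causal"),
        LocusSpec("shared_causal"),
        LocusSpec("shared_causal"),
        LocusSpec("shared_causal"),
        LocusSpec("linked_causal", r2_target=0.25),
        LocusSpec("linked_causal", r2_target=0.25),
        LocusSpec("null"),
    )
    ld_decay: float = 0.9  # target adjacent-haplotype allelic correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_subject_per_type: int = 20
    nb_dispersion: float = 0.3  # var = mu + phi mu^2
    eqtl_effect: float = 0.5  # planted cis effect, log-mean per allele
    eqtl_cell_types_per_gene: int = 3
    gwas_n: int = 100_000
    ase_overdispersion: float = 0.1  # beta-binomial ICC phi
    ase_mean_umis: float = 30.0
    ase_kappa: float = 1.0  # logit(allelic fraction) = kappa * effect
    planted_eqtls: tuple[PlantedEqtl, ...] | None = None  # None -> derive from loci
    interaction_effects: tuple[InteractionEffect, ...] = ()
    n_background_genes: int = 40  # genes with no nearby variants (trans-free)
    n_batches: int = 2
    batch_sd: float = 0.3  # per-gene log-scale batch shift SD
    hidden_factor_sd: float = 0.2  # loading SD on the 50% of genes affected
    library_sd: float = 0.3  # log-normal cell library size SD
    covariate_effect_sd: float = 0.1
    baseline_mean_range: tuple[float, float] = (0.5, 5.0)  # counts/cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.variants_per_locus <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_variants(self) -> int:
        return self.n_loci * self.variants_per_locus

    @property
    def n_genes(self) -> int:
        return self.n_loci + self.n_background_genes

    def gene_ids(self) -> list[str]:
        return ([f"gene{i}" for i in range(self.n_loci)]
                + [f"bg{i}" for i in range(self.n_background_genes)])

    def variant_ids(self) -> list[str]:
        return [f"v{l}_{j}" for l in range(self.n_loci)
                for j in range(self.variants_per_locus)]


@dataclass
class SimTruth:
    """Ground truth of one synthetic study."""

    planted_eqtls: tuple[PlantedEqtl, ...]
    interaction_effects: tuple[InteractionEffect, ...]
    expr_causal: dict[str, str]  # locus gene -> expression causal variant
    trait_causal: dict[str, str | None]  # locus gene -> trait causal variant
    scenario: dict[str, str]  # locus gene -> scenario
    gwas_z: dict[str, float]
    baseline: np.ndarray  # per-gene baseline mean counts per cell
    covariate_loadings: np.ndarray  # genes x 4 (age, sex, rin, pmi)
    hidden_loadings: np.ndarray  # genes

    def planted_genes(self) -> list[str]:
        return sorted({e.gene_id for e in self.planted_eqtls})


def _rng(config: SimConfig, stream: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream, stage])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _bvn_cdf_zero_mean(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T."""
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(min(h, k))
    if abs(rho) < 1e-12:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    s = np.sqrt(1.0 - rho * rho)
    if h == 0.0 and k == 0.0:
        return 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    if h == 0.0:
        h = 1e-12
    if k == 0.0:
        k = 1e-12
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    c = 0.0 if h * k > 0 or (h * k == 0 and h + k >= 0) else 0.5
    return (0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
            - float(special.owens_t(h, ah)) - float(special.owens_t(k, ak)) - c)


@lru_cache(maxsize=4096)
def _latent_rho(target_r: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation giving allelic (phi) correlation target_r.

    Thresholding attenuates correlation, so the latent value exceeds the
    target; if even rho -> 1 cannot reach it (mismatched frequencies), the
    maximum attainable is used.
    """
    if target_r <= 0.0:
        return 0.0
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi(rho: float) -> float:
        return (_bvn_cdf_zero_mean(z1, z2, rho) - p1 * p2) / denom

    hi = 0.99999
    if phi(hi) <= target_r:
        return hi
    return float(brentq(lambda r: phi(r) - target_r, 0.0, hi, xtol=1e-6))


def _variant_panel(config: SimConfig) -> tuple[list[VariantRecord], np.ndarray]:
    """Deterministic variant metadata (ids, positions, alleles, MAFs)."""
    rng = _rng(config, 0, 100)
    lo, hi = config.maf_range
    variants: list[VariantRecord] = []
    mafs = np.empty(config.n_variants)
    idx = 0
    for l in range(config.n_loci):
        base = (l + 1) * _LOCUS_SPACING_BP
        locus_maf = rng.uniform(lo, hi)
        for j in range(config.variants_per_locus):
            maf = float(np.clip(locus_maf + rng.normal(0.0, 0.03), lo, hi))
            mafs[idx] = maf
            a1, a2 = ("A", "G") if idx % 2 == 0 else ("C", "T")
            variants.append(VariantRecord(
                id=f"v{l}_{j}", chrom="1", pos=base + j * _VARIANT_SPACING_BP,
                a1=a1, a2=a2, eaf=maf))
            idx += 1
    return variants, mafs


def simulate_genotypes(config: SimConfig, stream: int = 0,
                       subject_prefix: str = "S") -> GenotypeMatrix:
    """Diploid dosages from thresholded AR(1) Gaussian haplotypes.

    Loci are independent blocks; within a locus adjacent variants have
    allelic correlation ~ ``ld_decay`` on the haplotypes.
    """
    variants, mafs = _variant_panel(config)
    rng = _rng(config, stream, 101)
    n_hap = 2 * config.n_subjects
    m = config.n_variants
    eps = rng.standard_normal((n_hap, m))
    x = np.empty((n_hap, m))
    for idx in range(m):
        if idx % config.variants_per_locus == 0:
            x[:, idx] = eps[:, idx]
        else:
            rho = _latent_rho(round(config.ld_decay, 6),
                              round(float(mafs[idx - 1]), 4),
                              round(float(mafs[idx]), 4))
            x[:, idx] = rho * x[:, idx - 1] + np.sqrt(1.0 - rho * rho) * eps[:, idx]
    alleles = (x < stats.norm.ppf(mafs)[None, :]).astype(float)
    dosage = alleles[0::2] + alleles[1::2]
    subjects = [f"{subject_prefix}{stream}_{i}" for i in range(config.n_subjects)]
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# truth / annotation
# ---------------------------------------------------------------------------

def gene_annotation(config: SimConfig) -> list[GeneAnnotation]:
    """One gene per locus (centered in the locus variant span) plus
    background genes on a variant-free chromosome."""
    genes = []
    span = config.variants_per_locus * _VARIANT_SPACING_BP
    for l in range(config.n_loci):
        base = (l + 1) * _LOCUS_SPACING_BP
        start = base + span // 2
        genes.append(GeneAnnotation(f"gene{l}", "1", start, start + 10_000, "+"))
    for i in range(config.n_background_genes):
        start = (i + 1) * 1_000_000
        genes.append(GeneAnnotation(f"bg{i}", "2", start, start + 10_000, "+"))
    return genes


def build_truth(config: SimConfig, genotypes: GenotypeMatrix) -> SimTruth:
    """Fix causal variants, planted effects and nuisance loadings.

    The expression causal variant sits mid-locus; for a linked-causal
    scenario the trait causal variant is the panel variant whose realized
    r2 with the eSNP is closest to the requested target.
    """
    rng = _rng(config, 0, 102)
    m = config.variants_per_locus
    expr_causal: dict[str, str] = {}
    trait_causal: dict[str, str | None] = {}
    scenario: dict[str, str] = {}
    gwas_z: dict[str, float] = {}
    planted: list[PlantedEqtl] = []
    for l, locus in enumerate(config.loci):
        gene = f"gene{l}"
        esnp = f"v{l}_{m // 2}"
        expr_causal[gene] = esnp
        scenario[gene] = locus.scenario
        gwas_z[gene] = locus.gwas_z
        if locus.scenario == "null":
            trait_causal[gene] = None
            continue
        # planted cis-eQTL, cell-type specific
        types = tuple(rng.choice(config.cell_types,
                                 size=min(config.eqtl_cell_types_per_gene,
                                          len(config.cell_types)),
                                 replace=False))
        planted.append(PlantedEqtl(gene, esnp, types, config.eqtl_effect))
        if locus.scenario == "shared_causal":
            trait_causal[gene] = esnp
        elif locus.scenario == "linked_causal":
            cols = genotypes.dosage[:, l * m:(l + 1) * m]
            r = np.corrcoef(cols, rowvar=False)[m // 2]
            r2 = r ** 2
            r2[m // 2] = np.inf  # exclude the eSNP itself
            j = int(np.argmin(np.abs(r2 - locus.r2_target)))
            trait_causal[gene] = f"v{l}_{j}"
        else:
            raise ValueError(f"unknown scenario {locus.scenario!r}")
    if config.planted_eqtls is not None:
        planted = list(config.planted_eqtls)
    n_genes = config.n_genes
    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    cov_load = rng.normal(0.0, config.covariate_effect_sd, size=(n_genes, 4))
    hidden = np.where(rng.random(n_genes) < 0.5,
                      rng.normal(0.0, config.hidden_factor_sd, size=n_genes), 0.0)
    truth = SimTruth(
        planted_eqtls=tuple(planted),
        interaction_effects=tuple(config.interaction_effects),
        expr_causal=expr_causal, trait_causal=trait_causal,
        scenario=scenario, gwas_z=gwas_z,
        baseline=baseline, covariate_loadings=cov_load, hidden_loadings=hidden,
    )
    _validate_truth(config, truth)
    return truth


def _validate_truth(config: SimConfig, truth: SimTruth) -> None:
    genes = set(config.gene_ids())
    snps = set(config.variant_ids())
    for e in truth.planted_eqtls:
        if e.gene_id not in genes or e.variant_id not in snps:
            raise ValueError(f"planted eQTL {e} refers to absent gene/variant")
    for e in truth.interaction_effects:
        if e.gene_id not in genes or e.variant_id not in snps:
            raise ValueError(f"interaction effect {e} refers to absent gene/variant")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimConfig, genotypes: GenotypeMatrix,
                        stream: int = 0) -> CovariateTable:
    """Age/sex/RIN/PMI, subject-level batch, and an ordinal Lewy-score.

    Pathology (Lewy body) scores follow the Braak-style 0-6 ordinal scale,
    drawn independently of genotype.
    """
    rng = _rng(config, stream, 103)
    n = genotypes.n_subjects
    df = pd.DataFrame({
        "subject_id": genotypes.subjects,
        "age": rng.normal(75.0, 8.0, n).round(1),
        "sex": rng.integers(0, 2, n),
        "rin": np.clip(rng.normal(7.5, 1.0, n), 3.0, 10.0).round(2),
        "pmi": np.clip(rng.normal(5.0, 3.0, n), 0.5, 24.0).round(2),
        "batch": [f"b{i}" for i in rng.integers(0, config.n_batches, n)],
        "pathology_score": rng.integers(0, 7, n),
    })
    groups = np.where(df["pathology_score"] == 0, "control",
                      np.where(df["pathology_score"] <= 3, "prodromal", "PD"))
    df["group"] = groups
    return CovariateTable(df)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def simulate_cells(config: SimConfig, genotypes: GenotypeMatrix,
                   covariates: CovariateTable, truth: SimTruth,
                   stream: int = 0) -> CellCountMatrix:
    """Negative-binomial UMI counts per cell with planted cis effects.

    Per cell, log mean = log baseline + library offset + batch shift
    + effect * dosage (planted cell types) + interaction * dosage * score
    + known-covariate and hidden-factor contributions.
    """
    rng = _rng(config, stream, 104)
    n = genotypes.n_subjects
    types = list(config.cell_types)
    cells_per = config.cells_per_subject_per_type
    gene_ids = config.gene_ids()
    n_genes = len(gene_ids)
    cov = covariates.aligned(genotypes.subjects)

    # per-subject fixed contributions (genes x subjects)
    known = np.column_stack([
        cov["age"].to_numpy(float), cov["sex"].to_numpy(float),
        cov["rin"].to_numpy(float), cov["pmi"].to_numpy(float)])
    known = (known - known.mean(axis=0)) / known.std(axis=0)
    subj_log = truth.covariate_loadings @ known.T  # genes x subjects
    hidden_factor = rng.standard_normal(n)
    subj_log += np.outer(truth.hidden_loadings, hidden_factor)
    batch_codes = pd.Categorical(cov["batch"]).codes
    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_batches, n_genes))
    subj_log += batch_shift[batch_codes].T
    score = cov["pathology_score"].to_numpy(float)

    vid_index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    gid_index = {g: i for i, g in enumerate(gene_ids)}

    meta_rows = []
    blocks = []
    cell_counter = 0
    for t_idx, ctype in enumerate(types):
        # genes x subjects log-mean for this cell type
        log_mu = np.log(truth.baseline)[:, None] + subj_log.copy()
        for e in truth.planted_eqtls:
            if ctype in e.cell_types:
                dos = genotypes.dosage[:, vid_index[e.variant_id]]
                log_mu[gid_index[e.gene_id]] += e.effect * np.nan_to_num(dos)
        for e in truth.interaction_effects:
            if ctype == e.cell_type:
                dos = genotypes.dosage[:, vid_index[e.variant_id]]
                log_mu[gid_index[e.gene_id]] += e.size * np.nan_to_num(dos) * score
        # expand to cells
        mu_subj = np.exp(log_mu)  # genes x subjects
        n_cells = n * cells_per
        lib = np.exp(rng.normal(0.0, config.library_sd, size=n_cells))
        mu = np.repeat(mu_subj.T, cells_per, axis=0) * lib[:, None]
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu * config.nb_dispersion)
        else:
            lam = mu
        counts = rng.poisson(lam)
        blocks.append(scipy.sparse.csr_matrix(counts))
        subj_rep = np.repeat(genotypes.subjects, cells_per)
        batch_rep = np.repeat(cov["batch"].to_numpy(), cells_per)
        meta_rows.append(pd.DataFrame({
            "cell_id": [f"c{stream}_{cell_counter + i}" for i in range(n_cells)],
            "subject_id": subj_rep,
            "cell_type": ctype,
            "batch": batch_rep,
        }))
        cell_counter += n_cells
    counts = scipy.sparse.vstack(blocks, format="csr")
    meta = pd.concat(meta_rows, ignore_index=True)
    return CellCountMatrix(counts=counts, cell_meta=meta, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(config: SimConfig, genotypes: GenotypeMatrix, truth: SimTruth,
                  stream: int = 0, ridge_eps: float = 1e-6) -> SummaryStatsTable:
    """LD-aware marginal z-scores: z ~ MVN(R z*, R), per locus.

    beta = z / sqrt(2 eaf (1-eaf) n), se = beta / z (i.e. 1/sqrt(2pq n)),
    matching a unit-variance quantitative trait scale.
    """
    rng = _rng(config, stream, 105)
    m = config.variants_per_locus
    rows = []
    for l in range(config.n_loci):
        gene = f"gene{l}"
        sl = slice(l * m, (l + 1) * m)
        cols = genotypes.dosage[:, sl]
        R = np.corrcoef(cols, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        np.fill_diagonal(R, 1.0)
        w, V = np.linalg.eigh(R)
        if w.min() < ridge_eps:
            R = R + (ridge_eps - w.min()) * np.eye(m)
            w, V = np.linalg.eigh(R)
        zstar = np.zeros(m)
        causal = truth.trait_causal.get(gene)
        if causal is not None:
            zstar[int(causal.split("_")[1])] = truth.gwas_z[gene]
        L = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
        z = R @ zstar + L @ rng.standard_normal(m)
        variants = genotypes.variants[sl]
        eaf = np.nanmean(cols, axis=0) / 2.0
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.gwas_n)
        beta = z * se
        p = 2.0 * stats.norm.sf(np.abs(z))
        for j, v in enumerate(variants):
            rows.append((v.id, v.chrom, v.pos, v.a1, v.a2, eaf[j],
                         beta[j], se[j], max(p[j], 1e-300), config.gwas_n))
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2",
                                     "eaf", "beta", "se", "p", "n"])
    return SummaryStatsTable(trait="gwas", table=df)


# ---------------------------------------------------------------------------
# bulk tissue expression
# ---------------------------------------------------------------------------

def simulate_bulk(config: SimConfig, genotypes: GenotypeMatrix,
                  covariates: CovariateTable, truth: SimTruth,
                  stream: int = 0, noise_sd: float = 0.25):
    """Per-subject tissue-homogenate expression (all cell types mixed).

    The bulk signal is the equal-weight mixture of the per-cell-type
    expected log-means, so a planted effect restricted to a few cell
    types is diluted by the mixture — mirroring the partial recovery of
    cell-type eQTLs in bulk cohorts.  Returns a
    :class:`~cellqtl.pseudobulk.PseudobulkExpression` in the
    ``normalized_mean`` state with cell type label ``"bulk"``.
    """
    from .pseudobulk import PseudobulkExpression

    rng = _rng(config, stream, 107)
    n = genotypes.n_subjects
    gene_ids = config.gene_ids()
    cov = covariates.aligned(genotypes.subjects)
    known = np.column_stack([
        cov["age"].to_numpy(float), cov["sex"].to_numpy(float),
        cov["rin"].to_numpy(float), cov["pmi"].to_numpy(float)])
    known = (known - known.mean(axis=0)) / known.std(axis=0)
    subj_log = truth.covariate_loadings @ known.T
    subj_log += np.outer(truth.hidden_loadings, rng.standard_normal(n))
    batch_codes = pd.Categorical(cov["batch"]).codes
    batch_shift = rng.normal(0.0, config.batch_sd,
                             size=(config.n_batches, len(gene_ids)))
    subj_log += batch_shift[batch_codes].T
    score = cov["pathology_score"].to_numpy(float)
    vid_index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    gid_index = {g: i for i, g in enumerate(gene_ids)}
    mix = np.zeros((len(gene_ids), n))
    for ctype in config.cell_types:
        log_mu = np.log(truth.baseline)[:, None] + subj_log
        add = np.zeros_like(log_mu)
        for e in truth.planted_eqtls:
            if ctype in e.cell_types:
                dos = genotypes.dosage[:, vid_index[e.variant_id]]
                add[gid_index[e.gene_id]] += e.effect * np.nan_to_num(dos)
        for e in truth.interaction_effects:
            if ctype == e.cell_type:
                dos = genotypes.dosage[:, vid_index[e.variant_id]]
                add[gid_index[e.gene_id]] += e.size * np.nan_to_num(dos) * score
        mix += np.exp(log_mu + add)
    values = np.log(mix / len(config.cell_types))
    values += rng.normal(0.0, noise_sd, size=values.shape)
    return PseudobulkExpression(cell_type="bulk",
                                subjects=list(genotypes.subjects),
                                genes=gene_ids, values=values.T,
                                state="normalized_mean")


# ---------------------------------------------------------------------------
# phased allele counts (ASE)
# ---------------------------------------------------------------------------

def simulate_ase(config: SimConfig, genotypes: GenotypeMatrix, truth: SimTruth,
                 stream: int = 0) -> PhasedAlleleCounts:
    """Beta-binomial phased UMI counts at the locus eSNPs.

    Only heterozygous subjects (dosage exactly 1) emit rows.  In planted
    cell types the effect-allele fraction is sigmoid(kappa * effect);
    everywhere else it is 0.5.
    """
    rng = _rng(config, stream, 106)
    vid_index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    planted = {(e.gene_id, e.variant_id): e for e in truth.planted_eqtls}
    phi = config.ase_overdispersion
    rows = []
    for gene, esnp in truth.expr_causal.items():
        dos = genotypes.dosage[:, vid_index[esnp]]
        het = np.where(dos == 1.0)[0]
        e = planted.get((gene, esnp))
        for ctype in config.cell_types:
            if e is not None and ctype in e.cell_types:
                mu = float(special.expit(config.ase_kappa * e.effect))
            else:
                mu = 0.5
            totals = rng.poisson(config.ase_mean_umis, size=len(het))
            if phi > 0:
                theta = (1.0 - phi) / phi
                pvals = rng.beta(mu * theta, (1.0 - mu) * theta, size=len(het))
            else:
                pvals = np.full(len(het), mu)
            a1 = rng.binomial(totals, pvals)
            for idx, s in enumerate(het):
                if totals[idx] == 0:
                    continue
                rows.append((genotypes.subjects[s], ctype, esnp, gene,
                             int(a1[idx]), int(totals[idx])))
    df = pd.DataFrame(rows, columns=["subject_id", "cell_type", "variant_id",
                                     "gene_id", "a1_umis", "total_umis"])
    return PhasedAlleleCounts(df)
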