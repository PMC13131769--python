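# Methods

This note records the statistical models, the synthetic study design, the
numerical choices, and the known limitations of `cellqtl`.

## Pseudobulk expression model

Single-cell UMI counts are normalized per cell to counts-per-10k
(UMI / cell total × 10⁴); cells with zero total are excluded. Pseudobulk
expression is the mean of normalized values over a subject's cells of one
type; subjects with fewer than `min_cells` (default 10) cells of a type
are missing for that type rather than estimated from too few cells. The
floor is configurable because there is no canonical value; 10 keeps the
per-subject mean's sampling noise below the biological signal at typical
per-gene counts.

Adjustment proceeds in two stages.

*Batch.* `meanvar` recenters and rescales each batch per gene to the
pooled moments — exact location/scale removal, the testable core. `eb`
first shrinks the per-batch location and scale estimates toward
across-gene priors (normal for location, inverse-gamma for scale, moment
matched, solved by fixed-point iteration) — the parametric
empirical-Bayes treatment appropriate when batches are small.

*Known + hidden covariates.* Each gene is regressed on age, sex, RIN and
PMI; the top `n_hidden` principal components of the column-standardized
residual matrix serve as surrogate variables, and the returned matrix is
the residual on known covariates plus surrogates. Surrogate extraction by
residual PCA (rather than an iteratively reweighted surrogate-variable
algorithm) is deliberate: it is deterministic, fast, and captures the
same residual structure at the scale this package targets. Column
standardization stops high-expression genes from monopolizing the
directions. `n_hidden` defaults to 30 capped at
n − rank(known) − 1; the pipeline driver further caps it at one tenth of
the gene-panel size and estimates the surrogates **from the background
(variant-free) genes only**. On a desk-scale panel a strong cis effect is
itself a top variance direction, so estimating factors from control genes
that cannot carry the effect of interest (the control-gene strategy of
RUV-style correction) is what keeps the surrogates from absorbing the
signal under test. On transcriptome-scale data this distinction is
immaterial.

Z-scaling divides each gene's residual by its sample SD (ddof = 1), so
downstream betas are in SD of expression per effect allele; zero-SD genes
are dropped.

## cis-eQTL and dynamic models

For each gene and each candidate variant within 1 Mb of the gene body
(positions 1-based, window inclusive at both ends), expression is
regressed on dosage with an intercept; p comes from the two-sided *t*
tail at n − 2 df. Pairs with fewer than 20 complete subjects, or zero
dosage variance among them, are skipped — 20 prevents degenerate *t*
tests and is configurable. Missing dosages are excluded pairwise, never
imputed.

Candidate variants come in three classes: genome-wide-significant GWAS
variants (p ≤ 5×10⁻⁸), sub-threshold variants (p ≤ 1×10⁻⁶ within 2 Mb of
a locus lead), and LD proxies (r² ≥ 0.4 with either, computed on the
supplied genotype panel — pluggable in principle). Variants with panel
MAF < 0.05 are removed first.

The dynamic model adds a pathology interaction:
expression ~ dosage + score + dosage·score, with the two-sided *t* test
on the interaction coefficient; records at p ≤ 0.01 are flagged. By
default raw (uncentered) dosage and score enter the model; `center=True`
is available because the main-effect interpretation differs. The ordinal
Lewy-body-style score is treated as numeric.

## Meta-analysis

Fixed effects: inverse-variance weights, Cochran's Q. Random effects:
DerSimonian–Laird τ² (moment estimator clipped at 0). RE2: the
likelihood-ratio statistic of H₀: β = 0, τ² = 0 against the free model
under βᵢ ~ N(β, seᵢ² + τ²), with τ² maximized by an 80-iteration
golden-section search on the profile likelihood over
[0, 100·max seᵢ²] (the τ² = 0 boundary is checked explicitly; the
search is vectorized over records).

The textbook asymptotic null for the RE2 statistic is the boundary
mixture ½χ²₁ + ½χ²₂. At the study counts this package routinely meets
(k = 2–4), that mixture is measurably conservative: the boundary weight
P(τ̂² > 0) is ≈ 0.16 / 0.23 / 0.26 at k = 2/3/4, not ½, and realized
type-I error at α = 0.05 is ≈ 0.03. The default null is therefore an
empirical table — 50,000 fixed-seed null statistics per k (the null law
does not depend on a common SE scale), with the analytic mixture tail
stitched on beyond the table so extreme p-values remain available. This
plays the role the original meta-analysis software fills with tabulated
small-sample p-values. `null="asymptotic"` selects the textbook mixture.
One consequence worth stating: when τ̂² = 0 the RE2 statistic equals
z²_FE and its mixture p necessarily exceeds the FE p, so RE2 is *not*
uniformly more significant than FE/RE under homogeneity — its advantage
is power under heterogeneity, which the test suite demonstrates with an
opposite-sign alternative.

Downstream consumers take p from RE2 and effect/SE from RE, the
convention for this test family.

## LD, clumping, π₁

LD is the signed Pearson correlation of dosage columns over pairwise
complete observations. Clumping is greedy: smallest-p unassigned variant
(ties: position, then id — determinism the reference tool leaves
unstated) becomes a lead; unassigned variants with p ≤ p2, within the kb
window of the lead (lead-to-member distance), and r² ≥ the threshold
join it. Chunk assignment gives records on one clump a shared eQTL
identity across cell types; a chunk is "detected" in a cell type when
any member passes the significance threshold there. π₁ uses the fixed-λ
Storey estimator (λ = 0.5); spline smoothing is out of scope. Stepwise
conditional analysis for secondary signals within a chunk is not
implemented; the chunking layer is the hook for it.

## Colocalization

Wakefield log-ABFs with prior effect SDs W½ = 0.15 for the quantitative
(z-scaled expression) trait and 0.2 for the case-control trait, the
conventional defaults; hypothesis priors p1 = p2 = 1e-4, p12 = 1e-5.
Posteriors are assembled in log space with `logsumexp`; the H3 mass
e^(L1+L2) − e^L12 is computed via `log1p` and clipped at zero with a
warning if cancellation turns it negative. Under the single-causal-variant
assumption each eQTL signal is paired with every GWAS LD chunk whose span
overlaps the gene's cis window; the SNP set is every shared cis SNP
within the clump distance window (500 kb) of the chunk lead — not just
chunk members, because truncating either association profile to the
other trait's significant SNPs blurs exactly the H3-vs-H4 contrast the
method needs (restricting to chunk members measurably raised
false-positive colocalizations at linked loci in simulation). When betas
are unavailable for a trait, lABFs can be reconstructed from p, MAF and N
via V ≈ 1/(2·N·maf·(1−maf)).

## SMR, HEIDI, multi-SNP SMR

The instrument must satisfy |z_eQTL| ≥ 3; HEIDI candidates additionally
need eQTL p < 1.57×10⁻³ and r² to the instrument in [0.05, 0.9], pruned
so no pair exceeds r² 0.9, truncated to the 20 strongest eQTL z-scores;
fewer than 3 candidates means the test is reported absent. The HEIDI
statistic sums squared standardized deviations dᵢ = b_xy(i) − b_xy(top);
the covariance of d comes from the delta method with cross-SNP
correlations equal to LD r within each trait (GWAS and eQTL cohorts
independent), and the null is a Satterthwaite scaled-χ² matched to the
eigen-moments of the correlation matrix of z_d. Multi-SNP SMR sums T_SMR
over the instrument plus the HEIDI set, with eigenvalues of the r²
matrix as the weighted-χ² weights, again Satterthwaite-matched — a
simplified variant of the reference tool's multi-SNP test, validated by
calibration rather than value matching (type-I ≈ 0.05 in the suite; the
approximation is mildly conservative because T_SMR ≤ z_g²).

Genes whose HEIDI test is absent are excluded from prioritization by
default (`heidi_missing="pass"` relaxes this): a gene whose linkage
status cannot be checked should not be called a shared-causal hit.

## Beta-binomial allelic imbalance

Phased UMI counts are summed to (subject, cell type, variant); groups
whose summed total is below 20 UMIs are dropped (boundary inclusive).
The model is a1ᵢ ~ BetaBinomial(totalᵢ, μ, φ) in the
intraclass-correlation parameterization (α = μθ, β = (1−μ)θ,
θ = (1−φ)/φ; φ → 0 is binomial). Maximization is Nelder–Mead on
(logit μ, logit φ) from μ starts {0.3, 0.5, 0.7}, with the φ = 0
boundary checked explicitly; the test is an LRT against μ = 0.5 with φ
free (overdispersion as nuisance), referred to χ²₁. Two consequences of
keeping φ free under the null: the test is calibrated under
overdispersed balanced data, and totally imbalanced data (every subject
all-a1) has its LRT bounded by 2n·log2, since a degenerate φ → 1 null
can explain all-or-nothing counts — the p is then ~10⁻⁷ at n = 20, not
arbitrarily small. `fix_phi=0` pins the overdispersion and recovers the
pure-binomial LRT. Intercept-only models are fitted (no covariates);
reference-bias correction belongs upstream in read processing.

Concordance between ASE log-odds (aligned to the eQTL effect allele) and
eQTL betas is a Pearson correlation with its *t*-based p.

## Synthetic study design

The generator's defaults are the conditions under which the pipeline is
validated; they are chosen once, not tuned per experiment:

- **Genotypes:** haplotypes are AR(1) Gaussians thresholded at MAF
  quantiles; the latent lag-1 correlation is obtained from the requested
  allelic correlation (default 0.9) by numerically inverting the
  tetrachoric relation (Owen's-T bivariate normal CDF + Brent), since
  thresholding attenuates correlation. Loci are independent 40-variant
  blocks 10 Mb apart; MAFs drift around a per-locus level within
  [0.05, 0.5]. Realized adjacent dosage r² ≈ 0.76 at the default.
- **Cohorts:** three datasets of 400 subjects, nine brain cell types
  (dopaminergic, glutamatergic and GABAergic neurons, oligodendrocytes,
  OPCs, astrocytes, microglia, endothelial cells, pericytes), 20 cells
  per subject and type — a desk-scale stand-in for population cohorts.
- **Expression:** negative-binomial counts (φ = 0.3) with log-normal
  library sizes, per-gene baselines 0.5–5 counts/cell, batch shifts
  (SD 0.3, 2 batches), small known-covariate loadings, one hidden factor
  loading on half the genes, and planted cis effects of 0.5 log-units
  per allele restricted to 3 of 9 cell types per eGene. 40 background
  genes on a variant-free chromosome anchor the surrogate-variable
  estimation.
- **Scenarios:** five shared-causal loci, two linked-causal decoys
  (trait causal variant chosen at realized r² ≈ 0.25 to the eSNP), one
  null locus; GWAS non-centrality z* = 8 at causal variants, summary
  statistics drawn directly as z ~ MVN(R z*, R) with R the realized
  dosage correlation (ridge-regularized when needed),
  β = z/√(2p(1−p)N), N = 100,000.
- **ASE:** heterozygous subjects (dosage exactly 1) emit beta-binomial
  counts with logit(μ) = κ·effect (κ = 1 by default — the paper-style
  coupling between eQTL effect and allelic log-odds is not identified
  from data, so it is a configurable model choice), φ = 0.1, ~30 UMIs
  per subject and cell type.
- **Bulk cohorts:** per-subject tissue expression is the equal-weight
  mixture of per-cell-type expected means plus noise, so cell-type
  -restricted effects are diluted ~3/9 — the mechanism behind partial
  bulk recovery. Bulk cohorts are fresh subject draws.

What the generator does **not** emulate: realistic cell-type
proportions, doublets, ambient RNA, reference bias in phased counts,
fine-scale recombination structure, and case-control GWAS sampling
(summary statistics are simulated directly in z-space because the
downstream stages consume summary statistics only). Passing tests
therefore demonstrate statistical correctness and calibration of the
pipeline, not robustness to those artifacts.

Every generator is byte-deterministic given the config seed; independent
streams are derived per stage and dataset.

## Pipeline problem sizes

The validation studies run the full pipeline at the default conditions
above: 20 seeds for the recovery study (five shared + two linked + one
null locus each) and 20 seeds of an all-null configuration; calibration
experiments use 5,000 simulated tests for the OLS and RE2 nulls, 1,000
for the dynamic interaction, 400 beta-binomial fits, and 500 HEIDI
replicates. These sizes give binomial error bands a few times smaller
than the effects being checked while keeping the whole suite in minutes.

## Known limitations

- Multi-allelic sites are rejected at genotype input, with a log entry.
- Strand-ambiguous palindromic variants are dropped during allele
  harmonization when eaf ∈ [0.4, 0.6] (window configurable); no strand
  inference is attempted.
- The RE beta/SE forwarded downstream is DerSimonian–Laird; the
  reference software's "conservative" RE variant is underspecified, and
  DL is the standard choice.
- Conditional (stepwise) secondary-signal analysis is not implemented.
- The SMR significance threshold is always computed from the realized
  forwarded-gene count (0.05/n). Printed figures elsewhere for this
  threshold disagree with each other at face value (a stated constant vs
  the stated ratio); computing it resolves the ambiguity.
- HEIDI power at weak GWAS signals is modest; the four-tier conjunction
  relies on colocalization and HEIDI jointly to reject linkage, and the
  recovery study measures exactly that joint behavior.
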