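# Methods

## Problem setting

Given per-SNP association p-values for two phenotypes (no individual-level
genotypes), a gene annotation, and a reference genotype panel for estimating
linkage disequilibrium (LD), the pipeline asks which genes are associated
with *both* phenotypes. Gene-level aggregation is essential: per-SNP signals
below genome-wide significance can still concentrate within a gene, and LD
makes the per-SNP statistics within a gene strongly dependent, so naive
combination rules are miscalibrated.

## SNP-to-gene assignment

Internally all coordinates are 1-based inclusive (BED input is converted on
read); chromosome labels are normalized so `chr1` and `1` match. Two
boundary rules are implemented:

* `plain` — SNPs with position in `[start − pad, end + pad]`.
* `ldbin` — SNPs inside the gene plus any SNP within `ld_window_kb`
  (default 1000) of the boundary whose squared dosage correlation with at
  least one within-gene SNP strictly exceeds `r2_threshold` (default 0.8).
  The window bound is this package's choice: the high-LD-buddy rule itself
  gives no search limit, and an unbounded scan is quadratic without a
  biological rationale at typical LD ranges.

A SNP may belong to several overlapping genes. Genes with fewer than two
assigned SNPs carry no aggregable signal and are dropped (counted in the
assignment report). SNPs monomorphic in the panel are removed up front:
their correlation is undefined and they carry no association information.

## LD estimation and conditioning

LD is the Pearson correlation of panel dosage columns (composite LD — valid
for unphased panels and standard for summary-statistic methods). Missing
genotypes are mean-imputed per variant before correlation. Empirical
correlation matrices can be numerically indefinite (duplicated variants,
more SNPs than samples, rounding); since the simulation null needs a
factorizable covariance, eigenvalues below `psd_floor = 1e-8` are raised and
the matrix rescaled back to unit diagonal, iterating until the smallest
eigenvalue clears the floor. A matrix already compliant is returned
unchanged, making the repair exactly idempotent; the perturbation scale
(~1e-8) is far below LD estimation error.

## Simulation gene test

The gene statistic is `T = Σ q_i` where `q_i` is the upper-tail χ²₁ quantile
of `p_i` (`p = 1` contributes 0 but still counts toward n). Under the null
with LD matrix Σ, `T` is distributed as `Σ z_i²` for `z ~ MVN(0, Σ)`; the
test samples that null directly (eigenfactorization of the conditioned Σ —
deterministic given matrix and seed) and reports the add-one empirical
p-value `(r + 1)/(m + 1)`, which is never zero and never below
`1/(m + 1)`. Simulation counts escalate through stages (default
10³ → 10⁴ → 10⁶, the demo uses 10³ → 10⁴ → 10⁵) whenever fewer than 100
simulated statistics reach the observed one, so null genes stay cheap while
significant genes get resolution. Per-gene seeds are a stable hash of
(global seed, gene id), making scans reproducible bit-for-bit and
independent of gene order or parallel scheduling. All assigned SNPs enter
the statistic by default; a top-k restriction exists but is off.

## Correlated Fisher (set-screen) test

Fisher's `X₀² = −2 Σ ln p_i` has mean `2N` under the null; dependence
inflates its variance, approximated through the Brown/Kost–McDermott
polynomial `cov(−2 ln p_i, −2 ln p_j) ≈ ρ_ij (3.25 + 0.75 ρ_ij)`, giving
`σ² = 4N + 2 Σ_{i<j} cov_ij`. The statistic is rescaled to `x² = X₀²·4N/σ²`
and referred to a χ² with fractional `df = 8N²/σ²`, evaluated through the
gamma form of the χ² distribution.

Two deliberate choices:

* **Variance expansion.** The displayed variance in some descriptions of
  this method omits the factor 2 on the off-diagonal sum. With the standard
  expansion `Var(ΣX_i) = ΣVar + 2Σ_{i<j}Cov`, a gene consisting of perfect
  copies of one marker collapses exactly to the single-marker p-value (df
  = 2) — duplicated information adds no evidence, as it must. Without the
  factor 2 that invariance fails (df = 8/3 for two copies). The package uses
  the standard expansion; `strict_printed_sigma=True` reproduces the
  factor-free form for audit.
* **ρ = r² by default.** The per-SNP p-values are two-sided, so
  `−2 ln p_i` is a function of `|z_i|`; the dependence between two such
  statistics is governed by the squared genotype correlation, not its
  absolute value. Null simulations confirm this sharply: over 2,000
  synthetic null genes the rejection rate at α = 0.05 is 0.032 with
  `ρ = |r|` (conservative, outside the 99% binomial band) and 0.056 with
  `ρ = r²` (inside it). `ρ = |r|` remains available by configuration for
  comparison with analyses that used signed-correlation inputs.

Known limitation: the scaled-χ² form matches only two moments. At large
scan sizes a KS test against uniformity can detect the residual misfit
(D ≈ 0.04 in our null scans), which shows up as mild anti-conservatism in
the far tail (α = 0.01) even when the α = 0.05 rate is nominal. The
simulation test has no such approximation error and serves as the
calibration anchor; requiring both methods to agree also limits the
practical impact.

## Cross-phenotype logic

Per method, candidates are genes with `p < 0.05` (strict) in both
phenotypes. Each candidate's two p-values are combined by Fisher's method,
`x² = −2(ln P₁ + ln P₂)` on 4 df — the two GWAS are independent cohorts, so
no dependence correction applies — and declared significant when
`meta p < 0.05/(n_candidates × n_phenotypes)`. The divisor's second factor
is interpreted as the number of phenotypes and is configurable; with two
phenotypes and two methods the numeric threshold is the same either way.
The final shared-gene set is the intersection of the two methods'
significant sets (exact gene-id match after whitespace/case normalization —
no alias resolution). The meta-analysis always combines one method's own
per-phenotype p-values; methods are never mixed before the intersection.

One reference panel serves both gene tests. The tests were historically run
with different panels (by different software); here panel choice is an
input, and internal consistency between the assignment r², the simulation
Σ, and the set-screen ρ is worth more than replicating that accident.

## Expression validation

Candidate genes are checked in two-group log2 expression data: `logFC =
mean(case) − mean(control)`, an unequal-variance (Welch) two-sample test,
and a Bonferroni threshold of 0.05 divided by the number of genes actually
tested. Requested genes absent from a matrix become explicit untested
records (validation panels report blanks, not errors). A moderated
(empirical-Bayes) statistic as used by microarray pipelines would shrink
per-gene variances; with the group sizes this stage targets (15–40 per
group) the ordinary Welch test is close and has no tuning parameters, so
exact reproduction of moderated p-values is out of scope — direction and
magnitude of logFC are the validation surface, summarized per gene across
datasets as consistent-decrease / consistent-increase / inconsistent /
not-evaluable (fewer than two significant calls).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth for every planted effect:

* **Panel.** One AR(1) latent-Gaussian block per gene
  (`corr = ρ^|i−j|`, default ρ = 0.8); two latent haplotypes per sample are
  thresholded at per-SNP MAF quantiles (MAF ~ U(0.05, 0.5)) and summed to
  dosages. Blocks are independent; genes sit far apart (1 Mb) on cycling
  chromosomes.
* **Summary statistics.** Per phenotype, `z ~ MVN(λ, R̂)` with `R̂` the
  panel's conditioned empirical LD and `λ_j = Σ_c R̂_{j,c}·δ_c` over the
  phenotype's causal SNPs (one per causal gene, mid-block); `p` is the
  two-sided normal tail. Sampling z directly is orders of magnitude faster
  than simulating cohorts and is exactly the model under which both gene
  tests are derived, which makes calibration checks sharp — but it also
  means the tests are evaluated under their own assumptions: real data
  deviate through unmodeled stratification, allele-frequency spectra,
  imputation error and cross-block LD, none of which the generator emulates.
* **Expression.** Controls ~ Normal(baseline 8.0, sd 0.5) on the log2
  scale; cases shifted by the planted logFC.

Demo conditions (fixed once): 400 panel samples (reference-panel scale),
60 genes of 4–12 SNPs; 6 pleiotropic genes with z-scale deltas 6/6/7/7/8/8,
6 + 6 phenotype-specific genes at delta 5, 42 null; expression cohorts of
39/24 and 15/15 samples with planted logFC −0.8 and −1.0 for the shared
genes; demo seed 17. A delta-5 gene clears the nominal filter in roughly
9 of 10 realizations per phenotype, so a demonstration meant to be recovered
in full plants its shared effects above that boundary while the specific
genes sit on it. All generator output round-trips through the package's
readers and writers.

## Numerical conventions

* p ≤ 0 on input is clipped to 1e-300 (so `−2 ln p` stays finite); p > 1 is
  treated as corrupt and the row dropped with a logged count.
* Fractional df always go through `scipy.stats.chi2`, which accepts them via
  its gamma parameterization; set-screen outputs are floored at 1e-300.
* p-value columns are written in full-precision scientific notation, and
  readers reparse them with correctly-rounded conversion, so
  write-then-read is exact to the bit (pandas' default float parsing is not
  correctly rounded).
* All stochastic stages derive sub-seeds from a single global seed via a
  stable hash; identical configs reproduce identical output files, verified
  by SHA-256 digests in the run manifest.

## Problem sizes used by the test suite

Unit and acceptance tests run at desk scale: null calibration on 2,000
single-block genes (300 panel samples, 5–10 SNPs per gene, vegas at a single
10³ stage, ample for measuring a 0.05 rejection rate), oracle comparisons at
10⁵ simulations, uniformity checks at 10⁴ SNPs, expression calibration at
500 replicates and 2,000 null genes. The full suite runs in well under five
minutes on one CPU.
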