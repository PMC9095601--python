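# Methods

`raresum` tests whether cases carry an excess of rare, putatively damaging
variants in a gene, using *public genotype summary counts* (per-variant AC,
AN and homozygous-alternate counts, as published by gnomAD) in place of
sequenced controls. This note records the statistical model, the defaults
and why they were chosen, what the synthetic data emulate, and the known
limitations.

## Carrier tables and exact tests

For a gene, let `m` be the number of cases, `n` the number of controls and
`k` the number of carriers (samples with qualifying alleles) among them.
Conditioning on all three margins, the case-carrier count `x` is central
hypergeometric under the null of no association, so Fisher's exact test is
exact, and with `K` ethnicity strata the exact
Cochran–Mantel–Haenszel statistic `S = Σ x_i` has the convolution of the
per-stratum hypergeometric PMFs as its null distribution. Two-sided P
values use the minimum-likelihood rule (sum of probabilities of outcomes no
more likely than the observed one, relative tolerance `1 + 1e-7`); this
convention reproduces the published carrier-table P values to three
significant figures and is the dominant one for exact conditional tests.
The two-sided convention for the exact CMH is not standardized; we use the
same minimum-likelihood rule there, which reduces bitwise to the Fisher
support when `K = 1` (the `K = 1` path literally delegates). The CMH null
is computed by direct PMF convolution rather than a network algorithm:
at realistic stratum counts (`K ≤ 6`) the convolution is exact, fast and
simpler to audit; equivalence with exhaustive enumeration is asserted in
the test suite for all configurations with ≤ 10⁴ outcomes.

Odds ratios are conditional MLEs under the noncentral hypergeometric
likelihood — the estimate consistent with the exact test — solved from
`E_ψ[x] = x_obs` over the exponentially tilted central PMF (summed over
strata for CMH). Boundary tables report open bounds (0 or ∞), degenerate
margins report NA. P values are never clamped below the smallest achievable
support value.

## Carrier-count models from summary counts

A sample qualifies under the dominant model with ≥ 1 alternate allele over
the gene's qualifying variants, under the recessive model with ≥ 2, and
under the double-heterozygous model with ≥ 2 distinct carried variants
(without phasing this includes same-haplotype pairs). Cases with genotypes
are counted directly. For summary-count cohorts the per-variant genotype
frequencies are exact when the homozygote count is published
(`p2 = nhomalt/(AN/2)`, `p1 = (AC − 2·nhomalt)/(AN/2)`), else
Hardy–Weinberg at `AC/AN`. Assuming independent variants,

    p_DOM  = 1 − Π p_i0
    p_2HET = Σ_{i<j} (1 − p_i0)(1 − p_j0) Π_{k≠i,j} p_k0
    p_REC  = Σ_i p_i2 Π_{j≠i} p_j0 + p_2HET

keeping only the dominant-order terms (three or more simultaneously carried
rare variants are negligible at these frequencies). The recessive and
double-het expressions are *products* over the remaining variants; a sum
there would exceed 1 and not be a probability. The expressions are
validated against 10⁷-draw Monte-Carlo genotype simulation (within 3
standard errors for 1, 2 and 4 variants). Expected control counts are the
probabilities scaled by the control cohort size, rounded to nearest (ties
to even); the cohort size per gene is the rounded mean of `AN/2` over the
gene's qualifying variants, matching how the LD test sets its haplotype
totals. Whether the original tool rounds or floors is unstated; nearest
was chosen and is configurable in effect via the count itself.

## Consistent QC and filtering

Defaults: sites need depth ≥ 10 in ≥ 90% of samples in *both* cohorts;
variants must PASS both cohorts' filters, be off the blacklist and have
missingness ≤ 0.1 on both sides (missingness is `1 − AN/(2N)`, so the
cohort size must be supplied for summary-count cohorts). Allele-frequency
filtering uses the *joint* AF pooled over cases and controls; stratified
runs compare the maximum per-ethnicity joint AF against the threshold,
which catches variants common in one ancestry but diluted in the pool —
the classic population-stratification false positive. Order of
application: coverage, then status/missingness, then AF, so the attrition
log attributes each loss to one stage; every excluded variant carries
exactly one primary reason.

The blacklist combines variants failing either sequencing platform's
filter with variants whose exome/genome AFs disagree; since the original
discrepancy thresholds live in unpublished supplementary material, the
default rule here is a two-sided exact two-proportion test at α = 1e-5
plus fold change ≥ 5 — a conservative stand-in with the same intent, both
knobs configurable.

Variant categories are rule sets over consequence annotations with
optional REVEL gates: "pathogenic" (stopgain, frameshift insertion or
deletion, or missense with REVEL ≥ 0.65), "nonfunctional" (synonymous, or
missense with REVEL < 0.2; the ProxECAT-style denominator) and
"synonymous". Score-gated consequences lacking a REVEL value are excluded
and logged.

## Calibration: sampling the exact null

Exact-test P values on rare variants are heterogeneous and discrete —
"P = 1" has large probability — so U(0,1)-based diagnostics mislead. We
sample null P values *directly from each gene's support CDF* (margins held
fixed; no re-testing, no phenotype permutation), average the
within-replicate order statistics, and regress observed on expected
−log10 P through the origin over the least-significant 95% of ranks; the
slope is the inflation factor λ_emp. Through the origin because the QQ
reference line passes through it; the top-5% exclusion protects the slope
from true signals. Both conventions are arguments. The two
uniform-assumption comparators (slope over the 0.5–0.95 quantile band, and
the two-point slope anchored at the highest-rank P = 1) are implemented as
described by their source; on discrete nulls they are biased away from 1
while λ_emp is centered at 1. Note the 0.5–0.95 band estimator is simply
*undefined* when more than half the P values equal 1 (the band is all
ties), which happens when carrier totals are very small; calibration
simulations comparing the estimators therefore draw carrier totals
`k ≤ 60` at an in-house-scale control cohort (8175) so the comparator
exists. Defaults: 100 replicates for λ in QQ plots, ≥ 1000 when the null
distribution of λ itself is reported; benchmarking on simulated nulls
reuses the other N−1 replicates for the expected values (leave-one-out).

## FDR control for discrete tests

Three discreteness-aware procedures, all operating on the observed P
values plus either the sampled null matrix or the support CDFs:

* **RBH_P / RBH_UL** (resampling): with `R(p)` observed rejections at
  threshold `p` and `R*(p)` the per-replicate null rejections, the
  estimated true-rejection count is `s(p) = R(p) − M*(p)` (mean) or
  `R(p) − Q*_β(p)` (1−β quantile; β defaults to 0.05, the source being
  silent). The adjusted value is `E[R*/(R* + s)]` when `s` is large
  enough, else the fraction of replicates with any null rejection;
  monotonized and capped at 1.
* **Adaptive discrete step-down**: critical constants
  `τ_j = max{t ∈ support : Σ of the (G−j+1) smallest F_g(t)/(1−F_g(t)) ≤ jα}`,
  adjusted values `max_{j≤k} min(1, (1/j) Σ_{(G−j+1) smallest} F_g(p_(j))/(1−F_g(p_(j))))`.
  Genes that cannot achieve small P values contribute nothing at small
  thresholds, which is exactly where the power gain over
  Benjamini–Hochberg comes from. The non-adaptive step-up variant
  (`Σ_g F_g(t) ≤ kα`) is also provided; it — not the adaptive step-down —
  is the procedure whose continuous-uniform limit is exactly BH, and the
  test suite asserts that reduction on the step-up form.

Plain BH is retained as the baseline comparator. In the mixture
simulations shipped with the acceptance suite (400 genes, 5% signals at
carrier odds ratio 15, 200 replicates) all three control FDR at 0.05
within binomial error and the discrete-aware methods reject at least as
many true signals as BH. The measured power gain at these settings is a
few percent relative — the published double-digit gains arise at other
margin/signal configurations not reproduced here.

## LD detection from pooled counts

Two biallelic variants define haplotype probabilities
`(p11, p10, p01, p00)`, reparametrized by the marginal allele frequencies
`s, t` and the haplotype odds ratio `θ = p11·p00/(p10·p01)`. Nested public
subsets (controls ⊂ non-cancer ⊂ all, each split by sex) subtract into six
disjoint, independent pooled-count sets per ethnicity. Within set `i`,
given alternate counts `(x_i, y_i)` among `n_i` haplotypes, the likelihood
marginalizes the unobserved double-alternate haplotype count `r` over
`[max(0, x+y−n), min(x, y)]` with multinomial terms under HWE, computed in
log space. Positive LD (θ > 1) is tested by a one-sided LRT maximizing
over `(logit s, logit t, log θ)` — unconstrained versus `log θ ≤ 0` as a
box bound — with analytic gradients (validated against central finite
differences to 1e-6) and four starts including the independence solution;
P values from the upper tail of χ²₁. A conservative ½χ²₀ + ½χ²₁ option
exists but is off by default, matching the stated choice. The additive
genotype coding is the `n = 2` special case, so the full-genotype test is
the same likelihood on the 3×3 genotype-combination table; it is
substantially more powerful at equal sample size.

Numerical note: the closed-form root for `p11` given `(s, t, θ)` must be
evaluated as `2c/(b + √(b² − 4ac))`; the textbook `(b − √·)/(2a)` form
loses up to five significant digits to cancellation in exactly the
rare-variant regime and corrupts the likelihood surface.

Operating characteristics at six sets of 20 000 haplotypes: type I error
at α = 0.05 is ≈ 0.05 for AF ≥ 5e-3 but ≈ 0.066 at AF = 1e-3 — the χ²₁
tail is approximate for the one-sided boundary test at sparse counts, a
limitation the method's description itself concedes. Power rises with θ
and AF; because the pooled counts only expose LD through the covariance
of six (x, y) pairs, moderate LD (θ ≈ 500 at AF ≥ 5e-3 gives within-set
correlation ≈ 0.5) is detected only about half the time, and the pairs
detected in practice are near-perfect-LD (MNV-like) pairs. The
unconstrained θ̂ is median-biased upward by a factor ≈ 2–2.6 in this
regime; the bias does not shrink with `n_i` because the information is
capped by the number of independent sets.

The within-gene scan restricts to variants with AF ≤ 0.01, AC ≥ 10 and
missingness ≤ 0.1, uses the rounded average AN over the gene's qualified
variants as the haplotype total, controls FDR by BH across the scan, flags
θ̂ > 150 as high LD, and stores pairs with P < 0.1.

Downstream corrections: for control-side recessive/double-het estimation,
each connected component of the FDR < 0.05 LD graph keeps only its
highest-AF variant (ties break to the lexicographically smallest key);
case-side double-het carriers whose every supporting heterozygous pair has
an LD-test P < 0.1 are not counted for the recessive or double-het models
(homozygotes are immune). Pruning never increases estimated control
counts. Without these corrections the independence-based control
estimates understate the true co-carrier counts whenever a high-LD pair is
present, while the case counts (from genotypes) include them — the
false-positive mechanism the corrections remove.

## Pipeline

The gene universe is every gene with ≥ 1 qualified variant; genes with
zero carriers in cases and controls combined have a single-point null and
are excluded from testing and λ estimation. Samples labeled "other"
(ethnicity unassigned) are never used in stratified runs. For CMH runs the
per-stratum tables are reported along with a combined conditional-MLE odds
ratio, labeled as such. Runs are deterministic given the seed; per-stage
variant attrition is mandatory output. The ProxECAT-style comparator pools
functional and non-functional allele counts into a 2×2 table and applies
the two-sided Fisher's exact test (replacing the original likelihood-ratio
version, which is inaccurate at small counts).

## Synthetic data

The generators emulate the target study design: a modest fully genotyped
case cohort, a large control cohort seen only through summary counts
(aggregated from a latent simulated genotype matrix, so true model counts
are known exactly and aggregation conserves AC by construction),
per-position coverage, and annotations that drive category selection.
Allele frequencies are log-uniform on [1e-5, 1e-3] (the rare-variant
focus); planted risk genes instead fix their variants at AF 2.5e-4 — an
order of magnitude under the 1e-3 joint-AF threshold, so the filters keep
them even after case enrichment (a planted variant near the threshold
censors its own signal when a strong carrier draw pushes its joint AF over
the line), while the gene's combined carrier frequency (a few per
thousand) matches the published predisposition-gene tables — and inflate
the case carrier odds by the target odds ratio, refusing effects that
would saturate more than 90% of cases. Planted LD pairs replace two variants'
genotypes with draws from the four-haplotype distribution at the requested
θ. Null-support generators draw margins `(m, n, k)` with k uniform and x
central hypergeometric.

What the synthetic data do *not* contain: population substructure within
strata, admixture, sequencing artifacts, platform batch effects,
annotation error, or real LD beyond the planted pairs. Passing tests
therefore demonstrate the statistical machinery under its stated
assumptions, not robustness to the confounders that motivate the careful
QC in real applications.

## Problem sizes in the shipped checks

The acceptance suite runs: the nine published carrier tables; support
enumeration up to 10⁴ outcomes; λ calibration at 2000 genes × 1000 null
replicates (leave-one-out); FDR mixtures at 400 genes × 200 replicates;
LD type I at 250 replicates per AF, power at 80, recovery at 50; count
validation at 10⁷ Monte-Carlo draws; and end-to-end recovery over 50
seeded cohorts of 2000 genes (500 cases, 5000 summary-count controls).
`scripts/acceptance.py` recomputes the same quantities at reduced
replicate counts and writes them as JSON.

## Known limitations

* The recessive/double-het probabilities ignore third-order carrier
  combinations; at AF ≳ 0.05 per variant the truncation error becomes
  visible.
* χ²₁ for the one-sided LRT is mildly anti-conservative at AC ≈ 20 per
  set and conservative in the well-powered regime; the mixture option
  trades one for the other.
* The double-heterozygous model cannot distinguish compound
  heterozygotes from same-haplotype pairs without phasing.
* Ethnicity labels are taken as input; no ancestry inference is
  performed, and residual substructure within a stratum is not modeled.
* Covariate adjustment is out of scope by design — summary counts do not
  support it.
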