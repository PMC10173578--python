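# Methods

`netmr` implements a network (mediation) Mendelian randomization
analysis over GWAS summary statistics: univariable two-sample MR from an
exposure to an outcome and to a set of candidate mediators, multivariable
MR conditioning on those mediators, and the decomposition of the total
causal effect into direct and mediated components. This note records the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic-data generator does and does not emulate.

## Model and assumptions

Each SNP *j* contributes a harmonized pair of association estimates
(β̂ˣⱼ, σˣⱼ) for the exposure and (β̂ʸⱼ, σʸⱼ) for the outcome, measured in
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, independence from confounders, exclusion restriction), the
per-SNP ratio β̂ʸⱼ/β̂ˣⱼ estimates the causal effect θ. For a binary
outcome all effects live on the log-odds scale; odds ratios are a
presentation transform (`exp`) applied at the end, never the working
scale.

### Univariable estimators

- **Wald ratio** — β̂ʸ/β̂ˣ with first-order SE σʸ/|β̂ˣ|.
- **IVW** — zero-intercept weighted regression of β̂ʸ on β̂ˣ with weights
  σʸ⁻²: θ̂ = Σwβ̂ˣβ̂ʸ / Σw(β̂ˣ)². The default variance model is
  *multiplicative random effects*: the fixed-effect SE is inflated by
  max(1, √(Q/(n−1))), where Q is Cochran's Q at the estimate. This is
  the dominant two-sample default; the floor at 1 means the
  random-effects SE never undercuts the fixed one.
- **MR-Egger** — weighted regression with a free intercept after
  orienting every β̂ˣ ≥ 0 (flipping the paired β̂ʸ), which the intercept
  needs to be interpretable as mean directional pleiotropy. Slope and
  intercept use t(n−2) reference distributions with the *classical
  estimated-scale* (σ̂-scaled) covariance rather than the floored
  multiplicative scaling: with the floor the intercept statistic is no
  longer t-distributed and its type-I error drifts below nominal,
  whereas the classical form is exactly calibrated under the null —
  which is also what the calibration acceptance test checks.
- **Maximum likelihood** — each SNP's (β̂ˣⱼ, β̂ʸⱼ) are independent
  normals centred at (γⱼ, θγⱼ) with known SEs. Profiling out γⱼ leaves
  g(θ) = Σⱼ(β̂ʸⱼ − θβ̂ˣⱼ)²/(σʸⱼ² + θ²σˣⱼ²), minimised by bounded scalar
  search (tolerance 1e-12, bracket ±max(1, 50·SE_IVW) around the IVW
  point). The SE comes from the numerical curvature of the profile
  (the profile curvature equals the θ-block of the full-model observed
  information). As σˣ → 0 this reduces to fixed-effect IVW.
- **MR-RAPS** — solves Σⱼ ψ(tⱼ(θ))·(−∂tⱼ/∂θ) = 0 with
  tⱼ = (β̂ʸⱼ − θβ̂ˣⱼ)/√(σʸⱼ² + θ²σˣⱼ² + τ²), ψ the identity (ℓ₂) or the
  Huber function with constant c = 1.345 (configurable). Roots are
  bracketed at ±max(1, 10·SE_IVW) around the IVW estimate; the bracket
  widens once (×5) before failing. With overdispersion enabled, τ² is
  estimated by method of moments — Σψ(tⱼ)tⱼ = (n−1)·E[ψ(Z)Z] with
  Z ~ N(0,1), alternated with the θ root until both are stable — and
  floored at 0. The SE is a sandwich estimate whose middle term is
  model-based (E[ψ(Z)²]·Σuⱼ²) rather than empirical so it stays
  positive on exactly-consistent data.

P-values use the normal reference for Wald/IVW/ML/RAPS and t(n−2) for
both Egger coefficients.

### Sensitivity suite

- **Cochran's Q** in the IVW (df = n−1) and Egger (df = n−2)
  frameworks; the IVW Q is the same quantity that drives the
  multiplicative SE scaling (shared code path). Heterogeneity is
  reported, never used to auto-drop SNPs.
- **Leave-one-out** — one IVW refit per omitted SNP; an omission is
  flagged when its CI excludes the full-set estimate or the sign flips.
- **Outlier test (MR-PRESSO style)** — the observed statistic is
  Σⱼwⱼ(β̂ʸⱼ − θ̂₋ⱼβ̂ˣⱼ)² with θ̂₋ⱼ the leave-one-out fixed-effect IVW
  estimate; its null distribution comes from parametric redraws of both
  betas at the observed SEs (default 1000 draws, mandatory seed).
  Per-SNP outlier p-values are simulated residual tails with Bonferroni
  adjustment across SNPs (outliers declared at 0.05 only when the
  global test is itself significant at 0.05); the corrected estimate
  refits IVW without the outliers, and the distortion test compares the
  raw/corrected shift against refits with random same-size non-outlier
  subsets removed. Identical seeds give bit-identical results.
- **Steiger directionality** — per-SNP variance explained via
  r² = z²/(z² + n) with z = β̂/σ; binary traits use the effective sample
  size n_eff = 4/(1/n_cases + 1/n_controls). This choice matters for a
  binary outcome such as stroke: raw n would overstate the outcome-side
  r². Summed r² on the two sides are compared with the normal test on
  the difference of Fisher-transformed correlations. Equal r² is
  reported as direction_correct = False with p = 1.
- **Analytic power (binary outcome)** — under the linearized logistic
  model the IVW log-odds estimate has variance ≈ 1/(n·K(1−K)·r²), so
  power is the two-sided normal tail at noncentrality
  √(n·K(1−K)·r²)·|ln OR|. The formula is validated against (and
  documented by) a Monte-Carlo oracle that simulates summary statistics
  under the same model, estimates by IVW, and tests at α — agreement
  within ±0.03 at n = 50,000, K = 0.1, r² = 0.02, OR = 1.3. It returns
  exactly α at OR = 1 and is monotone in n, r², and |ln OR|.

### Instrument selection

SNPs pass the genome-wide threshold P < 5e-8 for whichever trait is the
exposure of the contrast at hand, then greedy LD clumping at r² < 0.001
within a 10 Mb window: sort ascending by p (ties by position, then id),
keep the best remaining SNP, remove correlated neighbours, repeat. The
window is interpreted as |Δpos| ≤ 10 Mb inclusive on the same
chromosome (the looser "at least 10 Mb" reading would make the window
unbounded). LD comes from a user-supplied r² matrix; without one the
clumper treats *every* same-chromosome SNP within the window as
correlated — conservative, and the only defensible offline fallback
when no reference panel is available. Instrument strength uses the
squared-t approximation F = (β̂ˣ/σˣ)² per SNP (the R²-based form
F = (n−2)·r²/(1−r²) is asymptotically equivalent at GWAS sample sizes);
a mean F ≤ 10 flags the set as weak. Confounder screening is file-based:
a two-column (snp, reason) exclusion list replaces interactive database
lookups, keeping runs reproducible and offline.

### Harmonization

Outcome records are aligned to the exposure's effect allele: order swaps
negate β and reflect EAF; complementary-strand codings are translated
first. Palindromic SNPs (A/T, C/G) are dropped by default
(`palindrome_policy="drop"`); the `infer_by_eaf` policy orients them by
frequency agreement but still drops any SNP whose EAF is missing or
within 0.08 of 0.5 on either side, where strand is not inferable.
Positions are 1-based throughout.

### Multivariable MR and mediation

Multivariable IVW regresses β̂ʸ on the SNP × exposure matrix of betas
(zero intercept, weights σʸ⁻²); coefficient SEs come from the weighted
normal equations, inflated by max(1, √(Q/(n−p))) under the default
multiplicative model, so a single-exposure fit reproduces univariable
IVW exactly. The joint instrument pool is the union of each included
exposure's significant SNPs, re-clumped jointly with the minimum
p across exposures as the ranking key, and harmonized to the primary
exposure's allele coding.

The **default mediation method is the difference method** (two-step
MVMR): indirect = total − direct with the direct effect the exposure
coefficient conditional on the mediator(s), and PM = 100·indirect/total
(percent, 2 decimals). This choice is forced by arithmetic: the
published PMs are reproducible from the published total and adjusted
ORs by the difference method (e.g. 100·(1 − ln 0.836/ln 0.711) ≈ 47.5%
against the printed 47.35%), whereas a product of univariable
coefficients gives materially different values (≈37% for the same
mediator). The product method (a×b with the product delta SE) is
provided for sensitivity. PM is reported unbounded with a quality flag
outside [0, 100].

PM uncertainty defaults to the delta method treating the total and
direct estimates as independent normals — knowingly an approximation,
because the two instrument sets share SNPs — so a
bootstrap-over-instruments alternative (`pm_bootstrap`, independent
resampling of the univariable and multivariable sets) is provided and
both can be reported. No exact PM confidence interval is attempted.

## Synthetic-data generator

`DagSpec` fixes a causal graph — one exposure, k mediators, one binary
outcome — with edge coefficients a (exposure→mediator), b
(mediator→outcome, log-odds), and c (direct, log-odds); the estimands
are total = c + Σaᵢbᵢ, indirectᵢ = aᵢbᵢ, PMᵢ = aᵢbᵢ/total, all available
in closed form via `true_effects` and stored with every simulated study.

Summary statistics are generated directly, without individual-level
genotypes: each trait's instruments get true effects scaled so they
explain exactly h² of the trait's unit variance; effects propagate
through the DAG by path products; observed betas are truth plus
independent noise per trait (two-sample independence is structural —
no draws are shared), with theoretical SEs 1/√(2f(1−f)·n) for
continuous traits and the linearized logistic approximation
1/√(2f(1−f)·n·K(1−K)) for the binary outcome. Allele frequencies are
uniform on [0.05, 0.5]; palindromic SNPs (rate 0.1) and flipped allele
codings in non-exposure tables (rate 0.2) exercise harmonization.
Optional directional pleiotropy adds outcome offsets to a fraction of
SNPs, oriented relative to the allele that raises the SNP's own trait
(a constant offset under symmetric effect draws would cancel after
Egger's sign orientation); an overdispersion component τ adds zero-mean
outcome noise to all SNPs. SNPs occupy distinct 25 Mb slots across 22
chromosomes so that true instruments survive distance-only clumping.

Default conditions mirror the motivating study design: 50
instruments/trait, n = 100,000 per GWAS, outcome case fraction 0.09
(the stroke GWAS's 40,585/446,696), total effect ln(0.711), four
mediators with b = (ln 1.317, ln 1.220, ln 1.429, 0.1) and a chosen so
the PM split is (30, 18, 12, 5)% — combined PM 65%. The b for the
fourth mediator and the PM split are generator choices (the source
tables don't pin them down); they were fixed once at values a
practitioner would call realistic and are not tuned.

What the generator does **not** emulate: LD between instruments (beyond
user-supplied toy matrices), sample overlap between GWAS, allele
frequency differences between cohorts, genome-build issues, winner's
curse in instrument discovery, or non-collapsibility of the odds ratio
(effects are propagated linearly on the log-odds scale). Passing
recovery tests therefore demonstrates correctness of the estimators and
plumbing under the stated model, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

- All estimator tolerances: scalar minimisation/root-finding at 1e-12;
  oracle-equivalence tests assert 1e-10 for linear-algebra paths and
  1e-4 against grid searches.
- se = 0 edge: p-value is 1 for a zero estimate, 0 otherwise.
- A zero exposure beta makes the Wald ratio an error; all-zero exposure
  betas make IVW an error. In multivariable fits an all-zero column is
  dropped and reported NaN; rank deficiency among non-zero columns is
  an error.
- Clumping ties break deterministically (p, then position, then id), so
  output is independent of input row order.
- Empirical p-values in the outlier test use the (1+hits)/(1+draws)
  form, so they are never exactly zero.
- PM with a zero total effect is an error (flagged as undefined in the
  generator's closed-form estimands).

## Problem sizes in the shipped tests

Calibration uses 2000 null replicates (20 SNPs each); outlier detection
200 replicates at 1000 simulation draws; DAG recovery 200 replicates of
the full default study; the power oracle 5000 Monte-Carlo replicates.
These sizes give Monte-Carlo SEs comfortably inside the asserted bands
(e.g. ±1 PM point for the recovery mean) while keeping the whole suite
around half a minute on one CPU.

## Known limitations

- The distance-only clumping fallback discards genuinely independent
  same-chromosome SNPs within 10 Mb; supply an r² matrix to avoid it.
- The RAPS overdispersion moment estimator is simpler than a full joint
  likelihood and can sit at τ² = 0 for under-dispersed data.
- The delta-method PM interval ignores total/direct dependence; prefer
  the bootstrap when the instrument sets overlap heavily.
- Correlated instruments (generalized IVW), weighted-median/mode
  estimators, and radial variants are out of scope.
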