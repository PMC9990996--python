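# Methods

## Scope and model

`cismr` estimates causal effects of cis-regulated molecular traits (gene
expression; DNA methylation) on complex outcomes from marginal summary
statistics alone, and judges whether the underlying association signals are
shared. Everything operates under the standard asymptotic model for GWAS
summary data: for a region with LD (signed correlation) matrix `R` and
standardized per-variant causal effects `b~`, the vector of marginal
z-scores is distributed `MVN(sqrt(n) R b~, R)`. All estimators, the Bayes
factors, the conditional analysis and the simulator share this one model,
which is what makes the synthetic calibration exercises internally
consistent.

Effect scales: quantitative traits carry per-SD betas, binary traits
log-odds betas with `n` interpreted as an effective sample size
(`4/(1/n_cases + 1/n_controls)` for real data). Beta and SE are
authoritative everywhere; p-values are recomputed from `|beta/se|` whenever
a source file disagrees by more than 10% relative (counted in the load
report, never silently).

## Harmonization

Outcome records are aligned to the exposure's effect allele by allele
matching, allowing strand complements. Palindromic variants (A/T, C/G)
cannot be strand-resolved from alleles; they are dropped when either
trait's effect-allele frequency lies in [0.42, 0.58] or is missing, and
otherwise aligned by frequency agreement (same side of 0.5). The procedure
is an involution: harmonizing an already-harmonized pair is the identity.
The ambiguity window is configurable; the default mirrors common two-sample
MR practice.

## Instrument selection and conditional analysis

Clumping is the greedy PLINK-style rule on the exposure (QTL) p-values:
take the smallest p <= 5e-8 as an index (ties by position, then id), absorb
unassigned variants with r^2 >= 0.01 within 1000 kb, repeat. One deliberate
extension: a candidate index correlated at >= r^2 threshold with an
already-chosen index — possible when two strong signals sit farther apart
than the window — is absorbed rather than promoted, so the index set always
satisfies max pairwise r^2 < threshold. The window default (1000 kb) matches
the 1 Mb cis design and is configurable.

Approximate conditional analysis residualizes z-scores on a condition set C
using the reference LD:

    z_j|C = (z_j − r_jC R_CC^-1 z_C) / sqrt(1 − r_jC R_CC^-1 r_Cj)

with a 1e-6 ridge on `R_CC` when its condition number exceeds 1e8, and a
collinearity error when the denominator falls to <= 1e-6. Betas are rebuilt
as `z|C * se` with the original SE retained — a deliberate simplification
of full joint conditional estimation (which also rescales by the residual
phenotypic variance); for the strong, well-separated signals this package
decomposes, the approximation is accurate and the simulation tests confirm
residual statistics are null-calibrated after conditioning on the causal
variant.

## MR estimators

Wald ratio `b_out/b_exp` with first-order delta SE `se_out/|b_exp|`
(a second-order option adds the exposure-uncertainty term); fixed-effect
IVW across independent (post-clumping) instruments. Random-effects IVW is
intentionally absent: cis loci carry one-to-few instruments, where the
heterogeneity variance is undefined. The first-order SE neglects
`theta^2 se_exp^2`, which is negligible exactly when the instrument is
strong relative to the outcome noise; see the mediation scenario note below
for where this bites. Instruments weaker than |z| = 1 attach an explicit
weak-instrument warning. The transcriptome scan Bonferroni-corrects at
`alpha / (number of exposures actually estimated against that outcome)`.

## Colocalization

Per-variant evidence is the asymptotic Bayes factor
`log ABF = 0.5 log(1−r) + r z^2/2`, `r = W^2/(se^2+W^2)`, with effect-prior
SD `W` = 0.15·sd_y (quantitative) or 0.2 (log-odds). Pairwise posteriors
over H0–H4 use priors `p1 = p2 = 1e-4`, `p12 = 1e-5` — the canonical
single-causal-variant defaults — with every sum in log space; the H3 term
is the full cross product minus the coincident diagonal, computed with a
signed log-domain correction so no catastrophic cancellation occurs. With
one variant, H3 is structurally zero. "PPA" in reports means PP(H4) alone,
not PP(H3)+PP(H4).

The three-trait engine enumerates all subset-partition configurations
(15 for three traits; k = 4 supported for testing) with per-cardinality
priors (1e-4 single-trait, 1e-6 two-trait, 1e-7 all three); a
configuration's prior is the product over its groups. The sum over
assignments of *distinct* variants to groups is evaluated exactly by signed
inclusion–exclusion over partitions of the group set (Moebius coefficients
`(−1)^{|B|−1}(|B|−1)!`), which is O(#partitions · m) — no cubic loops. The
headline statistic `ppa_full` is the posterior of the single configuration
in which all three traits share one variant; partial-sharing posteriors are
all reported for sensitivity use. CpGs are scanned within 100 kb of the
gene's coordinates (inclusive), the maximum `ppa_full` is reported along
with the full per-CpG table, and no multiplicity adjustment over CpGs is
applied — that choice is left to the user. Multi-signal eQTL loci are
decomposed by conditioning all three traits on the other index variants and
scanning each isolated signal in turn.

## Downstream layers

Effect matrices are per-outcome z-scored (so log-odds and per-SD columns
are comparable) with missing cells imputed at the column mean (zero) for
distance purposes only and tracked in a mask; a raw-beta mode exists.
Clustering is complete-linkage on Euclidean distances with rows and columns
pre-sorted by id for deterministic leaf order. Gene-set enrichment is the
exact hypergeometric upper tail from log-factorials. The tissue-replication
report counts primary-tissue effects with proxy-tissue p < 0.05 (the
heuristic threshold), its complement, the reverse comparison and sign
concordance. For "inverse relationship" questions between trait gene-sets
the package exposes sign-concordance counts and an exact binomial sign
test as a transparent surrogate — no model-based claim is made. The
phenome-wide scan thresholds at `0.05 / (number of outcomes)`.

## Synthetic data

The generator draws marginal z-scores directly from
`MVN(sqrt(n) R b~, R)` over an AR(1) LD grid (`r_ij = rho^|i−j|`,
default rho = 0.9, m = 200 variants at 2 kb spacing), with per-variant
`se = 1/sqrt(2 f (1−f) n)` and MAFs uniform on (0.05, 0.5) except at causal
sites, where the frequency is pinned at 0.30 so expected z-scores are
exact. Reference panels come from Gaussian-copula haplotype thresholding of
the same LD. An individual-level mode (phenotype = dosage·beta + noise,
then per-variant OLS) cross-validates the shortcut at small n.

What the simulator emulates: LD-induced correlation of marginal statistics,
shared vs distinct causal variants, sample-size asymmetry between QTL and
GWAS sources, truncated variant coverage of probe-centred mQTL releases,
and vertical pleiotropy with a known causal ratio. What it does not:
realistic human LD block structure, allele-frequency/LD coupling from
demography, assortative or family effects, horizontal pleiotropy, and
binary-trait likelihood effects beyond the effective-n approximation.
Passing calibration here therefore shows the machinery is correct under its
own asymptotic model, not that real-data violations of that model are
handled.

Canonical scenarios (sample sizes mirror the study conditions — brain eQTL
n = 1194, brain mQTL n = 500, whole-blood eQTL n = 31 684, GWAS effective
n = 50 000; causal effects sized for expected |z| = 8 at the causal
variant):

- `H4-shared` / `H3-distinct`: one causal variant shared vs two separated
  by 80 grid steps (r^2 ≈ 0.9^160, far below 0.01);
- `three-way-shared`: expression, methylation and outcome on one variant;
- `two-independent-eQTL-signals`: eQTLs at two separated sites, only one
  shared with methylation and outcome — the conditional-decomposition test
  bed;
- `null`: instrumented exposures, no outcome effect anywhere;
- `mediation`: three independent instruments (expected |z| = 12) with
  outcome effects exactly 0.3× the exposure effects;
- `truncated-mQTL-coverage`: three-way sharing with the methylation
  statistics restricted to ±20 kb of the probe.

The mediation scenario uses a whole-blood-scale exposure (n = 31 684)
rather than the brain-scale one: the first-order Wald/IVW standard error
omits the `theta^2 se_exp^2` term, and with a n = 1194 exposure against a
n = 50 000 outcome that term dominates, so no faithful first-order
implementation could hold 95% CI coverage near nominal. At blood scale the
neglected term is ~14% of the variance and measured coverage sits at ~0.93,
inside the accepted [0.92, 0.98] band — a known, documented property of the
estimator rather than a defect.

## Numerical choices

- All probability sums in log space (`logsumexp`, signed where subtraction
  occurs); degenerate cancellations collapse to exact zeros, not negatives.
- `two_sided_p` computes `2*Phi(−|z|)` via the log survival function and
  floors at the smallest positive double (5e-324) so it never returns
  exactly zero; `log_two_sided_p` gives the exact log-scale value past that
  floor.
- Coordinates are 1-based inclusive throughout; the cis flank (default
  1 Mb) and the CpG window (100 kb) include both endpoints.
- Ties are broken deterministically everywhere (p, then position, then id
  in clumping; id sort before clustering), so every run is byte-reproducible
  from its config and seed.
- Monomorphic panel variants are excluded with a warning; LD matrices are
  symmetrized, clipped to [−1, 1] and given an exact unit diagonal on
  construction.

## Problem sizes used in the shipped checks

Calibration runs use 200 replicates for pairwise colocalization and
mediation recovery, 100 for three-trait colocalization, and 1000 replicates
of a 10-exposure null scan (m = 12-variant regions) for the family-wise
error measurement; component oracles use 10-variant clumping instances and
6×4 effect matrices. These sizes give Monte-Carlo error comfortably inside
the asserted bounds while keeping the full suite around two minutes on one
CPU.

## Known limitations

- Single-causal-variant assumption per trait inside each (conditioned)
  colocalization run; no SuSiE-style multi-signal colocalization.
- Conditional analysis approximates joint estimation (SE kept marginal).
- IVW assumes post-clumping instrument independence; no correlated-
  instrument covariance weighting.
- No pleiotropy-robust MR estimators (Egger, weighted median) — out of the
  package's scope.
- No liftover, multi-allelic variants, or INDEL strand logic in
  harmonization.
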