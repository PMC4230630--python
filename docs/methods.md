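# Methods

`hapcc` implements the statistical pipeline of a candidate-gene
case–control association study: per-SNP genotype statistics, and
haplotype-frequency inference from unphased multilocus genotypes with
case–control haplotype tests.  Its reference application is the CDH1
(E-cadherin) gastric-cancer study design — five CDH1 polymorphisms
(promoter −160C→A/rs16260, intron 1 48+6T→C/rs3743674, exon 13
2076C→T/rs1801552, intron 12 1937−13T→C/rs2276330, exon 14
2253C→T/rs33964119) typed in 107 diffuse-type cases, 60 intestinal-type
cases and 134 controls — but every routine is generic over biallelic SNP
panels.

## Data model

Genotypes are stored as **unordered allele pairs** (`("C","A")` ≡
`("A","C")` after normalisation), not 0/1/2 dosages, so heterozygote
identity is explicit and label-swaps are mechanical.  Markers are nominal:
no strand flipping or complementing is ever attempted.  Missing-data
policy: single-locus routines drop samples missing at that one marker;
multi-locus (EM) routines drop samples missing at *any* analysis marker.
This is the simplest policy that keeps strata internally consistent, and
the reference study reports no missingness to emulate.

## Single-locus statistics

* **Allele frequency** — het/2 + hom-variant over typed samples
  (equivalently, variant chromosomes over total chromosomes).
* **Hardy–Weinberg** — a 1-df χ² goodness-of-fit against (p², 2pq, q²)
  at the sample allele frequency, and an exact test that enumerates every
  heterozygote count compatible with the observed allele counts
  (probabilities ∝ n!/(n_aa! n_ab! n_bb!)·2^n_ab) and sums configurations
  no more probable than the observed one.
* **Case–control association** — Pearson χ² on the 2×k genotype table
  with **no continuity correction** (this is what reproduces the reference
  study's printed statistics, e.g. 10.7858 for −160), k reduced by
  dropping categories empty in both groups; and the
  **Fisher–Freeman–Halton** exact test, which enumerates all 2×k tables
  with the observed margins via a column-by-column convolution over the
  first-row subtotal and sums multivariate-hypergeometric probabilities
  ≤ the observed one (ties resolved with a 1e-7 relative tolerance, since
  the probabilities are floating-point products).  Enumeration is bounded
  (default 2×10⁶ candidate tables) and refuses larger problems rather than
  silently approximating.
* **Odds ratios** — the default report is the **crude cross-product OR**
  with a Woolf log-normal 95% CI.  The reference study's text says its ORs
  were covariate-adjusted, but every printed OR equals the crude
  cross-product of its printed counts exactly (e.g. 44×84/(48×44) =
  1.750), so the crude OR is what the package reports by default;
  logistic-regression adjusted ORs (statsmodels, Newton/IRLS, Wald CIs)
  are a separate call.  A zero cell makes the OR undefined (reported as a
  dash, matching the study's tables) unless the Haldane–Anscombe +0.5
  correction is explicitly enabled.  Note the printed CI for the rare
  homozygote at −160 (1.467–14.565) is not Woolf-compatible (Woolf gives
  1.59–12.0); it was likely a regression Wald interval under an unstated
  coding, so only the heterozygote CI is checked against the published
  value, at 5% relative tolerance.
* **Group comparisons** — 2×2 Pearson χ²/Fisher exact and two-sample t
  tests (pooled or Welch), accepting `(mean, sd, n)` summaries because
  published tables rarely contain raw values.  Both t variants are offered
  because the study's printed age p-value (0.0001) matches neither
  exactly; neither is asserted against it.

## EM haplotype estimation

An individual heterozygous at k of the analysis loci is consistent with
2^(k−1) unordered haplotype pairs.  With diplotype pair (h₁,h₂) having
probability c·f(h₁)f(h₂) under random mating (c = 2 if h₁ ≠ h₂), the
observed-data likelihood is L(f) = Π_i Σ_pairs c·f(h₁)f(h₂), maximised by
EM: E-step — posterior pair weights ∝ c·f(h₁)f(h₂); M-step — f(h) =
expected count of h over 2N chromosomes.  Identical multilocus genotypes
are collapsed into patterns, so each iteration is a handful of
vectorised operations regardless of sample size.

Numerical choices:

* convergence when the log-likelihood increment drops below **1e-8**;
  iteration cap **10,000** (a small fraction of fits at n ≈ 100 need
  ~1,100 iterations — a spurious haplotype's frequency decays only
  geometrically — so a 1,000 cap would make them error spuriously);
* **10 restarts** by default: one initialisation at the product of
  observed allele frequencies, the rest Dirichlet(1) draws from a
  caller-supplied seed (a seed is required whenever restarts are
  stochastic; there is no hidden global RNG), best final likelihood wins;
* haplotypes with fitted frequency below **min_freq = 1e-4** are flagged
  rare but never dropped from output; the flag's only analytic role is
  df counting in the global test;
* the EM trajectory preserves per-marker allele frequencies at every
  iteration (each compatible pair carries exactly the individual's
  alleles), which is enforced as a test invariant at 1e-9;
* individuals heterozygous at more than 12 loci are rejected — the
  complete-data expansion is exponential and this package targets small
  candidate-gene panels, not chromosome-scale phasing.

## Haplotype association

* **Per-haplotype ORs** — OR(h) = (case f(h)/f(ref)) / (control
  f(h)/f(ref)) against a reference haplotype, default the most frequent
  pooled haplotype (the reference study's choice of reference varies
  inconsistently between its marker sets, so "auto" is the default and
  any haplotype can be forced).  CIs are Woolf intervals on expected
  counts f·2N; this **ignores phase uncertainty** in the EM frequencies
  and therefore understates interval width for ambiguous data — a
  documented limitation.  A haplotype whose expected count f·2N falls
  below 10⁻³ of a chromosome is treated as absent (undefined OR, like a
  true zero): EM frequencies can converge to arbitrarily small positive
  values, and a ratio against 10⁻⁸ of a chromosome is noise.
* **Global test** — the reference study never names the method behind its
  global haplotype p-values, and its raw joint genotypes were never
  deposited, so those p-values are not reproducible.  The package defines
  the global test as the EM likelihood-ratio statistic
  2(ℓ_case + ℓ_control − ℓ_pooled) from three EM fits, floored at 0, with
  df = H−1 where H counts haplotypes with pooled frequency above
  min_freq, referred to χ².  **Calibration caveat**: with rare haplotypes
  at study-scale samples (e.g. a 0.37% haplotype is ~1.8 expected copies
  in 482 chromosomes) the χ² reference is slightly anti-conservative —
  simulation at n = 107/134 under the control pool puts the empirical
  size near 0.06–0.07 at nominal 0.05.  The companion
  **permutation test** (case/control labels shuffled, statistic
  recomputed; the pooled fit is label-invariant and reused) is exact up
  to Monte-Carlo error and is the recommended p-value when rare
  haplotypes are present.
* **LD** — D, D′ and r² for the variant alleles of a marker pair, from a
  two-locus EM fit; monomorphic markers yield an undefined sentinel.

## Synthetic data

The generator draws two haplotypes i.i.d. per individual from a
group-specific pool (HWE random mating within group, by construction),
collapses to unphased genotypes, adds age ~ Normal truncated at 18 years
(the study population is adult; resampling, not clipping), sex ~
Bernoulli(male fraction), and optional independent per-call missingness.
All draws flow from one seeded generator in a fixed order, so datasets
are bit-reproducible.

`default_scenario()` encodes the reference study's conditions: group
sizes 107/60/134; the first three markers share the study's published
first-marker-set haplotype pools (case pool for diffuse cases; control
pool for controls *and* intestinal cases, for which no separate pool was
published — a deliberate null group); each printed percentage column is
renormalised to sum exactly to 1 (the control column prints to 100.02%).
The second published marker set's control column is internally
inconsistent (sums to ~115%; one entry is almost certainly a misprint),
which is why the first set anchors the generator; the second set's
printed frequencies are used only for normalisation-invariant ratio
arithmetic.  The two markers outside the haplotype set are simulated
independently at their published control variant-allele frequencies
(7/134 and 12/134) in all groups — no five-locus joint distribution was
ever published, so inter-set LD is *not* emulated.  Consequently, passing
tests demonstrate correct statistical machinery under HWE with known
three-locus haplotype structure; they say nothing about genotyping error,
population stratification, or LD between the simulated-independent
markers and the rest.

## Problem sizes used in checks

Parameter-recovery checks use n = 5,000 per group (recovery within 0.015
per haplotype frequency); margin checks n = 10,000 (3 binomial SEs);
null calibration of the global LRT uses 500 replicates at the study's
107/134; permutation-vs-asymptotic agreement uses n = 600 per group with
400 permutations.  These sizes make every Monte-Carlo tolerance an
explicit multiple of its binomial/normal standard error.

## Known limitations

* Haplotype-OR CIs ignore phase uncertainty (bootstrap is the remedy;
  the permutation test covers the global hypothesis).
* The asymptotic global LRT is mildly anti-conservative with rare
  haplotypes (see above).
* No Armitage trend test, no haplotype regression with covariates, no
  partition–ligation phasing for large panels, no population-structure
  or genotyping-error modelling.
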