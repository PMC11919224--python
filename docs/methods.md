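# Methods

## Score construction

The weighted polygenic risk score is `wPRS = Σ G_i · W_i` with `W_i =
ln(OR_i)` and `G_i` the risk-allele dosage in `[0, 2]`. Dosages are accepted
as reals because imputed data are fractional; the sum extends linearly.

Panel harmonization applies three rules in order, each with its own
provenance count: (1) a variant must be present in *both* genotyped datasets
being compared (matched by variant id); (2) strand-ambiguous SNPs — A/T and
C/G pairs, whose strand cannot be inferred from the alleles — are excluded;
(3) the remaining variants must be orientable against each dataset's
observed allele pair, directly, by allele swap, or by reverse-complement
strand flip (attempted only for non-ambiguous SNPs, where it is
unambiguous). Records with OR < 1 are re-oriented to the opposite allele
with OR → 1/OR, so all weights are non-negative; the complementary dosage
(2 − d) used for swapped variants makes the score invariant to this choice
up to the orientation itself. HLA classical alleles enter as biallelic
presence/absence pseudo-markers (token alleles, e.g. `P`/`A`) that take part
in intersection and orientation but skip nucleotide strand logic.

Missing genotypes propagate as NaN and are resolved only at scoring time:
the default `complete` policy sums over observed variants (reporting
`n_variants_used` so users can filter), and `mean-impute` substitutes the
Hardy-Weinberg expectation `2p_i` when allele frequencies are supplied. The
default was chosen as the least-assumption option; no-missingness inputs are
unaffected by the choice.

Group summaries use the arithmetic mean and the sample SD (n − 1
denominator), kept at full precision internally. The two-decimal rendering
helper re-quantizes through a short decimal representation with half-up
rounding, because binary floats store an exact decimal mean like 22.435 as
22.43499…, which plain rounding would display as 22.43 rather than the
conventional 22.44.

## Cohort statistics

Case-control location difference uses the Welch unequal-variance t-test
(Welch–Satterthwaite degrees of freedom). Discrimination uses the ROC curve
and AUC, which equals the Mann–Whitney U statistic scaled to [0, 1] with
ties counted one half. The AUC confidence interval is DeLong's closed-form
placement-variance interval by default — deterministic and standard for a
single in-sample AUC — with a seeded stratified bootstrap as an option.
P-values are stored at machine precision; the conventional `< 2.2e-16`
floor is applied only in human-readable rendering.

## Family-vs-population subsampling

Testing ~10 familial scores against thousands of population scores in one
Welch test is dominated by the population's tiny standard error, so the
population is subsampled: by default 100 independent draws of 500 scores
without replacement (within a draw), each Welch-tested against the full
familial vector, summarised by the p-value range and the per-draw direction
of the mean difference. Draws overlap across iterations; each iteration has
its own substream spawned from the master seed, so increasing the iteration
count extends rather than reshuffles earlier draws. Three contrasts are
configured: familial cases vs population cases, familial cases vs controls,
and unaffected relatives vs controls.

## Kinship and the mixed model

Kinship uses the classical recursion on an acyclic pedigree with unrelated
founders (`φ(i,i) = (1 + φ(f_i, m_i))/2`, `φ(i,j) = (φ(f_i,j) + φ(m_i,j))/2`
recursing on the deeper individual). Monozygotic twin groups are collapsed
onto one genetic representative before the recursion, which yields all the
right consequences at once: co-twins get `φ` equal to the self-kinship
(relationship 1 in `Φ2 = 2φ`), a co-twin is a genetic parent of the twin's
children, and children of two co-twins are genetic half-siblings. `Φ2` is
positive semidefinite for every valid pedigree (property-checked on random
pedigrees).

Scores are rank-transformed to normality before mixed-model contrasts using
the Blom offset — value at tie-averaged rank r among n maps to
`Φ⁻¹((r − 3/8)/(n + 1/4))` — the common default in genetics software; the
result is invariant to any monotone transform of the input, and fixed
effects on the transformed trait are in SD units.

The polygenic model `y = Xβ + g + e`, `cov(g) = σ²_g Φ2`, `cov(e) = σ²_e I`
is fitted by maximum likelihood. With `V = σ²(h²Φ2 + (1 − h²)I)`, the
eigendecomposition `Φ2 = U diag(d) U′` rotates the model into independent
coordinates with variances `σ²(h²d_k + 1 − h²)`; for each `h²` the GLS
estimate of β and the closed-form ML `σ²` give a profile likelihood that is
maximised over `h² ∈ [0, 1)` by a 26-point grid followed by bounded scalar
refinement (the grid includes 0, so the ML likelihood can never fall below
the OLS embedding). The boundary constraint `σ²_g ≥ 0` is enforced by the
parametrisation; no ½χ² mixture is applied to fixed-effect tests, since the
boundary affects the variance component, not β.

The group effect is tested two ways: a likelihood-ratio test against the
model without the group column (χ², 1 df; ML is used rather than REML
because fixed-effect LRTs require it) and a Wald t-test. Wald standard
errors use the degrees-of-freedom-adjusted residual variance `RSS_w/(n − p)`
with a t reference on `n − p` df — a small-sample correction chosen so that
with `Φ2 = I` the Wald test reproduces the ordinary least-squares t-test
exactly; the reported `σ²_g`/`σ²_e` point estimates remain ML. Population
cohort members enter contrasts as an unrelated identity block. When both
groups are unrelated the two variance components are not separately
identified (the profile is flat in `h²`), but β, its tests and the total
variance are unaffected.

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure the analysis assumes, with defaults
chosen as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_variants` / `n_hla` | 167 / 26 | panel size after intersection and ambiguity exclusion in the motivating MS analysis |
| `large_effect_or` / freq | 2.9 / 0.15 | HLA-DRB1\*15:01-like major allele, European-scale frequency |
| `or_range` | (1.05, 1.6) | scale of non-HLA common-variant effects (the largest excluded OR in the motivating analysis was 1.589) |
| `freq_range` | (0.1, 0.9) | common variants only |
| `disease_prevalence` | 0.05 | scaled-up prevalence (see below) |
| `liability_h2_polygenic` | 0.18 | calibrated so case-control AUC ≈ 0.75 (below) |
| `n_cases` / `n_controls` | 500 / 900 | cohort scaled to the ~0.57 case:control ratio of the motivating cohort |
| `min_affected_per_family` | 3 | multicase ascertainment criterion |

Disease follows a liability-threshold model: liability = genetic score +
independent Gaussian environment, with the environmental variance set so the
score explains `liability_h2_polygenic` of liability variance, and affection
when liability exceeds the normal-approximation threshold at 1 − prevalence.
MS's true population prevalence (~0.1%) would make rejection sampling of
families with ≥ 3 affected members astronomically slow and is not itself the
quantity under study; a prevalence of 0.05 preserves the liability-threshold
geometry (threshold selection, familial correlation of liability) while
keeping case and family ascertainment tractable. The polygenic share 0.18
was then set from the liability-theory prediction of the case-control score
separation — `E[s|case] − E[s|control] ≈ h²·i` with selection intensity
`i = φ(z)/K` — to put the AUC at ≈ 0.75, and verified by simulation
(observed 0.746–0.768 across seeds). Consequently passing tests show the
*procedures* behave correctly under a correctly-specified liability model;
they say nothing about LD structure, rare or family-private variants, shared
family environment, or gene-environment interaction, none of which are
simulated. In particular, the real HLA region's strong LD is deliberately
ignored (variants are in linkage equilibrium).

Families are generated by gene dropping on a three-generation template (two
founders, 5–7 offspring, a married-in spouse with children, an MZ pair with
probability 1/3): founders draw haplotypes from population frequencies, each
child receives one allele per parent uniformly at random per variant, and MZ
co-twins copy genotypes exactly but draw independent environments.
Multicase families are ascertained by rejection sampling (simple and exact,
rather than importance weighting); the attempt count is reported as the
empirical ascertainment rate.

## Problem sizes used in tests and the acceptance script

The test suite checks the procedures at the sizes the analyses use: the
kinship oracle runs 10⁶ gene drops per pedigree on five random pedigrees;
type-I error uses 1,000 null replicates (binomial 95% band around 5%) and
power 200 replicates at the study's 9–10 vs 500 group sizes; heritability
recovery uses 200 replicates of 50 six-sib sibships (n = 300, true h² =
0.6); and the qualitative familial-enrichment pattern is checked over ten
full pipeline runs. The acceptance script runs one full default study plus
the heritability recovery at the same sizes.

## Known limitations

- The mixed model is univariate with additive polygenic and residual
  components only: no dominance, household/shared-environment, or X-linked
  components.
- The LRT for the group effect relies on the χ²₁ asymptotics of ML; with
  very small groups the Wald t-test (also reported) is the safer reference.
- Harmonization matches variants by id; positional fallback is limited to
  what the caller supplies as ids (e.g. `chrom:pos` keys).
- The published familial analysis used restricted cohort data; its exact
  p-values are not recomputable here. The bundled fixture reproduces the
  published per-family score table exactly, and the simulator reproduces the
  qualitative pattern of the familial comparisons; one published cell (the
  affected SD of the two-member family 3) computes to 0.156 from the
  published individual scores but was printed as 0.15, and is therefore
  checked unrounded.
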