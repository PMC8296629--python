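# Methods

## The augmented-design model

The screen assumes an additive block structure: an observation of entry *i*
in block *j* is `y_ij = μ + g_i + β_j + ε_ij`. Repeated checks (controls)
present in every block identify the block effects. With `c` checks and `b`
blocks, the block correction factor is

    R_j = (B_j − M) / c,

where `B_j` sums the check values in block *j* and `M` sums the checks'
across-block means. For a complete check layout this equals the
least-squares estimate of `β_j` under the sum-to-zero convention (block mean
of checks minus their grand mean), which is what the equivalence tests
assert. Adjusted values are `y − R_j`: subtracting the estimated block
deviation centres blocks, so within-block differences are untouched and the
mean of a check's adjusted values across blocks equals its grand mean
exactly. When a check is replicated *within* a block, its within-block mean
enters `B_j`, so unequal check replication does not distort the block sums.

The error variance of an adjusted-entry-vs-check-mean difference is
estimated from the checks alone: `CME` is the residual mean square of the
b × c two-way (block + check, no interaction) layout of within-block check
means, computed in closed form from the balanced decomposition (an
independent linear-model fit serves as the test oracle). The variance of a
difference and the resulting threshold are

    S²_vc = CME (b+1)(c+1) / (b c),     MSD = t · √S²_vc.

A tested entry is called *higher* (*lower*) than a check when its adjusted
value exceeds (falls below) the check's mean of adjusted values by more than
the MSD, with strict inequality at the boundary.

Two deliberately exposed choices:

* **Degrees of freedom.** The residual df of the check layout is
  `(b−1)(c−1)` and is the default for the t quantile. Some published
  descriptions of this threshold print the ratio `(b−1)/(c−1)` instead,
  which is non-integral in general; `df_mode="paper-literal"` reproduces
  that literal reading for comparability. The product form is the
  statistically defensible default.
* **Sidedness.** The default t quantile is two-sided at α = 0.05
  (t at 0.975). Screens that only ever ask the directional "significantly
  higher" question can switch to one-sided.

FRS adjustment operates on replicate-level FRS values directly; it is not
recomputed from separately adjusted FLN and FRN (a ratio of adjusted counts
would not be a linear adjustment). Genotype-level FRS defaults to the mean
of replicate-level percentages; the ratio-of-means form
`100·mean(FRN)/mean(FLN)` is available for data published only as trait
means. A replicate with flowers but no fruit has FRS 0; a replicate with no
flowers has undefined FRS and is excluded from means rather than coerced to
zero.

## Selection and trajectory classification

A genotype is a tolerance candidate iff it is called higher than the
designated sensitive control at T2 or at T3; T1 never enters the rule.
Candidates are classified into a total, mutually exclusive pattern set:
higher at T2 only; higher at both T2 and T3, split by the FRS trajectory
into monotone decline (`FRS(T3) ≤ FRS(T2)`; a tie is treated as no evidence
of recovery) and recovery (`FRS(T3) > FRS(T2)`); higher at T3 only; or not
tolerant. For evaluation against simulated truth the patterns map onto the
three response archetypes: T2-only and both-regime-monotone → tolerant,
T3-only and both-regime-recovery → adaptive, not tolerant → sensitive.
Group summary percentages round half away from zero to the integer, with the
exact value reported alongside.

## Confirmation statistics

* **Dunnett's test** compares every genotype mean with a control under a
  pooled one-way error. The single-step adjusted p-value
  `P(max_i |T_i| ≥ t_obs)` is evaluated by deterministic quadrature of the
  classical one-factorization: conditional on the control's standardized
  mean `z₀` and the pooled scale `u = S/σ`, the comparisons are independent,
  so the joint probability is a product of normal-CDF differences integrated
  over `z₀` (80-node Gauss–Hermite) and `u` (128-node Gauss–Legendre over
  the effective support of the chi density). This reproduces R's
  `multcomp::glht` single-step p-values to ~1e-10 and, unlike randomized-QMC
  evaluations of the multivariate t integral, is exactly reproducible and
  accurate well below 1e-6 — the reason the p-value is computed in-package
  while scipy's implementation serves as an independent cross-check in the
  tests. Two-sided by default with the direction reported; a one-sided
  alternative is exposed. Genotypes with fewer than two replicates are
  excluded and reported, never silently dropped.
* **Tukey HSD ranking** uses the standard studentized-range pairwise test;
  the compact letter display is built by the insert-and-absorb algorithm
  (start from one column holding all genotypes; each significant pair splits
  the columns containing both; subset columns are absorbed), with letters
  assigned in descending mean order so 'a' marks the best group. Two
  genotypes share a letter iff their pairwise comparison is non-significant.
* **Genotype × environment ANOVA** fits `Y_ijk = μ + G_i + E_j + GxE_ij +
  e_ijk` on balanced tables only; unbalanced input is rejected with guidance
  rather than silently choosing among sum-of-squares types. Empty cells are
  reported by name.
* **Cross-trial correlations** are Pearson correlations of genotype means
  over the genotypes common to two trials (≥ 3 required), flagged at the
  0.05 and 0.01 levels.

## DEG filtering

A gene is *expressed* when RPKM > 0 in at least one sample. The DEG rule
keeps a gene when `|LFC| ≥ 2` (boundary inclusive) and `p < 0.01` (boundary
strict); both thresholds are parameters. The p-value used is the unadjusted
one by default — matching the stated rule of the workflows this module
post-processes — with an opt-in switch to an adjusted-p column. Positive LFC
means higher expression in the first-named genotype of the contrast id.
Contrast intersection reports, per gene, presence and overexpressing side in
each contrast, plus common-to-all and unique-to-one flags. Upstream read
alignment, counting and the differential test itself are out of scope; the
module consumes their tabular output.

## The synthetic-data generator

The generator emulates the augmented greenhouse screen: `b = 6` blocks,
five checks present in every block (three sensitive — one designated for
tolerance calls — one tolerant, one adaptive), each tested entry in a single
block, all genotypes observed at T1/T2/T3. Archetype FRS curves are
sensitive 90/40/10, tolerant 90/75/50 and adaptive 90/25/55 percent at
T1/T2/T3 — the three canonical response shapes with the adaptive recovery
`FRS(T3) > FRS(T2)` built in.

Counts are generated hierarchically. FLN is gamma-Poisson (negative
binomial) around the archetype's regime mean plus a normal block effect
(SD 5 flowers) with dispersion `d = 0.05` (variance `m + d·m²`); FRN is
binomial given FLN with success probability drawn from a beta distribution
centred on the archetype curve with concentration κ = 150. FRN ≤ FLN
therefore holds by construction and generated tables always validate. Block
effects act on the FLN latent mean only — fruit set is conditionally
independent of block given FLN — a simplification that makes the FRS block
factors small and is stated here deliberately.

Default FLN means (80/70/45-ish per regime, varying slightly by archetype)
are per-replicate flower totals: a replicate is a bag of about three plants
producing a few trusses over a multi-week regime, so its total flower count
is an order of magnitude above single-truss counts. The defaults were fixed
a priori by a power argument: with per-observation FRS noise
SD ≈ √(p(1−p)/n_fln + p(1−p)/κ)·100 ≈ 7 points at T2, the check residual
gives CME ≈ 50–80, hence MSD ≈ 2.1·√(1.4·CME) ≈ 17–20 points — comfortably
below the 35-point tolerant-vs-sensitive gap at T2 and the 40+-point gaps at
T3, putting per-entry detection power near 99% while the two-sided MSD call
holds the false-positive rate of sensitive entries near 5%. That is what
makes ≥ 90% archetype recovery on 200 simulated genotypes an expected
property rather than a tuned one.

The noise-free limit (dispersion 0, block SD 0, κ = None) is fully
deterministic with rounded counts, so realised FRS equals the archetype
curve exactly whenever `FLN × FRS/100` is integral — the regression tests
use flat FLN = 80, for which all default curve values are integral.

The DEG generator draws null genes with `LFC ~ N(0, 0.5)` and
`p ~ U(0, 1)`, spiked genes with `|LFC| ≥ spike_lfc` (default 3, random
sign) and `p ~ U(0, 1e-4)`, and per-sample log-normal RPKM with a
configurable silent fraction (default 10%) set to zero in every sample.
Under the defaults a null gene passes the 2/0.01 filter with probability
`2Φ(−4)·0.01 ≈ 6.3e-7`, so the expected kept count on 10,000 nulls + 100
spikes is 100.006 with a binomial SD of 0.08 — the calibration the
acceptance checks assert.

## What the simulations do and do not show

Passing the recovery tests shows the estimator chain (block factors, CME,
MSD, calls, patterns) is correct and well-powered under additive block
effects, beta-binomial fruit set and overdispersed flower counts. Real
screens add features the generator omits: spatial trends within blocks,
genotype-specific flowering phenology, regime carry-over on the same plants,
non-additive block × genotype interaction, and measurement or recording
error. Results on real data therefore depend on those assumptions
approximately holding; the augmented design itself offers no internal
replication to test them for tested entries.

## Numerical notes and problem sizes

* Closed-form balanced decompositions are used for `R_j` and CME; both are
  tested against linear-model fits at 1e-9.
* The Dunnett quadrature's node counts (80 Hermite × 128 Legendre, chi
  support truncated at 1e-14 tail mass) give ~1e-12 absolute accuracy for
  the group counts used in practice; each p-value costs ~20 ms.
* Default test problem sizes — 200-genotype screens, 400-replication type-I
  calibration of the ANOVA F test, 10,100-gene DEG tables — keep the full
  suite runnable on a laptop in a few minutes while leaving the asserted
  margins (≥ 90% recovery observed at ~97%, 3-SD calibration bands) wide.
* Degenerate inputs fail loudly: blocks without checks, checks absent from a
  block, unbalanced ANOVA tables, genotypes with < 2 replicates in
  replicated analyses, FLN = 0 replicates (undefined FRS, excluded from
  means), empty RPKM maps.

## Known limitations

* No mixed-model (REML) alternative to the classical augmented adjustment;
  no spatial row/column models.
* Balanced-only ANOVA; users with unbalanced confirmations must average or
  subsample to replicate level first.
* The MSD call treats the check mean as the reference without propagating
  its own sampling error beyond what `S²_vc` encodes; that is inherent to
  the published threshold form.
* The DEG stage filters existing per-contrast statistics; it performs no
  normalisation or shrinkage of its own.
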