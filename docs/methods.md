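# Methods

## The screen

The screen asks, per cancer type, which genes' expression tracks somatic
mutation burden. Its underlying model is deliberately minimal: mutation load
is treated as an ordinal proxy for accumulated DNA damage, expression
z-scores as an ordinal proxy for pathway activity, and the association is
measured by Spearman's rank correlation — no linearity, normality or
homoscedasticity is assumed, only monotonicity. Everything downstream
(top-K lists, recurrence, tripartition, complex chi-square) is set algebra
and contingency-table testing on the ranked output.

### Mutation loads

A sample's load is its count of somatic mutation *events*: two hits in one
gene count twice. Three classes are tallied — all events, missense
substitutions, and sense (synonymous) substitutions. "Sense" is interpreted
as synonymous/silent: the missense-vs-sense contrast is the standard
nonsynonymous/synonymous dichotomy used to separate selection-driven from
mutational-pressure signal. Unknown variant-class strings are mapped to
`other` with a warning rather than aborting multi-thousand-row ingests; they
count toward the all-events load only. Samples present in the expression
matrix but absent from the mutation table receive load 0 when a roster is
supplied (the pipeline rosters every expression sample), since an absent
sample in a MAF extract usually means "no calls", not "not assayed".

### Expression z-scores

z = (x − μ_ref)/σ_ref per gene, reference population defaulting to all
cohort samples, sd with ddof = 1. The reference is configurable because
public z-score matrices differ in their reference convention (all samples
vs diploid-only); the transform is idempotent when reference = all, and
location-scale invariant, both property-tested. Zero-variance genes have no
defined z-score and are dropped with an enumerated log line.

### Spearman correlation and p-values

ρ is the Pearson correlation of average-ranked data (ties get average
ranks); the screen path vectorizes this as one matrix product per cohort and
is tested to 1e-12 against the scalar implementation and a brute-force
oracle. Two-sided p-values: for n > 10 the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df; for n ≤ 10 exact enumeration of all n!
permutations of the rank vector (ties handled by enumerating with
multiplicity); a perfectly monotone pair returns the closed-form exact
probability 2/n!. The crossover at n = 10 keeps enumeration below ~4M
permutations; `min_samples` defaults to 20, so screens normally use the
t path, whose type-I error at 0.05 is calibrated within ±0.01 on a
20,000-gene null cohort in the acceptance suite.

### Ranking and tie-breaks

Genes are ranked by ρ, not p: within one cancer type n is constant, so the
orderings coincide except under ties, and rank thresholds transfer between
cohorts of different size where ρ thresholds do not. Boundary ties at the
top-K cut break by smaller p, then lexicographic gene symbol — an arbitrary
but deterministic rule, audited under input permutation. No multiple-testing
correction is applied inside the screen (thresholding is by rank); a BH
column is emitted for information.

### Cross-cancer aggregation

"Showing positive correlation in a cancer type" means membership in that
type's top-K positive list, not merely ρ > 0. Recurrence counts per gene and
direction feed (i) recurrent-gene lists at a `min_cancers` threshold and
(ii) the tripartition positive-only / negative-only / positive-negative /
unclassified, which provably partitions the input gene set.

### Complex chi-square

A complex (m genes, a in category) is compared against its **full parent
pathway** (M genes, A in category) — the complex is not removed from row 2 —
with the Pearson chi-square without continuity correction,
χ² = N(ad−bc)²/(r₁r₂c₁c₂), N = m + M, df = 1. This convention is fixed by a
reconciliation requirement: with a 124-gene pathway split 73/19/16/16, it
simultaneously yields p = 0.0439 for a 6/6 positive-only complex vs 73/124,
p = 0.0099 for 11/19 vs 35/124, and p = 0.0356 for 6/19 vs 16/124 — the
worked examples frozen in the test suite (to printed 4-decimal precision;
0.0438 in some reports is the truncated form of 0.043890). The "negative"
category pools negative_only with positive_negative — genes negative in at
least one cancer type — which is what makes the 11/19 vs 35 = 19 + 16 table
consistent. Degenerate tables (a category empty, or exhaustive, across both
rows) return χ² = 0, p = 1 with a flag instead of dividing by zero. The
implementation is verified to 1e-10 against an independent Σ(O−E)²/E oracle
and `scipy.stats.chi2_contingency` on 1,000 random valid tables.

### Hypergeometric over-representation

Pathway enrichment of the recurrent gene lists uses the standard upper-tail
hypergeometric P(X ≥ k) on an explicit background (the screened gene
universe), BH-adjusted across sets. This is a generic over-representation
statistic on user-supplied GMT collections; it makes no attempt to replicate
any specific annotation service's database or modified scores.

## Combination index

Effects are fraction-affected, E = 1 − survival (the natural reading of an
MTT viability readout; an inhibition-normalized variant would be a
preprocessing step on the survival column). CI = (E_A + E_B)/E_AB with
verdict synergistic/antagonistic below/above 1 (tolerance 1e-9 for
"similar"); E_AB = 0 gives an explicit NA row. Replicates are averaged
before CI; per-replicate CIs are emitted alongside for dispersion. Two
properties of this formula worth knowing:

* it is **effect-additive, not independence-based**: an exact
  Bliss-independent surface gives CI = (E_A+E_B)/(E_A+E_B−E_A·E_B) ≥ 1
  always, so CI < 1 certifies super-Bliss interaction;
* even under genuine super-Bliss interaction CI rises above 1 once
  single-agent effects are large (as E_A, E_B → 1, CI → 2). With the
  α = 2 synergy transform, CI < 1 holds while single-agent effects stay
  below ≈ 0.45 each. Synergy surfaces for testing are therefore sampled in
  the sub-EC50 window a short-term cytotoxicity assay actually covers
  (single-agent effects ≲ 0.35 at the top dose), where the all-rows CI < 1
  property is robust.

Tumor volume: 0.52·L·W² from caliper length/width; L < W is auto-swapped
with a warning since caliper axes are easily transposed at the bench.

## Synthetic cohorts

The generator emulates exactly the features the screen consumes:

* **Loads** ~ negative binomial with mean 210 events/sample (a pan-cancer
  exome-scale average, ~1.5M events over ~7k samples) and shape k = 0.7
  (variance μ + μ²/k), spreading per-sample loads over orders of magnitude
  as real cohorts show. Poisson would understate this overdispersion
  grossly. Both parameters are per-cancer overridable.
* **Variant classes** multinomial with default mix
  (missense .58, silent .25, nonsense .07, insertion .04, deletion .06) —
  substitution-dominated, missense:silent ≈ 2.3:1, a thin indel tail.
* **Background expression** i.i.d. N(0,1) per gene and sample: already a
  z-score under the internal reference, with no gene-gene covariance.
* **Planted genes** via a Gaussian copula on load ranks: with
  z_load = Φ⁻¹((rank − ½)/n) and expression = r·z_load + √(1−r²)·ε,
  choosing r = 2 sin(πρ_s/6) (the bivariate-normal Spearman↔Pearson
  relation) makes the realized Spearman correlation converge to the target
  ρ_s; targets ±1 short-circuit to an exactly monotone map. This closed form
  was chosen over numerically solving a rank-blend weight: same guarantee,
  no solver. Load ties (average ranks) attenuate the realized ρ slightly;
  at the default load distribution the bias is well inside the ±0.05 band
  verified at n = 2000.
* **Dose-response** Hill curves E(d) = d^h/(d^h + EC50^h) per agent;
  combination E_AB = 1 − (1 − E_bliss)^α with E_bliss = E_A + E_B − E_A·E_B.
  α = 1 is exact Bliss; the transform is monotone in α and keeps effects in
  [0,1]. Gaussian noise is added to survivals then clipped.

All randomness flows from one seed through `numpy` SeedSequence spawning;
same spec ⇒ byte-identical output files.

**What passing tests do and do not show.** The generator has no mutational
signatures, copy-number structure, expression covariance, or
confounding between load and unrelated expression programs. Recovery and
calibration results therefore demonstrate correctness of the statistical
machinery under the stated sampling model, not robustness of the screen to
the correlated noise of real tumor cohorts. Results that depend on a real
cohort (specific recurrent-gene counts, per-gene ρ values, database-backed
pathway p-values, CI ranges of particular cell lines) are out of scope by
construction and are nowhere reproduced or hard-coded.

## Problem sizes and numerical choices

Calibration and recovery checks use 200-sample × 20,000-gene cohorts
(a realistic single-cohort scale at which the vectorized screen runs in
seconds); the end-to-end complex-recovery scenario uses 3 cancers × 120
samples × 3,012 genes with K = 400, sized so a top-400 cut covers ~13% of
the universe per direction per cancer — K must be small relative to the
gene universe for list membership to be informative, as it is in a
~20k-gene transcriptome. Planted recovery uses ρ = ±0.5, comfortably above
the null ordering noise (sd ≈ 1/√(n−1) ≈ 0.07 at n = 200) but far from
deterministic rank 1, so the ≥90% top-400 recovery criterion is a real test
of the ranking path. Ties broken as described; ρ clipped to [−1,1] against
rounding; p capped at 1.

## Known limitations

* Exact Spearman p is factorial-time and hard-capped at n ≤ 10.
* The hypergeometric stage is a generic ORA; it will not reproduce
  database-specific enrichment p-values.
* `recurrent_genes` treats direction lists independently; a gene can be
  recurrent in both directions.
* The CI formula's verdict is per dose pair; no median-effect (Chou–Talalay)
  linearization, Loewe isobolograms or response-surface fitting.
* The pipeline assumes per-cancer inputs fit in memory as dense matrices.
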