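# Methods

## Instrument coding and scoring

A questionnaire instrument is a versioned JSON catalogue of items, each
declaring its domain (`food_consumption`, `dietary_habits`, `lifestyle`),
coding category, admissible answer levels and adherence rule. Four coding
categories cover the usual dichotomization patterns of Mediterranean-diet
indices: *moderate* (1 = intake within the moderate range, 0 = abuse),
*recommended* (1 = adequate intake, 0 = under-consumption), *limit*
(1 = active restraint, 0 = unrestricted) and *simple* presence/absence.
*Tripartite* items have three ordered consumption levels and expand to
three mutually exclusive one-hot indicators (`item.low`, `item.moderate`,
`item.high`), of which the moderate level carries the item's adherence
point — intermediate consumption is the adherent behaviour for foods such
as dairy and wine.

The bundled default instrument has 28 items split 15/7/6 across the three
domains with two tripartite items (dairy, wine), so it emits 32 indicators,
28 of which contribute to the score. The published index does not reproduce
its full item wording or per-item thresholds, so the default file uses
simplified ordinal answer levels (`below/recommended`,
`none/moderate/excess`, `unrestricted/limits`, `no/yes`,
`low/moderate/high`) that preserve the coding semantics; every analysis is
instrument-agnostic, and users studying a concrete questionnaire should
supply their own instrument JSON with the real levels and thresholds.

The adherence score is the integer sum of the 28 score-carrying indicators.
Quartile stratification uses linear interpolation between order statistics
(the rank `p·(n−1)` convention, numpy's default) and strict inequalities:
low means score < Q1, high means score > Q3, scores exactly on a quartile
are intermediate. With heavily tied integer scores the three groups are
therefore deliberately unbalanced — strictness is part of the definition,
not an artefact. Group shares are reported with largest-remainder rounding
so the printed percentages sum to exactly 100; with counts 84/104/325 of
513 this yields 16.4% / 20.3% / 63.3%, whereas naive per-entry rounding
would print 63.4% for the third share and a total of 100.1.

## Statistically validated network

All unordered pairs of non-degenerate indicator columns are tested with the
two-sided Fisher exact test: the p-value is the total hypergeometric
probability, at the observed margins, of tables no more likely than the
observed one (ties in probability are resolved with a relative tolerance of
1e−7 to absorb floating-point noise between mathematically tied terms; the
test suite checks agreement with exact rational enumeration to 1e−12). The
implementation enumerates the hypergeometric support with log-factorials
(`scipy.special.gammaln`), which makes an all-pairs scan over hundreds of
cohorts cheap; all pairwise co-occurrence counts come from a single
matrix product.

Constant columns carry no 2×2 information and are excluded from testing
(reported as `excluded_nodes`); `m` counts the pairs actually tested and the
Bonferroni rule retains edges with `min(1, m·p) < α` (default α = 0.05).
Edge sign comes from the sample odds ratio `ad/bc` relative to 1; a single
zero cell gives a legitimately infinite log OR, flagged as ±inf rather than
coerced. Pairs of structurally exclusive indicators — the one-hot triple of
a tripartite item — are tested like any other pair, because dissociation
edges are informative output, but they are annotated
(`structural_exclusive`) so consumers can filter their guaranteed negative
association.

## Map-equation communities

Community detection runs on the positive-edge subgraph only: negative edges
encode dissociation and have no meaning for a co-occurrence random walk.
Edges are unweighted — the validation step retains links but assigns them
no strength. The two-level map equation for an undirected, unweighted graph
uses degree-proportional stationary probabilities `p_α = k_α / 2E` and

    L(M) = plogp(q) − 2·Σ_i plogp(q_i) − Σ_α plogp(p_α)
           + Σ_i plogp(q_i + Σ_{α∈i} p_α),      plogp(x) = x·log2(x),

with `q_i` the probability of exiting module i (cut edges over 2E). With a
single module the index codebook vanishes and L equals the entropy of the
stationary distribution — a property the tests verify directly.

The optimizer is a seeded multi-restart greedy search: single-node moves to
neighbouring modules followed by merges of adjacent modules, iterated to a
fixed point, best of 10 restarts, and never worse than the one-module
partition by construction. On a 200-graph random battery of graphs with at
most 8 nodes it attains the exhaustive-search optimum over all set
partitions; networks of 32 indicators are far below the scale where a
Louvain-style aggregation hierarchy would matter. Isolated nodes become
singleton modules with zero flow and zero codelength contribution. Module
labels are contiguous from 1 in node order.

## Enrichment

A group contrast builds one 2×2 table per indicator (group membership ×
indicator value), takes the Fisher exact p, and Bonferroni-corrects over
the indicators tested (or a caller-supplied wider family: cluster profiling
corrects over communities × indicators). The default contrast for the
adherence analysis is the opposite extreme (low vs high); cluster profiling
contrasts each community against the rest of the cohort.

The point estimate is the unconditional sample log OR — the quantity forest
plots display — while the p-value remains the conditional exact test. The
95% interval is the Woolf logit interval `logOR ± z·√(1/a+1/b+1/c+1/d)`,
computed on the Haldane–Anscombe corrected table (0.5 added to every cell)
whenever any cell is zero. When the uncorrected OR itself is 0 or ∞ the
unbounded side is omitted: a group with zero events reports only the upper
confidence bound. Coverage of the interval is checked by simulation
(2000 tables, n = 200 per arm, true log OR = 1): empirically 93–97%.

## Respondent clustering

Respondents are compared with the Jaccard distance over all emitted
indicators (tripartite levels included); two all-zero profiles have
distance 0 by convention, with a warning. Linkage is UPGMA (average), the
common choice for binary Jaccard profiles, with scipy's deterministic
lowest-index tie-break. k is user-set, or chosen by maximal mean silhouette
over k = 2..12. On gradient-structured data (a continuous latent trait
rather than discrete mixture components) Jaccard/UPGMA characteristically
produces one dominant cluster plus small outlier communities; tests of
score-vs-trait ordering therefore weight clusters by membership instead of
treating a 2-member outlier's mean as one rank observation. Singleton
communities are skipped in profiling, with a warning.

## Covariate models

The score is regressed on age, sex (0 = female, 1 = male), BMI and smoking
(0/1) by OLS with classical standard errors; rank-deficient designs are
rejected with the offending columns named. The smoker vs non-smoker
comparison defaults to Welch's t-test, with a Mann–Whitney option for
skewed score distributions. Under a null simulation the age term's type-I
error at α = 0.05 is verified to lie in [0.03, 0.07] over 2000 replicates.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the scale of a ~500-respondent questionnaire study:

- **Size and marginals.** Default n = 513. Per-item baseline adherence
  probabilities are a fixed spread from 0.30 to 0.82 (mean ≈ 0.56), giving
  a mean score near 15.5.
- **Latent trait.** Each respondent's trait is standard normal, shifted by
  +1 for the older age component and by −0.5 for smokers; every score
  indicator's logit gains `trait_effect × trait` (default 0.35). With these
  defaults the simulated score sd is ≈ 3.4 and smokers average about one
  point lower — the scale a real cohort of this kind shows.
- **Covariates.** Age is a two-component mixture: young N(22, 3²) with
  weight 0.94 and older N(60, 8²) with weight 0.06 (mixture mean ≈ 24.5,
  sd ≈ 10), smoking prevalence 0.34, female share 0.67, BMI N(22.9, 3.7²).
- **Planted modules.** Disjoint indicator sets share a per-respondent
  standard-normal factor entering each member's logit with a loading
  calibrated by Gauss–Hermite quadrature so that the model-implied pairwise
  log OR equals the configured strength — no copula machinery needed, and
  the calibration is verified against Monte-Carlo simulation in the tests.
- **Raw answers.** Indicator draws are inverted through the instrument's
  coding rule back to admissible raw answers (the non-adherent mass of a
  tripartite item splits evenly between its low and high levels), so the
  whole pipeline can run from a raw cohort CSV.
- **Null generator.** Independent Bernoulli columns with user marginals,
  for family-wise error calibration; degenerate marginals (0 or 1) are
  rejected.

What the generator does **not** emulate: real food-frequency semantics,
energy intake, item-specific non-response styles, or covariate-indicator
effects beyond the single latent trait. Passing tests therefore demonstrate
that the pipeline recovers the structure it targets when that structure is
present and stays quiet when it is absent — not that any particular real
cohort has such structure.

## Validation experiment sizes and choices

- Family-wise error: 500 null cohorts (n = 513, 32 indicators, marginals
  uniform in [0.2, 0.8]); the fraction with ≥ 1 retained edge stays below
  0.05 — comfortably so, since exact-test discreteness makes Bonferroni
  conservative.
- Module recovery: 50 cohorts with two planted 6-indicator modules
  (log OR = 2) and the trait switched off, isolating the co-occurrence
  signal; adjusted Rand index between planted and detected labels over the
  module members is ≥ 0.9 in at least 45/50 runs.
- Enrichment sensitivity: 50 cohorts with a strong planted trait
  (`trait_effect = 0.8`, a clearly detectable planted effect rather than
  the descriptive default 0.35); mean share of score indicators flagged as
  over-represented in the high-adherence group ≥ 0.9. The two recovery
  experiments are configured separately because a strong global trait
  connects all indicators and would blur planted module boundaries, while a
  zero trait gives the extremes contrast nothing to detect.
- The 2000-replicate OLS null uses n = 200 per replicate; sizes throughout
  were chosen to make the full suite a few minutes of one-CPU compute.

## Known limitations

- Bonferroni (chosen for the family-wise guarantee the validated-network
  construction is named for) is conservative for 496 discrete exact tests;
  a false-discovery-rate screen would retain more edges at the cost of the
  FWER interpretation.
- The Woolf interval is asymptotic; exact conditional-MLE intervals are out
  of scope.
- The map-equation optimizer is exact-by-test only up to the scales probed;
  for networks orders of magnitude larger an aggregation phase (or an
  external Infomap binary) would be the right tool.
- Quartile strata on heavily tied integer scores can be strongly
  unbalanced; this follows from the strict-inequality definition.
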