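# Methods

## Scope and data model

The package analyzes collections of patient medication reviews: free-text
comments plus per-review metadata (drug label, age in years, gender,
time-on-medication category, a 1–5 overall-satisfaction rating, source
site, post date). Age is stratified as 19–44 / 45–64 / ≥65 and time on
medication as <1 month / 1 month–<1 year / ≥1 year, the categories used
throughout the stratified tables. One topic model is fitted per drug
label, never pooled, so cohort-size imbalance between drugs cannot leak
across models.

## Eligibility filtering

Three exclusion rules are applied in a fixed order, each record logged
under the first rule it matches:

1. **empty comment** — comment missing or whitespace-only. A separate
   side-effects field does not rescue an empty main comment by default
   (a side-effects-only post has no narrative to mine); the
   `side_effect_rescues` switch inverts this.
2. **spam** — comment contains `http`, `.com` or `www.`
   (case-insensitive substring match on the main comment only).
3. **age** — age missing or under 19; age exactly 19 is eligible.

Female-authored reviews are retained: they may be caregivers or partners
reporting the patient's experience. The precedence only affects log
attribution, never the surviving set, and the filter log reconciles
exactly (input = output + Σ removed). Filtering is idempotent and
order-preserving.

## Preprocessing

Comments pass through: case-folding → deletion of punctuation and digit
characters → whitespace tokenization → removal of tokens shorter than 2
characters → a whole-token typo-correction map → left-to-right merging of
listed bigrams into `a_b` unigrams (default inventory:
"erectile dysfunction", "side effect"; merged tokens are never
re-merged) → stopword removal (whole-token match against a standard
English list, configurable) → Porter stemming with **stem completion**:
every stem is replaced by the surface form with the highest corpus
frequency among forms sharing that stem, ties to the lexicographically
smallest form. Bigram tokens are stemmed component-wise.

The Porter stemmer is implemented in-package from the classic algorithm
description and unit-tested against known input/output pairs.

The document-term matrix orders the vocabulary by descending corpus
frequency, ties lexicographic, so serialized matrices are
bit-reproducible. Documents emptied by preprocessing are dropped and
reported; they later carry a missing primary topic. An all-empty corpus
is a hard error. The whole chain is a pure function of (texts, config).

## LDA by collapsed Gibbs sampling

Standard collapsed Gibbs for LDA: token topic resampled from
(n_dk−· + α)(n_kv−· + β)/(n_k−· + Vβ), with z initialized uniformly at
random from the seed. Defaults: α = 50/K, β = 0.1, 2000 sweeps, 500
burn-in, thinning lag 10. φ and θ are posterior-mean estimates averaged
over retained samples (more stable than a single draw); primary topics
use the **final** sample's token counts n_dk, matching the
"topic most frequently mentioned in the review" reading, with ties to
the lowest topic index. θ-argmax is available as an alternative and
coincides except near ties. The sampler also tallies per-token marginal
assignment frequencies over retained samples, which is what the
exact-enumeration tests compare against. A per-sweep collapsed
log p(w|z) trace is kept as a convergence diagnostic. The inner loop is
numba-compiled; given (DTM, params, seed) the full z trace is
deterministic.

Topic-number selection fits one model per candidate K (same seed and
schedule, α rescaled to 50/K) and minimizes **topic density**: the mean
cosine similarity over all unordered pairs of φ rows. Low density means
distinct, independent topics; the per-K score table is returned for
plotting. Ties go to the smaller K. The criterion is pluggable — density
is one published convention among several cited for this step.

## Downstream statistics

* **Share tables**: primary-topic counts per stratum with percentages
  over the column denominator, rounded half-up to one decimal (the
  printed style). Documents with missing primary topic or stratum leave
  the relevant denominator.
* **Fisher exact**: 2×2 tables use exact two-sided p by hypergeometric
  enumeration (tables with probability ≤ observed). r×c tables use Monte
  Carlo with fixed margins — rows drawn sequentially from multivariate
  hypergeometric distributions — with p = (1+hits)/(reps+1) and its
  standard error reported; default 10⁵ replicates (the pipeline and the
  acceptance script use 2×10⁴, a sampling-size choice that keeps p-value
  noise near 3×10⁻³ at a fraction of the cost). A brute-force
  enumeration routine for small tables serves as the reference.
* **Welch t** (default; pooled variance available via ANOVA's 2-group
  identity) and **one-way ANOVA** with (g−1, N−g) df go through
  scipy.stats behind the module surface. Two-sided throughout; no
  multiple-testing correction (α = .05 per test), which every report
  notes.
* **Rating grids**: n / mean / sample SD (ddof = 1, reported missing for
  n < 2) per topic × stratum with the per-row ANOVA across strata and a
  between-drug Welch t.

## Synthetic data generator

The generator draws data from exactly the model the analysis assumes,
plus the metadata structure the filters and stratified tables need:

* φ_k ~ Dir(β_gen), where β_gen may be a scalar, a V-vector, or a K×V
  matrix (block-structured rows give the well-separated corpora used in
  recovery tests);
* each document gets an age stratum (default marginals 0.26/0.57/0.17)
  and time-on-medication stratum (0.42/0.28/0.30, roughly the published
  cohort composition), and θ_d ~ Dir(α_age ⊙ tilt_time) so topic
  prevalence varies on both axes;
* document lengths are Poisson(mean 100) truncated at ≥1 — review length
  statistics are generally unreported, so the mean is a free,
  documented config choice;
* ratings are round-half-up-then-clip to 1..5 of
  3 + effect(true primary topic) + stratum shifts + N(0, sd); with sd = 0
  the group means are exact, which the rating-law tests exploit;
* contaminant records (spam URLs, empty comments, age 18 or missing) are
  appended after the eligible documents of each drug with binomial
  counts recorded in a generator log, giving the filter tests exact
  expected values. Contaminant types are disjoint by construction, so
  per-rule removal counts must equal injection counts exactly.

Default cohort sizes are 463 and 919 eligible reviews with 5 topics —
the scale of the study this pipeline targets.

The vocabulary consists of fixed-length consonant-only nonsense codes
chosen so that no Porter rule fires: the preprocessing chain is provably
the identity on clean tokens, and recovery tests can compare fitted φ
directly against the generating matrix (projected onto the DTM's
vocabulary ordering). Rendered comments decorate a configurable fraction
of tokens with punctuation/digits/case changes that cleaning must strip
without changing token counts. What the generator deliberately does
**not** emulate: English prose, realistic word frequencies (no Zipf
tail), topic correlation structure, reviewer-level effects, or real site
field layouts. Passing recovery tests therefore demonstrates
correctness of the inference machinery, not performance on real
language.

## Reproducibility

A single global seed drives everything through named substreams
(SHA-256 of `"{seed}:{stage}"`, truncated below 2³¹), so stages can be
re-run in isolation and two runs from one config produce byte-identical
artifacts; the run manifest records a config hash and per-file
checksums. All tie-breaks (vocabulary order, topic index, lexicographic
stem completion) are deterministic.

## Validation problem sizes

The heavier checks run at sizes chosen to make the statistical
assertions sharp while keeping the full suite quick: sampler-vs-
enumeration uses corpora of ≤ 6 tokens (where all K^T assignments are
enumerable) with ~4000 retained samples at lag 25, and agreement is
required within 3 Monte-Carlo standard errors; parameter recovery uses
K = 3, V = 50, 400 documents × ~100 tokens with block-structured topics
(mean aligned cosine ≥ 0.90 required; observed ≈ 0.999); topic-number
selection uses 10 replicates of 200-document corpora with candidates
{2,3,4,5} (≥ 9/10 required). Monte-Carlo Fisher checks use 4×10⁴
replicates against full enumeration on small-margin tables.

## Known limitations

* Mean-pairwise-cosine is one reasonable reading of "density-based"
  topic-number selection; other criteria (e.g. adjacency-weighted
  variants) could be slotted in via the same interface.
* The Gibbs sampler is single-chain; convergence is monitored only via
  the collapsed likelihood trace.
* Stem completion is corpus-dependent: the same token can complete
  differently in different corpora, which is faithful to the procedure
  but means vocabularies are not transferable across fits.
* The r×c Fisher p is a Monte-Carlo estimate; exact network algorithms
  are out of scope.
* No regression layer (e.g. rating ~ topic + age + time); the analysis
  stops at the stratified tests it mirrors.
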