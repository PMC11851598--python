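# Methods

This note documents the models, algorithms, default parameters and
numerical choices in `scaletrim`, and what the synthetic-data conditions do
and do not establish about real questionnaire data.

## Data model

Items carry a subscale label, a wording, a reverse flag and (for reverse
items) a straightforward rephrasing. Responses are ordinal 1..K (K = 5 by
default, the common five-point Likert width); missing cells are allowed and
propagate as NaN. Two deliberately separate transformations handle reverse
wording:

* **Reverse scoring** (`x -> K+1-x`) feeds the response-based analyses
  (GRM, CFA, alpha). It is applied exactly once and tracked with a `scored`
  flag — applying it twice silently would corrupt the data, so a second
  application raises.
* **Rephrasing** feeds the semantic analyses: a reverse-worded item is
  embedded via its straightforward rewording, never its original text, and
  never silently — a reverse item without a rephrasing is an error.

## Embeddings and the semantic similarity index

The semantic route needs one vector per item wording. The default backend
is a deterministic offline encoder: hashed character n-gram counts
(n ∈ {3, 4}, signed hashing into 2^16 buckets) projected to d dimensions
(default 64) by a fixed Gaussian projection keyed on (bucket, d, salt), then
length-normalized. It is bit-stable across runs and platforms, needs no
downloads, and preserves the one property the selection rule uses: texts
sharing more n-grams have higher cosine similarity. A transformer backend
(mean pooling, e.g. 768-dimensional BERT vectors) is an optional adapter;
it raises a descriptive error when the dependency or weights are absent.
Embeddings are not length-normalized at storage for transformer backends —
cosine similarity normalizes internally — while the fallback normalizes
only to stabilize its own scale.

The *semantic similarity index* of an item is its mean cosine similarity
with the other items of the same subscale (a whole-scale scope is available
via `scope="scale"`; the subscale scope is the default because selection
operates per subscale). Lower index = more semantically unique. Selection
keeps the k lowest-index items per subscale, at full precision (no rounding
before ranking), with ties broken deterministically by bank order.

A note on what the index can and cannot do: within a set of equally
redundant items (equal-size planted clusters), all items share the same
expected index, so the ranking among them is noise. What the index reliably
does is separate *unique* items from *redundant* ones — the property the
tests assert.

## Graded response model

Samejima's model for ordered categories with the logistic boundary form
`P*_k(θ) = 1/(1 + exp(−a(θ − b_k)))`, scaling constant D = 1 (so printed
discriminations are on the conventional modern scale for Baker's bands:
very low < 0.25 ≤ low < 0.65 ≤ moderate < 1.35 ≤ high < 1.70 ≤ very high).

Estimation is marginal maximum likelihood EM with one latent dimension per
call (each subscale is fit separately):

* quadrature: 61 equally spaced rectangle-rule nodes on [−5, 5], weighted
  by the standard-normal density and renormalized. Doubling the node count
  changes estimates by < 1e−3 (asserted in tests);
* M-step: per-item quasi-Newton (L-BFGS-B) on the expected complete-data
  log-likelihood, warm-started, with an order-preserving parameterization
  (log a, b₁, log threshold gaps) and a bounded in (0.05, 10);
* convergence: maximum absolute parameter change < 1e−4, **or** a stalled
  log-likelihood (improvement < 1e−7). The stall criterion matters for flat
  directions — e.g. the thresholds of an item whose discrimination sits at
  the lower bound are unidentified and can drift below any parameter
  tolerance without changing the fit. Hitting the iteration cap (500)
  raises, carrying the last iterate and trace;
* missing responses contribute nothing to the likelihood for that item;
  items showing fewer than two observed categories are excluded and
  reported;
* standard errors: outer-product-of-scores (BHHH) per item block, with
  complete-data scores from the Fisher identity and central differences.

Person scoring is EAP (posterior mean under the N(0,1) prior) by default,
with MAP available; persons with no observed responses score 0 with SD 1
and a flag. Item information uses the standard polytomous form
`I(θ) = a² Σ_k (Q_{k−1} − Q_k)² / P_k` with `Q_k = P*_k(1 − P*_k)`; the
test information function is the sum over items.

Identification note: at least three informative items are needed for stable
joint estimation — with two, the likelihood has a ridge (one discrimination
can rise while another falls) along which EM crawls indefinitely. Test
fixtures therefore always contain ≥ 3 informative items.

## Polychoric correlations and ordinal CFA

Polychorics are two-stage ML (Olsson): stage-1 thresholds from
inverse-normal cumulative margins (unobserved categories are collapsed
out), stage-2 correlation maximizing the bivariate-normal contingency
likelihood, searched on [−0.999, 0.999] by bounded Brent. The bivariate
normal CDF is evaluated through Owen's T function (`scipy.special.owens_t`),
which agrees with `scipy.stats.multivariate_normal` to ~1e−7 and is fast
enough for pairwise assembly of large matrices. A boundary solution (e.g.
perfect concordance) is clamped and flagged, its asymptotic variance marked
unreliable. The asymptotic variance otherwise comes from the observed
information (numerical curvature of the profile likelihood). Assembly is
pairwise-complete with a configurable minimum pair count (default 50).

The CFA is congeneric (each item loads on one factor, factor variances
fixed to 1) and fit by DWLS: minimize
`F = Σ_pairs (r − σ(λ, φ))² / w` over loadings λ (|λ| ≤ 1.5) and factor
correlations φ (|φ| ≤ 0.999), where `w` is the asymptotic variance of the
√n-scaled polychoric estimate (n·var(ρ̂); unreliable entries fall back to
1). The test statistic is the unscaled `chi² = (n−1)·F_min` with
`df = p(p−1)/2 − free parameters`; mean/variance-adjusted (WLSMV-style)
statistics are not implemented. Weighting by the variance of the *scaled*
statistic is what puts chi² on the conventional scale — a correctly
specified model at n = 5000 yields chi² ≈ df, CFI ≈ 1, RMSEA ≈ 0 (asserted
as a fixed-point test). The optimizer multi-starts from three fixed
initializations.

Fit indices against the independence baseline (zero correlations, same
thresholds, df_b = p(p−1)/2):

* CFI = 1 − max(chi²−df, 0) / max(chi²_b−df_b, chi²−df, 0)
* TLI = ((chi²_b/df_b) − (chi²/df)) / ((chi²_b/df_b) − 1), reported
  unclipped (it legitimately exceeds 1 when chi² < df)
* RMSEA = sqrt(max(chi²−df, 0) / (df·(n−1)))
* SRMR = root mean square of the unique-pair correlation residuals

A saturated model (df = 0) reports TLI and RMSEA as not-applicable (None,
never NaN); threshold rules treat not-applicable indices as satisfied,
since a saturated model fits perfectly. Two built-in rules: the ant-colony
stopping rule (CFI > .95, TLI > .95, RMSEA < .05, strict) and the
Hu–Bentler adequacy rule (CFI ≥ .95, TLI ≥ .95, SRMR ≤ .08).

## Heuristic searches

Both searches operate per subscale on fixed-size k-subsets and are exactly
reproducible under their seed.

**Ant colony** (defaults: 20 ants, ≤ 100 iterations, evaporation 0.05 per
iteration, initial pheromone 1): each ant samples k distinct items with
probability proportional to per-item pheromone; after each iteration all
pheromone is multiplied by 0.95 and the iteration-best subset deposits its
score onto its members. Deposits are `max(score, 0)` and a strictly
positive floor keeps sampling probabilities valid — the update assumes an
objective on a roughly unit scale, which both built-in objectives satisfy.
The default objective fits the congeneric ordinal CFA on the candidate
subset (the subscale's polychoric matrix is computed once and subset per
candidate, with caching) and scores it as φ = mean(CFI, TLI) − RMSEA; the
search stops early once the best subset passes the stopping rule,
mirroring the "iterate until satisfactory fit" usage this method is known
for. A failing candidate scores −∞ and is logged; the search continues.

Design caveat, and why the objective is pluggable: *fit indices measure
misfit, not item strength*. Inside a correctly specified congeneric family
every subset fits, so the fit objective cannot rank strong items above weak
ones — for that task (planted-structure recovery, reliability-maximal short
forms) substitute the reliability objective (`alpha_objective`) or any
custom callable; an information-based objective slots in the same way.

**Genetic algorithm** (defaults: population 30, 60 generations, crossover
0.8, mutation 0.2, elitism 1): tournament selection of size 2, uniform
subset crossover repaired to exactly k items, swap mutation. Fitness is
Cronbach's alpha of the subset — with k fixed, the classical "maximize
consistency with fewest items" objective reduces to this. The initial
population can be seeded.

**Exhaustive search** enumerates all k-subsets (refusing more than 10,000
candidates), breaking ties by enumeration (lexicographic bank) order. It is
the oracle the heuristics are validated against: on 8-choose-4 pools with
graded loadings both heuristics attain its optimum on ≥ 19/20 seeds, and
they recover 4 strong items planted among 14 weak ones on ≥ 18/20 seeds.
The oracle fixtures use a *single* factor with graded loadings — a pool
containing two equally strong factors has two near-tied optima separated
only by sampling noise, which is an ill-posed benchmark for any stochastic
search.

## Synthetic data: what it emulates, what it does not

The generators target the operating point of a well-measured two-factor
attachment questionnaire: 2 subscales × 18 items, 5 categories,
discriminations drawn uniformly from 1.15–2.24 (anxiety) and 1.55–2.58
(avoidance), thresholds spread over about [−2.5, 2.5], latent-trait
correlation 0.4, n = 2000 persons for estimation-quality checks (scaled
down where a test only needs structure, e.g. 6–8 items or a few hundred
persons for plumbing tests).

* `simulate_grm_responses` draws correlated multivariate-normal traits and
  samples each response from the item's category distribution.
* `generate_clustered_embeddings` builds vectors
  `v = √between·g + √(within−between)·c_j + √(1−within)·ε` from orthonormal
  directions, with the noise ε drawn in the orthogonal complement of the
  structural subspace so realized mean cosines meet their targets within
  ±0.05 at moderate dimension (self-checked at generation time).
* `generate_coupled_fixture` plants an exact rank correlation between true
  discrimination and the semantic index: pairwise cosines are exactly
  √(s_i s_j) for redundancy weights s, so the index is strictly monotone in
  s, and the discrimination values are re-assigned by a seeded swap search
  until the rank correlation hits the requested coupling (achievable rank
  correlations are discrete at small m; the nearest half-step is accepted,
  always within the ±0.1 contract, self-checked).

What passing these tests shows: the estimators recover their own generating
models at realistic sizes, the searches find optima the oracle certifies,
and the full pipeline reproduces the qualitative cross-method patterns
(short forms tracking full-form abilities above 0.9; identical selections
giving a correlation of exactly 1; planted negative discrimination-vs-
similarity coupling detected as a negative, significant Spearman row).
What it does not show: anything about real item wordings (synthetic
embeddings are generated directly, not from text), response styles,
local dependence, multidimensionality within subscales, or non-ignorable
missingness — none of which the generators emulate.

## Correlation utilities

Pearson correlations require length ≥ 3 and nonzero variance; identical
vectors short-circuit to exactly 1 so that "two methods selected the same
items" reads as r = 1 rather than r = 1 − ε. Spearman correlations use
mid-ranks for ties; the two-sided p-value is exact (full permutation
distribution, vectorized) for n ≤ 9 and the t approximation otherwise.
Parameter-vs-similarity tables flag rows at α = .05 two-sided with no
multiple-testing correction, matching common reporting practice for such
tables.

## Known limitations

* Unidimensional GRM only; no partial-credit/Rasch family, no DIF.
* Raw (unscaled) DWLS chi-square; fit indices from scaled statistics will
  differ from other software on the same data.
* The ant colony's default fit objective is a scalarization chosen for its
  stopping-rule semantics, not a claim that fit can rank subsets within a
  well-specified family (see above).
* The offline embedding backend captures lexical, not semantic, similarity;
  conclusions about specific transformer models require the optional
  backend and real wordings.
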