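# Methods

This note records the statistical methods implemented in `sentispace`, the
exact formulas used, and the reasoning behind the non-obvious choices.

## 1. Lexicon-based emotion scoring

The affective lexicon follows the Dalian-style ontology: seven main
categories — four negative (anger, disgust, fear, sadness) and three
positive (surprise, good, happy) — subdivided into 21 subcategory codes
(happy: PA, PE; good: PD, PH, PG, PB, PK; surprise: PC; anger: NAU;
sadness: NB, NJ, NH, PF; fear: NI, NC, NG; disgust: ND, NE, NN, NK, NL).
Each entry carries a part of speech, sense count, intensity on the canonical
odd grid {1, 3, 5, 7, 9}, and polarity v(w) ∈ {−1, +1}. Word sentiment is

    s(w) = intensity(w) × v(w).

Off-grid intensities in 1–9 are accepted with a warning, since published
lexicon excerpts contain values 4 and 6. Files coded with 0/1 polarity are
mapped 0 → −1 at parse time; a signed polarity is required for s(w) to be
negative for negative words. When a surface form has several senses, the
entry with the largest |intensity| is used. A document's emotion profile
sums s(w) per main category over its tokens; the dominant category is the
one with the largest absolute total, ties broken toward negative categories
(a conservative choice for public-health monitoring, where missing negative
affect is the costlier error). A document is negative when its summed score
falls at or below a threshold (default 0).

## 2. Feature construction

TF-IDF is computed exactly as

    tf(w, d)  = C(w, d) / |d|
    idf(w)    = max( ln( D / (1 + df(w)) ), 0 )
    tfidf     = tf × idf

with natural logarithms and no row normalization by default (an optional L2
flag exists). The +1 in the denominator and the clamp at zero mean a word
appearing in every document, or in more than D/e documents after the +1
shift, scores zero. This variant deliberately differs from common library
implementations, so it is authored directly and tested against a dense
brute-force oracle at 1e−12.

## 3. Topic models

**BTM.** Short texts are modeled at the biterm level: every unordered
within-document word pair is a draw from a corpus-level mixture. Collapsed
Gibbs sampling assigns topic z to biterm (w1, w2) with probability

    p(z = k) ∝ (n_k + α) (n_{w1|k} + β)(n_{w2|k} + β)
               / ((2 n_k + Mβ)(2 n_k + Mβ + 1)),

and the point estimates are θ_k = (n_k + α)/(|B| + Kα) and
φ_{k,w} = (n_{w|k} + β)/(2 n_k + Mβ). Defaults: α = 1, β = 0.01,
500 iterations.

**LDA.** Standard collapsed Gibbs with symmetric priors α = 50/K and
β = 0.01, 1000 iterations by default.

Both samplers run in numba-jitted kernels with an internal xorshift64*
generator, so a fixed seed yields bit-identical results across runs and
platforms.

**Topic-count selection.** K is chosen by held-out perplexity, but naive
fold-in perplexity — inferring a held-out document's topic mixture from all
of its words and then scoring those same words — is biased toward large K:
the document's own words inform the mixture, so extra topics always help,
and grid search returns the maximum regardless of the true structure. The
package therefore defaults to **document-completion perplexity**: each
held-out document's mixture is inferred from its even-position tokens only,
and the odd-position tokens are scored under that mixture. On planted
corpora with K* = 3, completion perplexity with LDA recovers K = 3 in 9 of
10 seeds, whereas fold-in returned the grid maximum in every seed. Fold-in
remains available via `perplexity(..., method="fold-in")`. Selection uses
LDA by default; BTM fits are supported but their completion perplexity is a
less reliable K-selector on these corpora (5/10 seeds).

**Vocabulary reduction.** Word vectors come from a PPMI-weighted document
co-occurrence matrix factored by SVD (sign-fixed for determinism); k-means
clusters the vocabulary and every word is replaced by its cluster's
highest-frequency member before topic modeling. Cluster-representative maps
always send representatives to themselves.

## 4. Polarity classification

Logistic regression minimizes the mean negative log-likelihood plus
(λ/2)‖w‖² (bias unpenalized) with scipy's L-BFGS-B from a zero start, giving
deterministic fits on sparse TF-IDF features. The implementation is checked
against an independent full-Newton oracle (agreement within 1e−4) and
against scikit-learn with the equivalent C = 1/(λn). Multinomial naive
Bayes with additive smoothing is implemented directly and must match a
hand-computed Bayes posterior to 12 decimal places; out-of-vocabulary
tokens are ignored, and an empty document returns the class prior.

Evaluation counts the confusion matrix directly. Precision, recall, and F1
are defined as 0 when their denominator is 0, and every such case is
reported in `zero_division_flags` rather than silently suppressed. Both
macro and support-weighted averages are provided.

## 5. Space-time aggregation

A classifier's positive-class probability ŝ ∈ [0, 1] is rescaled to

    score = 2 ŝ − 1 ∈ [−1, 1],

so the sign reads directly as net sentiment. (A plain "shift by one", ŝ − 1,
can never be positive; the affine map above is the only monotone surjection
of [0,1] onto [−1,1] fixing the endpoints, and is what the daily series
requires.) The daily score S_D is the mean of rescaled scores over a day's
documents; monthly values are document-weighted means of daily scores.

The study window is partitioned into three fixed stages — Jul–Oct 2020,
Nov 2020–Feb 2021, Mar–Jun 2021 — and each (region, stage) cell is
summarized by its document count and the fraction of documents whose
dominant lexicon category is negative. Empty cells are reported with n = 0
and a missing proportion, and propagate as missing through adjacent-stage
differencing rather than being treated as zeros.

**Natural breaks.** Regional proportions are classified with the exact
Fisher–Jenks optimizer: an O(K n²) dynamic program over prefix sums that
minimizes total within-class sum of squared deviations; reported breaks are
class maxima. Tests compare it against exhaustive partition search.

**Spatial similarity.** The statistic is the mean absolute difference of
per-region values across the edges of a region adjacency graph (smaller =
smoother). The null distribution shuffles values over regions; the
one-sided Monte Carlo p-value uses the +1 correction,
p = (1 + #{null ≤ observed}) / (P + 1), so p ∈ [1/(P+1), 1].

## 6. Synthetic corpora and oracle checks

The generator plants: K* topics (Dirichlet-concentrated or disjoint uniform
blocks over the vocabulary), per-stage emotion-word injection at rate 0.3,
stage negativity 0.8 / 0.5 / 0.2, and per-region effects obtained by
smoothing iid noise twice over the adjacency graph (inducing positive
spatial autocorrelation). A document's polarity label is 0 iff injected
negative words strictly outnumber positive ones. The probability of that
event has a closed form — summing over document lengths L, injection counts
m ~ Binomial(L, rate), and P(Binomial(m, q) > m/2) — which the realized
corpora must match within sampling error (±0.04 at 3000 documents). Ground
truth (topic assignments, injection positions, region effects) is
token-consistent with the emitted corpus, enabling exact recovery checks.

Problem sizes used in the recovery suites (2000-document topic corpora,
3000-document fraction checks, 12-region chains with effect scale 0.25 and
4000 documents for the spatial test) are the package's own desk-scale
choices, selected so each property is detectable with margin on one CPU in
minutes.
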