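# Methods

`tweetmine` is a desk-scale reimplementation of an infoveillance workflow for
characterizing a health topic on a microblogging stream: collect
keyword-filtered posts, summarize the stream (volume, spikes, hashtags,
retweets, user concentration), hand-label a sample by several raters, train a
semi-supervised deep-belief-network (DBN) topic classifier on bag-of-stems
features, evaluate it with stratified cross-validation, and use score
thresholds to retrieve confident examples of a category. Because no public
tweet corpus accompanies the original antibiotic study, the package ships a
seeded synthetic generator that reproduces the statistical structure the
analysis assumes; all tests and experiments run against it.

## The synthetic stream

`synthetic.GeneratorConfig` defines one collection run. Defaults are the
package's study conditions and stay fixed across tests and experiments:

| parameter | default | rationale |
|---|---|---|
| `n_days` | 60 | one-season desk-scale collection window |
| `base_rate` | 100 tweets/day | Poisson mean; desk-scale stand-in for a stream averaging thousands/day |
| `spike_days` | one ×5 day at index 30 | news-driven bursts are roughly single-day; ×5 matches the observed max-to-mean ratio (~2.4×) order of magnitude and guarantees Z > 2 |
| `category_prior` | (21, 88, 28, 38, 72, 132, 16, 15, 7)/417 | the labeled-set class counts of the antibiotic study (the printed per-class counts sum to 417, not the printed total of 416; the actual sum is used) |
| `retweet_prob` | 0.279 | the reported retweet share (27.9%) |
| `hashtag_prob` | 0.386 | reported hashtag usages per tweet (228,451/591,091) |
| `rater_agreement` | 0.75 | chosen analytically so 3 simulated raters over the default prior give Fleiss' kappa near the reported 0.47 (simulated value ≈ 0.48) |
| `tokens_per_tweet` | (6, 14) | short-post regime; emergent character lengths spread over several 10-char bins |
| `n_users`, user Zipf | 3300 accounts, exponent 0.6 | ≈0.55 accounts per expected tweet (the reported 327,930 users / 591,091 tweets); exponent chosen so a few percent of accounts contribute ~20% of tweets, the reported concentration regime (1.3% of users → 22.68% of tweets) |
| Zipf exponents | background 1.1, hashtags 1.3 | heavy-tailed token/tag activity; finite support with exact rank^(−s) normalization |

Tweet text is a space-joined sequence of *already-stemmed* tokens, so the
feature stage's Snowball stemmer is the identity on synthetic text: generator
correctness is decoupled from stemmer behavior. Each original tweet carries
at least one signature stem of its generating category (each further token is
a signature with probability `signature_token_rate=0.3`, otherwise a Zipf
background stem), making categories recoverable in principle — the
parameter-recovery experiment measures how well the classifier does so.
Retweets copy an earlier original verbatim with an `RT @user:` prefix and set
the platform linkage field, exercising both retweet conventions the reader
supports. Timestamps spread uniformly over each UTC day; only day resolution
matters downstream.

What the generator does **not** emulate: real English morphology (so stemmer
quality is tested separately on real words), topic drift, follower-graph
structure, bursty within-day timing, or label noise correlated with content.
Passing tests therefore demonstrate the pipeline's correctness and the
classifier's ability to recover a planted class structure — not performance
on the 2014 antibiotic stream.

## Ingest and filtering

Tweets travel as JSON Lines in a documented subset of the Twitter API v1.1
payload. Timestamps are ISO-8601 with offset, resolved to UTC on read; day
boundaries are UTC midnights (the original study states no timezone).
Include-keyword matching is token-boundary with a prefix rule
("antibiotic" matches "antibiotics") because keyword lists of this kind mix
stems, full names, and misspellings and the platform's exact matching rule is
not recoverable; exclude patterns are plain substrings so a cashtag like
`$abx` — the stock-ticker noise that contaminated the original collection —
is caught even though `$` never survives tokenization. The historical
140-character limit is not enforced on read; length features clamp instead.

## Corpus analytics

Daily counts are dense (zero-filled) over the store's date span. Spike
flagging uses Z scores with the population SD (divisor *n*) over the full
series, including spike days — matching a whole-collection "mean ± SD"
description; no robust or rolling baseline is attempted. A constant series
flags nothing. Percentages in reports are exact fractions rendered with
round-half-even; several of the original study's printed percentages are
truncations (e.g. 164,973/591,091 = 27.9099…% printed as 27.90%, and a
9.06% hashtag share printed as 9.0%), so this package reports the exactly
rounded values. Retweet tallies key on the source id when present, else on
the lowercased, prefix-stripped, whitespace-collapsed text.

## Rater adjudication and agreement

Items are labeled when at least 2 raters agree (unique winner with 3 raters);
otherwise dropped. Fleiss' kappa follows the standard fixed-panel formula;
the degenerate case where every vote lands on one category (chance agreement
1) returns 1.0 with a warning. Incomplete vote tables are rejected rather
than imputed, since the formula assumes a constant number of ratings per
item. The implementation is cross-checked against
`statsmodels.stats.inter_rater.fleiss_kappa` in the test suite.

## Features

A tweet's vector is: presence bits for a class-informed stem vocabulary (up
to the top 50 stems per labeled class plus the top 1000 stems over the whole
corpus, occurrence-counted after stopword removal, ties broken
lexicographically, first-seen deduplication in scheme order), ten one-hot
length bins of width 10 characters, and one URL bit — with a 1372-stem
vocabulary this is the 1383-dimension layout of the original classifier.
Length is the raw character count of the stored text (including any `RT @…`
prefix) and clamps into the top bin at ≥ 100 characters, since ten bins of
width ten only cover 0–99 while real posts reach 140. Encoding is binary
presence, not counts. The overall top-1000 list is computed over the full
supplied corpus (configurable). The English Snowball (Porter2) stemmer is
implemented in-package from the published algorithm definition, including
its exceptional-form tables.

## The classifier

Architecture: input → 700 → 700 → 300 sigmoid hidden layers → softmax output
with one unit per category (9 by default; scores sum to 1). Pretraining is
greedy layer-wise CD-1 on Bernoulli RBMs — learning rate 0.05, 10 epochs per
layer, batch 10, weights initialized N(0, 0.01²), biases zero; each deeper
RBM trains on the mean-field (probability) outputs of the previous layer
rather than samples, the usual lower-variance choice. The negative phase
samples hidden states but takes the final visible and hidden phases as
probabilities. Fine-tuning is plain mini-batch SGD (no momentum or decay) on
softmax cross-entropy — batch 10, 200 epochs, learning rate 0.1 — with
inverted dropout (rate 0.5) on hidden layers only, so prediction-time passes
need no rescaling and are fully deterministic. The original description
leaves the pretraining hyperparameters, dropout rate, and optimizer details
unstated; the values above are conventional defaults and all configurable.
Where the source text is internally inconsistent about the output layer
("11 nodes" in one sentence, a 9-class multinomial elsewhere), 9 output
units are used.

All randomness flows through seeded `numpy` generators: a full
pretrain + fine-tune replay with one seed reproduces weights bit-identically.
Numerically, sigmoids are computed in the sign-split stable form and softmax
is max-shifted.

## Evaluation

Stratified k-fold assignment shuffles each class (seeded) and deals
round-robin, so per-class fold counts differ by at most one and a class with
fewer members than folds appears in exactly that many folds. The headline
accuracy is pooled over all held-out predictions (a pooled ratio, not a
fold average). Per-class metrics are one-vs-rest on the class's softmax
score with a closed (≥) threshold. AUC is the exact Mann–Whitney statistic
(midranks for ties), which equals trapezoidal integration of the swept ROC
curve — the suite checks the two routes against each other and against
scikit-learn. The break-even point interpolates linearly between the two
adjacent sweep points when precision and recall cross between thresholds;
if they never cross, the point minimizing |precision − recall| is reported.
Precision is undefined (omitted) at zero predicted positives.

## Experiments and problem sizes

`experiments.parameter_recovery_cv` generates a disjoint-signature corpus,
takes 2,000 labeled (true generating categories) and 10,000 unlabeled
tweets, pretrains the RBM stack once on the unlabeled pool and reuses it
across the 10 folds — pretraining never sees labels or fold membership, so
this is statistically identical to pretraining per fold at a tenth of the
cost (per-fold pretraining remains available). Fine-tuning uses 20 epochs, a
scaled-down pass budget appropriate to a corpus of this size; batch size,
dropout, architecture, and learning rates are the library defaults. Observed
pooled 10-fold CV accuracy on this planted-structure task is ≈ 0.99, with
per-class AUCs near 1 — as expected when category signatures are disjoint by
construction; the experiment validates recovery, not real-world difficulty.

`scripts/acceptance.py` reruns the characterization, rater, CV, and
retrieval experiments from a single seed and writes the measured quantities
as JSON (see the README).

## Known limitations

- The synthetic stream is far easier than real text: disjoint signatures
  make near-perfect classification attainable, so absolute accuracy numbers
  do not transfer to real corpora.
- The stemmer implements the English Snowball algorithm only; no other
  languages.
- Retrieval tallies for prefix-style retweets conflate messages whose
  normalized text collides.
- Plain SGD can plateau on very small networks with small-variance
  initialization; the defaults target the full-width architecture, and the
  learning rate is configurable.
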