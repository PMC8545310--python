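# Methods

This note documents the models, parameters and design choices behind
each stage, what the synthetic generator does and does not emulate, and
the numerical conventions.

## Synthetic stream generator

The generator emulates a multi-region OSN message stream with known
ground truth. Its defaults are the study conditions the rest of the
package is validated under:

| parameter | default | meaning |
|---|---|---|
| `follow_distribution` | (.90, .092, .003, .001, .003)* | share of users per embeddedness type (Unique/Low/Moderate/High/Extreme) |
| `p_home_community` | 0.92 | probability a followed community lies in the user's home region |
| `p_declared_location` | 0.18 | share of users with a declared profile location |
| `base_rate` | 2.0 msg/user/day | Poisson mean, split across topics by `topic_shares` (uniform) |
| `communities_per_region` | 40 | gazetteer roster per region |
| topics | the ten standard topics | each with 25 exclusive tokens, 3 subtopics × 12 tokens, plus 40 shared tokens |

\* the printed shares sum to 99.9% after rounding and are normalized to
a proper distribution, so the Unique share is 0.9009.

Counts are Poisson per user-day-topic: daily message volumes in this
domain are reported only as daily means, and an independent-increment
count model is the simplest one consistent with day-by-day monitoring
plots. Message text is a bag of 5–15 tokens (≈55% subtopic, 25% topic,
20% shared when a subtopic applies) plus one emotion-marker token drawn
from the topic's emotion mixture and 0–2 hashtags formed by
concatenating vocabulary words. Follow counts per type are Unique 1,
Low 2, Moderate U{3..9}, High U{10..49}, Extreme U{50..80} (the open
upper bound is a convention; only "50 or more" is meaningful). Message
length and per-user rate distributions are module conventions — the
domain literature does not pin them down.

Randomness is a single seed fanned out through `SeedSequence` spawn
keys per purpose and per (user, day), so any slice of the stream can be
regenerated in isolation and two runs with one seed are byte-identical.

An `EventInjection` multiplies the Poisson rate of one (region, topic)
during its window, reroutes a fraction (default 0.8) of that topic's
messages to the event subtopic, and optionally replaces the emotion
mixture. This is the ground truth against which detection latency and
recovery are scored.

**What the generator does not emulate:** grammar and word order
(downstream stages are bag-of-words), retweet/cascade virality, bot
behavior beyond duplicate floods, multilingual text, and diurnal
patterns within a day. Passing tests therefore demonstrate the
pipeline's mechanics and statistical behavior under controlled
separability — not performance on real, adversarial, code-switching
social-media text.

## Geolocation

Declared locations win with confidence 1. Otherwise the user's region
is the majority region of gazetteer-resolved followed communities,
confidence = majority share. Ties break by the most specific
community-asset category present in the tied regions, then
lexicographically — deterministic and auditable; the underlying method
does not specify multi-city voting. The category vocabulary and its
specificity order (emergency > government > health > media > education
> business > religious > sports > culture > nonprofit) are this
package's convention. The gazetteer is an offline case-folded
name-to-location table replacing online geocoding; unresolved names are
collected, not fatal. E–I ties are community-follow edges; internal
means the community's region equals the assigned region. For
single-community (Unique) users, triangulation accuracy equals the
per-edge home probability, which is why the synthetic check centers on
0.92.

## Preprocessing

Fixed order: noise removal → tokenization → hashtag segmentation →
normalization (casefold, synonyms, spelling) → stopword removal →
lemmatization. Spelling correction replaces a token only when exactly
one lexicon word sits at Levenshtein distance 1 — ambiguity keeps the
original, trading recall for zero silent corruption. Hashtag
segmentation is greedy longest-match with the unsegmentable remainder
kept whole. Noise rules: a duplicate run (> 3 identical texts by one
user within an hour) keeps its first copy; text over 50% URLs is an ad;
per-user daily floods keep the earliest 100. Emoticons pass through as
opaque tokens. The bundled lexicons are small and illustrative; all are
plain text and pluggable per language.

## Topic model

Multinomial logistic regression (L2, C = 1.0 default) over token
counts; vocabulary = training tokens with frequency ≥ 5, capped at 2000
(the DBN input width) for bounded memory. Scoring is the normalized
exponential of per-class weighted sums; a binary fit is expanded to
two-row softmax form so scoring is uniform across class counts.
Assessment uses seeded stratified 10-fold CV *and* an 80/20 holdout —
both protocols are conventional for this task and they answer different
questions (model selection vs. final report). Prevalence reports drop
topics under 2% of messages while keeping them in the denominator.

## Subtopic model

RBMs are binary-visible (counts binarized at ≥ 1) and trained with
CD-1; per-epoch mean reconstruction error is recorded as the learning
diagnostic. The reference stack is 2000-1000-500 units, 1000 epochs at
learning rate 0.01; tests and the pipeline use smaller stacks since the
synthetic vocabularies are tiny. The printed reference configuration
ends in 6 units, which conflicts with a 100-subtopic head; this package
treats the first three widths as the feature stack and sizes the head
at l = K (default 100), since the softmax needs one output per
subtopic.

Discovery-then-supervision: k-means (seeded) partitions DBN features
into K pseudo-subtopics, each named by its highest-lift token, and the
pseudo-labels fine-tune the softmax head — the only reading that
reconciles "unsupervised discovery" with "softmax trained on partial
labeled data". The fine-tuning objective is the L2-penalised
cross-entropy with penalty λ/2 on the head and on the RBM weight
matrices; 1/m is one over the number of training samples (the symbol is
overloaded in the source formulation; the L-BFGS memory m = 6 is a
separate knob). λ defaults to 2 — unusually strong, but it is the
stated reference value and is config-exposed. Gradient descent uses
backtracking line search (the cost trace is non-increasing by
construction; failure to decrease raises a step-size error rather than
diverging silently). L-BFGS runs through `scipy.optimize.minimize`
with `maxcor = m`. Deep fine-tuning (backprop into the RBM weights) is
flag-controlled and off by default: the head-only problem is convex and
the deep gradient is not specified by the source formulation.

## Change detector

The 30% rule needs a baseline, which the source leaves implicit. The
default is the trailing 7-day mean with a 5-count floor — the floor
suppresses the small-count false alarms that plague low-volume series —
and a literal day-over-day mode is provided. Calendar days are UTC.
Consecutive same-direction flags merge into one event with onset at the
first flag. Attribution takes the mode of subtopic assignments in a
±3-day window (ties: lexicographically first, annotated) and the top-25
non-stopword tokens as keywords. Emotion windows cover onset ±15 days,
each emotion series divided by its own maximum (all-zero series stay
zero); truncated windows warn.

Detection behavior is count-driven: with per-topic daily means around
λ, the relative Poisson noise is ~1/√λ, so the 30% rule is only
meaningful when λ ≳ 100. The recovery checks therefore run at ~150
messages/topic/day; lower-volume series are exactly where the baseline
floor and threshold choice matter.

## Affect analyzer

The tree is grown over vocabulary *words* (the word-routing reading of
the growth procedure; the alternative class-incremental reading is
noted but the growth rules themselves are identical either way). Words
are embedded by their per-emotion co-occurrence profile; each node
scores a word against its children by prototype dot products, softmax
over children, top-3 sorted outputs → growth rule. Conventions where
the rules are silent:

* threshold equality (o₁−o₂ = α or o₂−o₃ = β) resolves to new_child,
  the most conservative structural action, and is logged;
* a word with zero likelihood under every child grows the structure;
* at a full node the decision is new_child; if there is no room the
  word descends into its best child, and at the depth cap it is
  absorbed into that child — capacity and depth invariants hold after
  every insertion, and the construction log records each decision;
* merging takes the two highest-likelihood children and retrains the
  merged node on their union.

Defaults: α = β = 0.1, max depth 3, max children per branch 5 (10 and
20 are supported). Node classifiers default to width-1 bag-of-token
softmax scorers trained by mini-batch SGD (momentum 0.9, weight decay
0.001, learning rate 0.1); a width-3 convolutional token-window variant
over the profile embeddings (fixed random filters, trained head,
max-pooled) is config-exposed. Routing labels during training come from
subtree-vocabulary overlap; leaves hold softmax emotion heads. Polarity
maps joy and surprise to positive (surprise configurable) and
anger/disgust/fear/sadness to negative.

## Metrics

Accuracy, sensitivity, precision, F-measure and G-mean
(√(TP_rate × TN_rate)) from confusion counts; any zero-denominator
metric is reported as None, never 0. Multi-class reduction is
one-vs-rest per class then macro average (undefined classes are
excluded from the mean). Detection latency is the signed day offset
between detected and injected onset, matched by (region, topic);
misses are excluded from the mean offset and counted in the miss rate.
A naive two-consecutive-days baseline exists in the test harness as
the latency comparator.

## Problem sizes and tolerances

Statistical tests use 3-standard-error bands around analytically known
targets (binomial for shares and accuracies; empirical SE over
permutation replicates for the emotion null, whose single-run accuracy
varies at the marker-group level rather than per message). Oracle
equivalence tests use 1e-9; hand-computed closed forms 1e-12; the
fine-tuning gradient check 1e-5 relative against central differences.
Monte-Carlo checks run at 100–200 replicates; recovery streams use one
region, one topic, 75 users × 2 msg/day (λ = 150/day) over 14 days —
sizes chosen so the quantities under test are estimated well while the
suite stays quick. Known limitations: the RBM stack is modest and
CPU-bound by design; no GPU paths; the tree classifier is validated on
separable marker vocabularies, which bounds what its accuracy numbers
say about natural text.
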