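# Methods

This note records what the package computes, the assumptions behind
each stage, the defaults and why they were chosen, and what the
synthetic evaluation does and does not establish.

## The analysis

The object of study is the vocabulary clinicians use when documenting
ceilings of treatment, limitation of life-sustaining treatment and
end-of-life care, and the association of that vocabulary with death
within 7 days of the note that contains it. The window is deliberately
short: it confines the claim to short-term prognostication, where
in-hospital death certification makes the outcome ascertainment
reliable, and avoids modelling tense or time-course language.

The pipeline runs: tokenize → phrase → embed → expand seeds → query →
associate → project. Each stage is a pure function of declared inputs;
a manifest records input hashes and the seed, and a fixed seed
reproduces every artefact byte for byte in single-threaded mode.

## Tokenization and phrasing

Tokens are lowercase maximal alphanumeric runs; digits are kept,
punctuation splits ("I.T.U." → `i t u`). No stemming, lemmatization or
stop-word removal is applied.

The phraser scores adjacent pairs with the discounted normalized
co-occurrence score `score(a,b) = (c(a,b) − δ)·N/(c(a)·c(b))`, the
de-facto standard collocation statistic in this ecosystem, with
δ = min_count = 10 so that any pair seen fewer than 10 times scores
non-positive. Merging is greedy left-to-right and non-overlapping
within a pass; two sequential fit+apply passes produce up to 4-gram
tokens (two bigrams, or bigram+unigram, can pair in pass 2), and a
span cap guarantees no token ever covers more than four source words.

The default merge threshold is 20. On template-generated synthetic
text, whole sentences are collocational: at looser thresholds the
first pass absorbs frequent function words into background bigrams,
which collapses their standalone counts and lets pass 2 glue template
words onto the planted phrases. Threshold 20 separates the planted
collocations (pass-2 scores in the hundreds) from these boundary
artifacts (scores below ~15) with margin on both sides; on natural
text any value in the 10–50 range behaves similarly and the threshold
is exposed everywhere.

## Embeddings

Architecture: skip-gram with negative sampling. The training
objective for a (centre c, context o) pair with k negatives is
`−log σ(u_c·v_o) − Σ log σ(−u_c·v_n)`, negatives drawn from the
unigram^0.75 distribution. Defaults: dimension 300, window 10 (dynamic:
the half-width is drawn uniformly from 1..10 per position), 2 epochs,
minimum word frequency 10, k = 5 negatives, learning rate 0.025
decaying linearly to 1e-4 over all scheduled pairs, no frequency
subsampling. Dimension, window, epochs and frequency floor are the
study conditions; the remainder are the conventional minimal
configuration for this trainer. The inner loop is true per-pair SGD,
JIT-compiled, with an explicit xorshift64* stream for negative
sampling, so single-threaded training is bit-deterministic per seed.
Similarity queries use the input vectors only; top-k neighbour search
is exact with ties broken by vocabulary index.

Multi-word seed phrases resolve to vocabulary tokens through the
fitted phraser (the underscore-joined form first, then the phraser's
own segmentation); seeds that do not collapse to a single known token
are reported as unresolved rather than failing the expansion.

## Cohort retrieval

A phrase term carries tokens, a slop and a fuzzy flag. The span rule:
a document window of at most `len(tokens) + slop` tokens matches when
every query token can be assigned a distinct position whose token
matches. This order-free span semantics covers both worked examples
("family discussion"~5 matching "discussion with the family"; slop 0
forcing adjacency) and is exactly testable against exhaustive
enumeration; it deliberately approximates the edit-move slop semantics
of production search engines. Fuzzy matching applies per token: query
tokens of ≥5 characters match within one restricted
Damerau–Levenshtein edit (insertion, deletion, substitution, adjacent
transposition); shorter tokens must match exactly so that "of" never
fires on "or". An inverted index plus a deletion-neighbourhood table
(SymSpell construction) supplies candidate documents; correctness is
defined solely by the span rule, which the index only accelerates.

Patients are aggregated by unique patient id (an alternative reading —
counting clinical episodes — would only change the denominator
bookkeeping). The control cohort is every patient with at least one
in-range document and no match in any group; it is disjoint from every
group by construction, while group-to-group overlap is allowed.

## Outcomes

`died_within_window` is inclusive on both ends: death on the document
day counts, death exactly `window_days` after counts, death before the
document never does. The choice is isolated in one function so the
exclusive alternative is a one-line change. A matched patient counts
as a death only if one of their *matched* documents precedes the death
by at most the window; control deaths are counted symmetrically over
all the control patient's in-range documents. Relative risk is
computed on unrounded rates — rounding the group percentage first
gives visibly different second decimals (72.0 vs 71.89 on the
"unsurvivable" row). Rows whose death count arrives suppressed ("<10")
in a counts file are carried with their n but no derived rate.
Display suppression of small counts (default floor 10) never alters
the underlying numerics. No confidence intervals or hypothesis tests
are produced; the analysis reports absolute counts and their ratios.

## Concept embeddings and projection

Concepts are abstract phrase→ID pairs with surface variants, not
ontology entities. Mentions are linked with the same per-token fuzzy
rule, leftmost-longest and non-overlapping per concept. A concept's
vector is the incremental mean, over its mentions, of the mean word
vector within 10 tokens either side of the mention (the mention's own
tokens excluded; out-of-vocabulary context words skipped). The mean-of-
context-means is the minimal update rule delivering spelling- and
variant-robust concept vectors; concepts with no linked mention carry
no vector and are reported. Concept training runs on the unphrased
token stream so that variant windows align token-by-token; context
vectors are looked up in the phrased vocabulary, which retains the
relevant context words as unigrams.

The 2-D projection is exact (non-Barnes–Hut) t-SNE, appropriate for
tens of concepts: per-point Gaussian bandwidths found by bisection to
match the target perplexity (default 5, chosen for ~30–40 concept
points) to within 1e-3; symmetrized joint p; Student-t q; gradient
descent (learning rate 100, adaptive gains, momentum 0.5→0.8) with
early exaggeration 12 for the first 250 of 1000 iterations. The
reported KL divergence is always computed against the un-exaggerated p
so descent is comparable across phases.

## The synthetic corpus

The generator emulates the features the analysis relies on, at desk
scale (default 50 000 patients, mean 4 documents each, against the
motivating cohort's ~425 000 episodes):

- **Documents.** Per patient, 1 + negative-binomial(r = 2) documents
  (right-skewed, like real EHR usage), each 2–4 neutral ward-round
  sentences from a 26-sentence library, dated uniformly in the
  12-month window (day resolution).
- **Phrase groups.** Three groups of ten multi-word phrases (ceiling-
  of-care, end-of-life, LST-limitation) with 7-day mortality 0.576,
  0.575 and 0.567 and a 0.8% background — the rates of the motivating
  cohort. Each planted patient receives one phrase inside one of ten
  group-specific sentence templates; templates within a group share
  content words (so same-group embeddings cluster) and differ across
  groups. The ten a-priori seed phrases all appear among the planted
  phrases, so default seed expansion exercises the planted structure.
  A patient planted in several groups has all sentences placed in the
  same note, which keeps per-group mortality recovery unbiased for
  overlapping cohorts. Template slots are wrapped in high-frequency
  function words, varied across templates, so that phrase boundaries
  are not themselves collocations.
- **Typos.** Each whitespace token is independently corrupted with
  probability 0.01 (a realistic clinical typing error rate) by one
  internal transposition, deletion or substitution; first and last
  characters survive, so "resuscitation" can become "resusciation".
  Tokens shorter than 5 characters are exempt: below that length the
  fuzzy matcher is off by design, and an irrecoverable typo would
  confound cohort retrieval rather than exercise it.
- **Mortality.** A planted patient dies uniformly 0–7 days after their
  phrase note with the group rate (the maximum rate when planted in
  several groups); a non-planted patient dies 0–7 days after a random
  note with probability 0.008; a further 5% of survivors receive a
  distant death 30–365 days after their last note to exercise the
  window boundary. Deaths never precede the patient's first note.
- **Plant log.** Every plant records patient, group, canonical phrase,
  document and the corrupted surface form — the ground truth for
  recovery tests.

Dense-planting variant: embedding experiments need every phrase to
clear the frequency floor of 10, so `embedding_config` raises the
per-group planting probability to 0.15 (default corpus 2 500 patients,
~37 mentions per phrase). Mortality-recovery experiments use the
sparse default (2% per group at 50 000 patients, cohorts of ~1 000).

**What passing does and does not show.** The generator plants exactly
the structure the method assumes: clean group-conditional mortality,
context-coherent phrase groups, single-edit typos. Recovery therefore
demonstrates the correctness of the machinery (retrieval is unbiased,
the arithmetic is right, embeddings recover planted co-occurrence
structure) — not that real clinical language is this separable, that
real typos are single edits, or that real mortality is conditionally
independent of everything but the phrase group. The real-world
neighbour lists and the published three-cluster concept geometry
cannot be reproduced without the original corpus.

## Numerical and design choices

- Restricted Damerau–Levenshtein (optimal string alignment) rather
  than unrestricted: adjacent transposition counts one edit, no
  substring is edited twice; implemented in-repo since no installed
  library provides the transposition-aware variant.
- Phraser pairs below min_count are pruned at fit time, making their
  score strictly negative and the score monotone in pair count.
- SGNS sigmoid arguments are clipped at ±8 to avoid overflow in the
  saturated regime.
- t-SNE requires ≥3 points and perplexity < n; three mutually
  equidistant inputs stay equidistant in 2-D to within 5%.
- Problem sizes in the test-suite and acceptance runs (50 000 patients
  for mortality recovery, 2 500 for embedding experiments, 5 seeds)
  are the package's desk-scale defaults; all are configurable.

## Known limitations

- The span rule is an approximation of edit-move slop; queries mixing
  very high slop with repeated query tokens can differ from production
  engines.
- Document text has no sentence-boundary awareness in embedding
  training: the context window crosses sentences within a note.
- The control rate absorbs tiny leakage from planted patients whose
  note fails retrieval (measured well under one binomial SE at the
  default typo rate).
- No survival modelling, competing risks, or multiplicity correction:
  the analysis is deliberately a contingency-table description.
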