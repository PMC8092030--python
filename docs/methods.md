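# Methods

This note documents the models and procedures implemented in `emovista`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Phase model and preprocessing

Posts are partitioned into four calendar phases of 2020 (inclusive date
windows): pre-pandemic (Jan 1 – Feb 29), first lockdown (Mar 1 – May 31),
easing of restrictions (Jun 1 – Jun 30), second lockdown (Jul 1 – Sep 30).
The windows partition the study period exactly; a post outside all windows
is dropped.

Bot and news accounts are defined operationally as users whose post count
strictly exceeds a quantile of the per-user count distribution (default
0.99).  A quantile rule was chosen because it is reproducible and
scale-free; there is no principled absolute volume threshold for "unusual
volume".  Within surviving users, a text repeated more than
`dup_threshold` times (default 1) keeps only its first chronological
occurrence.  Author ids are replaced by salted SHA-256 hashes (16 hex
chars): deterministic under a fixed salt, irreversible otherwise.

Tokenization lowercases, strips URLs and @-handles, reduces `#tag` to
`tag` and keeps maximal alphabetic runs.  Negators and valence modifiers
are protected from stop-word removal because the scorer depends on them.

## Emotion model

The discrete emotion space is Plutchik's eight basic emotions with its
four polar pairs (joy↔sadness, trust↔disgust, fear↔anger,
anticipation↔surprise).

**Lexicon expansion.**  Seed terms per emotion (shipped as a packaged TSV
drawn from the Plutchik emotion-word tradition) are expanded by training
skip-gram-with-negative-sampling embeddings on the corpus and taking each
seed's k nearest in-vocabulary neighbors with cosine ≥ τ, weighted by that
cosine.  A candidate near several emotions goes to the emotion of maximal
similarity (ties broken lexicographically), making lexicons pairwise
disjoint by construction.  Defaults: d=100, window=5, min_count=3,
epochs=10, k=20, τ=0.35 — small-corpus-appropriate values; τ and k are
artifact defaults validated on the synthetic recovery benchmark, not
empirical constants of any real corpus.  The SGNS trainer is a compact
single-threaded numpy implementation (mini-batch SGD over (center,
context) pairs, unigram^0.75 negative sampling with 5 negatives, linearly
decaying learning rate from 0.025, fixed symmetric window).  It is exactly
reproducible under a fixed seed, which off-the-shelf multi-threaded
trainers do not guarantee.

**Scoring.**  For each lexicon match of term *t* (emotion *e*, weight
*w*), the look-back window of 3 tokens before *t* is searched.  Modifier
factors compose multiplicatively (default intensifiers 1.5–2.0, inhibitors
0.4–0.6; magnitudes are artifact defaults, as only the direction
"increase or inhibit" is principled).  An odd number of negators in the
window flips the contribution to the wheel opposite, so double negation
restores the original emotion and the flip is an involution; a `discard`
mode drops negated contributions instead.  Flipping (rather than
discarding) is the default because it keeps scored mass inside the
eight-emotion space.  The dominant label is the argmax score with a fixed
documented tie-break order (anger < sadness < disgust < fear < joy <
surprise < trust < anticipation).  One dominant label per post feeds the
transition model; the full score vector is retained.

**Intensity profiles.**  raw(e) = Σ over the phase's posts of score(e);
normalized(e) = 100·raw(e)/Σraw.  `n_observations` counts (post, emotion)
pairs with nonzero contribution — observation level, not post level,
because the published observation counts exceed the corresponding
conversation counts, implying an observation-level denominator.  An
all-zero phase raises rather than returning an undefined profile.

**Transition models.**  Adjacent dominant-label pairs are counted within
each conversation's chronological sequence only; neutral posts are
skipped; sequences never span conversations, so no cross-thread adjacency
arises.  P row-normalizes C; never-observed source emotions leave their
row undefined (NaN) rather than smoothed, matching raw frequency
normalization; Laplace smoothing (configurable α) is available for
downstream consumers that need a fully defined chain.  Self-transitions
are counted.  Top-transition ranking sorts by probability, then count,
then fixed label order.

## Topics

Per-phase LDA (scikit-learn's batch variational implementation,
deterministic under a fixed seed).  K is user-fixed or selected from a
grid by maximal mean UMass coherence.  Each document gets a hard dominant
topic; documents whose maximal topic probability is below
min(1/K + 0.05, 1) are excluded from volume counting — the "prominent
topic" gate that omits general chatter.  Shares are percentages of the
counted documents.  Topic labels default to the top-3 terms and can be
overridden by a human-readable label map.

Keyphrases are RAKE-style: candidate phrases are maximal runs of non-stop
tokens; word score = degree/frequency over candidate co-occurrence; phrase
score = Σ word scores.

Topics are associated across phases by the cosine (clipped to [0,1]) of
the weight-averaged embedding centroids of their top-10 terms; an edge is
created at similarity ≥ 0.6 and only between distinct phases.

## GSOM behavior profiling

User features concatenate a topic block (distribution of the user's posts
over topic labels) and an emotion block (normalized summed scores); each
block sums to 1, so features live in [0,1].

The map starts as a 2×2 grid with seeded-random weights.  Growth threshold
GT = −D·ln(SF); the spread factor SF (default 0.3) controls granularity
independently of dimension.  Per input, the best-matching node and its
grid neighbors within the current radius move toward the input; the update
uses a Gaussian kernel over grid distance (winner at the full learning
rate).  A flat within-radius update was considered and rejected: while the
radius covers the young map, flat updates contract all node weights onto
the global mean and no topology forms — with the Gaussian falloff the
planted-cluster benchmark is recovered perfectly.  The winner accumulates
squared quantization error; on overflow a boundary winner grows a node
into every free adjacent position (new weights by the standard
interpolation/extrapolation case rules, clipped to [0,1] to stay in the
normalized input range; parent error reset to GT/2), and an interior
winner distributes error to its neighbors (factor FD, default 0.5).
Learning rate decays ×0.95 per epoch and the radius shrinks linearly from
3 to 1 over the 50 growth epochs; 50 smoothing epochs follow at half rate,
radius 1, no growth.  Training is deterministic under a fixed seed and
input order.

Profiles: nodes with ≥ min_hits best-matching inputs are merged by
union-find over lattice edges whose weight distance falls below a
self-calibrating ridge threshold — a two-means split of all adjacent-node
distances, applied only when the low and high groups separate by more
than 3× in mean (otherwise the map is one region).  A plain median cutoff
was considered and rejected: by construction it cuts half of the
within-region edges and fragments every region into many single-node
profiles.  Merging may pass through low-hit interpolating nodes;
components qualify through their min_hits nodes and absorb all hit nodes.
Each component becomes a profile labeled by its strongest mean feature
dimensions.

## Between-phase statistics

Each emotion's normalized intensity is a proportion p of n observations.
The Wilson score interval is

    (p + z²/2n ∓ z·√(p(1−p)/n + z²/4n²)) / (1 + z²/n)

with z the exact normal quantile (1.959964 at 95%, not 1.96 — the exact
value is required to reproduce published four-decimal bounds).  The
difference CI is the Newcombe hybrid: with A the larger-proportion sample,
d = p_A − p_B,

    lower = d − √((p_A−l_A)² + (u_B−p_B)²)
    upper = d + √((u_A−p_A)² + (p_B−l_B)²)

reported in percentage points with the difference always positive, the
convention of the published comparison table.  The chi-square test
reconstructs the 2×2 table as round(p·n) successes per sample and applies
Pearson's statistic with df=1 and no continuity correction (the corrected
variant fails to reproduce the published non-significant p-values).
Significance is declared at α=0.05; no multiple-testing correction is
applied, matching the published analysis.  Monte-Carlo coverage of the
95% difference CI is ≥93% over 2,000 simulated equal-proportion draws
(p ∈ {0.05, 0.15, 0.3}, n ∈ {500, 5000}) in the test suite.

## Synthetic data generator

The generator emulates the study conditions: four phase scenarios on the
2020 windows; per-phase Plutchik emotion mixtures (the two lockdown
phases use the published normalized intensity percentages as generating
mixtures; the pre-pandemic and easing phases follow the reported
narrative — sadness/fear dominant early, joy peaking during easing);
conversations of geometric length (mean 4 posts) with uniform timestamps
inside the window; tweet-scale posts of 8–25 tokens.  A post with true
emotion e draws ≥65% of its non-filler tokens from e's seed∪satellite
vocabulary (guaranteeing the ≥60% contract) including at least one seed,
so satellite terms co-occur with seeds and embedding expansion can recover
them; the remainder comes from the post's topic vocabulary plus ~30%
neutral filler.  Negators are inserted immediately before an emotion term
with probability 0.1.  Optional per-phase transition matrices drive
within-conversation emotion chains (default: mixture blended with 0.3
self-persistence, whose stationary law is exactly the mixture).  Users
carry a planted topic preference followed with probability 0.8 (the
ground-truth user clusters).  Bot accounts (default 2% of users) each emit
⌈20× the realized median organic per-user volume⌉ copies of a single
canned text; the organic stream contains exactly the configured number of
posts and bot posts are generated on top, so the volume and duplicate
filters can both be exercised while organic counts stay exact.

What passing the synthetic benchmarks shows: the pipeline's inference
machinery recovers known generating structure (mixtures within ±2 pp at
n=10,000; transition matrices within 0.05 max error at 10,000 transitions;
planted satellites with ≥90% recall/purity; planted user clusters at ≥95%
node purity).  What it does not show: performance on real language —
the generator produces bag-of-planted-words text with no syntax, sarcasm,
emoji, code-switching or topic drift, so real-corpus lexicon quality and
emotion precision will be lower and must be validated separately.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds named in
configuration; training loops are single-threaded; CSV floats are written
with a fixed format; the pipeline manifest records SHA-256 hashes of every
artifact, and rerunning a config reproduces them byte-for-byte.  Problem
sizes used by the test suite and the acceptance script (≈10,000-post
corpora for lexicon recovery, 10,000 transitions, 400-point GSOM
benchmarks, a ≈1,200-post end-to-end demo) were chosen so the full
verification cycle completes in a few minutes on one CPU while leaving
wide margins to every threshold.

## Known limitations

* The emotion scorer is lexicon-based: irony, sarcasm and emoji are out of
  scope, and negation scope is a fixed token window rather than syntactic.
* Dominant-label sequences discard within-post emotion mixtures (the full
  score vector is kept, but transitions are first-order and single-label).
* The GSOM implements the standard growth algorithm; forgetting/pruning
  variants that discard outdated map regions are not implemented.
* Published real-corpus quantities that depend on the undeposited original
  data (topic volumes, transition probabilities, profile counts) are
  format references only; the package reproduces the statistical table
  computable from printed inputs and validates everything else by planted
  recovery.
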