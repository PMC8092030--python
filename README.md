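# emovista

Phase-aware emotion surveillance for short social-media posts.

During a public-health crisis, the emotions people express in short online
posts are a measurable proxy for the mental state of a community.
`emovista` implements a complete infoveillance pipeline for tweet-scale
corpora partitioned into time phases (e.g. the pre-pandemic, first
lockdown, easing and second lockdown stages of 2020):

1. **Preprocessing** — text cleaning, removal of bot/news accounts by a
   per-user volume quantile, per-user duplicate collapse, salted-hash
   anonymization, calendar-phase assignment.
2. **Lexicon expansion** — skip-gram (SGNS) word embeddings trained on the
   corpus; the seed vocabularies of Plutchik's eight basic emotions
   (anger, sadness, joy, trust, anticipation, fear, disgust, surprise) are
   grown by nearest-neighbor querying above a cosine threshold τ.
3. **Emotion scoring** — a lexicon match of weight *w* contributes
   *w*·∏(modifier factors) to its emotion; a negator within the look-back
   window flips the contribution to the Plutchik wheel opposite
   (joy↔sadness, trust↔disgust, fear↔anger, anticipation↔surprise).
4. **Intensity profiles** — per-phase totals of the eight emotion scores,
   normalized to percentages summing to 100.
5. **Transition models** — first-order Markov chains over dominant
   emotions: adjacent pairs are counted inside each conversation thread,
   giving an 8×8 count matrix C and transition matrix
   P<sub>ij</sub> = C<sub>ij</sub>/Σ<sub>j</sub>C<sub>ij</sub>.
6. **Topics** — per-phase LDA with prominence-gated volume shares,
   RAKE-style keyphrase extraction, and a cross-phase topic-association
   graph built from embedding centroids.
7. **Behavior profiles** — a growing self-organizing map (GSOM) over user
   topic⊕emotion feature vectors.  The map starts as a 2×2 grid and grows
   boundary nodes when accumulated quantization error exceeds
   GT = −D·ln(SF); hit nodes merge into labeled profiles.
8. **Between-phase statistics** — per-emotion Pearson chi-square tests
   (2×2, df=1, uncorrected) and 95% CIs for the difference of two
   proportions by the Newcombe hybrid Wilson-score method.

Real crisis-era corpora generally cannot be redistributed, so the package
ships a first-class synthetic tweet-stream generator (`emovista.synth`)
with fully known ground truth — phase emotion mixtures, planted lexicon
neighborhoods, generating transition matrices, planted user clusters and
bot accounts — against which every stage's recovery is tested.

## Worked example

Comparing the published normalized emotion intensities of two lockdown
phases (first lockdown: n=36,317 emotion observations; second: n=10,604):

```python
from emovista import ProportionSample, chisq_two_proportions, newcombe_difference_ci

s1 = ProportionSample(0.1384, 36_317)   # anger, first lockdown: 13.84%
s2 = ProportionSample(0.1597, 10_604)   # anger, second lockdown: 15.97%
print(newcombe_difference_ci(s1, s2))   # (2.13, 1.3567, 2.9218)
print(chisq_two_proportions(s1, s2))    # (30.2479, 3.802e-08)
```

Anger intensity is 2.13 percentage points higher in the second lockdown,
with 95% CI (1.3567, 2.9218) pp and p < .001.  Running
`python examples/07_compare_lockdowns.py` prints the full eight-emotion
table:

```
emotion        diff                95% CI        p
anger          2.13  (  1.3567,   2.9218)  3.8e-08
sadness        0.35  ( -0.6563,   1.3461)     0.49  (not significant)
disgust        2.25  (  1.5691,   2.9518)    2e-11
fear           2.08  (  1.2365,   2.9399)  9.5e-07
joy            4.38  (  3.6308,   5.1097)  2.4e-27
surprise       0.58  (  0.3662,   0.7708)  1.1e-06
trust          0.93  (  0.4108,   1.4260)  0.00056
anticipation   0.22  ( -0.1257,   0.5406)      0.2  (not significant)
```

Every negative emotion except sadness is significantly more intense in the
second lockdown, and every positive emotion except anticipation is
significantly less intense — rising frustration, fading positivity.

The other scripts in `examples/` each demonstrate one capability
(simulation, lexicon expansion, scoring, transitions, topics, GSOM
profiling, the full pipeline); each prints its numbers with a note on what
they mean.

## Command line

A thin CLI wraps the library:

```bash
emovista run --config examples/demo_config.yaml --out demo_out
emovista simulate --out data/ --seed 1
emovista compare --a 13.84,36317 --b 15.97,10604
```

`run` executes the whole pipeline from one YAML config and writes every
stage artifact plus `manifest.json` (parameters, record counts, SHA-256
hashes).  Identical configs produce byte-identical outputs.

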