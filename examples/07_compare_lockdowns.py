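"""Two-proportion comparison of phase emotion intensities.

Given each emotion's normalized intensity (a proportion of n emotion
observations) in two phases, the Newcombe hybrid Wilson-score method gives
a 95% CI for the difference and a Pearson chi-square test (df=1, no
continuity correction) a p-value.  The inputs below are the published
normalized intensities of the two 2020 Australian COVID-19 lockdowns.
"""

from emovista import ProportionSample, chisq_two_proportions, newcombe_difference_ci

first = {"anger": 13.84, "sadness": 31.36, "disgust": 9.81, "fear": 17.58,
         "joy": 16.94, "surprise": 1.32, "trust": 6.56, "anticipation": 2.59}
second = {"anger": 15.97, "sadness": 31.01, "disgust": 12.06, "fear": 19.66,
          "joy": 12.56, "surprise": 0.74, "trust": 5.63, "anticipation": 2.37}
n1, n2 = 36_317, 10_604

print(f"{'emotion':13s} {'diff':>5s}  {'95% CI':>20s}  {'p':>7s}")
for emo in first:
    s1 = ProportionSample(first[emo] / 100, n1)
    s2 = ProportionSample(second[emo] / 100, n2)
    diff, lo, hi = newcombe_difference_ci(s1, s2)
    _chi2, p = chisq_two_proportions(s1, s2)
    flag = "" if p < 0.05 else "  (not significant)"
    print(f"{emo:13s} {diff:5.2f}  ({lo:8.4f}, {hi:8.4f})  {p:7.2g}{flag}")
# Every negative emotion except sadness is significantly higher in the
# second lockdown; every positive emotion except anticipation is
# significantly lower - rising frustration, fading positivity.
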