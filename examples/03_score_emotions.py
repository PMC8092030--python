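"""Score posts against emotion lexicons, with negation and modifiers.

A lexicon match contributes weight x modifier factors; a negator inside the
3-token look-back window flips the contribution to the Plutchik opposite
(joy<->sadness, trust<->disgust, fear<->anger, anticipation<->surprise).
Phase profiles then normalize the summed scores to percentages.
"""

from emovista import phase_intensity_profile
from emovista.emotions import DEFAULT_MODIFIERS, DEFAULT_NEGATORS, score_post

lookup = {"happy": ("joy", 1.0), "scared": ("fear", 0.8)}

for tokens in (["so", "happy", "today"],
               ["not", "happy", "today"],
               ["very", "scared", "tonight"]):
    pe = score_post(tokens, lookup, DEFAULT_NEGATORS, DEFAULT_MODIFIERS)
    nonzero = {e: round(s, 2) for e, s in pe.scores.items() if s > 0}
    print(f"{' '.join(tokens):24s} -> {nonzero}  dominant={pe.dominant}")
# "so happy" amplifies joy (1.5x); "not happy" lands on sadness (the wheel
# opposite); "very scared" gives fear 0.8 * 1.5 = 1.2.

posts = [score_post(t, lookup, DEFAULT_NEGATORS, DEFAULT_MODIFIERS)
         for t in (["happy"], ["happy"], ["scared"], ["not", "happy"])]
profile = phase_intensity_profile(posts, "demo_phase")
print("\nnormalized intensity profile (sums to 100):")
print({e: round(v, 2) for e, v in profile.normalized.items() if v > 0})
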