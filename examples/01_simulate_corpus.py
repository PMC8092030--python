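"""Generate a synthetic four-phase tweet stream with known ground truth.

The generator plants per-phase Plutchik emotion mixtures, emotion-specific
vocabulary neighborhoods, conversation threading and a few high-volume bot
accounts, and returns the latent variables so later stages can be scored.
"""

from collections import Counter

from emovista import build_default_vocabulary, default_scenarios, generate_corpus

vocab = build_default_vocabulary(seed=1)
posts, truth = generate_corpus(
    vocab, default_scenarios(n_posts_per_phase=500),
    n_users=150, bot_fraction=0.02, seed=1,
)

print(f"{len(posts)} posts from {len({p.user_id for p in posts})} users, "
      f"{len(truth.bot_user_ids)} of them bots")
print("example post:", posts[0].raw_text)

labels = Counter(truth.post_emotion[p.post_id] for p in posts
                 if truth.post_phase[p.post_id] == "first_lockdown")
total = sum(labels.values())
print("\nfirst-lockdown generating emotion frequencies (label share vs target):")
for emo, target in truth.emotion_mixtures["first_lockdown"].items():
    print(f"  {emo:13s} {labels[emo]/total:6.3f}  (target {target:.3f})")
# The empirical label shares track the configured mixture up to sampling
# noise; this is the ground truth downstream recovery is measured against.
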