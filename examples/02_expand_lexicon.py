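"""Expand the eight Plutchik seed lexicons with skip-gram embeddings.

Trains SGNS word vectors on a cleaned synthetic corpus, then harvests each
seed term's nearest neighbors above a cosine threshold.  Because the
generator plants satellite terms that only co-occur with their own
emotion's seeds, the expansion should recover them almost perfectly.
"""

from emovista import (build_default_vocabulary, default_scenarios,
                      expand_lexicons, generate_corpus, preprocess_corpus,
                      train_embeddings)

vocab = build_default_vocabulary(seed=1)
posts, truth = generate_corpus(vocab, default_scenarios(1500), seed=1)
clean, _ = preprocess_corpus(posts)

model = train_embeddings([p.clean_tokens for p in clean],
                         d=60, epochs=6, seed=1)
lexicon = expand_lexicons(model, vocab.seeds, k=20, tau=0.35)

hits = misses = 0
for emo in ("fear", "joy"):
    expanded = {t for t, (w, prov) in lexicon.entries[emo].items()
                if prov == "expanded"}
    planted = set(vocab.satellites[emo])
    print(f"{emo}: recovered {len(expanded & planted)}/{len(planted)} planted "
          f"satellites; spurious terms: {sorted(expanded - planted) or 'none'}")
    hits += len(expanded & planted)
    misses += len(planted - expanded)
print(f"\nrecall over these emotions: {hits/(hits+misses):.0%}")
# Each expanded term carries its seed-cosine as a weight in [0,1]; scores of
# matched posts are weighted by it downstream.
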