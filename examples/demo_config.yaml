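# Bundled demo configuration: a small synthetic four-phase corpus pushed
# through the complete pipeline.  All randomness derives from `seed`, so two
# runs of this config produce byte-identical outputs.
seed: 11
simulate:
  n_posts_per_phase: 400
  n_users: 120
  bot_fraction: 0.03
embedding:
  d: 50
  epochs: 5
  min_count: 2
topics_k: 3
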