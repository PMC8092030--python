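"""GSOM behavior profiling of user feature vectors.

The growing self-organizing map starts as a 2x2 grid and grows boundary
nodes where accumulated quantization error exceeds GT = -D ln(SF).  Hit
nodes are merged into labeled profiles along smooth lattice edges.
"""

import numpy as np

from emovista import GSOMConfig, derive_profiles, growth_threshold, train_gsom

print(f"growth threshold GT(D=2, SF=0.5) = {growth_threshold(2, 0.5):.4f}")
print(f"growth threshold GT(D=10, SF=0.1) = {growth_threshold(10, 0.1):.4f}")
# Lower spread factors raise the threshold and keep maps small.

rng = np.random.default_rng(42)
X = np.clip(np.vstack([rng.normal(0.2, 0.05, (200, 4)),
                       rng.normal(0.8, 0.05, (200, 4))]), 0, 1)
gmap = train_gsom(X, GSOMConfig(sf=0.3, seed=0))
profiles = derive_profiles(gmap, X, min_hits=3,
                           feature_names=["work", "family", "fear", "joy"])
print(f"\nmap grew to {gmap.n_nodes} nodes; "
      f"{len(profiles)} behavior profiles found:")
for p in profiles:
    print(f"  profile {p.profile_id}: {len(p.member_ids)} users, "
          f"strongest features: {p.label}")
# Two well-separated user groups yield exactly two profiles, each labeled
# by its strongest mean feature dimensions.
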