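"""Greedy identity clustering of unclassified repeat consensi.

Builds three artificial families, derives noisy variants of each, and
clusters them at two identity thresholds. For short random DNA even
unrelated sequences align near 50% identity (four-letter alphabet), so the
family structure shows at a stricter threshold while 50% merges broadly —
the same behaviour nucleotide clusterers exhibit at permissive cut-offs.
"""

import numpy as np

from repeatomekit import greedy_cluster, mutate_to_divergence, write_clstr

rng = np.random.default_rng(4)
bases = np.array(list("ACGT"))
ancestors = {f"fam{i}": "".join(rng.choice(bases, size=120)) for i in range(3)}

sequences = {}
for name, ancestor in ancestors.items():
    for v in range(4):
        variant, _ = mutate_to_divergence(ancestor, target_d=15.0, seed=rng)
        sequences[f"{name}_v{v}"] = variant

for threshold in (0.5, 0.7):
    clusters = greedy_cluster(sequences, threshold=threshold)
    print(f"threshold {threshold:.0%}: {len(sequences)} sequences -> "
          f"{len(clusters)} cluster(s)")

clusters = greedy_cluster(sequences, threshold=0.7)
print()
print(write_clstr(clusters, {k: len(v) for k, v in sequences.items()}))
print("At 70% identity the three planted families separate cleanly; each")
print("member lists its alignment identity to the representative (longest")
print("member, marked *). At 50%, chance similarity of random DNA already")
print("links unrelated 120-mers into one cluster.")
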