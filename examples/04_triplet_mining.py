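"""Joint-fusion online triplet mining over multi-label contexts.

Builds a tiny joint batch of labeled windows, mines every (anchor, positive,
negative) triplet satisfying the distance-and-compatibility condition
d(a,p) + alpha > d(a,n) and c(a,p) > c(a,n), and evaluates the triplet loss.
"""

import numpy as np

from tripledare import compatibility, mine_triplets, triplet_loss

rng = np.random.default_rng(4)
labels = np.array([
    [1, 0, 0, 1],   # walking, phone in hand
    [1, 0, 0, 1],   # walking, phone in hand  (same context as the anchor)
    [1, 0, 1, 0],   # walking, phone in pocket
    [0, 1, 1, 0],   # sitting, phone in pocket
    [0, 1, 0, 1],   # sitting, phone in hand
], dtype=np.int8)
embeddings = rng.standard_normal((5, 8))
alpha = 0.1

triplets = mine_triplets(embeddings, labels, alpha)
print(f"mined {len(triplets)} triplets from a batch of 5; first few:")
for t in triplets[:5]:
    print(f"  anchor {t.a}, positive {t.p} (c={compatibility(labels[t.a], labels[t.p])}), "
          f"negative {t.n} (c={compatibility(labels[t.a], labels[t.n])})")
print(f"triplet loss at margin {alpha}: {triplet_loss(embeddings, triplets, alpha):.4f}")
print("Each triplet pairs an anchor with a sample sharing more positive labels")
print("than the negative does; minimizing the hinge pulls compatible contexts")
print("together and pushes incompatible ones at least a margin apart.")
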