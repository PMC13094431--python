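"""Unsupervised tissue segmentation of a phantom section.

Simulates one section, TIC-normalizes it, picks features, runs bisecting
k-means under the correlation distance, and reports how well each
metabolic cluster co-localizes with the ground-truth tissue mask.
"""

import lipidmsi as lm
import lipidmsi.preprocess as pp
from lipidmsi.segmentation import bisecting_kmeans, score_overlap

datasets, truth = lm.simulate_dataset(lm.PhantomSpec(seed=1))
table = pp.pick_features(pp.tic_normalize(datasets[0]))
clusters = bisecting_kmeans(table, n_leaves=8, seed=1)
report = score_overlap(clusters, truth.mask)

print(f"{clusters.n_leaves} metabolic clusters; "
      f"adjusted Rand index vs tissue mask: {report.ari:.3f}")
for leaf, (label, dice, jac) in sorted(report.per_leaf.items()):
    print(f"  cluster {leaf}: best tissue {label:<8s} "
          f"Dice {dice:.2f}  Jaccard {jac:.2f}")
print("A Dice near 1.0 for the adipose-matched cluster shows the depots are "
      "recoverable from the lipid signature alone.")
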