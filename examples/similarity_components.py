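"""Inspect the similarity matrices the composite network is built from.

Computes the two DAG-based disease semantic models, the interaction-profile
kernels, and the integrated matrices on a synthetic dataset, and shows how
planted co-module membership is reflected in each.
"""

import numpy as np

from cnmda import SyntheticSpec, generate_dataset, semantic_similarity_matrices
from cnmda.pipeline import build_similarities

dataset, labels = generate_dataset(SyntheticSpec(seed=7))

ss1, ss2, has_dag = semantic_similarity_matrices(dataset.diseases, dataset.dags)
sd, s_m, kl = build_similarities(dataset)

g = labels.disease
off = ~np.eye(len(g), dtype=bool)
same = (g[:, None] == g[None, :]) & off
diff = (g[:, None] != g[None, :]) & off

print("disease semantic similarity (model 1): "
      f"within-module mean {ss1.values[same].mean():.3f}, "
      f"cross-module mean {ss1.values[diff].mean():.3f}")
print("disease semantic similarity (model 2): "
      f"within {ss2.values[same].mean():.3f}, cross {ss2.values[diff].mean():.3f}")
print("integrated disease similarity:          "
      f"within {sd.values[same].mean():.3f}, cross {sd.values[diff].mean():.3f}")

gm = labels.mirna
offm = ~np.eye(len(gm), dtype=bool)
same_m = (gm[:, None] == gm[None, :]) & offm
diff_m = (gm[:, None] != gm[None, :]) & offm
print("integrated miRNA similarity:            "
      f"within {s_m.values[same_m].mean():.3f}, cross {s_m.values[diff_m].mean():.3f}")
print(f"lncRNA kernel similarity range: [{kl.values.min():.3f}, {kl.values.max():.3f}], "
      "unit diagonal")
print("\nHigher within-module than cross-module means restore the planted "
      "grouping, which is\nwhat lets the walk propagate association evidence "
      "to the right candidates.")
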