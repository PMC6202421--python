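"""Predict miRNAs for a disease with no known miRNA associations.

All of one disease's known miRNA links are hidden; the walk is then seeded
only through the disease's lncRNA associations and its similarity to other
diseases.  The hidden miRNAs' ranks show how well the indirect evidence
recovers them.
"""

import numpy as np

from cnmda import SyntheticSpec, generate_dataset, new_disease_ranks

dataset, _ = generate_dataset(SyntheticSpec(seed=7))
disease = max(dataset.diseases.ids,
              key=lambda d: dataset.mda.values[dataset.diseases.index(d)].sum())
n_known = int(dataset.mda.values[dataset.diseases.index(disease)].sum())
print(f"hiding all {n_known} known miRNAs of {disease}")

records = new_disease_ranks(dataset, disease)
ranks = sorted(r.rank for r in records)
chance = (records[0].n_candidates + 1) / 2
print(f"ranks of the hidden miRNAs among {records[0].n_candidates + 1} candidates: "
      f"{[int(r) for r in ranks]}")
print(f"median rank {np.median(ranks):.1f} vs {chance:.1f} expected under random ranking")
print("\nA median well below chance means the lncRNA layer and disease "
      "similarity carry\nenough signal to rank a new disease's miRNAs without "
      "any direct training links.")
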