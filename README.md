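# cnmda

Prediction of disease-associated microRNAs by random walk with restart on a
three-layer composite network of lncRNAs, diseases and miRNAs.

Experimentally validating a miRNA–disease link is slow and expensive, so
computational prioritization of candidate miRNAs for a disease of interest
is a standard first step for researchers working on disease mechanisms and
biomarkers.  This package implements a composite-network approach: known
binary associations (miRNA–disease, lncRNA–disease, miRNA–lncRNA) form the
cross-layer edges of a three-layer graph whose within-layer edges are
similarities — MeSH-style DAG semantic similarity for diseases, a curated
functional-similarity matrix for miRNAs, and Gaussian interaction-profile
kernels as a fallback wherever curated similarity is unavailable.  A
restart walk over this graph then scores every miRNA for a query disease.

## Model

The composite adjacency, in layer order lncRNA / disease / miRNA, is

```
W = [ W_l    W_ld   W_lm ]
    [ W_ldᵀ  W_d    W_dm ]
    [ W_lmᵀ  W_dmᵀ  W_m  ]
```

with similarity blocks `W_l` (lncRNA kernel), `W_d` (integrated disease
similarity), `W_m` (integrated miRNA similarity) on the diagonal and binary
association blocks off it.  The transition matrix M is built per node: a
node reserves jump probability x, y or z for each other layer it has
associations in (x between lncRNA and disease layers, y between lncRNA and
miRNA, z between disease and miRNA), distributed uniformly over those
associations; the remaining mass stays within the layer, spread
proportionally to the similarity row.  Every row of M sums to 1.

The walk iterates

```
P(t+1) = (1 − δ) Mᵀ P(t) + δ P⁰
```

until ‖P(t+1) − P(t)‖₁ < 10⁻⁶, where δ is the restart probability and P⁰
the seed: an indicator on the query disease (weight β), uniform over its
known lncRNA associates (weight α), uniform over its known miRNA associates
(weight 1 − α − β).  Candidate miRNAs are ranked by the stationary miRNA
block w∞.  Defaults follow the published setting δ = 0.7 and
x = y = z = α = β = 1/3.

Disease similarity integrates two DAG-based semantic models — model 1
decays a term's contribution by Δ = 0.5 per level away from the disease,
model 2 weights terms by information content across the DAG corpus — and
falls back to the interaction-profile kernel
`K(u,v) = exp(−γ‖IP(u) − IP(v)‖²)`, γ normalized by the mean squared
profile norm, for pairs without semantic information.  miRNA similarity
uses the functional-similarity matrix where present, the kernel otherwise.

## Worked example

No external downloads are needed: the `cnmda.synthetic` module generates
self-contained datasets with planted disease–miRNA co-modules.

```python
from cnmda import Params, SyntheticSpec, generate_dataset, predict, loocv

dataset, labels = generate_dataset(SyntheticSpec(seed=7))
predictions, state = predict(dataset, "d000", Params())
for mirna, score, rank in predictions.entries[:3]:
    print(rank, mirna, round(score, 6))
print("LOOCV AUC:", round(loocv(dataset).auc, 4))
```

prints

```
1 m008 0.005296
2 m007 0.003374
3 m002 0.003204
LOOCV AUC: 0.8552
```

The three top-ranked candidates all belong to the query disease's planted
co-module, and leave-one-out cross-validation (each known association
hidden in turn and re-ranked against all unlabeled disease–miRNA pairs)
recovers held-out links with AUC ≈ 0.86, versus ≈ 0.5 on a null dataset
with the planted signal removed.  The scripts in `examples/` walk through
prediction, cross-validation, new-disease mode (all of a disease's miRNAs
hidden) and the similarity components, each printing and explaining its
numbers.

The same functionality is exposed on the command line:

```bash
cnmda simulate --out data --seed 7
cnmda predict --disease d000 --mda data/mda.tsv --lda data/lda.tsv \
              --mli data/mli.tsv --dag data/dag.tsv --fs data/fs.tsv
cnmda loocv   --mda data/mda.tsv --lda data/lda.tsv --mli data/mli.tsv
cnmda kfold   --k 5 --reps 10 --seed 1 --mda data/mda.tsv --lda data/lda.tsv --mli data/mli.tsv
```

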