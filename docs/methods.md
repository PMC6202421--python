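# Methods

## The prediction problem

Given curated binary associations between miRNAs and diseases, lncRNAs and
diseases, and miRNAs and lncRNAs, score every unlabeled disease–miRNA pair
so that true but unobserved associations rank high.  The premise is the
usual guilt-by-association one: functionally similar miRNAs tend to be
involved in similar diseases, and lncRNAs that interact with a disease's
miRNAs or are themselves disease-associated carry indirect evidence.  A
random walk with restart over a three-layer composite network propagates
the known associations globally rather than scoring each pair from its
local neighbourhood.

## Network construction

**Association layers.**  Three binary matrices: disease × miRNA (`W_dm`),
disease × lncRNA (`W_dl`), miRNA × lncRNA (`W_ml`).  Raw edge lists are
filtered so the disease and miRNA namespaces are those of the
disease–miRNA layer and the lncRNA namespace that of the filtered
lncRNA–disease layer; entries referring to unknown entities are dropped
and counted.  Entity ids match case-sensitively after whitespace trimming;
namespaces are sorted so matrix layouts are reproducible.

**Disease semantic similarity.**  Each disease carries a rooted ancestor
DAG (MeSH-style, supplied as a child–parent edge file).  Model 1 gives the
disease's own term contribution 1 and each ancestor Δ·max over its
children's contributions, evaluated in increasing distance from the
disease so children are always valued first (the max makes evaluation
order within a level irrelevant).  Δ defaults to 0.5, the customary value
for this construction, exposed as a parameter.  Model 2 weights a term by
−log(number of DAGs containing it / number of DAGs in the corpus); the
corpus is the set of supplied DAGs, so the shared root carries zero
information.  The logarithm base cancels in the similarity ratio; natural
log is used.  Either model scores a pair as the sum of both diseases'
contributions over shared terms divided by the sum of their total semantic
values; self-similarity is 1 by definition, and a 0/0 (both totals zero)
is guarded to 0 for distinct diseases.

**Kernels.**  The Gaussian interaction-profile kernel
`K(u,v) = exp(−γ‖IP(u) − IP(v)‖²)` with `γ = γ′ / mean‖IP‖²` is computed
from the rows of `W_dm` for diseases, its columns for miRNAs, and the
columns of `W_dl` for lncRNAs.  The lncRNA profile source is genuinely
open — lncRNA–miRNA profiles are a defensible alternative — so it is a
parameter (`lncrna_profile`), with disease profiles as the default since
the prediction target lives on the disease side.  γ′ defaults to 1 for all
three kernels.  An all-zero profile matrix leaves γ undefined and is
rejected; the synthetic generator re-wires isolated entities precisely so
this cannot happen in generated data.

**Integration.**  Disease pairs use the mean of the two semantic models
when both diseases have a DAG and the models give a positive score, the
kernel otherwise; miRNA pairs use the functional-similarity matrix where
it has a positive entry, the kernel otherwise.  These predicates are the
package's reading of "has semantic/functional similarity"; they are the
natural zero-information cutoffs and are documented here because no
sharper definition exists in the lineage of this construction.

**Transition matrix.**  Node-wise: an entity with associations into
another layer reserves that layer's jump parameter (x lncRNA↔disease, y
lncRNA↔miRNA, z disease↔miRNA), distributed uniformly over its
associations; the residual mass stays within the layer, proportional to
the similarity row.  Rows always sum to 1 because kernel similarities are
strictly positive — this is asserted, not silently repaired.  Similarity
diagonals (self-loops) are kept in the normalization, treating the
similarity rows exactly as written; `drop_self_loops` provides the common
variant that zeroes them first.  The published form of the within-layer
cases contains two typographical slips (a duplicated guard condition and a
transposed index); the implementation uses the unique reading under which
the four cases are exhaustive and the matrix row-stochastic, which the
test suite verifies directly.

## The walk

`P(t+1) = (1−δ) Mᵀ P(t) + δ P⁰`.  The transpose convention is deliberate:
with a row-stochastic M, multiplying the probability vector by Mᵀ is the
standard forward propagation that conserves total mass (the untransposed
form does not).  The map is a (1−δ)-contraction in L1, so the residual
after t steps is at most 2(1−δ)ᵗ; at δ = 0.7 and tolerance 10⁻⁶ this caps
iterations at 13.  A direct linear solve of `(I − (1−δ)Mᵀ)P = δP⁰` serves
as an independent oracle in tests and is exposed for small networks.

**Seeding.**  Per query disease: indicator on the disease (weight β),
uniform over its known lncRNA associates (α), uniform over its known miRNA
associates (1−α−β).  A block with no associates cannot receive mass; its
weight is redistributed proportionally over the remaining blocks rather
than silently dropped, which keeps P⁰ a probability vector and makes
new-disease prediction (no known miRNAs at all) a well-defined special
case of the same rule.  Defaults δ = 0.7, x = y = z = α = β = 1/3, L1
tolerance 10⁻⁶, iteration cap 1000.

## Evaluation protocol

**LOOCV.**  Each known association is zeroed in turn; kernels and
integrated similarities are recomputed from the masked matrix (masking
changes interaction profiles, so honest evaluation recomputes them —
`recompute_kernels=False` reuses the full-data similarities for speed and
changes the AUC by well under 0.1 at the scales tested); the transition
matrix is rebuilt; a walk is run from every disease (batched as one matrix
iteration); and the hidden pair's score is mid-ranked against the scores
of all pairs unlabeled in the full data — the global candidate set.  A
per-disease candidate set is available as an option, as it is the more
common convention elsewhere.

**k-fold.**  Known associations are randomly partitioned into k folds
(seeded; equal seeds give bit-identical results), each fold masked as a
block and its pairs ranked the same way.  Repetitions default to 100 to
match the mean ± sd reporting convention; the standard deviation is
reported both across repetitions and across folds, since either could be
meant by a ± value.  k equal to the number of associations reduces exactly
to LOOCV.

**AUC.**  The rank-sum (Mann–Whitney) identity with ties counted half:
each positive contributes `(n + 1 − rank)/n` over its n candidates, and
the AUC is the mean over positives.  This equals brute-force pair counting
exactly (verified on random instances) and handles per-fold variation in
candidate counts.  ROC points are emitted by sweeping the normalized rank
threshold.

**New-disease mode.**  All of one disease's known miRNAs are hidden; the
walk is seeded through the lncRNA block and the disease indicator alone,
and each hidden miRNA is ranked among all of that disease's candidates.

## Synthetic data

The generator emulates the statistical shape of the curated inputs at desk
scale, not their content: entities are partitioned into co-modules, and
each association matrix is Bernoulli(p_within) inside a module and
Bernoulli(p_background) across.  Default shape: 20 lncRNAs, 30 diseases,
40 miRNAs, 3 modules, p_within = 0.5, p_background = 0.02 — sizes chosen
so a full LOOCV (~200 folds, each rebuilding the model and running ~30
walks on a ~90-node network) completes in under a second while leaving
every code path non-degenerate.  Disease DAGs hang off one shared root,
with per-module ancestor chains (depth 3, branching 2) so same-module
diseases share deep ancestors and cross-module pairs share only the root;
depth 0 degenerates to identical single-root DAGs with similarity 1
everywhere.  The functional-similarity matrix is an exchangeable
symmetrized uniform background on [0, 0.3] plus a within-module boost
(default 0.5), clipped to [0, 1].  Isolated entities are re-wired with one
random edge because kernel bandwidths require non-degenerate profiles.
One RNG stream per artifact (associations, DAGs, functional similarity),
derived from the master seed by fixed offsets, so changing one shape
parameter never perturbs unrelated draws.

The null configuration used in tests and the acceptance script sets
p_within = p_background = 0.18, matching the planted configuration's
overall edge density, so the null differs only in the absence of module
structure.  What passing tests show: the pipeline recovers planted
block-structured signal transported through association profiles, DAG
ancestry and the functional-similarity matrix.  What they do not show:
performance on real curated data, whose degree distributions are heavily
skewed, whose MeSH hierarchy is far deeper and irregular, and whose
similarity matrices have very different spectra.  Published cross-
validation figures on curated resources are therefore not comparable to
the synthetic AUCs computed here.

## Numerical conventions

- Similarity matrices are validated symmetric within 1e-9 on input,
  then exactly symmetrized; transition row sums are checked within 1e-12.
- Association blocks are stored sparse inside the composite network;
  similarity blocks and the assembled transition matrix are dense (the
  intended scale is thousands of nodes at most).
- Exact score ties in rankings break lexicographically by miRNA id;
  AUC ties count half (midranks).
- Convergence is declared on the L1 difference of consecutive iterates;
  non-convergence raises, carrying the last residual, and a failed
  cross-validation fold is excluded with a warning rather than poisoning
  the aggregate.

## Known limitations

- The stationary disease and lncRNA blocks are computed but unused beyond
  normalization; only the miRNA block is ranked.
- No treatment of association confidence levels — all curated edges are
  binary and equally weighted.
- The three-layer structure is fixed; no generalization to more layers.
- Functional similarity is an input; the package does not re-derive it
  from miRNA target sets.
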