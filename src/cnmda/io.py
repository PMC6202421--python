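"""Readers and writers for the TSV formats used throughout the package.

Formats
-------
* association edge lists: two tab- (or whitespace-) separated columns,
  ``row-entity-id  col-entity-id``, optional ``#`` comments, optional header;
* disease hierarchies: two columns ``child-id  parent-id``;
* similarity matrices: square TSV with a header row and an id column;
* ranked predictions: ``disease  miRNA  score  rank``.

Entity ids are matched case-sensitively after trimming surrounding
whitespace; namespaces are sorted lexicographically so matrix layout is
deterministic across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    AssociationMatrix,
    ConsistencyError,
    Dataset,
    DegenerateDataError,
    DiseaseDAG,
    EntityKind,
    EntityNamespace,
    FormatError,
    SimilarityMatrix,
)

__all__ = [
    "read_association_table",
    "filter_to_shared_entities",
    "read_dag_file",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_association_table",
    "write_predictions",
]

logger = logging.getLogger(__name__)


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Parse a two-column id file, skipping blank lines, comments and an
    optional single header line."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}: {line!r}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def read_association_table(
    path: str | Path,
    row_kind: EntityKind,
    col_kind: EntityKind,
    *,
    rows: EntityNamespace | None = None,
    cols: EntityNamespace | None = None,
) -> AssociationMatrix:
    """Read a binary association matrix from a two-column edge list.

    Duplicate lines collapse to a single 1.  When ``rows``/``cols`` are not
    supplied the namespaces are the lexicographically sorted sets of ids seen
    in the file; supplying them pins the layout (ids outside the supplied
    namespace raise :class:`ConsistencyError`).
    """
    pairs = _read_pairs(path)
    if pairs and pairs[0] == (row_kind, col_kind):  # tolerated kind-named header
        pairs = pairs[1:]
    if rows is None:
        if not pairs:
            raise DegenerateDataError(f"{path}: empty edge list and no row namespace supplied")
        rows = EntityNamespace.from_ids(row_kind, (r for r, _ in pairs))
    if cols is None:
        if not pairs:
            raise DegenerateDataError(f"{path}: empty edge list and no column namespace supplied")
        cols = EntityNamespace.from_ids(col_kind, (c for _, c in pairs))
    values = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    for r, c in pairs:
        values[rows.index(r), cols.index(c)] = 1
    logger.info(
        "read %s: %d %s x %d %s, %d edges",
        path, len(rows), row_kind, len(cols), col_kind, int(values.sum()),
    )
    return AssociationMatrix(rows, cols, values)


def write_association_table(path: str | Path, matrix: AssociationMatrix) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(*np.nonzero(matrix.values)):
            fh.write(f"{matrix.rows.ids[i]}\t{matrix.cols.ids[j]}\n")


def filter_to_shared_entities(
    mda: AssociationMatrix,
    lda: AssociationMatrix,
    mli: AssociationMatrix,
    *,
    dags: Mapping[str, DiseaseDAG] | None = None,
    fs: SimilarityMatrix | None = None,
) -> Dataset:
    """Restrict the three raw association layers to mutually known entities.

    The miRNA-disease layer defines the disease and miRNA namespaces.
    lncRNA-disease rows for diseases absent from it are dropped, then
    miRNA-lncRNA entries are dropped when the miRNA is unknown to the
    miRNA-disease layer or the lncRNA is unknown to the filtered
    lncRNA-disease layer.  Idempotent on already-consistent inputs.
    """
    diseases = mda.rows
    mirnas = mda.cols

    kept_d = [d for d in lda.rows.ids if d in diseases]
    n_lda_before = int(lda.values.sum())
    lda_vals = np.zeros((len(diseases), len(lda.cols)), dtype=np.uint8)
    for d in kept_d:
        lda_vals[diseases.index(d), :] = lda.values[lda.rows.index(d), :]
    # lncRNAs that survive are those of the (re-rowed) LDA layer
    lncrnas = lda.cols
    if len(lncrnas) == 0:
        raise DegenerateDataError("no lncRNAs remain after filtering")
    lda_f = AssociationMatrix(diseases, lncrnas, lda_vals)
    n_lda_dropped = n_lda_before - int(lda_f.values.sum())

    mli_vals = np.zeros((len(mirnas), len(lncrnas)), dtype=np.uint8)
    n_mli_before = int(mli.values.sum())
    for m in mli.rows.ids:
        if m not in mirnas:
            continue
        for l in mli.cols.ids:
            if l not in lncrnas:
                continue
            mli_vals[mirnas.index(m), lncrnas.index(l)] = mli.values[
                mli.rows.index(m), mli.cols.index(l)
            ]
    mli_f = AssociationMatrix(mirnas, lncrnas, mli_vals)
    n_mli_dropped = n_mli_before - int(mli_f.values.sum())

    if len(diseases) == 0 or len(mirnas) == 0:
        raise DegenerateDataError("empty disease or miRNA namespace")
    logger.info(
        "filtered dataset: %d lncRNAs / %d diseases / %d miRNAs; dropped %d LDAs, %d MLIs",
        len(lncrnas), len(diseases), len(mirnas), n_lda_dropped, n_mli_dropped,
    )
    return Dataset(mda, lda_f, mli_f, dags=dags, fs=fs)


def read_dag_file(
    path: str | Path,
    diseases: Iterable[str],
) -> dict[str, DiseaseDAG]:
    """Build per-disease ancestor DAGs from a global child-parent edge file.

    For each disease of interest D the node set T(D) is D plus every term
    reachable by repeatedly following child->parent edges, and E(D) the
    induced parent->child edges.  A disease absent from the edge file becomes
    a single-node DAG (with a warning).  A cycle anywhere in the global file
    is rejected, naming one offending edge.
    """
    pairs = _read_pairs(path)
    g = nx.DiGraph()  # edge direction: parent -> child
    for child, parent in pairs:
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        parent, child = cycle[0][0], cycle[0][1]
        raise FormatError(f"{path}: hierarchy contains a cycle through edge ({child!r} -> parent {parent!r})")
    out: dict[str, DiseaseDAG] = {}
    for d in diseases:
        if d not in g:
            logger.warning("disease %r absent from %s; using a single-node DAG", d, path)
            out[d] = DiseaseDAG(d, frozenset({d}), frozenset())
            continue
        nodes = nx.ancestors(g, d) | {d}
        edges = frozenset((p, c) for p, c in g.edges() if p in nodes and c in nodes)
        out[d] = DiseaseDAG(d, frozenset(nodes), edges)
    return out


def read_similarity_matrix(
    path: str | Path,
    kind: EntityKind,
    *,
    tag: str = "",
) -> SimilarityMatrix:
    """Read a square similarity matrix (TSV, header row + id column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids_r = [str(i).strip() for i in df.index]
    ids_c = [str(c).strip() for c in df.columns]
    if ids_r != ids_c:
        raise FormatError(f"{path}: row and column ids differ (non-square or misordered matrix)")
    ns = EntityNamespace(kind, tuple(ids_r))
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > 1e-9:
        raise FormatError(f"{path}: matrix asymmetric (max |S - S^T| = {asym:.3g})")
    return SimilarityMatrix(ns, values, tag or Path(path).stem)


def write_similarity_matrix(path: str | Path, sim: SimilarityMatrix) -> None:
    df = pd.DataFrame(sim.values, index=sim.namespace.ids, columns=sim.namespace.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def align_similarity(sim: SimilarityMatrix, namespace: EntityNamespace) -> SimilarityMatrix:
    """Reindex a similarity matrix onto a target namespace.

    Entities missing from the source matrix get zero rows/columns and a unit
    diagonal — downstream integration treats a zero entry as "no similarity
    available" and falls back to the kernel.
    """
    n = len(namespace)
    values = np.eye(n)
    src = {name: i for i, name in enumerate(sim.namespace.ids)}
    present = [(j, src[name]) for j, name in enumerate(namespace.ids) if name in src]
    for j, sj in present:
        for k, sk in present:
            values[j, k] = sim.values[sj, sk]
    return SimilarityMatrix(namespace, values, sim.tag)


def write_predictions(path: str | Path, predictions: "RankedPredictions") -> None:
    """Write ranked candidate miRNAs as ``disease  miRNA  score  rank``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tmiRNA\tscore\trank\n")
        for mirna, score, rank in predictions.entries:
            fh.write(f"{predictions.disease}\t{mirna}\t{score:.17g}\t{rank}\n")


def write_dataset(outdir: str | Path, dataset: Dataset, *, dag_edges: Sequence[tuple[str, str]] | None = None) -> None:
    """Dump a dataset as the TSV file set consumed by the CLI subcommands."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_association_table(outdir / "mda.tsv", dataset.mda)
    write_association_table(outdir / "lda.tsv", dataset.lda)
    write_association_table(outdir / "mli.tsv", dataset.mli)
    if dag_edges is None and dataset.dags:
        edges = sorted({e for dag in dataset.dags.values() for e in dag.edges})
        dag_edges = [(child, parent) for parent, child in edges]
    if dag_edges:
        with open(outdir / "dag.tsv", "w", encoding="utf-8") as fh:
            for child, parent in dag_edges:
                fh.write(f"{child}\t{parent}\n")
    if dataset.fs is not None:
        write_similarity_matrix(outdir / "fs.tsv", dataset.fs)
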