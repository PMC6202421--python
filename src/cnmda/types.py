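"""Core containers: entity namespaces, binary association matrices,
similarity matrices, disease DAGs and the assembled dataset.

All matrices are indexed through :class:`EntityNamespace` objects so that a
row/column position always maps back to a stable entity identifier.  Layout
order is fixed when a namespace is created (readers sort lexicographically)
and reused everywhere downstream, which makes every matrix in the pipeline
bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EntityKind",
    "EntityNamespace",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "Dataset",
    "CnmdaError",
    "FormatError",
    "ConsistencyError",
    "DegenerateDataError",
    "ParameterError",
]

ENTITY_KINDS = ("lncRNA", "disease", "miRNA")
EntityKind = str

SYMMETRY_TOL = 1e-9


class CnmdaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CnmdaError):
    """A file or matrix does not satisfy its format contract."""


class ConsistencyError(CnmdaError):
    """Identifiers or dimensions disagree across inputs."""


class DegenerateDataError(CnmdaError):
    """Input data leave a layer empty or a kernel undefined."""


class ParameterError(CnmdaError):
    """A model parameter is outside its valid range."""


@dataclass(frozen=True)
class EntityNamespace:
    """An ordered set of unique entity identifiers of one kind.

    The position of an id in ``ids`` is its matrix index; all matrices over
    this namespace share that layout.
    """

    kind: EntityKind
    ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise ParameterError(f"unknown entity kind {self.kind!r}; expected one of {ENTITY_KINDS}")
        if len(self.ids) == 0:
            raise DegenerateDataError(f"empty {self.kind} namespace")
        index = {}
        for i, name in enumerate(self.ids):
            if name in index:
                raise ConsistencyError(f"duplicate {self.kind} id {name!r}")
            index[name] = i
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_ids(cls, kind: EntityKind, ids: Iterable[str], *, sort: bool = True) -> "EntityNamespace":
        ids = tuple(sorted(set(ids)) if sort else ids)
        return cls(kind, ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConsistencyError(f"{self.kind} id {name!r} not in namespace") from None

    def subset(self, keep: Iterable[str]) -> "EntityNamespace":
        """Namespace restricted to ``keep``, preserving the current order."""
        keep = set(keep)
        return EntityNamespace(self.kind, tuple(i for i in self.ids if i in keep))


@dataclass
class AssociationMatrix:
    """Binary bipartite association matrix with named row/column namespaces."""

    rows: EntityNamespace
    cols: EntityNamespace
    values: np.ndarray  # (len(rows), len(cols)) uint8, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ConsistencyError(
                f"association matrix shape {self.values.shape} does not match "
                f"namespaces ({len(self.rows)}, {len(self.cols)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "AssociationMatrix":
        return AssociationMatrix(self.cols, self.rows, self.values.T)

    def has_edge(self, row_id: str, col_id: str) -> bool:
        return bool(self.values[self.rows.index(row_id), self.cols.index(col_id)])

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.rows, self.cols, self.values.copy())


@dataclass
class SimilarityMatrix:
    """Square symmetric non-negative similarity matrix over one namespace.

    ``tag`` records provenance (e.g. ``"SS1"``, ``"KD"``, ``"SD"``) for
    logging and error messages only.
    """

    namespace: EntityNamespace
    values: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.namespace)
        if self.values.shape != (n, n):
            raise ConsistencyError(
                f"similarity matrix {self.tag or '<untagged>'} shape {self.values.shape} "
                f"does not match namespace size {n}"
            )
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise FormatError(
                f"similarity matrix {self.tag or '<untagged>'} asymmetric "
                f"(max |S - S^T| = {asym:.3g} > {SYMMETRY_TOL:g})"
            )
        if (self.values < 0).any():
            raise FormatError(f"similarity matrix {self.tag or '<untagged>'} has negative entries")
        # exact symmetry downstream
        self.values = (self.values + self.values.T) / 2.0

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.namespace, self.values.copy(), self.tag)


@dataclass
class DiseaseDAG:
    """Rooted ancestor DAG of a single disease.

    ``nodes`` is T(D): the disease's own term plus every ancestor term, and
    ``edges`` the induced parent->child pairs E(D).  ``term`` names the node
    that represents the disease itself (ordinarily the disease id; synthetic
    hierarchies may map several diseases onto a shared term).
    """

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (parent, child)
    term: str | None = None

    def __post_init__(self) -> None:
        if self.term is None:
            self.term = self.disease
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset(self.edges)
        if self.term not in self.nodes:
            raise ConsistencyError(f"DAG for {self.disease!r}: term {self.term!r} not in node set")
        for parent, child in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ConsistencyError(
                    f"DAG for {self.disease!r}: edge ({parent!r}, {child!r}) leaves node set"
                )

    def children_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {n: set() for n in self.nodes}
        for parent, child in self.edges:
            out[parent].add(child)
        return out

    def parents_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {n: set() for n in self.nodes}
        for parent, child in self.edges:
            out[child].add(parent)
        return out


@dataclass
class Dataset:
    """The three association layers plus optional similarity side information.

    Invariants: ``mda`` (disease x miRNA), ``lda`` (disease x lncRNA) and
    ``mli`` (miRNA x lncRNA) share namespaces — every disease in ``lda`` and
    every miRNA/lncRNA in ``mli`` appears in the corresponding ``mda``/``lda``
    namespace.  Use :func:`cnmda.io.filter_to_shared_entities` to establish
    this from raw edge lists.
    """

    mda: AssociationMatrix
    lda: AssociationMatrix
    mli: AssociationMatrix
    dags: Mapping[str, DiseaseDAG] | None = None
    fs: SimilarityMatrix | None = None

    def __post_init__(self) -> None:
        if self.mda.rows.kind != "disease" or self.mda.cols.kind != "miRNA":
            raise ConsistencyError("mda must be disease x miRNA")
        if self.lda.rows.kind != "disease" or self.lda.cols.kind != "lncRNA":
            raise ConsistencyError("lda must be disease x lncRNA")
        if self.mli.rows.kind != "miRNA" or self.mli.cols.kind != "lncRNA":
            raise ConsistencyError("mli must be miRNA x lncRNA")
        if self.lda.rows is not self.mda.rows and self.lda.rows.ids != self.mda.rows.ids:
            raise ConsistencyError("lda and mda disease namespaces differ")
        if self.mli.rows.ids != self.mda.cols.ids:
            raise ConsistencyError("mli and mda miRNA namespaces differ")
        if self.mli.cols.ids != self.lda.cols.ids:
            raise ConsistencyError("mli and lda lncRNA namespaces differ")
        if self.fs is not None and self.fs.namespace.ids != self.mirnas.ids:
            raise ConsistencyError("functional-similarity namespace differs from miRNA namespace")

    @property
    def diseases(self) -> EntityNamespace:
        return self.mda.rows

    @property
    def mirnas(self) -> EntityNamespace:
        return self.mda.cols

    @property
    def lncrnas(self) -> EntityNamespace:
        return self.lda.cols

    def known_pairs(self) -> list[tuple[str, str]]:
        """All known (disease, miRNA) associations in namespace order."""
        di, mi = np.nonzero(self.mda.values)
        return [(self.diseases.ids[d], self.mirnas.ids[m]) for d, m in zip(di, mi)]

    def with_mda(self, values: np.ndarray) -> "Dataset":
        """Copy of the dataset with a replacement disease x miRNA matrix."""
        return Dataset(
            AssociationMatrix(self.mda.rows, self.mda.cols, values),
            self.lda,
            self.mli,
            self.dags,
            self.fs,
        )
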