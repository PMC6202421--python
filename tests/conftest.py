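"""Shared fixtures: tiny hand-built datasets and random composite networks."""

import numpy as np
import pytest

from cnmda import (
    AssociationMatrix,
    Dataset,
    DiseaseDAG,
    EntityNamespace,
    SyntheticSpec,
    build_model,
    generate_dataset,
)


@pytest.fixture
def tiny_dataset() -> Dataset:
    """2 lncRNAs / 2 diseases / 3 miRNAs with hand-readable associations.

    d1 is associated with l1, l2 and m1; d2 with l1 and m2, m3.
    """
    lnc = EntityNamespace("lncRNA", ("l1", "l2"))
    dis = EntityNamespace("disease", ("d1", "d2"))
    mir = EntityNamespace("miRNA", ("m1", "m2", "m3"))
    mda = AssociationMatrix(dis, mir, np.array([[1, 0, 0], [0, 1, 1]]))
    lda = AssociationMatrix(dis, lnc, np.array([[1, 1], [1, 0]]))
    mli = AssociationMatrix(mir, lnc, np.array([[1, 0], [0, 1], [1, 1]]))
    return Dataset(mda, lda, mli)


@pytest.fixture
def minimal_dataset() -> Dataset:
    """1 lncRNA / 1 disease / 1 miRNA, fully connected."""
    lnc = EntityNamespace("lncRNA", ("l1",))
    dis = EntityNamespace("disease", ("d1",))
    mir = EntityNamespace("miRNA", ("m1",))
    return Dataset(
        AssociationMatrix(dis, mir, np.ones((1, 1))),
        AssociationMatrix(dis, lnc, np.ones((1, 1))),
        AssociationMatrix(mir, lnc, np.ones((1, 1))),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The default planted-signal synthetic dataset (seed 7)."""
    return generate_dataset(SyntheticSpec())


def random_transition(seed: int, max_sizes=(10, 12, 14)):
    """A random composite transition matrix built through the full pipeline
    on a small random synthetic dataset."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(
        nl=int(rng.integers(2, max_sizes[0] + 1)),
        nd=int(rng.integers(2, max_sizes[1] + 1)),
        nm=int(rng.integers(2, max_sizes[2] + 1)),
        n_groups=int(rng.integers(1, 4)),
        p_within=float(rng.uniform(0.3, 0.9)),
        p_background=float(rng.uniform(0.0, 0.2)),
        seed=seed,
    )
    ds, _ = generate_dataset(spec)
    net, t = build_model(ds)
    return ds, net, t


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """Disease A with a single parent R (the worked two-node hierarchy)."""
    return DiseaseDAG("A", frozenset({"A", "R"}), frozenset({("R", "A")}))
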