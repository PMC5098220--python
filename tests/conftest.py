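import numpy as np
import pytest

from ppisign import (
    AnnotationStore,
    HomologMap,
    Pair,
    WorldConfig,
    generate_world,
)


@pytest.fixture
def tiny_store():
    """Four annotated proteins over a six-term vocabulary."""
    store = AnnotationStore()
    for protein, terms in {
        "A": {"GO:0000001", "GO:0000002"},
        "B": {"GO:0000002", "GO:0000003"},
        "C": {"GO:0000003", "GO:0000004"},
        "D": {"GO:0000005"},
    }.items():
        for t in terms:
            store.add(protein, t)
    store.n_read = sum(len(s) for s in store.protein_terms.values())
    return store


@pytest.fixture
def tiny_hmap():
    return HomologMap(
        hits={
            "A": [("B", 0.5), ("C", 1.0)],
            "B": [("C", 0.1)],
            # D and E have no homologs
        },
        e_cutoff=10.0,
    )


@pytest.fixture(scope="session")
def small_world():
    """A small but learnable world reused by pipeline-level tests."""
    cfg = WorldConfig(
        n_proteins=2000,
        n_activation=90,
        n_inhibition=30,
        n_others=90,
        n_universe_extra=200,
        seed=7,
    )
    return generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
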