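import numpy as np
import pytest

from ppistack.kb import AnnotationStore
from ppistack.ontology import GoDag


@pytest.fixture
def toy_dag() -> GoDag:
    """Per-branch toy: root r with children a (-> c) and b.

    Depths: r=0, a=b=1, c=2. Built identically in each of the three
    branches (term ids prefixed with the branch).
    """
    dag = GoDag()
    for branch in ("BP", "MF", "CC"):
        r, a, b, c = (f"{branch}:{x}" for x in "rabc")
        dag.add_root(r, branch)
        dag.add_term(a, [r])
        dag.add_term(b, [r])
        dag.add_term(c, [a])
    return dag


@pytest.fixture
def toy_store() -> AnnotationStore:
    store = AnnotationStore()
    store.ingest_record(
        {
            "id": "P1",
            "go_bp": ["BP:c"],
            "go_mf": ["MF:a"],
            "go_cc": ["CC:a"],
            "domains": ["d1"],
            "pathways": ["p1", "p2"],
            "sequence": "ACDEFGH",
        }
    )
    store.ingest_record(
        {
            "id": "P2",
            "go_bp": ["BP:a", "BP:b"],
            "go_mf": ["MF:a"],
            "go_cc": ["CC:b"],
            "domains": ["d3"],
            "pathways": ["p2", "p3"],
            "sequence": "CDEFGHI",
        }
    )
    return store


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
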