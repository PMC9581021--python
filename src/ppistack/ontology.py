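"""Gene Ontology style DAG and edge-based semantic similarity.

The similarity of two terms is the Pekar/Staab edge-based measure: with
``lcs`` the deepest common ancestor (lowest common subsumer),

    sim(t1, t2) = depth(lcs) / (d(t1, lcs) + d(t2, lcs) + depth(lcs))

where depth and distances are minimal edge counts along child->parent
edges. Term sets are aggregated by the symmetric best-match average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

logger = logging.getLogger(__name__)

BRANCHES = ("BP", "MF", "CC")


class CrossBranchError(ValueError):
    """Raised when two terms from different branches are compared."""


@dataclass
class GoDag:
    """Rooted DAG per ontology branch, edges directed child -> parent."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    roots: dict[str, str] = field(default_factory=dict)  # branch -> root term
    # memoized per-term ancestor maps and per-pair similarities; invalidated
    # on structural edits
    _ancestor_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _sim_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _invalidate(self) -> None:
        self._ancestor_cache.clear()
        self._sim_cache.clear()

    def add_root(self, term: str, branch: str) -> None:
        if branch not in BRANCHES:
            raise ValueError(f"unknown branch {branch!r}")
        self.graph.add_node(term, branch=branch)
        self.roots[branch] = term
        self._invalidate()

    def add_term(self, term: str, parents: Iterable[str]) -> None:
        parents = list(parents)
        if not parents:
            raise ValueError(f"non-root term {term!r} needs at least one parent")
        branch = self.graph.nodes[parents[0]]["branch"]
        self.graph.add_node(term, branch=branch)
        for parent in parents:
            if self.graph.nodes[parent]["branch"] != branch:
                raise ValueError(f"term {term!r} has parents in different branches")
            self.graph.add_edge(term, parent)
        self._invalidate()

    def branch_of(self, term: str) -> str:
        return self.graph.nodes[term]["branch"]

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors_with_distance(self, term: str) -> dict[str, int]:
        """Every ancestor of ``term`` (term included, distance 0) with the
        minimal edge count along child->parent edges."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self.graph, term)
            self._ancestor_cache[term] = cached
        return cached

    def depth(self, term: str) -> int:
        """Minimal edge distance from the branch root down to ``term``."""
        root = self.roots[self.branch_of(term)]
        return self.ancestors_with_distance(term)[root]

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        for term in self.graph.nodes:
            root = self.roots[self.branch_of(term)]
            if root not in self.ancestors_with_distance(term):
                raise ValueError(f"term {term!r} cannot reach its branch root")

    # -- file format: header naming branch roots, then child<TAB>parent ----

    def save(self, path: str | Path) -> None:
        lines = ["#roots\t" + "\t".join(f"{b}={r}" for b, r in sorted(self.roots.items()))]
        for child, parent in sorted(self.graph.edges):
            lines.append(f"{child}\t{parent}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GoDag":
        dag = cls()
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#roots\t"):
            raise ValueError(f"{path}: missing '#roots' header naming branch roots")
        for item in lines[0].split("\t")[1:]:
            branch, root = item.split("=", 1)
            dag.add_root(root, branch)
        pending: list[tuple[str, str]] = []
        for line in lines[1:]:
            if not line.strip() or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            pending.append((child, parent))
        # parents may appear after their own child lines; resolve iteratively
        while pending:
            progressed = []
            for child, parent in pending:
                if parent in dag.graph:
                    branch = dag.graph.nodes[parent]["branch"]
                    dag.graph.add_node(child, branch=branch)
                    dag.graph.add_edge(child, parent)
                else:
                    progressed.append((child, parent))
            if len(progressed) == len(pending):
                raise ValueError(f"{path}: dangling parents {sorted({p for _, p in progressed})}")
            pending = progressed
        dag.validate()
        return dag


def lcs_depth(dag: GoDag, t1: str, t2: str) -> tuple[str, int, int, int]:
    """Lowest common subsumer of two same-branch terms.

    Returns ``(lcs, depth(lcs), d(t1, lcs), d(t2, lcs))``. The LCS is the
    *lowest* common ancestor: minimal combined distance to the two terms,
    with remaining ties broken by maximal depth and then lexicographic term
    id, for determinism. (In a tree the closest common ancestor is also the
    deepest one; in a multi-parent DAG depth alone can prefer a strict
    ancestor over the term itself, which would break sim(t, t) = 1, so
    proximity is the primary criterion.)
    """
    if dag.branch_of(t1) != dag.branch_of(t2):
        raise CrossBranchError(
            f"terms {t1!r} ({dag.branch_of(t1)}) and {t2!r} ({dag.branch_of(t2)}) "
            "are in different branches"
        )
    anc1 = dag.ancestors_with_distance(t1)
    anc2 = dag.ancestors_with_distance(t2)
    common = anc1.keys() & anc2.keys()
    # every term reaches its branch root, so `common` is never empty
    best: Optional[str] = None
    best_key: Optional[tuple] = None
    for term in common:
        key = (anc1[term] + anc2[term], -dag.depth(term), term)
        if best_key is None or key < best_key:
            best, best_key = term, key
    assert best is not None
    return best, dag.depth(best), anc1[best], anc2[best]


def pekar_similarity(dag: GoDag, t1: str, t2: str) -> float:
    """Edge-based similarity in [0, 1]; 0 when both terms are the root."""
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cached = dag._sim_cache.get(key)
    if cached is not None:
        return cached
    lcs, depth, d1, d2 = lcs_depth(dag, t1, t2)
    denom = d1 + d2 + depth
    sim = 0.0 if denom == 0 else depth / denom
    dag._sim_cache[key] = sim
    return sim


def pair_go_similarity(
    dag: GoDag, terms_a: Iterable[str], terms_b: Iterable[str], branch: str
) -> float:
    """Symmetric best-match average over two term sets of one branch.

    Terms not in the DAG or outside ``branch`` are dropped; an empty side
    yields 0 (the missing-annotation convention).
    """
    ta = sorted(t for t in terms_a if t in dag and dag.branch_of(t) == branch)
    tb = sorted(t for t in terms_b if t in dag and dag.branch_of(t) == branch)
    if not ta or not tb:
        return 0.0
    sims = {(x, y): pekar_similarity(dag, x, y) for x in ta for y in tb}
    forward = sum(max(sims[(x, y)] for y in tb) for x in ta) / len(ta)
    backward = sum(max(sims[(x, y)] for x in ta) for y in tb) / len(tb)
    return (forward + backward) / 2.0
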