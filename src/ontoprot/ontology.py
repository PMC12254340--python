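"""Clinical-terminology graph construction and hierarchy cleanup.

Concepts are connected by "is a" subtype relations; edges point from the more
specific concept (child) to the more general one (parent).  Real terminology
releases are nominally hierarchical but contain occasional cycles from
cross-linked or overlapping classifications, so the graph is first reduced to a
DAG by a deterministic, hierarchy-preserving cycle breaker, and a
cohort-specific subgraph is then cut out around the diagnoses actually present
in a cohort.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

#: Relationship type identifier for "is a" subtype relations (RF2 convention).
IS_A_TYPE = "116680003"


class OntologyParseError(ValueError):
    """A concept or relationship table row could not be parsed."""


class OntologyValidationError(ValueError):
    """Parsed tables violate a structural invariant."""


@dataclass
class AcyclicOntology:
    """A DAG derived from a possibly-cyclic concept graph.

    ``removed_edges`` together with ``graph.edges`` partitions the input edge
    set; every removed edge participated in at least one directed cycle.
    """

    graph: nx.DiGraph
    removed_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self):
        return self.graph.nodes


@dataclass
class CohortSubgraph:
    """Induced subgraph around the cohort's diagnosis concepts."""

    graph: nx.DiGraph
    diagnosis_nodes: set[str]
    up_levels: int
    down_levels: int


def load_ontology(
    concept_table,
    relationship_table,
    isa_code: str = IS_A_TYPE,
    concept_columns: tuple[str, str, str] = ("id", "active", "term"),
    relationship_columns: tuple[str, str, str] = ("sourceId", "destinationId", "typeId"),
) -> nx.DiGraph:
    """Build the directed "is a" concept graph from two TSV tables.

    Only active, non-duplicated concepts enter the graph; edges referencing
    inactive or unknown concepts, self-loops, and non-"is a" rows are dropped
    (counts are kept in ``graph.graph["dropped"]``).  Duplicate concept rows
    are tolerated when their terms agree and rejected otherwise.
    """
    id_col, active_col, term_col = concept_columns
    concepts: dict[str, str] = {}
    with open(concept_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {id_col, active_col, term_col} - set(reader.fieldnames or ())
        if missing:
            raise OntologyParseError(
                f"concept table lacks column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            cid, active, term = row.get(id_col), row.get(active_col), row.get(term_col)
            if cid in (None, "") or active in (None, "") or term is None:
                raise OntologyParseError(f"malformed concept row at line {lineno}")
            if active not in ("0", "1"):
                raise OntologyParseError(
                    f"concept table line {lineno}: active flag must be 0 or 1, got {active!r}"
                )
            if active != "1":
                continue
            if cid in concepts:
                if concepts[cid] != term:
                    raise OntologyValidationError(
                        f"duplicate active concept {cid!r} with conflicting terms "
                        f"({concepts[cid]!r} vs {term!r}) at line {lineno}"
                    )
                continue
            concepts[cid] = term

    g = nx.DiGraph()
    for cid, term in concepts.items():
        g.add_node(cid, term=term)

    src_col, dst_col, type_col = relationship_columns
    dropped = {"unknown_endpoint": 0, "non_isa": 0, "self_loop": 0, "duplicate": 0}
    with open(relationship_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {src_col, dst_col, type_col} - set(reader.fieldnames or ())
        if missing:
            raise OntologyParseError(
                f"relationship table lacks column(s) {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            child, parent, rtype = row.get(src_col), row.get(dst_col), row.get(type_col)
            if child in (None, "") or parent in (None, "") or rtype in (None, ""):
                raise OntologyParseError(f"malformed relationship row at line {lineno}")
            if rtype != isa_code:
                dropped["non_isa"] += 1
                continue
            if child == parent:
                dropped["self_loop"] += 1
                continue
            if child not in concepts or parent not in concepts:
                dropped["unknown_endpoint"] += 1
                continue
            if g.has_edge(child, parent):
                dropped["duplicate"] += 1
                continue
            g.add_edge(child, parent)
    g.graph["dropped"] = dropped
    return g


def _dfs_back_edges(g: nx.DiGraph) -> set[tuple[str, str]]:
    """Back edges of a deterministic top-down DFS, as child->parent pairs.

    The traversal runs against the edge direction — from hierarchy roots
    (concepts without parents) toward leaves — so that genuine subtype edges
    are walked in their natural order and cycle-closing cross links are the
    ones flagged as back edges.  Start nodes are roots first, then remaining
    nodes, each group in sorted order; children are visited sorted.  Removing
    the back edges leaves a maximal acyclic subset of the edges, which
    anchors the hierarchy-level scoring used by :func:`break_cycles`.
    """
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in g.nodes}
    roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
    others = sorted(n for n in g.nodes if g.out_degree(n) > 0)
    back: set[tuple[str, str]] = set()
    for start in roots + others:
        if color[start] != WHITE:
            continue
        stack = [(start, iter(sorted(g.predecessors(start))))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if color[child] == WHITE:
                    color[child] = GREY
                    stack.append((child, iter(sorted(g.predecessors(child)))))
                    advanced = True
                    break
                if color[child] == GREY:
                    # traversal stepped node=>child against the edge direction,
                    # so the offending original edge is child -> node
                    back.add((child, node))
            if not advanced:
                color[node] = BLACK
                stack.pop()
    return back


def hierarchy_levels(g: nx.DiGraph) -> dict[str, int]:
    """Longest-path level of each concept below the hierarchy roots.

    Roots (concepts with no parents, i.e. no outgoing edges) sit at level 0;
    a child's level is one more than its deepest parent.  Levels are computed
    on the maximal acyclic edge subset found by a deterministic DFS, so they
    are defined even when ``g`` contains cycles.
    """
    back = _dfs_back_edges(g)
    acyclic = nx.DiGraph()
    acyclic.add_nodes_from(g.nodes)
    acyclic.add_edges_from(e for e in g.edges if e not in back)
    level: dict[str, int] = {}
    # Edges run child -> parent, so process parents before children.
    for node in reversed(list(nx.topological_sort(acyclic))):
        parents = list(acyclic.successors(node))
        level[node] = 0 if not parents else 1 + max(level[p] for p in parents)
    return level


def backwardness(edge: tuple[str, str], level: dict[str, int]) -> int:
    """Cycle-breaking score: child level minus parent level.

    A well-formed hierarchy edge has a strictly positive score (the child is
    deeper than its parent); cycle-closing edges tend to score <= 0.
    """
    child, parent = edge
    return level[child] - level[parent]


def break_cycles(g: nx.DiGraph) -> AcyclicOntology:
    """Reduce the concept graph to a DAG by removing "backward" edges.

    Hierarchy levels are fixed once from a deterministic maximal acyclic edge
    subset; then, repeatedly, each non-trivial strongly connected component
    loses its edge with the most negative child-minus-parent level difference
    (ties broken lexicographically by ``(child_id, parent_id)``) until no
    directed cycle remains.  Every removed edge lay on a cycle, and the result
    is deterministic for a given input graph.
    """
    dag = g.copy()
    removed: list[tuple[str, str]] = []
    if dag.number_of_nodes() == 0:
        return AcyclicOntology(dag, removed)
    level = hierarchy_levels(g)
    while True:
        sccs = [c for c in nx.strongly_connected_components(dag) if len(c) > 1]
        if not sccs:
            break
        for comp in sorted(sccs, key=lambda c: min(c)):
            internal = [
                (u, v) for u, v in dag.edges(comp) if u in comp and v in comp
            ]
            victim = min(internal, key=lambda e: (backwardness(e, level), e))
            dag.remove_edge(*victim)
            removed.append(victim)
    return AcyclicOntology(dag, removed)


def extract_subgraph(
    dag: AcyclicOntology,
    diagnoses,
    up_levels: int = 2,
    down_levels: int = 2,
) -> CohortSubgraph:
    """Induced subgraph on diagnoses plus a bounded ancestry/descent window.

    Ancestors follow the child->parent edge direction, descendants the
    reverse.  Unknown diagnosis ids are skipped with a warning; an empty
    (effective) diagnosis set is an error.
    """
    g = dag.graph
    known = {d for d in diagnoses if d in g}
    unknown = set(diagnoses) - known
    if unknown:
        warnings.warn(
            f"skipping {len(unknown)} diagnosis id(s) absent from the ontology: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}",
            stacklevel=2,
        )
    if not known:
        raise ValueError("no diagnosis concept is present in the ontology graph")

    def bounded_reach(neighbors, levels):
        seen = set(known)
        frontier = set(known)
        for _ in range(levels):
            frontier = {m for n in frontier for m in neighbors(n)} - seen
            seen |= frontier
        return seen

    keep = bounded_reach(g.successors, up_levels) | bounded_reach(
        g.predecessors, down_levels
    )
    return CohortSubgraph(g.subgraph(keep).copy(), known, up_levels, down_levels)


def max_root_depth(sub: CohortSubgraph) -> tuple[dict[str, int], int]:
    """Longest directed path from each diagnosis to a root of the subgraph.

    Roots are subgraph nodes without parents (no outgoing edges).  Returns the
    per-diagnosis depth map and its maximum — the connectivity metric used to
    pick the ancestry/descent window.
    """
    g = sub.graph
    depth: dict[str, int] = {}
    for node in reversed(list(nx.topological_sort(g))):
        parents = list(g.successors(node))
        depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
    per_dx = {d: depth[d] for d in sub.diagnosis_nodes}
    return per_dx, max(per_dx.values())


def select_window_depth(
    dag: AcyclicOntology,
    diagnoses,
    candidate_depths=(1, 2, 3),
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest window depth at which diagnosis-to-root depth saturates.

    The metric is the maximum over diagnoses of the longest path to a subgraph
    root.  The chosen depth is the smallest candidate whose metric equals the
    next candidate's ("no further increase"); if the metric still grows at the
    last candidate, that candidate is returned with a warning.
    """
    candidates = list(candidate_depths)
    if not candidates or sorted(candidates) != candidates:
        raise ValueError("candidate_depths must be nonempty and ascending")
    metrics = []
    for d in candidates:
        sub = extract_subgraph(dag, diagnoses, up_levels=d, down_levels=d)
        _, m = max_root_depth(sub)
        metrics.append(m)
    table = pd.DataFrame({"window_depth": candidates, "max_root_depth": metrics})
    for i in range(len(candidates) - 1):
        if metrics[i] == metrics[i + 1]:
            return candidates[i], table
    warnings.warn(
        "diagnosis-to-root depth still increasing at the largest candidate "
        f"window ({candidates[-1]}); returning it",
        stacklevel=2,
    )
    return candidates[-1], table


def write_edge_list(g: nx.DiGraph, path) -> None:
    """Write a child/parent edge-list TSV."""
    pd.DataFrame(sorted(g.edges), columns=["child_id", "parent_id"]).to_csv(
        path, sep="\t", index=False
    )
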