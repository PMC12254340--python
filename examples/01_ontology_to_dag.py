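"""Build a clinical concept graph, break its cycles, and pick the subgraph window.

Generates a small synthetic terminology (a forest of "is a" subtype trees with
a few injected cycle-closing cross links), loads it through the TSV reader,
reduces it to a DAG, and selects the ancestry/descent window at which the
diagnosis-to-root depth metric saturates.
"""

import tempfile

from ontoprot import ontology, simulate

onto = simulate.make_ontology(n_branches=5, depth=2, children_per_node=4,
                              cycle_edge_count=8, seed=7)
with tempfile.TemporaryDirectory() as d:
    onto.write(f"{d}/concepts.tsv", f"{d}/relationships.tsv")
    g = ontology.load_ontology(f"{d}/concepts.tsv", f"{d}/relationships.tsv")

print(f"concept graph: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
print(f"rows dropped by the loader: {g.graph['dropped']}")

dag = ontology.break_cycles(g)
injected = set(map(tuple, onto.truth["cycle_edges"]))
hit = sum(e in injected for e in dag.removed_edges)
print(f"cycle breaking removed {len(dag.removed_edges)} edges "
      f"({hit} of the {len(injected)} injected cycle-closers)")

diagnoses = onto.truth["leaves"][:40]
depth, table = ontology.select_window_depth(dag, diagnoses)
print(table.to_string(index=False))
print(f"-> window depth {depth}: the smallest window at which the maximum "
      "diagnosis-to-root path length stops growing")
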