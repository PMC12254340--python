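"""Embed a cohort subgraph and choose the cluster number by silhouette saturation.

Walks the subgraph with second-order biased random walks (p=3, q=1.5, 20
walks of length 20 per node), trains 128-dimensional skip-gram embeddings,
sweeps k for three clustering methods, fits the saturating silhouette curve
s(k) = a - b*exp(-beta*k), and applies the 97%-of-asymptote rule.
"""

import tempfile
import warnings

warnings.simplefilter("ignore")

from ontoprot import clustering, embedding, ontology, simulate

onto = simulate.make_ontology(n_branches=6, depth=3, children_per_node=(3, 3, 4),
                              cycle_edge_count=5, seed=3)
cohort, ct = simulate.make_cohort(onto.truth, n_participants=200,
                                  rare_diagnosis_count=30, n_diagnoses=40,
                                  n_controls=25, concentrated=True, seed=4)
with tempfile.TemporaryDirectory() as d:
    onto.write(f"{d}/c.tsv", f"{d}/r.tsv")
    g = ontology.load_ontology(f"{d}/c.tsv", f"{d}/r.tsv")
dag = ontology.break_cycles(g)
diagnoses = set(ct["diagnoses"])
sub = ontology.extract_subgraph(dag, diagnoses, up_levels=2, down_levels=2)
print(f"cohort subgraph: {sub.graph.number_of_nodes()} nodes around "
      f"{len(diagnoses)} diagnoses")

emb = embedding.embed_subgraph(sub, seed=42)
curves = clustering.silhouette_sweep(emb, diagnoses, k_min=5, k_max=30, seed=42)
for c in curves:
    fit = clustering.fit_saturation(c)
    print(f"{c.method:>14}: asymptote a={fit.asymptote:.3f}, k_opt={fit.k_opt}")
method, k = clustering.choose_best_method(curves)
print(f"chosen: {method} at k={k} (highest observed silhouette at its own k_opt)")

assignment = clustering.assign_clusters(emb, diagnoses, method, k, seed=42)
before, after, _ = clustering.underpowered_reduction(assignment, cohort)
print(f"diagnoses with <5 patients: {before} -> clusters with <5 patients: {after}")
print("pooling semantically related rare diagnoses removes most underpowered groups")
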