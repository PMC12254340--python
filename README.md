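# ontoprot

Ontology-guided aggregation of rare-disease patients, with the proteomic QC
and statistics to profile the resulting groups.

Pediatric cohorts contain long tails of rare diagnoses — hundreds of
conditions carried by fewer than five patients each — that individually
permit no group statistics. `ontoprot` pools such patients by semantic
similarity of their diagnoses in a clinical terminology: the "is a" concept
graph is cleaned to a DAG, a cohort-specific subgraph is cut out, its nodes
are embedded by biased random walks (node2vec: p = 3, q = 1.5, 20×20 walks,
128 dimensions), and diagnoses are clustered with the number of clusters k
chosen where the cosine-silhouette curve s(k) = a − b·e^(−βk) reaches 97%
of its fitted asymptote a. Cluster membership then drives body-fluid
proteomics: coefficient-of-variation profiles per cluster, and Welch's
t-test differential expression of each cluster against healthy controls
with Benjamini–Hochberg FDR control. The statistical layer also provides
age/sex ANCOVA for single diseases, sex/age ANOVA with trajectory modules,
urine–plasma correlation, KNN-imputed PCA, and mDIA channel QC (labeling
efficiency, channel-q cutoff sweep).

Everything is testable without access to licensed terminologies or
deposited cohort data: the `simulate` module generates ontologies, cohorts,
intensity matrices and precursor reports with recorded ground truth
(injected cycle edges, rare-tail counts, planted age/sex/cluster/batch
effects, MNAR missingness).

## Worked example

`examples/05_full_study.py` runs the whole chain at smoke scale — synthetic
terminology → DAG → subgraph → embedding → silhouette-selected clustering →
participant mapping → CV profile → cluster-vs-control DE — and scores it
against the generator's planted truth:

```
$ python examples/05_full_study.py
clustering: agglomerative at k=5
underpowered diagnoses before: 30, underpowered clusters after: 0
overall biological CV: 42.1% vs lowest cluster median 34.1%
planted-effect recovery: sensitivity 0.96, empirical FDR 0.091 (44 cluster-protein discoveries)
```

Thirty diagnoses too rare to analyse individually collapse into clusters
that all hold ≥5 patients; within-cluster variability sits below the
overall biological CV; and 24 of 25 proteins planted with a +1.5 log2
disease effect resurface in the cluster-vs-control comparisons, with the
false fraction of discovery pairs held near the nominal BH level.

The other examples each exercise one capability and print what the numbers
mean: `01` graph cleanup and window selection, `02` embedding and
cluster-number choice, `03` QC (filters, CVs, ComBat, channel-q sweep),
`04` confounder-adjusted vs naive differential expression.

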