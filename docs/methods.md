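# Methods

`ontoprot` implements an ontology-guided aggregation workflow for rare
pediatric disorders together with the proteomic QC and statistics needed to
profile the resulting patient clusters. This note records the models, the
parameter choices and their rationale, the synthetic study conditions, and
the known limitations.

## Clinical-terminology graph and DAG

Concepts connected by "is a" subtype relations form a directed graph with
edges pointing child → parent. Only active, non-duplicated concepts enter
the graph; self-loops, duplicate edges, non-subtype rows, and edges touching
inactive or unknown concepts are dropped and counted. Because real
terminology releases contain occasional cycles (cross-linked or overlapping
classifications), the graph is reduced to a DAG before any ancestry
semantics are used.

**Cycle breaking.** The breaker scores every edge by *backwardness* —
child hierarchy level minus parent hierarchy level — where levels are
longest-path distances below the roots, computed on a maximal acyclic edge
subset found by a deterministic top-down depth-first search (roots first,
children in sorted order). A well-formed subtype edge scores ≥ 1; an edge
that points from an ancestor back down to a descendant scores ≤ 0. While a
non-trivial strongly connected component remains, its lowest-scoring edge is
removed, ties broken lexicographically by `(child_id, parent_id)`. The
procedure is deterministic for a given input, removes only edges that lie on
cycles, and on synthetic hierarchies with injected cycle-closing cross links
it removes exactly those links in virtually all cases (measured in the
acceptance checks). The DFS anchoring matters: traversing *with* the edge
direction (child to parent) would enter cycles through the injected link and
misclassify a genuine chain edge as the back edge.

**Cohort subgraph.** The induced subgraph contains the cohort's diagnosis
concepts plus ancestors within `up_levels` and descendants within
`down_levels` directed steps (both default 2). The window is selected by a
saturation rule on graph connectivity: for each candidate depth, compute the
longest path from each diagnosis to a root *of the subgraph*, and take the
smallest depth whose maximum equals the next candidate's ("no further
increase"). If the metric still grows at the largest candidate, that
candidate is returned with a warning. Subgraph roots (rather than roots of
the full terminology) are used because the metric is meant to measure
connectivity of the structure the embedding will actually see.

## Node embedding

Subgraph nodes are embedded with second-order biased random walks feeding a
skip-gram model with negative sampling. Defaults: return parameter p = 3,
in-out parameter q = 1.5, 20 walks of length 20 per node, dimension 128,
context window 10, seed 42. Walks run on the **undirected** view of the DAG:
directed walks drift monotonically toward roots or leaves and starve sibling
co-occurrence, which is the signal the clustering needs.

The trainer is implemented in-package (numba kernels) because no
pre-packaged word2vec implementation is part of the dependency set: one
thread, an explicit xorshift RNG advanced in program order, dynamically
shrunk context windows (the word2vec convention), 5 epochs, 5 negative
samples per positive pair drawn from a unigram^0.75 table, learning rate
decaying linearly from 0.025 to 1e-4. Single-threaded execution plus the
explicit RNG makes repeated runs bit-identical — the determinism contract
the downstream clustering and the reproduction script rely on. Walk
generation uses binary search over sorted CSR neighbor lists to evaluate the
1/p : 1 : 1/q second-order weights exactly; the empirical transition
frequencies match the analytic law in the tests.

## Cluster-number selection

For each clustering method (k-means; agglomerative with average linkage on
cosine distances; spectral on a `(1 + cosine similarity)/2` affinity) the
cosine-distance silhouette is recorded over an ascending k grid (study
range 10–200, step 1 by default). Each curve is summarized by a saturating
exponential

    s(k) = a − b·exp(−β·k),    b ≥ 0, β > 0,

fitted by nonlinear least squares with a multi-start β grid (1e-3 … 1).
The working k is the smallest evaluated k whose *fitted* value reaches 97%
of the asymptote `a`; fitting the smoothed curve rather than the raw scores
keeps the rule stable under silhouette noise. The constraint b ≥ 0 keeps
the family monotone non-decreasing, which is the regime the rule is meant
for; on a curve that declines after an early peak the fit degenerates and
the rule saturates immediately, so sweeps should end before k exhausts the
data (the planted-recovery experiments sweep to 1.8× the expected k). The
method whose *observed* silhouette at its own k_opt is highest wins; ties
break toward smaller k_opt, then method name.

Only diagnosis concepts are clustered; ancestor/descendant nodes shape the
embedding but receive no label. Silhouettes of degenerate partitions (fewer
than two distinct labels, or identical points) are recorded as missing,
never fabricated.

## Proteomic QC and preprocessing

Matrices are proteins × samples, raw positive intensities with NaN for
missing; zeros in input are treated as missing by default because DIA
outputs conflate the two. The preprocessing chain is: identification-count
filters → log2 → ComBat batch correction. Filters act on identification
counts, which are scale-invariant, so their position before the log2
transform cannot change the outcome.

- **Fixed-count filter** (urine default): drop samples with fewer than 800
  identified proteins (strict; exactly 800 is kept).
- **IQR filter** (plasma default): drop samples whose count falls below
  Q1 − 1.5·IQR, quartiles by linear interpolation (the quantile convention
  is stated because it changes borderline removals). One-sided: high counts
  are never removed.
- **ComBat**: parametric empirical-Bayes location–scale adjustment,
  implemented in-package with NaN-aware statistics (no packaged
  implementation is among the dependencies). On complete data it matches
  Bioconductor's `sva::ComBat` to ~1e-6 (the iterative EB solver's stopping
  tolerance); the test suite runs that comparison through `Rscript`.
  Per-protein overall means are preserved; missing entries stay missing.

**Coefficients of variation** are computed on *raw* intensities as
100·sd/mean with the sample standard deviation (ddof 1; unbiased under
normality and conventional in proteomics QC). Analytical CVs use
reference-channel or pooled-QC samples, biological CVs use distinct cohort
participants; proteins with fewer than two present values in the subset are
skipped. Completeness uses a strict "more than 60% valid" rule.

**mDIA channel QC.** Labeling efficiency is the intensity-weighted fraction
of labeled precursors. The channel-q sweep takes a report from a sample
labeled only in the light (Δ0) channel — so every intermediate/heavy (Δ4/Δ8)
identification is false — and evaluates cutoffs 0.05 … 0.5 in steps of
0.05; the recommended cutoff is the largest whose false-channel ratio stays
under 1%.

## Statistics

All tests run on log2 intensities, two-sided, complete-case per protein;
the BH family is always the set of proteins tested within one comparison.
BH is the standard step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1,
implemented directly so it can be verified *exactly* against a brute-force
enumeration oracle.

- **Welch DE**: t = (x̄_A − x̄_B)/√(s²_A/n_A + s²_B/n_B) with
  Welch–Satterthwaite degrees of freedom, vectorized over proteins; built
  for highly unbalanced designs (clusters as small as 2 against a
  131-sample control pool). Zero variance in both groups gives p = 1 when
  the means agree and a flagged missing p otherwise.
- **ANCOVA**: per protein, ordinary least squares of intensity on a disease
  indicator plus age (years) and sex (binary indicator); the p-value is the
  coefficient t-test (the model-derived pairwise comparison), while the
  reported log2FC is the plain difference of group means — both stored to
  avoid ambiguity. A single-sex design drops the sex covariate with a
  warning and a per-protein note.
- **Sex/age ANOVA**: one-way F over sex × integer-year age cells, after
  dropping proteins under 70% valid values; per protein only cells with ≥2
  present values enter. Significant proteins can be summarized into
  trajectory modules: z-scored per-cell means, agglomerative clustering
  (Euclidean, average linkage) cut at n_modules.
- **Cross-fluid correlation**: per-protein Pearson r over participant-paired
  samples (≥5 pairs), significant when |r| > 0.4 and BH q < 0.01.
- **PCA**: KNN imputation (k = 5) — the only imputation in the package —
  then per-feature standardization and SVD-based PCA; loadings are
  orthonormal.

## Synthetic data

The generator produces the full study shape with recorded ground truth:

- **Ontology**: a forest of rooted subtype trees (per-level fan-out
  configurable; wide leaf fan-out mimics fine-grained diagnosis families)
  plus injected ancestor→descendant edges, each of which provably closes a
  directed cycle; a few inactive and duplicate concept rows exercise the
  loader.
- **Cohort**: diagnoses drawn from the leaves, an exact rare-tail count of
  diagnoses with <5 patients, ages uniform integers in 3–17, balanced
  sexes, and a well-child control arm. With `concentrated=True` diagnoses
  arrive as whole sibling families — the regime in which semantic
  aggregation can pool related rare conditions, mirroring a real cohort's
  structure of a few hundred conditions collapsing into a few dozen
  clusters.
- **Intensities**: per protein, log2 intensity = baseline (N(20, 1.7²),
  spanning about five orders of magnitude) + age slope·(age − 10) + sex
  offset + cluster effect + plate shift + noise, exponentiated to the raw
  scale. Defaults: 10% of proteins carry age slopes (sd 0.05 log2/year),
  10% carry ±0.5 log2 sex offsets, plate shifts are N(0, 0.25) per
  (plate, protein) with 96-sample plates, biological noise targets a 40%
  raw-scale CV (log2 sd via sd = √ln(1 + CV²)/ln 2) and analytical noise
  21%, matching the body-fluid workflows being emulated. QC-pool samples
  carry only analytical noise. Missingness is MNAR — dropout probability
  logistic-decreasing in log2 abundance (steepness 1 per log2 unit), with
  the intercept calibrated by root finding so the realized overall rate
  matches the target (default 0.30). Planted cluster effects are ±1.5 or
  +1.5 log2 shifts (`effect_signs`) on 50 proteins per affected branch.
- **Precursor report**: light-channel rows whose labeled intensity share is
  exact by construction, plus spurious Δ4/Δ8 rows at a configured rate with
  q-values above a planted boundary, so the sweep's recommended cutoff is
  known.

What the generator does **not** emulate: peptide-level chemistry, retention
time or spectra, correlated protein modules, longitudinal sampling,
non-additive batch effects, and diagnosis co-morbidity (one primary
diagnosis per participant, matching the cohort-table convention). Passing
tests therefore show that the algorithms recover planted structure under
realistic noise, missingness and batch geometry — not that they resolve
every pathology of real clinical data.

## Study-scale reproduction settings

The `paper-scale` preset runs 1000 diseased participants plus 131 controls,
300 diagnoses (260 in the rare tail) sampled as sibling families from a
15-branch terminology with leaf fan-out 7, and 2000 proteins — the same
order of magnitude as the study being emulated, sized to finish in a few
minutes on one CPU. The end-to-end evaluation plants +1.5 log2 effects on
50 proteins in each of three branches. Sensitivity counts planted proteins
significant in at least one *powered* cluster (≥5 patients — the same
threshold that defines an underpowered category); the empirical FDR is the
false fraction of (cluster, protein) discovery pairs across powered
families, which is the quantity per-family BH actually controls (a
protein-union FDR would double-penalize true effects rediscovered by
sibling clusters).

## Known limitations

- **Welch with tiny groups is anticonservative in the far tail.** At n = 4
  vs 131 on Gaussian nulls, P(p < 0.001) ≈ 0.006 rather than 0.001 (the
  Satterthwaite approximation degrades when the small group's variance has
  ~3 degrees of freedom; scipy's implementation agrees to machine
  precision). Consequently BH over 10⁴ null proteins still yields tens of
  "discoveries" from such comparisons. The package reports DE for clusters
  as small as 2 — small-cluster volcano results are exploratory and should
  be read with this caveat — while calibrated error control is claimed only
  for powered clusters.
- **MNAR interacts with variance structure.** A cluster with much lower
  biological variance than the control pool acquires a systematic observed
  mean offset on low-abundance proteins, because dropout censors the
  control pool asymmetrically. Welch DE on observed values inherits that
  bias; it is visible in the generator when a very-low-CV cluster is
  planted.
- The cycle-breaking scoring is a deterministic, testable variant of
  ensemble hierarchy-based edge removal; the exact ensemble used by the
  emulated workflow is not public, so removed-edge lists need not coincide
  on real terminologies.
- Spectral clustering on near-duplicate embeddings (identical sibling
  leaves) can be numerically fragile at large k; the sweep records missing
  silhouettes rather than failing.
- UMAP coordinates are deterministic for a fixed `random_state` but not
  stable across library versions; downstream results never depend on them.
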