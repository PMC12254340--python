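"""End-to-end orchestration: synthetic study -> clusters -> cluster DE.

Thin composition of the library modules, used by the examples and the
reproduction script; every step is available individually.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering, embedding, integrate, ontology, qc, simulate


@dataclass
class PipelineResult:
    dag: ontology.AcyclicOntology
    subgraph: ontology.CohortSubgraph
    emb: embedding.EmbeddingMatrix
    curves: list
    method: str
    k_opt: int
    assignment: clustering.ClusterAssignment
    underpowered_before: int
    underpowered_after: int
    cmap: integrate.ClusterCohortMap
    cv_ranking: pd.DataFrame | None
    overall_cv: float | None
    de_results: dict[int, pd.DataFrame]
    sim: dict


def run_synthetic_study(
    preset: str = "smoke",
    seed: int = 42,
    k_min: int = 10,
    k_max: int = 200,
    k_step: int = 1,
    methods=clustering.METHODS,
    intensity_overrides: dict | None = None,
    plant_top_branches: tuple[int, float] | None = None,
    min_ids: int | None = 800,
    alpha: float = 0.05,
) -> PipelineResult:
    """Full synthetic run: ontology -> DAG -> subgraph -> embedding ->
    silhouette-selected clustering -> participant mapping -> CV profile ->
    cluster-vs-control differential expression.

    The intensity matrix is filtered on identification counts, log2
    transformed, and batch corrected before testing.
    """
    sim = simulate.simulate_all(preset, seed=seed,
                                intensity_overrides=intensity_overrides,
                                plant_top_branches=plant_top_branches)
    with tempfile.TemporaryDirectory() as d:
        sim["ontology"].write(f"{d}/c.tsv", f"{d}/r.tsv")
        g = ontology.load_ontology(f"{d}/c.tsv", f"{d}/r.tsv")
    dag = ontology.break_cycles(g)
    diagnoses = set(sim["cohort_truth"]["diagnoses"])
    sub = ontology.extract_subgraph(dag, diagnoses, up_levels=2, down_levels=2)
    emb = embedding.embed_subgraph(sub, seed=seed)

    n_dx = len(diagnoses)
    k_hi = min(k_max, n_dx - 1)
    k_lo = min(k_min, max(2, n_dx // 4))
    curves = clustering.silhouette_sweep(
        emb, diagnoses, methods=methods, k_min=k_lo, k_max=k_hi, step=k_step,
        seed=seed,
    )
    for c in curves:
        clustering.fit_saturation(c)
    method, k_opt = clustering.choose_best_method(curves)
    assignment = clustering.assign_clusters(emb, diagnoses, method, k_opt, seed=seed)
    n_before, n_after, _ = clustering.underpowered_reduction(assignment, sim["cohort"])

    m = sim["matrix"]
    if min_ids is not None:
        m, _ = qc.filter_min_ids(m, min_ids=min_ids)
    m_log2 = qc.batch_correct(qc.log2_transform(m))
    cmap = integrate.map_participants(assignment, sim["cohort"], m.meta)
    fluid = m.meta["fluid"].iloc[0]
    try:
        cv_ranking, _, overall_cv, _ = integrate.cluster_cv_profile(m, cmap, fluid)
    except ValueError:
        cv_ranking, overall_cv = None, None
    de_results, _ = integrate.cluster_de(m_log2, cmap, fluid, alpha=alpha)
    return PipelineResult(
        dag, sub, emb, curves, method, k_opt, assignment,
        n_before, n_after, cmap, cv_ranking, overall_cv, de_results, sim,
    )


def planted_effect_recovery(result: PipelineResult, min_patients: int = 5) -> dict:
    """Sensitivity and empirical FDR for planted cluster-effect proteins.

    A planted protein counts as recovered when it is significant in at least
    one cluster-vs-control comparison; a discovery is false when the protein
    carries no planted cluster effect.  Only clusters pooling at least
    ``min_patients`` participants enter the evaluation — the powered groups
    the aggregation exists to create.  Welch's test against a large control
    pool is anticonservative in the far tail below that size (its
    Satterthwaite approximation breaks down when the small group's variance
    is estimated from 1-2 degrees of freedom), so discoveries from smaller
    clusters are reported by the pipeline but not treated as calibrated.
    """
    truth = result.sim["intensity_truth"]
    per_branch = {int(b): set(ps)
                  for b, ps in truth["cluster_effect_proteins"].items()}
    planted = set().union(*per_branch.values()) if per_branch else set()
    branch_of = result.sim["ontology"].truth["branch_of"]
    cohort_d = result.sim["cohort"].query("group == 'diagnosed'")
    pc = result.cmap.participant_cluster
    cluster_n: dict[int, int] = {}
    for part, cl in pc.items():
        cluster_n[cl] = cluster_n.get(cl, 0) + 1

    # FDP over (cluster, protein) discovery pairs: a pair is true when the
    # protein carries a planted effect for a branch actually represented in
    # that cluster.  This is the quantity per-family BH controls in aggregate;
    # the union of discovered proteins would double-penalize true effects
    # rediscovered by sibling clusters.
    true_pairs = false_pairs = 0
    recovered: set = set()
    for cl, df in result.de_results.items():
        if cluster_n.get(cl, 0) < min_patients:
            continue
        parts = [p for p, c in pc.items() if c == cl]
        branches = set(
            cohort_d[cohort_d["participant_id"].isin(parts)]["diagnosis_id"].map(
                branch_of
            )
        )
        truth_here = set().union(*[per_branch.get(b, set()) for b in branches]) \
            if branches else set()
        sig = set(df.index[df["significant"].astype(bool)])
        true_pairs += len(sig & truth_here)
        false_pairs += len(sig - truth_here)
        recovered |= sig & truth_here
    n_pairs = true_pairs + false_pairs
    if not planted:
        return {"sensitivity": np.nan, "fdr": np.nan,
                "n_planted": 0, "n_discovery_pairs": n_pairs}
    return {
        "sensitivity": len(recovered) / len(planted),
        "fdr": false_pairs / n_pairs if n_pairs else 0.0,
        "n_planted": len(planted),
        "n_discovery_pairs": n_pairs,
    }
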