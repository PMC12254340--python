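"""Joining diagnosis clusters with the cohort and its intensity matrices.

A cluster assignment on diagnosis concepts is propagated to participants via
their primary diagnosis; controls (group label "Well child (finding)") form
the reference pool and never enter a disease cluster.  On top of that mapping
sit the per-cluster CV profiles (the interindividual-variability argument for
aggregation) and the cluster-vs-control Welch differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .qc import IntensityMatrix, cv_per_protein
from .stats import welch_de

CONTROL_LABEL = "Well child (finding)"


@dataclass
class ClusterCohortMap:
    """Participant/sample bookkeeping behind cluster-level statistics."""

    participant_cluster: dict[str, int]
    cluster_samples: dict[tuple[int, str], list[str]]  # (cluster, fluid) -> sample ids
    control_samples: dict[str, list[str]]  # fluid -> sample ids
    unmapped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def clusters(self) -> list[int]:
        return sorted({c for c, _ in self.cluster_samples})

    def fluids(self) -> list[str]:
        fl = {f for _, f in self.cluster_samples} | set(self.control_samples)
        return sorted(fl)


def map_participants(
    assignment: ClusterAssignment,
    cohort: pd.DataFrame,
    meta: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
) -> ClusterCohortMap:
    """Map each diagnosed participant to a cluster and pool the controls.

    ``cohort`` needs participant_id / diagnosis_id / group columns; ``meta``
    is sample metadata (sample_id index, participant_id / fluid columns).
    Participants with several rows keep the first listed diagnosis (with a
    warning); diagnoses without a cluster label are collected in the
    ``unmapped`` report rather than failing.
    """
    first = cohort.drop_duplicates("participant_id", keep="first")
    if len(first) < len(cohort):
        warnings.warn(
            f"{len(cohort) - len(first)} extra diagnosis row(s); "
            "keeping the first listed diagnosis per participant",
            stacklevel=2,
        )
    is_control = first["group"] == control_label
    controls = set(first.loc[is_control, "participant_id"])

    participant_cluster: dict[str, int] = {}
    unmapped_rows = []
    for row in first[~is_control].itertuples(index=False):
        cl = assignment.labels.get(row.diagnosis_id)
        if cl is None:
            unmapped_rows.append(
                {"participant_id": row.participant_id, "diagnosis_id": row.diagnosis_id}
            )
        else:
            participant_cluster[row.participant_id] = cl

    cluster_samples: dict[tuple[int, str], list[str]] = {}
    control_samples: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()  # one sample per participant per fluid
    for sample_id, srow in meta.iterrows():
        part, fluid = srow["participant_id"], srow["fluid"]
        if srow.get("role", "cohort") != "cohort":
            continue
        if (part, fluid) in seen:
            continue
        seen.add((part, fluid))
        if part in controls:
            control_samples.setdefault(fluid, []).append(sample_id)
        elif part in participant_cluster:
            key = (participant_cluster[part], fluid)
            cluster_samples.setdefault(key, []).append(sample_id)
    return ClusterCohortMap(
        participant_cluster,
        cluster_samples,
        control_samples,
        pd.DataFrame(unmapped_rows, columns=["participant_id", "diagnosis_id"]),
    )


def cluster_cv_profile(
    m_raw: IntensityMatrix,
    cmap: ClusterCohortMap,
    fluid: str,
    min_samples: int = 2,
) -> tuple[pd.DataFrame, dict[int, pd.Series], float, pd.DataFrame]:
    """Interindividual CV distribution per cluster, ranked by median CV.

    Returns (ranking table, per-cluster CV series, overall biological CV
    median across all cohort samples of the fluid, skip report).  The overall
    CV is the contrast figure: aggregation pays off when within-cluster
    medians sit below it.
    """
    available = set(m_raw.values.columns)
    rows, skip_rows, dists = [], [], {}
    all_cluster_samples: list[str] = []
    for (cl, fl), samples in sorted(cmap.cluster_samples.items()):
        if fl != fluid:
            continue
        samples = [s for s in samples if s in available]
        all_cluster_samples.extend(samples)
        if len(samples) < min_samples:
            skip_rows.append({"cluster": cl, "reason": "fewer_than_2_samples",
                              "n_samples": len(samples)})
            continue
        cvs, med = cv_per_protein(m_raw, samples)
        dists[cl] = cvs
        rows.append({"cluster": cl, "n_samples": len(samples), "median_cv": med})
    if not rows:
        raise ValueError(f"no cluster has >= {min_samples} samples in fluid {fluid!r}")
    ranking = (
        pd.DataFrame(rows).sort_values("median_cv").reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    overall_samples = all_cluster_samples + [
        s for s in cmap.control_samples.get(fluid, []) if s in available
    ]
    _, overall = cv_per_protein(m_raw, overall_samples)
    skip = pd.DataFrame(skip_rows, columns=["cluster", "reason", "n_samples"])
    return ranking, dists, overall, skip


def cluster_de(
    m_log2: IntensityMatrix,
    cmap: ClusterCohortMap,
    fluid: str,
    alpha: float = 0.05,
    min_samples: int = 2,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Welch differential expression of every eligible cluster vs controls.

    BH runs within each cluster x fluid family.  Clusters (or a control pool)
    with fewer than ``min_samples`` samples are skipped with a reason code.
    """
    available = set(m_log2.values.columns)
    controls = [s for s in cmap.control_samples.get(fluid, []) if s in available]
    results: dict[int, pd.DataFrame] = {}
    skip_rows = []
    if len(controls) < min_samples:
        for (cl, fl), _ in sorted(cmap.cluster_samples.items()):
            if fl == fluid:
                skip_rows.append({"cluster": cl, "reason": "control_pool_too_small"})
        return results, pd.DataFrame(skip_rows, columns=["cluster", "reason"])
    for (cl, fl), samples in sorted(cmap.cluster_samples.items()):
        if fl != fluid:
            continue
        samples = [s for s in samples if s in available]
        if len(samples) < min_samples:
            skip_rows.append({"cluster": cl, "reason": "fewer_than_2_samples"})
            continue
        results[cl] = welch_de(m_log2.values, samples, controls, alpha=alpha)
    return results, pd.DataFrame(skip_rows, columns=["cluster", "reason"])


def de_summary(results_by_fluid: dict[str, dict[int, pd.DataFrame]]) -> pd.DataFrame:
    """Cluster x fluid significant-protein counts plus per-fluid unique totals.

    Cells for clusters without data in a fluid hold NA — "no data" is kept
    distinct from "tested, nothing significant".
    """
    clusters = sorted({cl for res in results_by_fluid.values() for cl in res})
    fluids = sorted(results_by_fluid)
    table = pd.DataFrame(index=pd.Index(clusters, name="cluster"), columns=fluids,
                         dtype="Int64")
    totals = {}
    for fluid, res in results_by_fluid.items():
        unique: set = set()
        for cl, df in res.items():
            sig = df.index[df["significant"].astype(bool)]
            table.loc[cl, fluid] = len(sig)
            unique |= set(sig)
        totals[fluid] = len(unique)
    table.loc["unique_total"] = pd.Series(totals, dtype="Int64")
    return table
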