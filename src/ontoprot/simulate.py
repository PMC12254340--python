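"""Synthetic ontologies, cohorts, intensity matrices, and precursor reports.

Every generator records its ground truth so downstream stages can be scored:
which extra edges close cycles, which diagnoses form the rare tail, which
proteins carry planted age/sex/cluster/batch effects and at what magnitude.
The generated data emulate the structure of a pediatric body-fluid proteomics
study: a tree-like clinical ontology with a few cycle-closing cross links, a
cohort aged 3-17 with a long tail of diagnoses carrying fewer than five
patients each, log-normal protein intensities with separate analytical and
biological noise, additive plate effects, and abundance-dependent (MNAR)
missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .integrate import CONTROL_LABEL
from .qc import IntensityMatrix

IS_A = "116680003"


def _log2_sd_from_cv(cv_percent: float) -> float:
    """Log2-scale sd giving a lognormal CV of ``cv_percent`` on the raw scale."""
    c = cv_percent / 100.0
    return float(np.sqrt(np.log1p(c * c)) / np.log(2.0))


@dataclass
class SyntheticOntology:
    concepts: pd.DataFrame  # id, active, term
    relationships: pd.DataFrame  # sourceId, destinationId, typeId
    truth: dict = field(default_factory=dict)

    def write(self, concept_path, relationship_path):
        self.concepts.to_csv(concept_path, sep="\t", index=False)
        self.relationships.to_csv(relationship_path, sep="\t", index=False)


def make_ontology(
    n_branches: int = 12,
    depth: int = 4,
    children_per_node=3,
    cycle_edge_count: int = 20,
    seed: int = 0,
    inactive_fraction: float = 0.02,
    duplicate_rows: int = 3,
) -> SyntheticOntology:
    """Forest of rooted trees plus injected cycle-closing edges.

    Each of ``n_branches`` trees has the given depth and fan-out
    (``children_per_node`` may be one integer or a per-level sequence, e.g. a
    wider fan-out at the leaf level mimics fine-grained diagnosis families);
    edges point child -> parent.  ``cycle_edge_count`` extra edges are added
    from an ancestor to one of its descendants (as if the ancestor were the
    child), each of which closes a directed cycle; they are recorded in the
    truth.  A few inactive and duplicate concept rows exercise the loader.
    """
    fanout = (
        [int(children_per_node)] * depth
        if np.isscalar(children_per_node)
        else [int(c) for c in children_per_node]
    )
    if len(fanout) != depth:
        raise ValueError("children_per_node sequence must have one entry per level")
    if min(n_branches, depth, min(fanout)) < 1 or cycle_edge_count < 0:
        raise ValueError("ontology shape parameters must be positive")
    rng = np.random.default_rng(seed)
    rows, edges = [], []
    branch_of: dict[str, int] = {}
    parent_of: dict[str, str] = {}
    leaves: list[str] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"{1000000 + counter}"

    for b in range(n_branches):
        root = new_id()
        branch_of[root] = b
        rows.append((root, "1", f"Branch {b} root (disorder)"))
        level = [root]
        for d in range(1, depth + 1):
            nxt = []
            for parent in level:
                for c in range(fanout[d - 1]):
                    node = new_id()
                    branch_of[node] = b
                    parent_of[node] = parent
                    rows.append((node, "1", f"Branch {b} depth {d} concept {node}"))
                    edges.append((node, parent))
                    nxt.append(node)
                    if d == depth:
                        leaves.append(node)
            level = nxt

    # ancestor -> descendant extra edges, each closing a directed cycle
    all_children = list(parent_of)
    pairs: list[tuple[str, str]] = []
    attempts = 0
    while len(pairs) < cycle_edge_count:
        attempts += 1
        if attempts > 100 * max(cycle_edge_count, 1):
            raise ValueError("cannot place the requested number of cycle edges")
        node = all_children[rng.integers(len(all_children))]
        chain = []
        cur = node
        while cur in parent_of:
            cur = parent_of[cur]
            chain.append(cur)
        if not chain:
            continue
        anc = chain[rng.integers(len(chain))]
        if (anc, node) not in pairs:
            pairs.append((anc, node))
    edges.extend(pairs)

    # loader fodder: inactive concepts and exact-duplicate active rows
    n_inactive = max(1, int(inactive_fraction * len(rows)))
    for i in range(n_inactive):
        rows.append((f"{9000000 + i}", "0", f"Retired concept {i}"))
    dup_sources = rng.choice(len(rows) - n_inactive, size=duplicate_rows, replace=False)
    for i in dup_sources:
        rows.append(rows[int(i)])
    # an edge touching an inactive concept, to be dropped by the loader
    edges.append((f"{9000000}", rows[0][0]))

    concepts = pd.DataFrame(rows, columns=["id", "active", "term"])
    rel = pd.DataFrame(edges, columns=["sourceId", "destinationId"])
    rel["typeId"] = IS_A
    truth = {
        "branch_of": branch_of,
        "leaves": leaves,
        "parent_of_leaf": {leaf: parent_of[leaf] for leaf in leaves},
        "cycle_edges": pairs,
        "n_tree_nodes": len(branch_of),
        "seed": seed,
    }
    return SyntheticOntology(concepts, rel, truth)


def make_cohort(
    truth: dict,
    n_participants: int = 1000,
    rare_diagnosis_count: int = 260,
    n_diagnoses: int = 300,
    n_controls: int = 131,
    min_age: int = 3,
    max_age: int = 17,
    concentrated: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort table with a long rare-diagnosis tail plus a well-child arm.

    Diagnoses are drawn from tree leaves; exactly ``rare_diagnosis_count`` of
    them receive fewer than five patients.  With ``concentrated=True`` the
    diagnoses are taken as whole sibling families (all leaves under a shared
    parent) rather than scattered uniformly — real cohorts recruit related
    conditions together, and this is what lets clustering pool related rare
    diagnoses into adequately sized groups.  Ages are uniform integers in
    [min_age, max_age]; sexes are balanced.  Returns (table, cohort truth).
    """
    rng = np.random.default_rng(seed)
    leaves = list(truth["leaves"])
    if n_diagnoses > len(leaves):
        raise ValueError(f"requested {n_diagnoses} diagnoses but only {len(leaves)} leaves")
    if rare_diagnosis_count > n_diagnoses:
        raise ValueError("rare_diagnosis_count cannot exceed n_diagnoses")
    if concentrated:
        parent_of = truth["parent_of_leaf"]
        groups: dict[str, list[str]] = {}
        for leaf in leaves:
            groups.setdefault(parent_of[leaf], []).append(leaf)
        parents = sorted(groups)
        order = rng.permutation(len(parents))
        chosen = []
        for gi in order:
            if len(chosen) >= n_diagnoses:
                break
            chosen.extend(groups[parents[gi]])
        chosen = chosen[:n_diagnoses]
    else:
        chosen = list(rng.choice(leaves, size=n_diagnoses, replace=False))
    rare_idx = rng.choice(n_diagnoses, size=rare_diagnosis_count, replace=False)
    rare_mask = np.zeros(n_diagnoses, dtype=bool)
    rare_mask[rare_idx] = True
    rare = [d for d, m in zip(chosen, rare_mask) if m]
    common = [d for d, m in zip(chosen, rare_mask) if not m]

    rare_counts = rng.choice([1, 2, 3, 4], size=len(rare), p=[0.45, 0.3, 0.15, 0.1])
    floor_common = 5 * len(common)
    remaining = n_participants - int(rare_counts.sum()) - floor_common
    if remaining < 0:
        raise ValueError(
            "infeasible allocation: rare tail plus five patients per common "
            f"diagnosis needs more than {n_participants} participants"
        )
    common_counts = np.full(len(common), 5, dtype=int)
    if len(common) and remaining > 0:
        extra = rng.multinomial(remaining, np.ones(len(common)) / len(common))
        common_counts += extra
    elif remaining > 0 and not len(common):
        raise ValueError("cannot place remaining participants without common diagnoses")

    rows = []
    pid = 0
    for dx, cnt in list(zip(rare, rare_counts)) + list(zip(common, common_counts)):
        for _ in range(int(cnt)):
            pid += 1
            rows.append(
                {
                    "participant_id": f"P{pid:05d}",
                    "age": int(rng.integers(min_age, max_age + 1)),
                    "sex": "male" if pid % 2 else "female",
                    "diagnosis_id": dx,
                    "group": "diagnosed",
                }
            )
    for _ in range(n_controls):
        pid += 1
        rows.append(
            {
                "participant_id": f"P{pid:05d}",
                "age": int(rng.integers(min_age, max_age + 1)),
                "sex": "male" if pid % 2 else "female",
                "diagnosis_id": "",
                "group": CONTROL_LABEL,
            }
        )
    table = pd.DataFrame(rows)
    cohort_truth = {
        "diagnoses": chosen,
        "rare_diagnoses": rare,
        "counts": {dx: int(c) for dx, c in
                   list(zip(rare, rare_counts)) + list(zip(common, common_counts))},
        "seed": seed,
    }
    return table, cohort_truth


def make_intensities(
    cohort: pd.DataFrame,
    n_proteins: int = 2000,
    base_mu_log2: float = 20.0,
    base_sigma_log2: float = 1.7,
    biological_cv: float = 40.0,
    analytical_cv: float = 21.0,
    age_effect_fraction: float = 0.10,
    age_slope_sd: float = 0.05,
    sex_effect_fraction: float = 0.10,
    sex_offset: float = 0.5,
    affected_branches: dict[int, float] | None = None,
    proteins_per_branch: int = 50,
    effect_signs: str = "mixed",
    branch_of_diagnosis: dict[str, int] | None = None,
    low_noise_branch: int | None = None,
    low_noise_cv: float = 12.0,
    batch_size: int = 96,
    batch_shift_sd: float = 0.25,
    batch_shifts: dict | None = None,
    missing_rate: float = 0.30,
    missing_steepness: float = 1.0,
    qc_per_batch: int = 1,
    fluid: str = "urine",
    seed: int = 0,
) -> tuple[IntensityMatrix, dict]:
    """Raw intensity matrix for one fluid with planted, recorded effects.

    Per sample s and protein j the log2 intensity is

        baseline_j + slope_j * (age_s - 10) + sex_j * [male]
        + cluster_effect(branch_s, j) + batch_shift(b_s, j) + noise,

    exponentiated to the raw scale.  Biological noise applies to cohort
    samples, analytical noise to per-batch QC-pool samples (which carry no
    participant effects).  Missingness is logistic in log2 abundance (MNAR),
    with the intercept calibrated so the realized overall rate matches
    ``missing_rate``.  All planted effects are returned in the truth dict.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if affected_branches and branch_of_diagnosis is None:
        raise ValueError("affected_branches requires branch_of_diagnosis")
    rng = np.random.default_rng(seed)
    proteins = [f"PG{j:05d}" for j in range(n_proteins)]
    baseline = rng.normal(base_mu_log2, base_sigma_log2, size=n_proteins)

    n_age = int(round(age_effect_fraction * n_proteins))
    n_sex = int(round(sex_effect_fraction * n_proteins))
    special = rng.choice(n_proteins, size=n_age + n_sex, replace=False)
    age_idx, sex_idx = special[:n_age], special[n_age:]
    slopes = np.zeros(n_proteins)
    slopes[age_idx] = rng.normal(0.0, age_slope_sd, size=n_age)
    sex_off = np.zeros(n_proteins)
    sex_off[sex_idx] = rng.choice([-sex_offset, sex_offset], size=n_sex)

    cluster_eff: dict[int, np.ndarray] = {}
    bad = []
    if affected_branches:
        known_branches = set(branch_of_diagnosis.values())
        for b, eff in affected_branches.items():
            if b not in known_branches:
                bad.append(f"branch {b} absent from branch_of_diagnosis")
                continue
            idx = rng.choice(n_proteins, size=proteins_per_branch, replace=False)
            vec = np.zeros(n_proteins)
            if effect_signs == "mixed":
                vec[idx] = eff * rng.choice([-1.0, 1.0], size=proteins_per_branch)
            elif effect_signs == "positive":
                vec[idx] = abs(eff)
            else:
                raise ValueError("effect_signs must be 'mixed' or 'positive'")
            cluster_eff[b] = vec
    if bad:
        raise ValueError("inconsistent effect spec: " + "; ".join(bad))

    part = cohort.reset_index(drop=True)
    n_cohort = len(part)
    order = rng.permutation(n_cohort)
    batch_of = np.empty(n_cohort, dtype=object)
    for pos, i in enumerate(order):
        batch_of[i] = f"plate{pos // batch_size + 1:02d}"
    batches = sorted(set(batch_of))
    shift: dict[str, np.ndarray] = {}
    for b in batches:
        if batch_shifts is not None and b in batch_shifts:
            v = batch_shifts[b]
            shift[b] = np.full(n_proteins, float(v)) if np.isscalar(v) else np.asarray(v, float)
        elif batch_shifts is not None:
            shift[b] = np.zeros(n_proteins)
        else:
            shift[b] = rng.normal(0.0, batch_shift_sd, size=n_proteins)

    sd_bio = _log2_sd_from_cv(biological_cv)
    sd_low = _log2_sd_from_cv(low_noise_cv)
    sd_ana = _log2_sd_from_cv(analytical_cv)

    sample_ids, meta_rows, cols = [], [], []
    for i, row in enumerate(part.itertuples(index=False)):
        sid = f"{fluid[:2].upper()}_{row.participant_id}"
        b = batch_of[i]
        branch = (
            branch_of_diagnosis.get(row.diagnosis_id)
            if branch_of_diagnosis is not None else None
        )
        x = baseline + slopes * (row.age - 10.0) + sex_off * (row.sex == "male")
        if branch is not None and branch in cluster_eff:
            x = x + cluster_eff[branch]
        x = x + shift[b]
        noise_sd = sd_low if (low_noise_branch is not None and branch == low_noise_branch) else sd_bio
        x = x + rng.normal(0.0, noise_sd, size=n_proteins)
        cols.append(x)
        sample_ids.append(sid)
        meta_rows.append(
            {"sample_id": sid, "participant_id": row.participant_id, "fluid": fluid,
             "batch": b, "role": "cohort", "age": row.age, "sex": row.sex,
             "diagnosis_id": row.diagnosis_id, "group": row.group}
        )
    for b in batches:
        for r in range(qc_per_batch):
            sid = f"{fluid[:2].upper()}_QC_{b}_{r}"
            x = baseline + shift[b] + rng.normal(0.0, sd_ana, size=n_proteins)
            cols.append(x)
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "participant_id": f"QC_{b}_{r}", "fluid": fluid,
                 "batch": b, "role": "qc_pool", "age": np.nan, "sex": "female",
                 "diagnosis_id": "", "group": "qc"}
            )

    log2_vals = np.column_stack(cols)
    # MNAR: dropout probability is logistic-decreasing in log2 abundance
    if missing_rate > 0:
        flat = log2_vals.ravel()

        def excess(c):
            return expit(-missing_steepness * (flat - c)).mean() - missing_rate

        lo, hi = flat.min() - 50, flat.max() + 50
        c0 = brentq(excess, lo, hi)
        pmiss = expit(-missing_steepness * (log2_vals - c0))
        mask = rng.random(log2_vals.shape) < pmiss
    else:
        mask = np.zeros(log2_vals.shape, dtype=bool)
        c0 = None

    raw = np.power(2.0, log2_vals)
    raw[mask] = np.nan
    values = pd.DataFrame(raw, index=pd.Index(proteins, name="protein"),
                          columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = {
        "baseline_log2": baseline.tolist(),
        "age_slope_proteins": [proteins[j] for j in age_idx],
        "sex_effect_proteins": [proteins[j] for j in sex_idx],
        "cluster_effect_proteins": {
            str(b): [proteins[j] for j in np.flatnonzero(v)]
            for b, v in cluster_eff.items()
        },
        "cluster_effect_log2": {str(b): float(abs(eff)) for b, eff in
                                (affected_branches or {}).items()},
        "batch_shift_sd": batch_shift_sd if batch_shifts is None else None,
        "biological_cv": biological_cv,
        "analytical_cv": analytical_cv,
        "low_noise_branch": low_noise_branch,
        "missing_rate": missing_rate,
        "missing_intercept": c0,
        "seed": seed,
    }
    return IntensityMatrix(values, scale="raw", meta=meta), truth


def make_precursor_report(
    n_precursors: int = 4000,
    delta0_fraction_labeled: float = 0.97,
    false_channel_rate: float = 0.10,
    d0_q_high: float = 0.15,
    false_q_low: float = 0.20,
    false_q_high: float = 0.60,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Precursor report from a light-channel-only labeled sample.

    Light (d0) rows carry labeled flags whose summed intensity share equals
    ``delta0_fraction_labeled`` exactly by construction; spurious d4/d8 rows
    appear at ``false_channel_rate`` of the d0 count with channel q-values
    drawn above ``false_q_low``, so a q cutoff at or below that boundary
    keeps the false-channel ratio at zero.
    """
    if not (0 <= delta0_fraction_labeled <= 1 and 0 <= false_channel_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    inten = rng.lognormal(mean=10.0, sigma=1.5, size=n_precursors)
    rows = []
    if delta0_fraction_labeled in (0.0, 1.0):
        labeled = np.full(n_precursors, delta0_fraction_labeled == 1.0)
    else:
        # random ~5% of precursors unlabeled, rescaled so the labeled
        # intensity share equals the requested fraction exactly
        n_unl = max(1, int(round(0.05 * n_precursors)))
        unl = rng.choice(n_precursors, size=n_unl, replace=False)
        labeled = np.ones(n_precursors, dtype=bool)
        labeled[unl] = False
        f = delta0_fraction_labeled
        target_unlabeled = (1.0 - f) / f * inten[labeled].sum()
        inten[~labeled] *= target_unlabeled / inten[~labeled].sum()
    for i in range(n_precursors):
        rows.append(
            {"run_id": "run1", "channel": "d0", "precursor_id": f"PC{i:05d}",
             "intensity": float(inten[i]),
             "channel_q": float(rng.uniform(0.0, d0_q_high)),
             "labeled": bool(labeled[i])}
        )
    n_false = int(round(false_channel_rate * n_precursors))
    false_ids = []
    for i in range(n_false):
        ch = "d4" if i % 2 == 0 else "d8"
        pid = f"FC{i:05d}"
        false_ids.append(pid)
        rows.append(
            {"run_id": "run1", "channel": ch, "precursor_id": pid,
             "intensity": float(rng.lognormal(8.0, 1.0)),
             "channel_q": float(rng.uniform(false_q_low, false_q_high)),
             "labeled": False}
        )
    report = pd.DataFrame(rows)
    truth = {
        "labeled_intensity_fraction": delta0_fraction_labeled,
        "false_precursors": false_ids,
        "false_q_low": false_q_low,
        "seed": seed,
    }
    return report, truth


PRESETS = {
    # 1000 diseased participants, 300 diagnoses with a rare tail, 2000
    # proteins: the same order of magnitude as a full pediatric body-fluid
    # study, runnable in minutes on one CPU.  Diagnoses arrive as whole
    # sibling families (wide leaf fan-out), so semantic clusters can pool
    # related rare conditions into powered groups.
    "paper-scale": dict(
        ontology=dict(n_branches=15, depth=3, children_per_node=(3, 3, 7),
                      cycle_edge_count=30),
        cohort=dict(n_participants=1000, rare_diagnosis_count=260, n_diagnoses=300,
                    n_controls=131, concentrated=True),
        intensities=dict(n_proteins=2000),
    ),
    "smoke": dict(
        ontology=dict(n_branches=6, depth=3, children_per_node=(3, 3, 4),
                      cycle_edge_count=6),
        cohort=dict(n_participants=200, rare_diagnosis_count=30, n_diagnoses=40,
                    n_controls=25, concentrated=True),
        intensities=dict(n_proteins=300),
    ),
}


def simulate_all(preset: str = "smoke", seed: int = 42, out_dir=None,
                 intensity_overrides: dict | None = None,
                 plant_top_branches: tuple[int, float] | None = None):
    """Generate ontology + cohort + one intensity matrix for a preset.

    ``plant_top_branches=(count, effect)`` plants cluster effects on the
    ``count`` branches best represented in the generated cohort — planted
    effects must address patients that actually exist.  Returns a dict of
    artifacts and truths; writes TSV/JSON files when ``out_dir`` is given.
    Byte-identical for identical seeds.
    """
    from collections import Counter

    cfg = PRESETS[preset]
    onto = make_ontology(seed=seed, **cfg["ontology"])
    cohort, cohort_truth = make_cohort(onto.truth, seed=seed + 1, **cfg["cohort"])
    ikw = dict(cfg["intensities"])
    ikw.update(intensity_overrides or {})
    if plant_top_branches is not None:
        count, eff = plant_top_branches
        rep = Counter(
            onto.truth["branch_of"][d]
            for d in cohort.loc[cohort["group"] == "diagnosed", "diagnosis_id"]
        )
        ikw.setdefault("affected_branches",
                       {b: eff for b, _ in rep.most_common(count)})
    ikw.setdefault("branch_of_diagnosis",
                   {d: onto.truth["branch_of"][d] for d in cohort_truth["diagnoses"]})
    matrix, itruth = make_intensities(cohort, seed=seed + 2, **ikw)
    out = {
        "ontology": onto,
        "cohort": cohort,
        "cohort_truth": cohort_truth,
        "matrix": matrix,
        "intensity_truth": itruth,
    }
    if out_dir is not None:
        import pathlib

        d = pathlib.Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        onto.write(d / "concepts.tsv", d / "relationships.tsv")
        cohort.to_csv(d / "cohort.tsv", sep="\t", index=False)
        matrix.values.to_csv(d / "intensities_raw.tsv", sep="\t")
        matrix.meta.to_csv(d / "sample_meta.tsv", sep="\t")
        truth = {"ontology": {k: v for k, v in onto.truth.items() if k != "branch_of"},
                 "cohort": cohort_truth, "intensities": itruth}
        with open(d / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True, default=str)
    return out
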