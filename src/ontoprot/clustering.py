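"""Cluster-number selection and diagnosis clustering on embeddings.

Three clustering families (k-means, agglomerative, spectral) are swept over a
range of k; each sweep's cosine-silhouette curve is summarized by a saturating
exponential fit s(k) = a - b*exp(-beta*k), and the working k is the smallest
evaluated k whose fitted silhouette reaches 97% of the asymptote a.  The
method whose observed silhouette at its own k_opt is highest wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity

from .embedding import EmbeddingMatrix

METHODS = ("kmeans", "agglomerative", "spectral")
THRESHOLD_FRACTION = 0.97


@dataclass
class SaturationFit:
    asymptote: float
    amplitude: float
    rate: float
    k_opt: int
    threshold_fraction: float = THRESHOLD_FRACTION
    fallback: bool = False  # argmax fallback after fit failure


@dataclass
class SilhouetteCurve:
    method: str
    ks: np.ndarray
    scores: np.ndarray  # NaN where silhouette is undefined
    fit: SaturationFit | None = None


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    method: str
    seed: int

    def to_frame(self, terms: dict[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.labels.items()), columns=["concept_id", "cluster"]
        )
        if terms:
            df.insert(1, "term", df["concept_id"].map(terms))
        return df


def _cluster_labels(X: np.ndarray, method: str, k: int, seed: int) -> np.ndarray:
    if method == "kmeans":
        return KMeans(n_clusters=k, random_state=seed, n_init="auto").fit_predict(X)
    if method == "agglomerative":
        # average linkage on cosine distance, consistent with the silhouette metric
        Z = linkage(pdist(X, metric="cosine"), method="average")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    if method == "spectral":
        aff = np.clip((cosine_similarity(X) + 1.0) / 2.0, 0.0, 1.0)
        model = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=seed,
            assign_labels="kmeans",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit_predict(aff)
    raise ValueError(f"unknown clustering method {method!r}")


def _safe_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(silhouette_score(X, labels, metric="cosine"))
    except ValueError:
        return np.nan


def silhouette_sweep(
    emb: EmbeddingMatrix,
    diagnosis_nodes,
    methods=METHODS,
    k_min: int = 10,
    k_max: int = 200,
    step: int = 1,
    seed: int = 42,
) -> list[SilhouetteCurve]:
    """Cosine-silhouette curves per method over k = k_min..k_max.

    Only the diagnosis nodes are clustered; the rest of the subgraph shaped
    the embedding but receives no label.  Degenerate partitions record a
    missing score with a warning rather than a fabricated value.
    """
    nodes = sorted(diagnosis_nodes)
    n = len(nodes)
    if not (n > k_min and k_max < n):
        raise ValueError(
            f"k range [{k_min}, {k_max}] infeasible for {n} diagnosis nodes; "
            f"try k_min < {n} and k_max <= {n - 1}"
        )
    X = emb.take(nodes).astype(np.float64)
    degenerate = bool(np.allclose(X, X[0], atol=1e-12))
    ks = np.arange(k_min, k_max + 1, step)
    curves = []
    for method in methods:
        scores = np.empty(len(ks))
        for i, k in enumerate(ks):
            if degenerate:
                scores[i] = np.nan
                continue
            labels = _cluster_labels(X, method, int(k), seed)
            scores[i] = _safe_silhouette(X, labels)
        if np.isnan(scores).any():
            warnings.warn(
                f"{method}: silhouette undefined at "
                f"{int(np.isnan(scores).sum())} of {len(ks)} k values",
                stacklevel=2,
            )
        curves.append(SilhouetteCurve(method, ks.copy(), scores))
    return curves


def _saturation(k, a, b, beta):
    return a - b * np.exp(-beta * k)


def fit_saturation(curve: SilhouetteCurve) -> SaturationFit:
    """Fit s(k) = a - b*exp(-beta*k) and apply the 97%-of-asymptote rule.

    Nonlinear least squares with a multi-start grid over beta; k_opt is the
    smallest evaluated k whose *fitted* value reaches 97% of a.  If every
    start fails, falls back to the argmax of the raw scores with a flag.
    """
    mask = ~np.isnan(curve.scores)
    ks = curve.ks[mask].astype(float)
    ss = curve.scores[mask]
    if len(ks) < 4:
        raise ValueError("need at least 4 finite (k, score) points")

    if np.ptp(ss) < 1e-12:  # constant curve: saturated from the start
        fit = SaturationFit(float(ss[0]), 0.0, 1.0, int(ks[0]))
        curve.fit = fit
        return fit

    a0 = float(np.max(ss))
    b0 = max(float(a0 - ss[0]), 1e-3)
    best = None
    # b >= 0 keeps the family monotone non-decreasing toward the asymptote
    for beta0 in (1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _saturation, ks, ss, p0=(a0, b0, beta0),
                    bounds=([-1.5, 0.0, 1e-8], [1.5, 3.0, 10.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = ss - _saturation(ks, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        k_opt = int(curve.ks[mask][np.argmax(ss)])
        warnings.warn("saturation fit failed; falling back to argmax silhouette",
                      stacklevel=2)
        fit = SaturationFit(np.nan, np.nan, np.nan, k_opt, fallback=True)
        curve.fit = fit
        return fit

    a, b, beta = (float(v) for v in best[1])
    fitted = _saturation(ks, a, b, beta)
    reach = np.flatnonzero(fitted >= THRESHOLD_FRACTION * a)
    k_opt = int(ks[reach[0]]) if reach.size else int(ks[-1])
    fit = SaturationFit(a, b, beta, k_opt)
    curve.fit = fit
    return fit


def choose_best_method(curves: list[SilhouetteCurve]) -> tuple[str, int]:
    """Pick the method with the highest observed silhouette at its own k_opt.

    Ties break toward the smaller k_opt, then method name order.  If every
    curve lacks a usable fit the choice is an error.
    """
    candidates = []
    for c in curves:
        try:
            fit = c.fit if c.fit is not None else fit_saturation(c)
        except ValueError:
            continue
        idx = np.flatnonzero(c.ks == fit.k_opt)
        score = float(c.scores[idx[0]]) if idx.size else np.nan
        if np.isnan(score):
            continue
        candidates.append((-score, fit.k_opt, c.method))
    if not candidates:
        raise RuntimeError("no clustering method produced a usable silhouette fit")
    _, k_opt, method = min(candidates)
    return method, int(k_opt)


def assign_clusters(
    emb: EmbeddingMatrix, diagnosis_nodes, method: str, k: int, seed: int = 42
) -> ClusterAssignment:
    """Final cluster labels for every diagnosis node; deterministic per seed."""
    nodes = sorted(diagnosis_nodes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds the {len(nodes)} diagnosis nodes")
    X = emb.take(nodes).astype(np.float64)
    if k == 1:
        labels = np.zeros(len(nodes), dtype=int)
    else:
        labels = _cluster_labels(X, method, k, seed)
    return ClusterAssignment(dict(zip(nodes, (int(x) for x in labels))), k, method, seed)


def underpowered_reduction(
    assignment: ClusterAssignment,
    cohort: pd.DataFrame,
    min_n: int = 5,
) -> tuple[int, int, pd.DataFrame]:
    """Count underpowered (< min_n patients) diagnoses before vs clusters after.

    ``cohort`` needs ``participant_id`` and ``diagnosis_id`` columns; rows
    whose diagnosis carries no cluster label (e.g. controls) are ignored.
    """
    df = cohort[cohort["diagnosis_id"].isin(assignment.labels)].copy()
    per_dx = df.groupby("diagnosis_id")["participant_id"].nunique()
    df["cluster"] = df["diagnosis_id"].map(assignment.labels)
    per_cluster = df.groupby("cluster")["participant_id"].nunique()
    n_before = int((per_dx < min_n).sum())
    n_after = int((per_cluster < min_n).sum())
    table = pd.DataFrame(
        {
            "cluster": per_cluster.index,
            "n_patients": per_cluster.values,
            "underpowered": per_cluster.values < min_n,
        }
    )
    return n_before, n_after, table


def umap_project(
    emb: EmbeddingMatrix,
    nodes=None,
    n_neighbors: int = 30,
    min_dist: float = 0.2,
    seed: int = 42,
) -> pd.DataFrame:
    """2-D UMAP projection of node vectors (deterministic via random_state)."""
    import umap

    nodes = sorted(nodes) if nodes is not None else list(emb.ids)
    if len(nodes) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} nodes, got {len(nodes)}"
        )
    X = emb.take(nodes).astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = umap.UMAP(
            n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed,
            n_components=2,
        ).fit_transform(X)
    return pd.DataFrame(coords, index=pd.Index(nodes, name="concept_id"),
                        columns=["umap1", "umap2"])


def plot_clusters(coords: pd.DataFrame, assignment: ClusterAssignment, path) -> None:
    """Scatter of the projection colored by cluster, median-centered labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = coords.index.map(assignment.labels)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.scatter(coords["umap1"], coords["umap2"], c=labels, cmap="tab20", s=12)
    for cl in sorted(set(labels.dropna())):
        sub = coords[labels == cl]
        ax.annotate(str(int(cl)), sub.median(), ha="center", fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sweep_to_frame(curves: list[SilhouetteCurve]) -> pd.DataFrame:
    """Long-format (method, k, silhouette) table of a sweep."""
    frames = [
        pd.DataFrame({"method": c.method, "k": c.ks, "silhouette": c.scores})
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
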