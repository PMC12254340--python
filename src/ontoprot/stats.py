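"""Per-protein statistical layer: BH FDR, ANOVA, ANCOVA, Welch tests,
cross-fluid correlation, and KNN-imputed PCA.

All tests run on log2 intensities, are two-sided, and are complete-case per
protein (imputation exists only in the PCA path).  The BH family is always
the set of proteins tested within one comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer
from sklearn.preprocessing import StandardScaler


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending sort, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the finite entries only; NaN rows stay NaN."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return q


def welch_de(
    m_log2: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch's t test per protein, group A vs group B, BH-adjusted.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with Welch-Satterthwaite
    degrees of freedom; built for highly unbalanced designs (n as small as 2
    against a large control pool).  Proteins with <2 present values in either
    group are skipped (``reason`` column); zero variance in both groups gives
    p = 1 when the means agree and a missing, flagged p otherwise.
    """
    A = m_log2[list(group_a)].to_numpy(dtype=float)
    B = m_log2[list(group_b)].to_numpy(dtype=float)
    na = np.sum(~np.isnan(A), axis=1)
    nb = np.sum(~np.isnan(B), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)

    testable = (na >= 2) & (nb >= 2)
    sa, sb = va / np.maximum(na, 1), vb / np.maximum(nb, 1)
    denom = np.sqrt(sa + sb)
    t = np.full(len(m_log2), np.nan)
    p = np.full(len(m_log2), np.nan)
    df = np.full(len(m_log2), np.nan)
    reason = np.array([""] * len(m_log2), dtype=object)
    reason[~testable] = "fewer_than_2_values_per_group"

    degen = testable & (denom == 0)
    equal_degen = degen & np.isclose(ma, mb)
    t[equal_degen], p[equal_degen] = 0.0, 1.0
    reason[degen & ~equal_degen] = "zero_variance_unequal_means"

    ok = testable & (denom > 0)
    t[ok] = (ma[ok] - mb[ok]) / denom[ok]
    df[ok] = (sa[ok] + sb[ok]) ** 2 / (
        sa[ok] ** 2 / (na[ok] - 1) + sb[ok] ** 2 / (nb[ok] - 1)
    )
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])

    q = _bh_with_nan(p)
    return pd.DataFrame(
        {
            "protein": m_log2.index,
            "n_case": na,
            "n_control": nb,
            "log2fc": ma - mb,
            "statistic": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": np.where(np.isfinite(q), q < alpha, False),
            "reason": reason,
        }
    ).set_index("protein")


def default_age_bins(ages: pd.Series) -> pd.Series:
    """Integer-year age groups (floor of age in years)."""
    return ages.astype(float).apply(np.floor).astype(int)


def anova_age_sex(
    m_log2: pd.DataFrame,
    meta: pd.DataFrame,
    min_valid: float = 0.70,
    alpha: float = 0.01,
    age_bins=None,
) -> pd.DataFrame:
    """One-way ANOVA over sex x age-group cells, BH at ``alpha``.

    Proteins with less than ``min_valid`` non-missing fraction are dropped
    before testing.  Per protein, only cells with >=2 present values enter the
    F statistic; proteins with fewer than 2 such cells are skipped with a
    reason code.
    """
    meta = meta.loc[list(m_log2.columns)]
    groups = meta["sex"].astype(str) + "|" + (
        default_age_bins(meta["age"]) if age_bins is None else meta["age"].map(age_bins)
    ).astype(str)
    keep = m_log2.notna().mean(axis=1) >= min_valid
    X = m_log2[keep]

    codes, _ = pd.factorize(groups)
    rows = []
    V = X.to_numpy(dtype=float)
    for i, protein in enumerate(X.index):
        v = V[i]
        samples = [v[(codes == g) & ~np.isnan(v)] for g in range(codes.max() + 1)]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            rows.append((protein, np.nan, np.nan, "fewer_than_2_testable_groups"))
            continue
        if all(np.allclose(s, s[0]) for s in samples) and len(
            {round(float(s[0]), 12) for s in samples}
        ) == 1:
            rows.append((protein, 0.0, 1.0, ""))
            continue
        F, p = sps.f_oneway(*samples)
        rows.append((protein, float(F), float(p), ""))
    out = pd.DataFrame(rows, columns=["protein", "F", "p", "reason"]).set_index("protein")
    out["q"] = _bh_with_nan(out["p"].to_numpy())
    out["significant"] = np.where(np.isfinite(out["q"]), out["q"] < alpha, False)
    return out


def trajectory_modules(
    sig_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    n_modules: int = 5,
    age_bins=None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Hierarchical trajectory modules of significant proteins.

    Rows are z-scored mean log2 intensities per sex x age cell; modules come
    from agglomerative clustering (Euclidean metric, average linkage) cut at
    ``n_modules``.  Returns (module label per protein, per-module trajectory
    table with mean and a normal-approximation 95% band per cell).
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    if len(sig_matrix) < n_modules:
        raise ValueError("need at least n_modules proteins")
    meta = meta.loc[list(sig_matrix.columns)]
    age = default_age_bins(meta["age"]) if age_bins is None else meta["age"].map(age_bins)
    cell = meta["sex"].astype(str) + "|" + age.astype(str)
    cell_means = sig_matrix.T.groupby(cell.to_numpy()).mean().T  # proteins x cells

    mu = cell_means.mean(axis=1)
    sd = cell_means.std(axis=1, ddof=1)
    nonconst = sd > 0
    if (~nonconst).any():
        warnings.warn(
            f"dropping {int((~nonconst).sum())} zero-variance protein(s) "
            "whose z-score is undefined",
            stacklevel=2,
        )
    Z = cell_means[nonconst].sub(mu[nonconst], axis=0).div(sd[nonconst], axis=0)

    if n_modules == 1:
        labels = pd.Series(0, index=Z.index, name="module")
    else:
        link = linkage(Z.to_numpy(), method="average", metric="euclidean")
        labels = pd.Series(
            fcluster(link, t=n_modules, criterion="maxclust") - 1,
            index=Z.index, name="module",
        )
    traj = []
    for mod in sorted(labels.unique()):
        block = Z[labels == mod]
        mean = block.mean(axis=0)
        half = 1.96 * block.std(axis=0, ddof=1) / np.sqrt(len(block))
        for c in Z.columns:
            sex, age_g = c.split("|")
            traj.append(
                {"module": mod, "sex": sex, "age_group": age_g,
                 "mean_z": float(mean[c]),
                 "lo95": float(mean[c] - half[c]) if len(block) > 1 else np.nan,
                 "hi95": float(mean[c] + half[c]) if len(block) > 1 else np.nan,
                 "n_proteins": int(len(block))}
            )
    return labels, pd.DataFrame(traj)


def ancova_disease(
    m_log2: pd.DataFrame,
    meta: pd.DataFrame,
    disease_samples,
    control_samples,
    alpha: float = 0.05,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-protein linear model: log2 intensity ~ disease + age + sex.

    The p-value is the two-sided t test of the disease coefficient; the
    reported ``log2fc`` is the plain difference of group means (stored
    alongside the adjusted coefficient to keep both unambiguous).  Complete
    cases only; if one sex is absent the sex covariate is dropped with a
    warning and noted per protein.
    """
    disease_samples, control_samples = list(disease_samples), list(control_samples)
    cols = disease_samples + control_samples
    sub = m_log2[cols]
    info = meta.loc[cols]
    disease = np.r_[np.ones(len(disease_samples)), np.zeros(len(control_samples))]
    age = info["age"].to_numpy(dtype=float)
    sex = (info["sex"].astype(str) == "male").to_numpy(dtype=float)

    sex_varies = len(np.unique(sex)) > 1
    if not sex_varies:
        warnings.warn("single-sex design: sex covariate dropped", stacklevel=2)

    Y = sub.to_numpy(dtype=float)
    rows = []
    for i, protein in enumerate(sub.index):
        y = Y[i]
        obs = ~np.isnan(y)
        nd = int((obs & (disease == 1)).sum())
        nc = int((obs & (disease == 0)).sum())
        if nd < min_n or nc < min_n:
            rows.append((protein, nd, nc, np.nan, np.nan, np.nan, np.nan,
                         "fewer_than_min_n_complete_cases"))
            continue
        cols_x = [np.ones(obs.sum()), disease[obs], age[obs]]
        note = "" if sex_varies else "sex_dropped"
        if sex_varies:
            if len(np.unique(sex[obs])) > 1:
                cols_x.append(sex[obs])
            else:
                note = "sex_dropped"
        X = np.column_stack(cols_x)
        yv = y[obs]
        n, k = X.shape
        if n <= k:
            rows.append((protein, nd, nc, np.nan, np.nan, np.nan, np.nan,
                         "insufficient_residual_df"))
            continue
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            rows.append((protein, nd, nc, np.nan, np.nan, np.nan, np.nan,
                         "singular_design"))
            continue
        beta = XtX_inv @ (X.T @ yv)
        resid = yv - X @ beta
        sigma2 = float(resid @ resid) / (n - k)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        coef = float(beta[1])
        if se == 0:
            tstat, pval = (0.0, 1.0) if coef == 0 else (np.nan, np.nan)
        else:
            tstat = coef / se
            pval = float(2.0 * sps.t.sf(abs(tstat), n - k))
        log2fc = float(np.nanmean(yv[disease[obs] == 1]) - np.nanmean(yv[disease[obs] == 0]))
        rows.append((protein, nd, nc, log2fc, coef, tstat, pval, note))

    out = pd.DataFrame(
        rows,
        columns=["protein", "n_case", "n_control", "log2fc", "coef_disease",
                 "statistic", "p", "note"],
    ).set_index("protein")
    out["q"] = _bh_with_nan(out["p"].to_numpy())
    out["significant"] = np.where(np.isfinite(out["q"]), out["q"] < alpha, False)
    return out


def fluid_correlation(
    urine_m: pd.DataFrame,
    plasma_m: pd.DataFrame,
    urine_participants: pd.Series,
    plasma_participants: pd.Series,
    alpha: float = 0.01,
    r_threshold: float = 0.4,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-protein Pearson correlation between paired urine and plasma values.

    Samples are paired by participant; proteins present in both matrices with
    at least ``min_pairs`` complete pairs are tested.  Significance requires
    |r| > ``r_threshold`` and BH q < ``alpha``.
    """
    u_by_part = {p: s for s, p in urine_participants.items()}
    p_by_part = {p: s for s, p in plasma_participants.items()}
    shared_parts = sorted(set(u_by_part) & set(p_by_part))
    if not shared_parts:
        raise ValueError("no participants with samples in both fluids")
    u_cols = [u_by_part[p] for p in shared_parts]
    p_cols = [p_by_part[p] for p in shared_parts]
    shared_prot = urine_m.index.intersection(plasma_m.index)

    U = urine_m.loc[shared_prot, u_cols].to_numpy(dtype=float)
    P = plasma_m.loc[shared_prot, p_cols].to_numpy(dtype=float)
    rows = []
    for i, protein in enumerate(shared_prot):
        obs = ~np.isnan(U[i]) & ~np.isnan(P[i])
        n = int(obs.sum())
        if n < min_pairs:
            rows.append((protein, n, np.nan, np.nan, "fewer_than_min_pairs"))
            continue
        u, p_ = U[i, obs], P[i, obs]
        if np.std(u) == 0 or np.std(p_) == 0:
            rows.append((protein, n, np.nan, np.nan, "zero_variance"))
            continue
        r, pval = sps.pearsonr(u, p_)
        rows.append((protein, n, float(r), float(pval), ""))
    out = pd.DataFrame(
        rows, columns=["protein", "n_pairs", "r", "p", "reason"]
    ).set_index("protein")
    out["q"] = _bh_with_nan(out["p"].to_numpy())
    out["significant"] = np.where(
        np.isfinite(out["q"]),
        (out["r"].abs() > r_threshold) & (out["q"] < alpha),
        False,
    )
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def knn_impute_pca(
    m_log2: pd.DataFrame,
    k_neighbors: int = 5,
    n_components: int = 2,
) -> PCAResult:
    """KNN imputation (k=5), per-feature standardization, then SVD-based PCA.

    The matrix is transposed so samples are observations and proteins are
    features; zero-variance features after imputation are dropped with a
    warning.
    """
    X = m_log2.T  # samples x proteins
    if (X.notna().sum(axis=1) == 0).any():
        raise ValueError("every sample must have at least one observed value")
    imputed = KNNImputer(n_neighbors=k_neighbors).fit_transform(X)
    var = imputed.var(axis=0)
    keep = var > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s) after imputation",
            stacklevel=2,
        )
    features = X.columns[keep]
    Z = StandardScaler().fit_transform(imputed[:, keep])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    comp_cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_cols),
        loadings=pd.DataFrame(pca.components_.T, index=features, columns=comp_cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
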