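"""Quality control and preprocessing for body-fluid protein intensity matrices.

Covers the preprocessing chain (log2 transform, identification-count filters,
empirical-Bayes batch correction), coefficient-of-variation statistics for
analytical and biological reproducibility, data completeness, and the
multiplexed-DIA channel QC (labeling efficiency and the channel q-value
cutoff sweep on a light-channel-only sample).

Matrices are proteins x samples.  Missing values are NaN; zeros in raw input
are treated as missing by default because DIA outputs conflate the two.
Filters operate on identification counts, which are scale-invariant, so the
filter/log2 order cannot change which samples survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

FLUIDS = ("urine", "neat_plasma", "pcan_plasma")
ROLES = ("cohort", "qc_pool", "reference_channel")

#: Fluid-scoped defaults for the identification-count filters: the stringent
#: fixed cutoff applies to urine, the one-sided IQR rule to the plasma fluids.
QC_FILTERS = {
    "urine": {"min_ids": 800},
    "neat_plasma": {"iqr": True},
    "pcan_plasma": {"iqr": True},
}


@dataclass
class IntensityMatrix:
    """Protein x sample intensity matrix with linked sample metadata."""

    values: pd.DataFrame
    scale: str = "raw"  # "raw" | "log2"
    meta: pd.DataFrame | None = None  # indexed by sample_id

    def __post_init__(self):
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.meta is not None:
            unknown = set(self.values.columns) - set(self.meta.index)
            if unknown:
                raise ValueError(
                    f"{len(unknown)} sample column(s) missing from metadata: "
                    f"{sorted(unknown)[:5]}"
                )

    def meta_for_samples(self) -> pd.DataFrame:
        return self.meta.loc[list(self.values.columns)]

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids (present in the matrix) matching metadata equality filters."""
        m = self.meta_for_samples()
        mask = pd.Series(True, index=m.index)
        for col, val in conditions.items():
            mask &= m[col].isin(val) if isinstance(val, (list, tuple, set)) else m[col] == val
        return list(m.index[mask])


def as_missing(values: pd.DataFrame, zeros_are_missing: bool = True) -> pd.DataFrame:
    out = values.astype(float)
    if zeros_are_missing:
        out = out.mask(out == 0.0)
    return out


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """log2 of every present intensity; missing stays missing."""
    if m.scale != "raw":
        raise ValueError("matrix is already on the log2 scale")
    vals = m.values
    if (vals <= 0).any().any():
        raise ValueError("raw intensities must be positive where present")
    return replace(m, values=np.log2(vals), scale="log2")


def id_counts(m: IntensityMatrix) -> pd.Series:
    """Present-protein (identification) count per sample."""
    return m.values.notna().sum(axis=0)


def filter_min_ids(m: IntensityMatrix, min_ids: int = 800):
    """Drop samples with fewer than ``min_ids`` identified proteins (strict <)."""
    counts = id_counts(m)
    removed = list(counts.index[counts < min_ids])
    kept = [c for c in m.values.columns if c not in removed]
    if not kept:
        raise ValueError(f"all samples fall below the {min_ids}-identification cutoff")
    return replace(m, values=m.values[kept]), removed


def filter_iqr_outliers(m: IntensityMatrix):
    """Drop samples whose identification count is below Q1 - 1.5*IQR.

    Quartiles use linear interpolation; the rule is one-sided (only low-count
    outliers are removed).  Returns (filtered, removed, threshold).
    """
    counts = id_counts(m)
    if len(counts) < 4:
        raise ValueError("need at least 4 samples for the IQR rule")
    q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
    threshold = q1 - 1.5 * (q3 - q1)
    removed = list(counts.index[counts < threshold])
    kept = [c for c in m.values.columns if c not in removed]
    return replace(m, values=m.values[kept]), removed, float(threshold)


# ---------------------------------------------------------------------------
# ComBat batch correction (parametric empirical Bayes), NaN-aware.


def _combat_standardize(X, batches, batch_index):
    n_batches = len(batches)
    n_prot = X.shape[0]
    obs = ~np.isnan(X)
    n_per_batch = np.array([obs[:, idx].sum(axis=1) for idx in batch_index]).T
    grand_n = obs.sum(axis=1)

    batch_mean = np.full((n_prot, n_batches), np.nan)
    for b, idx in enumerate(batch_index):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            batch_mean[:, b] = np.nanmean(X[:, idx], axis=1)
    # weighted grand mean over batches (weights = per-batch sample counts)
    weights = n_per_batch / np.maximum(grand_n[:, None], 1)
    stand_mean = np.nansum(weights * batch_mean, axis=1)

    # pooled variance around the per-batch means (location model residuals)
    fitted = np.empty_like(X)
    for b, idx in enumerate(batch_index):
        fitted[:, idx] = batch_mean[:, b][:, None]
    pooled_var = np.nansum((X - fitted) ** 2, axis=1) / np.maximum(grand_n, 1)
    pooled_sd = np.sqrt(pooled_var)
    pooled_sd[pooled_sd == 0] = 1.0
    Z = (X - stand_mean[:, None]) / pooled_sd[:, None]
    return Z, stand_mean, pooled_sd, n_per_batch


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def batch_correct(m: IntensityMatrix, batch: pd.Series | None = None) -> IntensityMatrix:
    """Location-scale batch adjustment with parametric empirical-Bayes priors.

    Per protein, batch means and variances are standardized away after
    shrinking the per-batch estimates toward their across-protein priors
    (normal prior on locations, inverse-gamma on scales).  Per-protein
    overall means are preserved; missing entries stay missing.
    """
    if m.scale != "log2":
        raise ValueError("batch correction expects a log2-scale matrix")
    if batch is None:
        if m.meta is None or "batch" not in m.meta.columns:
            raise ValueError("no batch labels: pass `batch` or provide meta['batch']")
        batch = m.meta_for_samples()["batch"]
    batch = batch.loc[list(m.values.columns)]

    batches = sorted(batch.unique())
    cols = np.asarray(m.values.columns)
    batch_index = [np.flatnonzero((batch == b).to_numpy()) for b in batches]
    for b, idx in zip(batches, batch_index):
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    if len(batches) == 1:
        return replace(m, values=m.values.copy())

    X = m.values.to_numpy(dtype=float)
    Z, stand_mean, pooled_sd, n_per_batch = _combat_standardize(X, batches, batch_index)

    corrected = np.full_like(Z, np.nan)
    for b, idx in enumerate(batch_index):
        sdat = Z[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g_hat = np.nanmean(sdat, axis=1)
            d_hat = np.nanvar(sdat, axis=1, ddof=1)
        ok = np.isfinite(g_hat) & np.isfinite(d_hat) & (d_hat > 0)
        g_star = g_hat.copy()
        d_star = np.where(np.isfinite(d_hat) & (d_hat > 0), d_hat, 1.0)
        if ok.sum() >= 2:
            g_bar = float(np.mean(g_hat[ok]))
            t2 = float(np.var(g_hat[ok], ddof=1))
            m_ = float(np.mean(d_hat[ok]))
            s2 = float(np.var(d_hat[ok], ddof=1))
            if t2 > 0 and s2 > 0:
                a_prior = (2 * s2 + m_**2) / s2
                b_prior = (m_ * s2 + m_**3) / s2
                g_sol, d_sol = _it_sol(
                    sdat[ok], g_hat[ok], d_hat[ok], g_bar, t2, a_prior, b_prior
                )
                g_star[ok] = g_sol
                d_star[ok] = d_sol
        corrected[:, idx] = (sdat - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = corrected * pooled_sd[:, None] + stand_mean[:, None]
    out[np.isnan(X)] = np.nan
    return replace(m, values=pd.DataFrame(out, index=m.values.index, columns=cols))


# ---------------------------------------------------------------------------
# CV, completeness, mDIA channel QC.


def cv_per_protein(m: IntensityMatrix, samples=None) -> tuple[pd.Series, float]:
    """Per-protein CV% = 100 * sd / mean over present raw intensities.

    Uses the sample standard deviation (ddof=1).  Proteins with fewer than
    two present values in the subset are skipped.  Returns (per-protein CV%,
    median CV%).  Analytical CVs use reference-channel or QC-pool samples;
    biological CVs use cohort participants.
    """
    if m.scale != "raw":
        raise ValueError("CVs are computed from raw intensities")
    vals = m.values if samples is None else m.values[list(samples)]
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute CVs")
    n = vals.notna().sum(axis=1)
    vals = vals[n >= 2]
    cv = 100.0 * vals.std(axis=1, ddof=1) / vals.mean(axis=1)
    return cv, float(cv.median())


def analytical_cv(m: IntensityMatrix) -> tuple[pd.Series, float]:
    """CV over reference-channel / QC-pool samples (repeated pooled material)."""
    samples = m.samples_where(role=("reference_channel", "qc_pool"))
    return cv_per_protein(m, samples)


def biological_cv(m: IntensityMatrix) -> tuple[pd.Series, float]:
    """CV across distinct cohort participants."""
    return cv_per_protein(m, m.samples_where(role="cohort"))


def completeness(m: IntensityMatrix, threshold: float = 0.60):
    """Per-protein valid-value fraction and the set strictly above ``threshold``.

    Returns (fractions, passing protein index, passing fraction of proteins).
    """
    frac = m.values.notna().mean(axis=1)
    passing = frac.index[frac > threshold]
    return frac, passing, float(len(passing) / len(frac)) if len(frac) else np.nan


def labeling_efficiency(report: pd.DataFrame) -> float:
    """Summed intensity of labeled precursors over summed total intensity."""
    if report.empty:
        raise ValueError("empty precursor report")
    total = float(report["intensity"].sum())
    if total == 0:
        raise ValueError("zero total precursor intensity")
    return float(report.loc[report["labeled"], "intensity"].sum()) / total


def channel_q_sweep(
    report: pd.DataFrame,
    cutoffs=None,
    fdr_target: float = 0.01,
) -> tuple[pd.DataFrame, float | None]:
    """False-channel ratio per channel-q cutoff on a light-only labeled sample.

    The input derives from a sample labeled only in the light channel, so any
    intermediate/heavy identification is false.  Per cutoff c the ratio is
    (#d4 + #d8 rows with q < c) / (#d0 rows with q < c); the recommended
    cutoff is the largest c keeping the ratio under ``fdr_target``.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.05, 0.501, 0.05), 2)
    q = report["channel_q"].to_numpy()
    is_d0 = (report["channel"] == "d0").to_numpy()
    is_false = np.isin(report["channel"].to_numpy(), ("d4", "d8"))
    rows = []
    for c in cutoffs:
        sel = q < c
        n0 = int((sel & is_d0).sum())
        nf = int((sel & is_false).sum())
        ratio = nf / n0 if n0 > 0 else np.nan
        rows.append({"cutoff": float(c), "n_d0": n0, "n_false": nf, "ratio": ratio})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["ratio"]).query("ratio < @fdr_target")
    recommended = float(ok["cutoff"].max()) if len(ok) else None
    return table, recommended


def load_intensity_tsv(matrix_path, meta_path=None, scale="raw",
                       zeros_are_missing=True) -> IntensityMatrix:
    """Read a protein x sample TSV (first column = protein group id)."""
    vals = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return IntensityMatrix(as_missing(vals, zeros_are_missing), scale=scale, meta=meta)


def qc_report(m: IntensityMatrix) -> dict:
    """Summary dictionary: per-sample ID counts, CV medians, completeness."""
    counts = id_counts(m)
    out = {
        "n_proteins": int(m.values.shape[0]),
        "n_samples": int(m.values.shape[1]),
        "median_ids_per_sample": float(counts.median()),
    }
    if m.scale == "raw" and m.meta is not None:
        try:
            out["analytical_cv_median"] = analytical_cv(m)[1]
        except (ValueError, KeyError):
            pass
        try:
            out["biological_cv_median"] = biological_cv(m)[1]
        except (ValueError, KeyError):
            pass
    _, _, frac_pass = completeness(m)
    out["completeness_gt60_fraction"] = frac_pass
    return out
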