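"""BH adjustment, Welch/ANOVA/ANCOVA testing, correlation, imputed PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ontoprot.stats import (
    anova_age_sex,
    ancova_disease,
    bh_adjust,
    fluid_correlation,
    knn_impute_pca,
    trajectory_modules,
    welch_de,
)


def bh_oracle(p):
    """Brute-force step-up oracle: for each p_i, minimize p_j*m/rank_j over
    every j with p_j >= p_i, where rank_j counts values <= p_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_enumerated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_ties_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.5] * 7), [0.5] * 7)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_array_equal(bh_adjust(p), bh_oracle(p))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def frame(rows, prefix="s"):
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(arr, index=[f"prot{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestWelchDe:
    def test_identical_groups_t_zero_p_one(self):
        m = frame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = welch_de(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res["statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_textbook_fixture_matches_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        m = frame([np.r_[a, b]])
        res = welch_de(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # independent formula evaluation
        sa, sb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / 2 + sb**2 / 2)
        p = 2 * sps.t.sf(abs(t), df)
        assert res["statistic"].iloc[0] == pytest.approx(t, rel=1e-12)
        assert res["p"].iloc[0] == pytest.approx(p, rel=1e-12)
        # and scipy as a second, independent route
        t2, p2 = sps.ttest_ind(a, b, equal_var=False)
        assert res["statistic"].iloc[0] == pytest.approx(t2, rel=1e-12)
        assert res["p"].iloc[0] == pytest.approx(p2, rel=1e-12)

    def test_log2fc_is_mean_difference(self):
        m = frame([[5.0, 7.0, 1.0, 1.0]])
        res = welch_de(m, ["s0", "s1"], ["s2", "s3"])
        assert res["log2fc"].iloc[0] == pytest.approx(5.0)

    def test_insufficient_values_skipped_with_reason(self):
        m = frame([[1.0, np.nan, 2.0, 3.0]])
        res = welch_de(m, ["s0", "s1"], ["s2", "s3"])
        assert res["reason"].iloc[0] == "fewer_than_2_values_per_group"
        assert not res["significant"].iloc[0]

    def test_degenerate_zero_variance_unequal_means_flagged(self):
        m = frame([[1.0, 1.0, 2.0, 2.0]])
        res = welch_de(m, ["s0", "s1"], ["s2", "s3"])
        assert np.isnan(res["p"].iloc[0])
        assert res["reason"].iloc[0] == "zero_variance_unequal_means"

    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(2000, 40))
        m = frame(X)
        res = welch_de(m, [f"s{i}" for i in range(4)],
                       [f"s{i}" for i in range(4, 40)])
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000) + 0.005


def sample_meta(n, seed=0, two_sexes=True):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.integers(3, 18, n),
            "sex": [("male" if i % 2 else "female") if two_sexes else "female"
                    for i in range(n)],
        },
        index=[f"s{j}" for j in range(n)],
    )


class TestAnovaAgeSex:
    def test_hand_fixture_matches_sums_of_squares_oracle(self):
        # three groups with clear differences, 4 samples each
        vals = np.r_[[1.0, 1.1, 0.9, 1.0], [2.0, 2.1, 1.9, 2.0],
                     [3.0, 3.1, 2.9, 3.0]]
        m = frame([vals])
        meta = pd.DataFrame(
            {"age": [5] * 4 + [6] * 4 + [7] * 4, "sex": ["female"] * 12},
            index=[f"s{j}" for j in range(12)],
        )
        res = anova_age_sex(m, meta, min_valid=0.5, alpha=0.01)
        groups = [vals[:4], vals[4:8], vals[8:]]
        grand = vals.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / 2) / (ssw / 9)
        assert res["F"].iloc[0] == pytest.approx(F, rel=1e-10)
        assert res["F"].iloc[0] == pytest.approx(
            sps.f_oneway(*groups).statistic, rel=1e-12
        )

    def test_planted_cell_shift_detected(self):
        rng = np.random.default_rng(1)
        n_cells, per = 6, 20
        meta = pd.DataFrame(
            {"age": np.repeat([5, 6, 7], 2 * per),
             "sex": np.tile(np.repeat(["male", "female"], per), 3)},
            index=[f"s{j}" for j in range(n_cells * per)],
        )
        X = rng.normal(0, 0.4, (30, n_cells * per))
        X[0, :per] += 2.0  # strong shift in one sex-age cell
        res = anova_age_sex(frame(X), meta, alpha=0.01)
        assert res["significant"].iloc[0]
        assert (res["significant"].iloc[1:].sum()) <= 2

    def test_low_validity_proteins_dropped(self):
        X = np.full((2, 20), 1.0)
        X[1, :12] = np.nan  # only 40% valid
        res = anova_age_sex(frame(X), sample_meta(20), min_valid=0.70)
        assert "prot1" not in res.index


class TestTrajectoryModules:
    def test_opposite_trends_split_into_modules(self):
        ages = np.repeat(np.arange(4, 12), 6)
        n = len(ages)
        meta = pd.DataFrame(
            {"age": ages, "sex": np.tile(["male", "female"], n // 2)},
            index=[f"s{j}" for j in range(n)],
        )
        rng = np.random.default_rng(0)
        up = np.tile(np.linspace(0, 2, n), (6, 1)) + rng.normal(0, 0.05, (6, n))
        down = np.tile(np.linspace(2, 0, n), (6, 1)) + rng.normal(0, 0.05, (6, n))
        labels, traj = trajectory_modules(frame(np.vstack([up, down])), meta,
                                          n_modules=2)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_module_and_zscore_normalization(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 24))
        meta = sample_meta(24, seed=3)
        with np.errstate(all="ignore"):
            labels, traj = trajectory_modules(frame(X), meta, n_modules=1)
        assert labels.nunique() == 1
        assert (traj["module"] == 0).all()

    def test_zero_variance_rows_dropped_with_warning(self):
        X = np.vstack([np.ones((1, 24)), np.random.default_rng(4).normal(size=(5, 24))])
        with pytest.warns(UserWarning, match="zero-variance"):
            labels, _ = trajectory_modules(frame(X), sample_meta(24), n_modules=2)
        assert "prot0" not in labels.index


def ancova_data(n_d=20, n_c=30, effect=1.0, age_slope=0.0, age_gap=0.0, seed=0,
                n_prot=1):
    rng = np.random.default_rng(seed)
    age_d = rng.uniform(3, 17, n_d) + age_gap
    age_c = rng.uniform(3, 17, n_c)
    ages = np.r_[age_d, age_c]
    sexes = ["male" if i % 2 else "female" for i in range(n_d + n_c)]
    sex_num = (np.array(sexes) == "male").astype(float)
    disease = np.r_[np.ones(n_d), np.zeros(n_c)]
    X = (
        effect * disease
        + age_slope * ages
        + 0.3 * sex_num
        + rng.normal(0, 0.5, (n_prot, n_d + n_c))
    )
    cols = [f"s{j}" for j in range(n_d + n_c)]
    meta = pd.DataFrame({"age": ages, "sex": sexes}, index=cols)
    return (pd.DataFrame(X, columns=cols,
                         index=[f"prot{i}" for i in range(n_prot)]),
            meta, cols[:n_d], cols[n_d:])


class TestAncovaDisease:
    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=12)
        m = frame([np.r_[vals[:6], vals[:6]]])
        meta = sample_meta(12, seed=5)
        res = ancova_disease(m, meta, [f"s{j}" for j in range(6)],
                             [f"s{j}" for j in range(6, 12)])
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_coefficients_match_statsmodels_oracle(self):
        import statsmodels.api as sm

        m, meta, dis, ctl = ancova_data(n_d=10, n_c=10, effect=0.8,
                                        age_slope=0.05, seed=6)
        res = ancova_disease(m, meta, dis, ctl)
        X = pd.DataFrame(
            {
                "const": 1.0,
                "disease": np.r_[np.ones(10), np.zeros(10)],
                "age": meta["age"].to_numpy(),
                "sex": (meta["sex"] == "male").astype(float).to_numpy(),
            }
        )
        fit = sm.OLS(m.iloc[0].to_numpy(), X).fit()
        assert res["coef_disease"].iloc[0] == pytest.approx(
            fit.params["disease"], rel=1e-8
        )
        assert res["p"].iloc[0] == pytest.approx(fit.pvalues["disease"], rel=1e-8)

    def test_confounded_age_biases_naive_but_not_adjusted(self):
        adj, naive = [], []
        for seed in range(20):
            m, meta, dis, ctl = ancova_data(
                n_d=50, n_c=131, effect=1.0, age_slope=0.1, age_gap=4.0,
                seed=seed,
            )
            res = ancova_disease(m, meta, dis, ctl)
            adj.append(res["coef_disease"].iloc[0])
            naive.append(res["log2fc"].iloc[0])
        assert abs(np.mean(adj) - 1.0) < 0.1
        assert np.mean(naive) - 1.0 > 0.25  # biased upward by age confound

    def test_single_sex_drops_covariate_with_warning(self):
        m, meta, dis, ctl = ancova_data(n_d=8, n_c=8, seed=7)
        meta["sex"] = "female"
        with pytest.warns(UserWarning, match="sex covariate"):
            res = ancova_disease(m, meta, dis, ctl)
        assert (res["note"] == "sex_dropped").all()

    def test_too_few_complete_cases_skipped(self):
        m, meta, dis, ctl = ancova_data(n_d=4, n_c=8, seed=8)
        m.loc["prot0", dis[:2]] = np.nan
        res = ancova_disease(m, meta, dis, ctl, min_n=3)
        assert res["reason" if "reason" in res else "note"].iloc[0] != ""
        assert np.isnan(res["p"].iloc[0])


class TestFluidCorrelation:
    def paired(self, u_vals, p_vals):
        n = len(u_vals[0])
        parts = [f"P{i}" for i in range(n)]
        u = pd.DataFrame(u_vals, columns=[f"u{i}" for i in range(n)],
                         index=["protA"]) if len(u_vals) == 1 else None
        u = pd.DataFrame(np.atleast_2d(u_vals),
                         columns=[f"u{i}" for i in range(n)],
                         index=[f"prot{i}" for i in range(len(u_vals))])
        p = pd.DataFrame(np.atleast_2d(p_vals),
                         columns=[f"p{i}" for i in range(n)],
                         index=[f"prot{i}" for i in range(len(p_vals))])
        u_parts = pd.Series(parts, index=u.columns)
        p_parts = pd.Series(parts, index=p.columns)
        return u, p, u_parts, p_parts

    def test_identical_vectors_r_one(self):
        x = [list(range(8))]
        res = fluid_correlation(*self.paired(x, x))
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_exact_negatives_r_minus_one(self):
        x = np.arange(8.0)
        res = fluid_correlation(*self.paired([x], [-x]))
        assert res["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(9)
        U = rng.normal(size=(30, 12))
        P = 0.5 * U + rng.normal(size=(30, 12))
        res = fluid_correlation(*self.paired(U, P))
        for i in range(30):
            u, p = U[i], P[i]
            r = ((u - u.mean()) * (p - p.mean())).sum() / np.sqrt(
                ((u - u.mean()) ** 2).sum() * ((p - p.mean()) ** 2).sum()
            )
            assert res["r"].iloc[i] == pytest.approx(r, rel=1e-10)

    def test_significance_needs_both_r_and_q(self):
        rng = np.random.default_rng(10)
        U = rng.normal(size=(40, 30))
        P = rng.normal(size=(40, 30))
        U[0] = np.linspace(0, 1, 30)
        P[0] = U[0] + rng.normal(0, 0.05, 30)
        res = fluid_correlation(*self.paired(U, P))
        assert res["significant"].iloc[0]
        assert res["significant"].iloc[1:].sum() == 0

    def test_too_few_pairs_skipped(self):
        x = np.arange(4.0)
        res = fluid_correlation(*self.paired([x], [x]))
        assert res["reason"].iloc[0] == "fewer_than_min_pairs"


class TestKnnImputePca:
    def test_complete_matrix_imputation_is_identity(self):
        rng = np.random.default_rng(11)
        m = frame(rng.normal(size=(20, 15)))
        res = knn_impute_pca(m)
        assert res.scores.shape == (15, 2)
        # orthonormal loadings
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-8)

    def test_planted_age_gradient_dominates_pc1(self):
        rng = np.random.default_rng(12)
        ages = rng.uniform(3, 17, 60)
        X = np.outer(rng.normal(0.2, 0.05, 200), ages) + rng.normal(
            0, 0.3, (200, 60)
        )
        X[rng.random(X.shape) < 0.1] = np.nan
        res = knn_impute_pca(frame(X))
        r = abs(np.corrcoef(res.scores["PC1"], ages)[0, 1])
        assert r > 0.8

    def test_empty_sample_rejected(self):
        X = np.ones((4, 3))
        X[:, 0] = np.nan
        with pytest.raises(ValueError):
            knn_impute_pca(frame(X))
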