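"""Intensity preprocessing, batch correction, CV/completeness, mDIA QC."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from ontoprot.qc import (
    IntensityMatrix,
    batch_correct,
    channel_q_sweep,
    completeness,
    cv_per_protein,
    filter_iqr_outliers,
    filter_min_ids,
    labeling_efficiency,
    log2_transform,
)


def matrix_from_counts(counts, n_proteins=2000, scale="raw"):
    """Samples with a prescribed number of present proteins each."""
    cols = {}
    for i, c in enumerate(counts):
        v = np.full(n_proteins, np.nan)
        v[:c] = 100.0
        cols[f"s{i}"] = v
    return IntensityMatrix(pd.DataFrame(cols), scale=scale)


class TestLog2Transform:
    def test_values_and_missing_propagation(self):
        m = IntensityMatrix(pd.DataFrame({"a": [2.0, 1.0, np.nan]}))
        out = log2_transform(m)
        assert out.scale == "log2"
        assert out.values["a"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(out.values["a"].iloc[2])

    def test_nonpositive_value_rejected(self):
        m = IntensityMatrix(pd.DataFrame({"a": [2.0, -1.0]}))
        with pytest.raises(ValueError, match="positive"):
            log2_transform(m)

    def test_double_transform_rejected(self):
        m = log2_transform(IntensityMatrix(pd.DataFrame({"a": [2.0]})))
        with pytest.raises(ValueError):
            log2_transform(m)


class TestFilterMinIds:
    def test_boundary_and_counting(self):
        m = matrix_from_counts([100, 800, 801, 799, 1500])
        out, removed = filter_min_ids(m, min_ids=800)
        assert sorted(removed) == ["s0", "s3"]
        assert list(out.values.columns) == ["s1", "s2", "s4"]

    def test_exactly_800_kept(self):
        m = matrix_from_counts([800])
        out, removed = filter_min_ids(m, min_ids=800)
        assert removed == []

    def test_all_removed_is_error(self):
        m = matrix_from_counts([10, 20])
        with pytest.raises(ValueError):
            filter_min_ids(m, min_ids=800)

    def test_idempotent(self):
        m = matrix_from_counts([100, 900, 950, 1200])
        once, _ = filter_min_ids(m, min_ids=800)
        twice, removed2 = filter_min_ids(once, min_ids=800)
        assert removed2 == []
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestFilterIqrOutliers:
    def test_identical_counts_remove_nothing(self):
        m = matrix_from_counts([500] * 6)
        out, removed, thr = filter_iqr_outliers(m)
        assert removed == []

    def test_low_outlier_removed_with_quantile_oracle(self):
        counts = [10, 100, 101, 102, 103]
        m = matrix_from_counts(counts)
        out, removed, thr = filter_iqr_outliers(m)
        q1, q3 = np.percentile(counts, [25, 75])  # linear interpolation
        assert thr == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert removed == ["s0"]

    def test_high_count_not_removed(self):
        m = matrix_from_counts([100, 101, 102, 103, 1900])
        _, removed, _ = filter_iqr_outliers(m)
        assert removed == []

    def test_idempotent(self):
        m = matrix_from_counts([10, 100, 101, 102, 103, 104])
        once, _, _ = filter_iqr_outliers(m)
        twice, removed2, _ = filter_iqr_outliers(once)
        assert removed2 == []
        pd.testing.assert_frame_equal(once.values, twice.values)


def planted_batch_matrix(shift=0.5, n_prot=300, n_per=20, seed=0, var_factor=1.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(20, 2, (n_prot, 1))
    A = base + rng.normal(0, 0.5, (n_prot, n_per))
    B = base + shift + rng.normal(0, 0.5 * np.sqrt(var_factor), (n_prot, n_per))
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    meta = pd.DataFrame(
        {"batch": ["A"] * n_per + ["B"] * n_per}, index=cols
    )
    vals = pd.DataFrame(np.hstack([A, B]), columns=cols)
    return IntensityMatrix(vals, scale="log2", meta=meta)


class TestBatchCorrect:
    def test_single_batch_is_identity(self):
        m = planted_batch_matrix()
        m.meta["batch"] = "A"
        out = batch_correct(m)
        assert np.allclose(out.values, m.values, atol=1e-10)

    def test_planted_shift_removed(self):
        # plate-sized batches, as in the cohort design
        m = planted_batch_matrix(shift=0.5, n_per=80, seed=1)
        out = batch_correct(m)
        a = out.values.filter(like="a").mean(axis=1)
        b = out.values.filter(like="b").mean(axis=1)
        assert (b - a).abs().mean() < 0.05

    def test_planted_variance_inflation_equalized(self):
        m = planted_batch_matrix(shift=0.0, var_factor=4.0, seed=2)
        out = batch_correct(m)
        va = out.values.filter(like="a").var(axis=1, ddof=1)
        vb = out.values.filter(like="b").var(axis=1, ddof=1)
        ratio = (vb / va).median()
        assert 0.8 < ratio < 1.25

    def test_singleton_batch_rejected(self):
        m = planted_batch_matrix(n_per=3)
        m.meta.loc["a0", "batch"] = "C"
        with pytest.raises(ValueError, match="C"):
            batch_correct(m)

    def test_missing_values_stay_missing_and_mean_preserved(self):
        m = planted_batch_matrix(seed=3)
        vals = m.values.copy()
        vals.iloc[::7, ::3] = np.nan
        m = IntensityMatrix(vals, scale="log2", meta=m.meta)
        out = batch_correct(m)
        assert np.array_equal(np.isnan(out.values), np.isnan(vals))
        assert np.allclose(
            out.values.mean(axis=1), vals.mean(axis=1), atol=0.05
        )

    def test_matches_reference_combat_implementation(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on a complete matrix."""
        m = planted_batch_matrix(shift=0.4, n_prot=80, n_per=10, seed=4)
        m.values.to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        m.meta["batch"].to_csv(tmp_path / "b.tsv", index=False, header=False)
        script = f"""
        suppressMessages(library(sva))
        X <- as.matrix(read.delim("{tmp_path}/x.tsv", check.names=FALSE))
        batch <- scan("{tmp_path}/b.tsv", what=character(), quiet=TRUE)
        out <- ComBat(dat=X, batch=batch, par.prior=TRUE)
        write.table(out, "{tmp_path}/r.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        expected = pd.read_csv(tmp_path / "r.tsv", sep="\t").to_numpy()
        ours = batch_correct(m).values.to_numpy()
        # agreement up to the EB solver's stopping tolerance
        assert np.abs(ours - expected).max() < 1e-5


class TestCvPerProtein:
    def test_constant_values_zero_cv(self):
        m = IntensityMatrix(pd.DataFrame([[5.0, 5.0, 5.0]], columns=list("abc")))
        cv, med = cv_per_protein(m)
        assert med == 0.0

    def test_one_two_three_is_fifty_percent(self):
        m = IntensityMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc")))
        cv, med = cv_per_protein(m)
        assert med == pytest.approx(50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.lognormal(3, 0.4, (50, 8)),
                            columns=[f"s{i}" for i in range(8)])
        cv1, _ = cv_per_protein(IntensityMatrix(vals))
        cv2, _ = cv_per_protein(IntensityMatrix(vals * 37.5))
        assert np.allclose(cv1, cv2)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.lognormal(3, 0.5, (100, 10)),
                            columns=[f"s{i}" for i in range(10)])
        vals[vals > np.quantile(vals, 0.9)] = np.nan
        cv, _ = cv_per_protein(IntensityMatrix(vals))
        for prot in vals.index[:20]:
            x = vals.loc[prot].dropna().to_numpy()
            if len(x) < 2:
                assert prot not in cv.index
                continue
            mean = x.sum() / len(x)
            sd = np.sqrt(((x - mean) ** 2).sum() / (len(x) - 1))
            assert cv[prot] == pytest.approx(100 * sd / mean, rel=1e-10)

    def test_log2_matrix_rejected(self):
        m = log2_transform(IntensityMatrix(pd.DataFrame([[1.0, 2.0]],
                                                        columns=list("ab"))))
        with pytest.raises(ValueError):
            cv_per_protein(m)

    def test_subset_below_two_samples_rejected(self):
        m = IntensityMatrix(pd.DataFrame([[1.0, 2.0]], columns=list("ab")))
        with pytest.raises(ValueError):
            cv_per_protein(m, ["a"])


class TestCompleteness:
    def test_fully_observed_all_pass(self):
        m = IntensityMatrix(pd.DataFrame(np.ones((5, 10)),
                                         columns=[f"s{i}" for i in range(10)]))
        _, passing, frac = completeness(m)
        assert frac == 1.0

    def test_strictly_greater_than_threshold(self):
        vals = np.full((3, 10), np.nan)
        vals[0, :9] = 1.0   # 90%
        vals[1, :6] = 1.0   # exactly 60% -> fails the strict rule
        vals[2, :2] = 1.0   # 20%
        m = IntensityMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(10)]))
        fracs, passing, frac = completeness(m, threshold=0.60)
        assert list(passing) == [0]
        assert frac == pytest.approx(1 / 3)


class TestLabelingEfficiency:
    def report(self, intensities, labeled):
        return pd.DataFrame({"intensity": intensities, "labeled": labeled})

    def test_all_or_none(self):
        assert labeling_efficiency(self.report([5.0, 5.0], [True, True])) == 1.0
        assert labeling_efficiency(self.report([5.0, 5.0], [False, False])) == 0.0

    def test_ninety_of_hundred(self):
        rep = self.report([40.0, 50.0, 10.0], [True, True, False])
        assert labeling_efficiency(rep) == pytest.approx(0.9)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            labeling_efficiency(self.report([0.0], [True]))


class TestChannelQSweep:
    def report(self, d0_q, false_q):
        rows = [{"channel": "d0", "channel_q": q, "intensity": 1.0,
                 "precursor_id": f"p{i}", "run_id": "r", "labeled": True}
                for i, q in enumerate(d0_q)]
        rows += [{"channel": "d4" if i % 2 else "d8", "channel_q": q,
                  "intensity": 1.0, "precursor_id": f"f{i}", "run_id": "r",
                  "labeled": False}
                 for i, q in enumerate(false_q)]
        return pd.DataFrame(rows)

    def test_no_false_rows_zero_ratio_everywhere(self):
        table, rec = channel_q_sweep(self.report([0.01] * 50, []))
        assert (table["ratio"] == 0).all()
        assert rec == 0.5

    def test_hand_placed_q_values_match_filtering_oracle(self):
        d0 = [0.01, 0.04, 0.12, 0.30]
        false = [0.08, 0.22, 0.45]
        table, rec = channel_q_sweep(self.report(d0, false))
        for _, row in table.iterrows():
            c = row["cutoff"]
            assert row["n_d0"] == sum(q < c for q in d0)
            assert row["n_false"] == sum(q < c for q in false)
            if row["n_d0"]:
                assert row["ratio"] == pytest.approx(row["n_false"] / row["n_d0"])

    def test_ratio_nondecreasing_when_d0_saturates(self):
        d0 = list(np.linspace(0.0, 0.04, 100))  # all identified below 0.05
        false = list(np.linspace(0.06, 0.5, 30))
        table, _ = channel_q_sweep(self.report(d0, false))
        ratios = table["ratio"].to_numpy()
        assert (np.diff(ratios) >= -1e-12).all()

    def test_recommended_cutoff_is_largest_below_one_percent(self):
        d0 = [0.01] * 1000
        false = [0.28] * 30  # ratio 0 below 0.28, then 3%
        table, rec = channel_q_sweep(self.report(d0, false))
        assert rec == pytest.approx(0.25)
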