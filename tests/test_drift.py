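"""Drift, drift-variance, the permutation test, VZ/VC."""

import numpy as np
import pandas as pd
import pytest

from txdrift.drift import (
    classify_variance,
    compute_drift,
    compute_vz,
    drift_variance_summary,
    drift_variance_test,
    scaled_vz_profile,
    variance_change,
)
from txdrift.io import AnalysisConfig, DesignError
from txdrift.simulate import SyntheticSpec, generate_dataset
from .conftest import make_samples


def cohort_matrix(samples, rows):
    return pd.DataFrame(
        {r.sample_id: [row[r.cohort][r.replicate - 1] for row in rows] for r in samples},
        index=[f"g{i}" for i in range(len(rows))],
    )


class TestDrift:
    def test_value_equal_to_reference_mean_is_zero(self, head_samples):
        m = cohort_matrix(
            head_samples,
            [{"young": [10, 20, 30], "aged": [20, 20, 20], "aged_treated": [20, 20, 20]}],
        )
        d = compute_drift(m, head_samples, "head")
        assert d.loc["g0", "head_4W_r1"] == pytest.approx(0.0)

    def test_tenfold_is_one(self, head_samples):
        m = cohort_matrix(
            head_samples,
            [{"young": [10, 20, 30], "aged": [200, 200, 200], "aged_treated": [2, 2, 2]}],
        )
        d = compute_drift(m, head_samples, "head")
        assert d.loc["g0", "head_4W_r2"] == pytest.approx(1.0)
        assert d.loc["g0", "head_4W-IF_r1"] == pytest.approx(-1.0)

    def test_global_scaling_invariance(self, head_samples):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.uniform(1, 100, size=(20, 9)),
            index=[f"g{i}" for i in range(20)],
            columns=[r.sample_id for r in head_samples],
        )
        d1 = compute_drift(m, head_samples, "head")
        d2 = compute_drift(m * 11.3, head_samples, "head")
        pd.testing.assert_frame_equal(d1, d2, atol=1e-12, check_exact=False)


class TestDriftVariance:
    def test_single_reference_replicate_all_zero(self):
        samples = [s for s in make_samples("head", 1)]
        m = pd.DataFrame(
            {r.sample_id: [3.0, 7.0] for r in samples}, index=["g0", "g1"]
        )
        d = compute_drift(m, samples, "head")
        s = drift_variance_summary(d, samples, "head", "young")
        assert s.drift_variance == 0.0

    def test_hand_variance_with_n_minus_one(self, head_samples):
        # pooled drift values {0, 1}: sample variance 0.5
        m = cohort_matrix(
            head_samples,
            [{"young": [10, 10, 10], "aged": [10, 10, 10], "aged_treated": [10, 10, 10]},
             {"young": [5, 5, 5], "aged": [5, 5, 5], "aged_treated": [5, 5, 5]}],
        )
        d = compute_drift(m, head_samples, "head")
        d_sub = pd.DataFrame({"a1": [0.0, 1.0]}, index=["g0", "g1"])
        solo = [type(head_samples[0])("a1", "head", "aged", 1)]
        s = drift_variance_summary(d_sub, solo, "head", "aged")
        assert s.drift_variance == pytest.approx(0.5)

    def test_reference_cohort_centered_near_zero(self, head_samples):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(
            rng.uniform(5, 50, size=(100, 9)),
            index=[f"g{i}" for i in range(100)],
            columns=[r.sample_id for r in head_samples],
        )
        d = compute_drift(m, head_samples, "head")
        young_ids = [r.sample_id for r in head_samples if r.cohort == "young"]
        # log10(x / arithmetic mean) has a small negative Jensen bias,
        # so "centered near zero" is a loose statement
        assert abs(d[young_ids].to_numpy().mean()) < 0.1

    def test_pool_cohort_mean_option(self, head_samples):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(
            rng.uniform(5, 50, size=(50, 9)),
            index=[f"g{i}" for i in range(50)],
            columns=[r.sample_id for r in head_samples],
        )
        d = compute_drift(m, head_samples, "head")
        s = drift_variance_summary(d, head_samples, "head", "aged", pool="cohort_mean")
        ids = [r.sample_id for r in head_samples if r.cohort == "aged"]
        assert s.drift_variance == pytest.approx(
            float(np.var(d[ids].mean(axis=1), ddof=1))
        )


class TestDriftVarianceTest:
    def test_cohort_vs_itself_p_one(self, head_samples):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.uniform(5, 50, size=(50, 9)),
            index=[f"g{i}" for i in range(50)],
            columns=[r.sample_id for r in head_samples],
        )
        d = compute_drift(m, head_samples, "head")
        p = drift_variance_test(d, head_samples, "head", "aged", "aged",
                                permutations=99, seed=0)
        assert p == 1.0

    def test_deterministic_given_seed(self, head_samples):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(
            rng.uniform(5, 50, size=(80, 9)),
            index=[f"g{i}" for i in range(80)],
            columns=[r.sample_id for r in head_samples],
        )
        d = compute_drift(m, head_samples, "head")
        args = (d, head_samples, "head", "aged", "young")
        assert drift_variance_test(*args, permutations=199, seed=5) == \
               drift_variance_test(*args, permutations=199, seed=5)

    def test_inflated_dispersion_detected(self):
        spec = SyntheticSpec(n_genes=2000, frac_drift=0.3, drift_cv_factor=4.0,
                             frac_age_up=0, frac_age_down=0, seed=12)
        matrix, samples, _ = generate_dataset(spec, "head")
        from txdrift.preprocess import filter_expressed
        filtered = filter_expressed(matrix, samples, "head", 1.0)
        d = compute_drift(filtered, samples, "head")
        p = drift_variance_test(d, samples, "head", "aged", "young",
                                permutations=999, seed=1)
        assert p <= 0.001

    def test_requires_min_permutations(self, head_samples):
        d = pd.DataFrame(np.zeros((5, 9)),
                         columns=[r.sample_id for r in head_samples])
        with pytest.raises(ValueError):
            drift_variance_test(d, head_samples, "head", "aged", "young",
                                permutations=10)


class TestVZ:
    def test_constant_replicates_zero(self, head_samples):
        m = cohort_matrix(
            head_samples,
            [{"young": [5, 5, 5], "aged": [1, 2, 3], "aged_treated": [5, 5, 5]}],
        )
        assert compute_vz(m, head_samples, "head", "young")["g0"] == 0.0

    def test_hand_arithmetic(self, head_samples):
        # replicates (1, 2, 3): mean 2, SD 1 (n-1) -> VZ 0.5
        m = cohort_matrix(
            head_samples,
            [{"young": [5, 5, 5], "aged": [1, 2, 3], "aged_treated": [5, 5, 5]}],
        )
        assert compute_vz(m, head_samples, "head", "aged")["g0"] == pytest.approx(0.5)

    def test_scale_invariance(self, head_samples):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(
            rng.uniform(1, 100, size=(20, 9)),
            index=[f"g{i}" for i in range(20)],
            columns=[r.sample_id for r in head_samples],
        )
        v1 = compute_vz(m, head_samples, "head", "aged")
        v2 = compute_vz(m * 3.7, head_samples, "head", "aged")
        pd.testing.assert_series_equal(v1, v2, atol=1e-12, check_exact=False)

    def test_n2_sd_convention(self):
        # thorax-style duplicate: SD = |x1 - x2| / sqrt(2)
        samples = make_samples("thorax", 2)
        m = pd.DataFrame(
            {r.sample_id: [10.0 if r.replicate == 1 else 14.0] for r in samples},
            index=["g0"],
        )
        vz = compute_vz(m, samples, "thorax", "aged")["g0"]
        assert vz == pytest.approx((4.0 / np.sqrt(2)) / 12.0)

    def test_single_replicate_raises(self):
        samples = make_samples("head", 1)
        m = pd.DataFrame({r.sample_id: [1.0] for r in samples}, index=["g0"])
        with pytest.raises(DesignError, match="aged"):
            compute_vz(m, samples, "head", "aged")


class TestVC:
    def test_equal_vz_gives_one(self):
        vc = variance_change(pd.Series([0.3]), pd.Series([0.3]))
        assert vc.iloc[0] == pytest.approx(1.0)

    def test_hand_ratio_flags_cutoff(self):
        vc = variance_change(pd.Series([0.8]), pd.Series([0.2]))
        assert vc.iloc[0] == pytest.approx(4.0, rel=1e-4)
        assert vc.iloc[0] > 3.75

    def test_double_zero_is_one_exactly(self):
        vc = variance_change(pd.Series([0.0]), pd.Series([0.0]))
        assert vc.iloc[0] == 1.0

    def test_negative_vz_rejected(self):
        with pytest.raises(ValueError):
            variance_change(pd.Series([-0.1]), pd.Series([0.2]))


class TestClassifyVariance:
    def test_boundary_and_counts(self, head_samples):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(
            rng.uniform(2, 100, size=(40, 9)),
            index=[f"g{i}" for i in range(40)],
            columns=[r.sample_id for r in head_samples],
        )
        cfg = AnalysisConfig()
        records, counts = classify_variance(m, head_samples, "head", cfg)
        for label in ("4W/1W", "4W/4W-IF", "1W/4W-IF"):
            brute = int((records[f"vc_{label}"] > 3.75).sum())
            assert counts[label].iloc[0] == brute
            assert records[f"high_vc_{label}"].sum() == brute

    def test_exactly_cutoff_not_flagged(self):
        cfg = AnalysisConfig()
        vc = pd.Series([3.75, 3.7500001, 1.0])
        assert ((vc > cfg.vc_cutoff) == [False, True, False]).all()

    def test_alternative_cutoff_supported(self, head_samples):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(
            rng.uniform(2, 100, size=(40, 9)),
            index=[f"g{i}" for i in range(40)],
            columns=[r.sample_id for r in head_samples],
        )
        _, strict = classify_variance(m, head_samples, "head", AnalysisConfig())
        _, loose = classify_variance(
            m, head_samples, "head", AnalysisConfig(vc_cutoff=3.5)
        )
        assert (loose.to_numpy() >= strict.to_numpy()).all()


class TestScaledVZ:
    def make_records(self):
        return pd.DataFrame(
            {"vz_aged": [0.8, 0.4, 0.0], "vz_aged_treated": [0.2, 0.4, 0.0]},
            index=["gA", "gB", "gZ"],
        )

    def test_hand_scaling(self):
        out = scaled_vz_profile(self.make_records(), ["gA"])
        assert out.loc["gA", "vz_aged"] == pytest.approx(1.0)
        assert out.loc["gA", "vz_aged_treated"] == pytest.approx(0.25)

    def test_equal_vz_both_one(self):
        out = scaled_vz_profile(self.make_records(), ["gB"])
        assert (out.loc["gB"] == 1.0).all()

    def test_double_zero_warns_ones(self):
        with pytest.warns(UserWarning, match="zero VZ"):
            out = scaled_vz_profile(self.make_records(), ["gZ"])
        assert (out.loc["gZ"] == 1.0).all()

    def test_values_in_unit_interval(self, head_samples):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(
            rng.uniform(2, 100, size=(30, 9)),
            index=[f"g{i}" for i in range(30)],
            columns=[r.sample_id for r in head_samples],
        )
        records, _ = classify_variance(m, head_samples, "head", AnalysisConfig())
        out = scaled_vz_profile(records, list(records.index))
        assert ((out > 0) & (out <= 1)).all().all()
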