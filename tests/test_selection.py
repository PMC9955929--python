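import numpy as np
import pytest

from kplsmwmr import (
    ConfigurationError,
    FeatureMatrix,
    KernelConfig,
    MWMRConfig,
    mwmr_select,
    pearson_r,
    redundancy_score,
    run_pipeline,
)
from kplsmwmr.weighting import WeightVector, minmax_normalize


def naive_mwmr(values, raw_weights, alpha, k, target="pool", aggregate="mean"):
    """Independent greedy reference: recomputes every |r| from scratch each
    step with the textbook covariance/sigma formula, no precomputation."""
    m = values.shape[1]
    w = minmax_normalize(raw_weights)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        sa, sb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
        return 0.0 if sa == 0 or sb == 0 else float((a * b).sum() / (sa * sb))

    agg = {"mean": np.mean, "max": np.max, "min": np.min}[aggregate]
    selected, pool = [], list(range(m))
    for step in range(k):
        best, best_key = None, None
        for j in pool:
            if step == 0:
                R = w[j]
            else:
                others = selected if target == "selected" else [q for q in pool if q != j]
                r = agg([abs(corr(values[:, j], values[:, q])) for q in others]) if others else 0.0
                R = alpha * w[j] - (1 - alpha) * r
            key = (R, raw_weights[j], -j)
            if best_key is None or key > best_key:
                best, best_key = j, key
        selected.append(best)
        pool.remove(best)
    return selected


def _fm(values):
    n, m = values.shape
    return FeatureMatrix(values, [f"f{j+1}" for j in range(m)], [str(i) for i in range(n)])


class TestPearson:
    def test_self_correlation_is_one(self):
        a = np.array([1.0, 2, 4, 8])
        assert pearson_r(a, a) == pytest.approx(1.0)

    def test_affine_anticorrelation_is_minus_one(self):
        a = np.array([1.0, 2, 4, 8])
        assert pearson_r(a, -2 * a + 7) == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_fixed_vectors(self):
        a = np.array([1.0, 4.0, 2.0, 7.0, 5.0, 3.0])
        b = np.array([2.0, 5.0, 1.0, 9.0, 4.0, 2.0])
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        expected = cov / (a.std() * b.std())
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_returns_zero(self):
        assert pearson_r(np.ones(4), np.array([1.0, 2, 3, 4])) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            pearson_r(np.ones(3), np.ones(4))


class TestRedundancyScore:
    def test_empty_selected_is_zero(self):
        assert redundancy_score(np.array([1.0, 2, 3]), []) == 0.0

    def test_identical_feature_max_aggregate_is_one(self):
        a = np.array([1.0, 5, 2, 4])
        assert redundancy_score(a, [a * 2], aggregate="max") == pytest.approx(1.0)

    def test_mean_aggregate_of_known_correlations(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        # construct vectors with prescribed correlation to a
        def with_r(r):
            b = r * a + np.sqrt(1 - r**2) * rng.normal(size=200)
            return b

        b1, b2 = with_r(0.2), with_r(0.6)
        expected = (abs(pearson_r(a, b1)) + abs(pearson_r(a, b2))) / 2
        got = redundancy_score(a, [b1, b2], aggregate="mean")
        assert got == pytest.approx(expected, abs=1e-12)


class TestMWMRSelect:
    def test_alpha_one_is_descending_weight_order(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 8))
        w = WeightVector(rng.normal(size=8), method="relieff")
        report, _ = mwmr_select(_fm(values), w, MWMRConfig(alpha=1.0, k=8))
        expected = [f"f{j+1}" for j in w.ranking()]
        assert report.feature_names == expected

    def test_k_one_returns_top_weight_any_alpha(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 5))
        w = WeightVector(np.array([0.1, 0.9, 0.3, 0.2, 0.5]), method="relieff")
        for alpha in (0.0, 0.3, 1.0):
            report, _ = mwmr_select(_fm(values), w, MWMRConfig(alpha=alpha, k=1))
            assert report.feature_names == ["f2"]

    @pytest.mark.parametrize("target", ["pool", "selected"])
    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.7, 1.0])
    def test_matches_naive_recomputed_oracle(self, alpha, target):
        rng = np.random.default_rng(int(alpha * 10) + (target == "pool"))
        for trial in range(5):
            values = rng.normal(size=(25, 12))
            raw = rng.normal(size=12)
            k = 4
            expected = naive_mwmr(values, raw, alpha, k, target=target)
            report, trace = mwmr_select(
                _fm(values),
                WeightVector(raw, method="relieff"),
                MWMRConfig(alpha=alpha, k=k, redundancy_target=target),
            )
            got = [int(nm[1:]) - 1 for nm in report.feature_names]
            assert got == expected

    def test_trace_criterion_is_stepwise_max_and_pool_shrinks(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(20, 6))
        w = WeightVector(rng.uniform(size=6), method="relieff")
        _, trace = mwmr_select(_fm(values), w, MWMRConfig(alpha=0.5, k=6))
        sizes = [s.candidate_pool_size for s in trace]
        assert sizes == [6, 5, 4, 3, 2, 1]

    def test_duplicate_never_chosen_at_alpha_zero_selected_mode(self, duplicated_dataset):
        """With redundancy against the selected set and alpha = 0, an exact
        duplicate (|r| = 1) of a chosen feature loses to any remaining
        candidate with lower correlation."""
        X, y = duplicated_dataset
        from kplsmwmr import relieff_weights

        w = relieff_weights(X, y)
        config = MWMRConfig(alpha=0.0, k=3, redundancy_target="selected")
        report, _ = mwmr_select(X, w, config)
        names = report.feature_names
        assert not ("f1" in names and "d1" in names)

    @pytest.mark.parametrize("alpha", [0.0, 0.2, 0.4, 0.5])
    def test_duplicate_loses_to_uncorrelated_candidate(self, duplicated_dataset, alpha):
        """Right after the duplicate's twin is selected, the duplicate scores
        alpha - (1 - alpha) while a zero-redundancy candidate scores at least
        -0 * (1 - alpha); for alpha <= 0.5 the duplicate can therefore never
        be the second pick (direct consequence of the criterion)."""
        X, y = duplicated_dataset
        from kplsmwmr import relieff_weights

        w = relieff_weights(X, y)
        report, _ = mwmr_select(
            X, w, MWMRConfig(alpha=alpha, k=2, redundancy_target="selected")
        )
        assert not ("f1" in report.feature_names and "d1" in report.feature_names)

    def test_permutation_invariance_up_to_names(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(30, 7))
        raw = rng.normal(size=7)
        config = MWMRConfig(alpha=0.4, k=3)
        report, _ = mwmr_select(_fm(values), WeightVector(raw, "relieff"), config)
        perm = rng.permutation(7)
        values_p = values[:, perm]
        names_p = [f"f{j+1}" for j in perm]
        Xp = FeatureMatrix(values_p, names_p, [str(i) for i in range(30)])
        report_p, _ = mwmr_select(Xp, WeightVector(raw[perm], "relieff"), config)
        assert report_p.feature_names == report.feature_names

    def test_k_equals_m_returns_all_features(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(15, 4))
        w = WeightVector(rng.uniform(size=4), "relieff")
        report, trace = mwmr_select(_fm(values), w, MWMRConfig(alpha=0.5, k=4))
        assert sorted(report.feature_names) == ["f1", "f2", "f3", "f4"]
        assert [s.chosen_feature for s in trace] == report.feature_names

    def test_k_larger_than_m_rejected(self):
        values = np.random.default_rng(0).normal(size=(10, 3))
        w = WeightVector(np.ones(3), "relieff")
        with pytest.raises(ConfigurationError):
            mwmr_select(_fm(values), w, MWMRConfig(alpha=0.5, k=4))


class TestRunPipeline:
    def test_default_synthetic_selects_informative_features(self, default_dataset):
        X, y = default_dataset
        report, _ = run_pipeline(X, y, mwmr=MWMRConfig(alpha=0.3, k=3))
        assert sorted(report.feature_names) == ["f1", "f2", "f3"]
        assert report.method == "kpls-mwmr"
        assert report.provenance["kernel"]["n_components"] > 0

    def test_alpha_endpoints_on_duplicated_fixture(self, duplicated_dataset):
        X, y = duplicated_dataset
        rep1, _ = run_pipeline(
            X, y,
            kernel=KernelConfig(n_components_p=3),
            mwmr=MWMRConfig(alpha=1.0, k=4, redundancy_target="selected"),
        )
        from kplsmwmr import KernelPLS, relieff_weights

        kpls = KernelPLS(n_components=3).fit(X, y)
        w = relieff_weights(kpls.reconstruction_, y)
        assert rep1.feature_names == [X.feature_names[j] for j in w.ranking()[:4]]

        rep0, _ = run_pipeline(
            X, y,
            kernel=KernelConfig(n_components_p=3),
            mwmr=MWMRConfig(alpha=0.0, k=2, redundancy_target="selected"),
        )
        assert not ("f1" in rep0.feature_names and "d1" in rep0.feature_names)

    def test_k_equals_m_exhaustive(self, duplicated_dataset):
        X, y = duplicated_dataset
        report, trace = run_pipeline(X, y, mwmr=MWMRConfig(alpha=0.5, k=4))
        assert sorted(report.feature_names) == sorted(X.feature_names)
        assert len(trace) == 4

    def test_stage_name_in_error_message(self):
        # identical samples make the median kernel width degenerate inside
        # the kernel stage; the stage name must surface in the message
        X = FeatureMatrix(
            np.ones((4, 2)), ["f1", "f2"], ["s1", "s2", "s3", "s4"]
        )
        from kplsmwmr import LabelVector

        y = LabelVector(np.array(["a", "a", "b", "b"]))
        with pytest.raises(ConfigurationError, match=r"\[kernel-pls\]"):
            run_pipeline(X, y)
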