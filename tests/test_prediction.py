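import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modsubnet import (
    ExpressionDataset,
    FeatureMatrix,
    ModuleSpec,
    SyntheticSpec,
    build_features,
    compare_medians,
    cv_discover_and_predict,
    evaluate,
    fit_predict_svr,
    generate_expression,
    generate_network,
    grow_subnetwork,
    sampling_experiment,
    select_top_genes_ftest,
    stratified_folds,
    subnetwork_activity,
    weight_network,
)


def _fm(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    idx = [f"s{i}" for i in range(X.shape[0])]
    return FeatureMatrix(
        pd.DataFrame(X, index=idx, columns=names), pd.Series(y, index=idx, dtype=float)
    )


class TestBuildFeatures:
    def test_singleton_subnetwork_equals_gene_row(self, toy_dataset):
        fm = build_features(["g0"], toy_dataset)
        np.testing.assert_allclose(
            fm.values["g0"].to_numpy(), toy_dataset.values.loc["g0"].to_numpy()
        )

    def test_columns_match_subnetwork_activity(self, toy_dataset, toy_network):
        sub = grow_subnetwork("g0", toy_network, toy_dataset, beta=1.0)
        fm = build_features([sub], toy_dataset)
        np.testing.assert_allclose(
            fm.values.iloc[:, 0].to_numpy(),
            subnetwork_activity(sub.members, toy_dataset),
            atol=1e-12,
        )

    def test_empty_feature_list_errors(self, toy_dataset):
        with pytest.raises(ValueError, match="empty"):
            build_features([], toy_dataset)


class TestSVR:
    def test_noiseless_linear_within_epsilon_band(self):
        x = np.linspace(0, 10, 30).reshape(-1, 1)
        y = 2.0 + 1.5 * x.ravel()
        train = _fm(x, y)
        test = _fm(x[:10], y[:10])
        pred = fit_predict_svr(train, test)
        assert np.max(np.abs(pred - y[:10])) < 0.2  # epsilon=0.1 plus slack

    def test_constant_ages_give_constant_predictions(self):
        rng = np.random.default_rng(0)
        train = _fm(rng.standard_normal((12, 3)), np.full(12, 7.0))
        test = _fm(rng.standard_normal((5, 3)), np.full(5, 7.0))
        pred = fit_predict_svr(train, test)
        assert np.ptp(pred) < 1e-9

    def test_duplicated_feature_column_harmless_on_noiseless_data(self):
        x = np.linspace(0, 10, 24).reshape(-1, 1)
        y = 3.0 * x.ravel() + 1.0
        single = fit_predict_svr(_fm(x, y), _fm(x, y))
        doubled = fit_predict_svr(
            _fm(np.hstack([x, x]), y), _fm(np.hstack([x, x]), y)
        )
        np.testing.assert_allclose(single, doubled, atol=0.05)

    def test_mismatched_features_error(self):
        a = _fm(np.zeros((4, 2)) + np.arange(4)[:, None], [1, 2, 3, 4])
        b = _fm(np.ones((4, 2)), [1, 2, 3, 4], names=["x", "y"])
        with pytest.raises(ValueError, match="feature names"):
            fit_predict_svr(a, b)


class TestEvaluate:
    def test_perfect_predictions(self):
        ev = evaluate([4.0, 7, 10, 13], [4.0, 7, 10, 13])
        assert ev.mse == 0.0 and ev.scc == pytest.approx(1.0)

    def test_constant_shift_keeps_scc_raises_mse(self):
        ev = evaluate([4.0, 7, 10, 13], [5.0, 8, 11, 14])
        assert ev.mse == pytest.approx(1.0)
        assert ev.scc == pytest.approx(1.0)

    def test_scc_is_sign_blind(self):
        ev = evaluate([1.0, 2, 3, 4], [4.0, 3, 2, 1])
        assert ev.scc == pytest.approx(1.0)
        assert ev.mse == pytest.approx(np.mean([9, 1, 1, 9]))

    def test_constant_predictions_warn_scc_zero(self):
        with pytest.warns(UserWarning, match="constant predictions"):
            ev = evaluate([1.0, 2, 3, 4], [2.0, 2, 2, 2])
        assert ev.scc == 0.0


class TestSamplingExperiment:
    def _pair(self, n_feats=6, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        genes = [f"g{i}" for i in range(n_feats)]
        samples = [f"s{i}" for i in range(20)]
        ages = np.repeat([4.0, 7, 10, 13], 5)
        mk = lambda: ExpressionDataset(
            pd.DataFrame(
                0.5 * ages + rng.standard_normal((n_feats, 20)),
                index=genes,
                columns=samples,
            ),
            pd.Series(ages, index=samples),
        )
        return mk(), mk(), genes

    def test_pool_equal_k_has_zero_ci_width(self):
        d_tr, d_te, genes = self._pair()
        res = sampling_experiment(genes, d_tr, d_te, k=len(genes), n_draws=20, rng_seed=1)
        assert res["summary"]["scc"]["ci_low"] == res["summary"]["scc"]["ci_high"]
        assert np.ptp(res["scc"]) == 0.0

    def test_reproducible(self):
        d_tr, d_te, genes = self._pair()
        a = sampling_experiment(genes, d_tr, d_te, k=3, n_draws=30, rng_seed=2)
        b = sampling_experiment(genes, d_tr, d_te, k=3, n_draws=30, rng_seed=2)
        np.testing.assert_array_equal(a["scc"], b["scc"])

    def test_median_matches_exhaustive_enumeration(self):
        d_tr, d_te, genes = self._pair(n_feats=5)
        k = 2
        evs = []
        for combo in itertools.combinations(genes, k):
            tr = build_features(list(combo), d_tr)
            te = build_features(list(combo), d_te)
            evs.append(evaluate(te.ages.to_numpy(), fit_predict_svr(tr, te)).scc)
        res = sampling_experiment(genes, d_tr, d_te, k=k, n_draws=4000, rng_seed=3)
        # with 4,000 draws over C(5,2)=10 subsets the sample median converges
        assert res["summary"]["scc"]["median"] == pytest.approx(
            np.median(evs), abs=0.02
        )

    def test_k_larger_than_pool_errors(self):
        d_tr, d_te, genes = self._pair()
        with pytest.raises(ValueError, match="exceeds"):
            sampling_experiment(genes, d_tr, d_te, k=len(genes) + 1, n_draws=5)


class TestStratifiedFolds:
    def _dataset(self, counts):
        ages = np.concatenate([[a] * n for a, n in counts])
        samples = [f"s{i}" for i in range(len(ages))]
        rng = np.random.default_rng(1)
        return ExpressionDataset(
            pd.DataFrame(
                rng.standard_normal((3, len(ages))),
                index=["g0", "g1", "g2"],
                columns=samples,
            ),
            pd.Series(ages, index=samples, dtype=float),
        )

    def test_balanced_case_exact(self):
        d = self._dataset([(4.0, 10), (10.0, 10)])
        folds = stratified_folds(d, n_folds=5, rng_seed=0)
        ages = d.ages.to_numpy()
        for f in range(5):
            for a in (4.0, 10.0):
                assert ((folds == f) & (ages == a)).sum() == 2

    def test_uneven_groups_near_balance(self):
        # group sizes akin to 9-17 arrays per age over 7 ages
        counts = [(a, n) for a, n in zip(range(4, 18, 2), (9, 12, 15, 17, 16, 21, 14))]
        d = self._dataset([(float(a), n) for a, n in counts])
        folds = stratified_folds(d, n_folds=5, rng_seed=2)
        ages = d.ages.to_numpy()
        for a, _ in counts:
            per_fold = [((folds == f) & (ages == a)).sum() for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_partition_properties(self):
        d = self._dataset([(4.0, 7), (10.0, 8)])
        folds = stratified_folds(d, n_folds=5, rng_seed=3)
        assert folds.min() >= 0 and folds.max() < 5
        assert len(folds) == d.n_samples  # every sample assigned exactly once


class TestFTestSelection:
    def _dataset(self):
        rng = np.random.default_rng(4)
        ages = np.repeat([4.0, 10.0, 16.0], 6)
        samples = [f"s{i}" for i in range(18)]
        rows = {
            "strong": np.repeat([0.0, 5.0, 10.0], 6) + 0.01 * rng.standard_normal(18),
            "noise1": rng.standard_normal(18),
            "noise2": rng.standard_normal(18),
            "flat": np.zeros(18),
        }
        return ExpressionDataset(
            pd.DataFrame(rows, index=samples).T, pd.Series(ages, index=samples)
        )

    def test_ordered_gene_first_flat_gene_last(self):
        d = self._dataset()
        top = select_top_genes_ftest(d, n_top=4)
        assert top[0] == "strong"
        assert top[-1] == "flat"

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        ages = np.repeat([4.0, 10.0], 8)
        samples = [f"s{i}" for i in range(16)]
        vals = rng.standard_normal((5, 16))
        d = ExpressionDataset(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(5)], columns=samples),
            pd.Series(ages, index=samples),
        )
        from sklearn.feature_selection import f_classif

        F, _ = f_classif(vals.T, ages)
        for i in range(5):
            t = stats.ttest_ind(vals[i, :8], vals[i, 8:], equal_var=True).statistic
            assert F[i] == pytest.approx(t**2, rel=1e-10)

    def test_n_top_exceeding_pool_warns(self):
        d = self._dataset()
        with pytest.warns(UserWarning, match="exceeds gene count"):
            top = select_top_genes_ftest(d, n_top=10)
        assert len(top) == 4


class TestCompareMedians:
    def test_identical_samples_p_near_one(self):
        a = list(range(10))
        assert compare_medians(a, a) > 0.9

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(15), rng.standard_normal(15) + 0.5
        assert compare_medians(a, b) == pytest.approx(compare_medians(b, a))

    def test_complete_separation_matches_exact_enumeration(self):
        a = np.arange(10, dtype=float)
        b = np.arange(100, 110, dtype=float)
        # exact two-sided tail for complete separation: 2 / C(20,10)
        from math import comb

        assert compare_medians(a, b) == pytest.approx(2 / comb(20, 10), rel=1e-9)


@pytest.fixture(scope="module")
def cv_instance():
    spec = SyntheticSpec(
        n_background_nodes=60,
        background_edge_prob=0.03,
        modules=[ModuleSpec(size=8) for _ in range(2)],
        rng_seed=31,
    )
    g, mem = generate_network(spec)
    d = generate_expression(spec, g, mem)
    return g, d


class TestCV:
    def test_runs_and_reports_folds(self, cv_instance):
        g, d = cv_instance
        res = cv_discover_and_predict(g, d, beta=3.0, k=5, n_folds=5, rng_seed=0)
        assert 1 <= len(res) <= 5
        for r in res:
            assert r["eval"] is None or (r["eval"].mse >= 0 and 0 <= r["eval"].scc <= 1)

    def test_leave_one_out_degenerate_runs(self, cv_instance):
        g, d = cv_instance
        small = d.subset_samples(d.samples[::5])  # 10 samples
        res = cv_discover_and_predict(
            g, small, beta=3.0, k=3, n_folds=small.n_samples, rng_seed=1
        )
        assert all(r["eval"] is None for r in res)
        assert all(len(r["predicted"]) == 1 for r in res)

    def test_leaky_discovery_not_worse_than_honest(self, cv_instance):
        g, d = cv_instance

        def mean_scc(discover_on, seeds):
            vals = []
            for s in seeds:
                res = cv_discover_and_predict(
                    g, d, beta=3.0, k=5, n_folds=5, rng_seed=s, discover_on=discover_on
                )
                vals += [r["eval"].scc for r in res if r["eval"] is not None]
            return np.mean(vals)

        seeds = range(3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            honest = mean_scc("train", seeds)
            leaky = mean_scc("all", seeds)
        # features chosen with access to test ages cannot underperform on average
        assert leaky >= honest - 0.05
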