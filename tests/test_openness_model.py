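import numpy as np
import pandas as pd
import pytest

from perd import openness_model as om
from perd import synthetic_data as synth
from perd.genomic_io import GenomicInterval
from perd.networks import EnhancerRecord, RegulatoryNetwork


def ols_oracle(X, y):
    """Normal-equations least squares with intercept, independent of sklearn."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]


class TestComputeOpenness:
    @pytest.mark.parametrize("bins, expected", [([0.2, 1.7, 0.9], 1.7), ([0.0], 0.0), ([3.5], 3.5)])
    def test_max_of_bins(self, bins, expected):
        assert om.compute_openness(bins) == expected

    def test_empty_and_negative(self):
        with pytest.raises(ValueError):
            om.compute_openness([])
        with pytest.raises(ValueError):
            om.compute_openness([-0.1, 1.0])


@pytest.fixture()
def toy_enhancer_expr():
    enh = EnhancerRecord(
        enhancer_id="e1",
        interval=GenomicInterval("chr1", 0, 100),
        target_genes=frozenset({"gA", "gB", "gC"}),
        binding_tfs=frozenset({"tX", "tY"}),
    )
    rng = np.random.default_rng(3)
    expr = pd.DataFrame(
        rng.uniform(2, 10, size=(5, 30)),
        index=["gA", "gB", "gC", "tX", "tY"],
        columns=[f"s{i}" for i in range(30)],
    )
    return enh, expr


class TestAssembleFeatures:
    def test_column_order_tfs_then_tgs(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        design, tfs, tgs, _ = om.assemble_features(enh, expr)
        assert list(design.columns) == ["tX", "tY", "gA", "gB", "gC"]
        assert tfs == ["tX", "tY"] and tgs == ["gA", "gB", "gC"]

    def test_gamma_zero_zeroes_tf_columns(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        design, _, _, _ = om.assemble_features(enh, expr, gamma_T=0.0)
        assert np.allclose(design[["tX", "tY"]].to_numpy(), 0.0)
        assert not np.allclose(design[["gA", "gB", "gC"]].to_numpy(), 0.0)

    def test_missing_feature_warns_and_drops(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        with pytest.warns(UserWarning, match="absent"):
            design, _, tgs, _ = om.assemble_features(enh, expr.drop(index="gB"))
        assert design.shape[1] == 4 and "gB" not in tgs

    def test_too_few_features_raises(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 2"):
                om.assemble_features(enh, expr.loc[["gA"]])

    def test_tgonly_mode_drops_tfs(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        design, tfs, tgs, _ = om.assemble_features(enh, expr, feature_mode="TGonly")
        assert tfs == [] and list(design.columns) == ["gA", "gB", "gC"]

    def test_log_detection_on_raw_scale(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        _, _, _, prep_log = om.assemble_features(enh, expr * 100)
        _, _, _, prep_no = om.assemble_features(enh, expr)
        assert prep_log.log_applied and not prep_no.log_applied


class TestFitEnhancerModel:
    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_zero_matches_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 5))
        w = rng.uniform(0.5, 1.5, size=5) * rng.choice([-1, 1], size=5)
        y = 2.0 + X @ w
        design = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        model = om.fit_enhancer_model(design, y, method="elastic_net", lambda_=0.0)
        b0, coefs = ols_oracle(X, y)
        assert np.allclose(model.coefficients, coefs, atol=1e-6)
        assert abs(model.intercept - b0) < 1e-6

    def test_huge_lambda_shrinks_to_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        y = 5.0 + X @ np.array([1.0, -1.0, 0.5, 2.0])
        design = pd.DataFrame(X, columns=list("abcd"))
        model = om.fit_enhancer_model(design, y, lambda_=1e6)
        assert np.abs(model.coefficients).max() < 1e-3
        pred = om.predict_openness(model, pd.DataFrame(X.T, index=list("abcd")))
        assert np.allclose(pred, y.mean(), atol=0.05)

    def test_constant_target_degenerate(self):
        design = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 3)), columns=list("abc"))
        model = om.fit_enhancer_model(design, np.full(10, 4.2), lambda_=0.1)
        assert model.degenerate
        pred = om.predict_openness(model, pd.DataFrame(np.zeros((3, 5)), index=list("abc")))
        assert np.allclose(pred, 4.2)

    def test_missing_values_rejected(self):
        design = pd.DataFrame([[1.0, np.nan], [2.0, 1.0], [3.0, 2.0]], columns=list("ab"))
        with pytest.raises(ValueError, match="missing"):
            om.fit_enhancer_model(design, np.array([1.0, 2.0, 3.0]), lambda_=0.0)

    def test_coefficient_norm_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.1, size=60)
        design = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        norms = []
        for lam in [0.0, 0.1, 1.0, 10.0, 100.0]:
            m = om.fit_enhancer_model(design, y, lambda_=lam)
            norms.append(np.abs(m.coefficients).sum())
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    @pytest.mark.parametrize("method", ["elastic_net", "random_forest", "svm"])
    def test_backends_predict_finite_nonnegative(self, method, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        design, tfs, tgs, prep = om.assemble_features(enh, expr)
        y = np.random.default_rng(4).uniform(0, 10, size=30)
        model = om.fit_enhancer_model(
            design, y, method=method, lambda_=0.1, seed=1,
            enhancer_id="e1", tf_features=tfs, tg_features=tgs, preprocessing=prep,
        )
        pred = om.predict_openness(model, expr)
        assert np.isfinite(pred).all() and (pred >= 0).all()
        if method == "random_forest":
            assert pred.max() <= y.max() + 1e-9

    def test_negative_predictions_clipped(self):
        design = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 0.5, 1.0]})
        model = om.fit_enhancer_model(design, np.array([2.0, 1.0, 0.0]), lambda_=0.0,
                                      tf_features=[], tg_features=["a", "b"])
        expr = pd.DataFrame({"s1": [10.0, 5.0]}, index=["a", "b"])
        clipped = om.predict_openness(model, expr)
        raw = om.predict_openness(model, expr, clip_negative=False)
        assert raw.iloc[0] < 0 and clipped.iloc[0] == 0.0

    def test_prediction_missing_feature_named(self, toy_enhancer_expr):
        enh, expr = toy_enhancer_expr
        design, tfs, tgs, prep = om.assemble_features(enh, expr)
        model = om.fit_enhancer_model(design, np.arange(30.0), lambda_=0.1,
                                      tf_features=tfs, tg_features=tgs, preprocessing=prep)
        with pytest.raises(KeyError, match="gB"):
            om.predict_openness(model, expr.drop(index="gB"))


class TestFitAll:
    def test_planted_recovery_noiseless(self, small_network):
        net, _ = small_network
        expr, openness, _, truth = synth.generate_paired_training(
            net, n_cells=60, noise_sd=0.0, seed=21
        )
        coll = om.fit_all(net, expr, openness, lambda_=0.0, seed=0)
        assert len(coll) == len(net) and not coll.skip_report
        for eid, model in coll.models.items():
            planted = truth.coefficients[eid]
            fitted = dict(zip(model.feature_names, model.coefficients))
            # generator standardizes by the same cohort stats as preprocessing,
            # so design-space coefficients equal the planted ones exactly
            for f, c in planted.items():
                assert abs(fitted[f] - c) < 1e-6
            pred = om.predict_openness(model, expr)
            assert np.allclose(pred, openness.loc[eid], atol=1e-6)

    def test_skip_report_for_sparse_enhancer(self, training_data):
        net, expr, openness, _, _ = training_data
        dropped = sorted(net.enhancers[0].target_genes | net.enhancers[0].binding_tfs)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coll = om.fit_all(net, expr.drop(index=dropped), openness, lambda_=0.1)
        skipped_ids = {eid for eid, _ in coll.skip_report}
        assert net.enhancers[0].enhancer_id in skipped_ids

    def test_no_shared_samples_errors(self, training_data):
        net, expr, openness, _, _ = training_data
        bad = expr.copy()
        bad.columns = [f"x{i}" for i in range(bad.shape[1])]
        with pytest.raises(ValueError, match="share no samples"):
            om.fit_all(net, bad, openness)

    def test_deterministic_given_seed(self, training_data):
        net, expr, openness, _, _ = training_data
        sub = RegulatoryNetwork(enhancers=net.enhancers[:5])
        a = om.fit_all(sub, expr, openness, method="elastic_net", lambda_=0.1, seed=3)
        b = om.fit_all(sub, expr, openness, method="elastic_net", lambda_=0.1, seed=3)
        for eid in a.models:
            assert np.array_equal(a.models[eid].coefficients, b.models[eid].coefficients)
        ra = om.fit_all(sub, expr, openness, method="random_forest", seed=3)
        rb = om.fit_all(sub, expr, openness, method="random_forest", seed=3)
        pd.testing.assert_frame_equal(om.predict_all(ra, expr), om.predict_all(rb, expr))


class TestSerialization:
    @pytest.mark.parametrize("method", ["elastic_net", "random_forest"])
    def test_round_trip_predictions(self, tmp_path, training_data, method):
        net, expr, openness, _, _ = training_data
        sub = RegulatoryNetwork(enhancers=net.enhancers[:4])
        coll = om.fit_all(sub, expr, openness, method=method, lambda_=0.1, seed=5)
        om.save_collection(coll, tmp_path / "models")
        back = om.load_collection(tmp_path / "models")
        pd.testing.assert_frame_equal(om.predict_all(coll, expr), om.predict_all(back, expr))
        assert back.config == coll.config
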