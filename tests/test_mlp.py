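"""Perceptron forward pass, gradients, rprop training and BIC topology selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gxemlp.mlp import (
    MLP,
    SelectionError,
    Topology,
    TrainConfig,
    WeightSet,
    cross_entropy,
    forward,
    gradients,
    init_weights,
    n_params,
    select_topology,
)


def _random_instance(rng, n_obs=25, m=2):
    # exposure kept small so sigmoids stay away from float saturation, where
    # finite differences of the clipped error no longer see the true gradient
    X = np.column_stack([rng.integers(0, 3, n_obs), rng.uniform(0, 5, n_obs)])
    y = rng.integers(0, 2, n_obs).astype(float)
    w = init_weights(Topology(2, m), rng)
    return X, y, w


class TestForward:
    def test_zero_weights_give_half(self):
        ws = WeightSet.from_flat(Topology(2, 1), np.zeros(n_params(Topology(2, 1))))
        assert forward(ws, np.array([1.0, 50.0])) == pytest.approx(0.5)

    def test_nested_logistic_by_hand(self):
        # hidden weights 0 -> h = sigma(0) = 1/2; output w0=0, w1=1 -> sigma(1/2)
        ws = WeightSet(Topology(2, 1), np.zeros((3, 1)), np.array([0.0, 1.0]))
        assert forward(ws, np.array([3.0, 7.0])) == pytest.approx(expit(0.5))

    def test_m0_equals_logistic_regression_probability(self):
        coef = np.array([-0.4, 0.8, -0.02])
        ws = WeightSet(Topology(2, 0), None, coef)
        x = np.array([2.0, 63.0])
        assert forward(ws, x) == pytest.approx(expit(coef @ np.array([1.0, *x])))

    def test_shape_mismatch_raises(self):
        ws = WeightSet(Topology(2, 0), None, np.zeros(3))
        with pytest.raises(ValueError):
            forward(ws, np.array([1.0, 2.0, 3.0]))

    def test_matrix_input_vectorized(self):
        rng = np.random.default_rng(0)
        X, _, w = _random_instance(rng)
        rows = np.array([forward(w, x) for x in X])
        np.testing.assert_allclose(forward(w, X), rows, rtol=1e-12)


class TestCrossEntropy:
    def test_perfect_fit_zero(self):
        assert cross_entropy([0, 1], [0.0, 1.0]) == pytest.approx(0.0, abs=1e-10)

    def test_coin_flip_log2(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2))

    def test_constant_prediction_equals_null_deviance(self):
        import statsmodels.api as sm

        y = np.array([0, 0, 1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        res = sm.GLM(y, np.ones((10, 1)), family=sm.families.Binomial()).fit()
        assert cross_entropy(y, np.full(10, y.mean())) == pytest.approx(-res.llf, rel=1e-10)

    def test_always_finite_after_clipping(self):
        assert np.isfinite(cross_entropy([1.0], [0.0]))


class TestGradients:
    @given(st.integers(0, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=20)
    def test_matches_central_finite_differences(self, m, seed):
        rng = np.random.default_rng(seed)
        X, y, ws = _random_instance(rng, m=m)
        g = gradients(ws, X, y)
        w0 = ws.flat()
        h = 1e-6
        for k in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[k] += h
            wm[k] -= h
            top = ws.topology
            fd = (
                cross_entropy(y, forward(WeightSet.from_flat(top, wp), X))
                - cross_entropy(y, forward(WeightSet.from_flat(top, wm), X))
            ) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_m0_is_glm_score(self):
        rng = np.random.default_rng(3)
        X, y, _ = _random_instance(rng, m=0)
        ws = init_weights(Topology(2, 0), rng)
        X1 = np.hstack([np.ones((len(X), 1)), X])
        mu = expit(X1 @ ws.output)
        np.testing.assert_allclose(gradients(ws, X, y), X1.T @ (mu - y), rtol=1e-10)

    def test_compiled_kernel_agrees_with_numpy(self, warm_kernels):
        from gxemlp import _rprop

        rng = np.random.default_rng(4)
        X, y, ws = _random_instance(rng, m=2)
        X1 = np.hstack([np.ones((len(X), 1)), X])
        grad = np.zeros(ws.flat().size)
        E = _rprop.loss_and_grad(X1, y, ws.flat(), 2, 1e-12, grad)
        assert E == pytest.approx(cross_entropy(y, forward(ws, X)), rel=1e-10)
        np.testing.assert_allclose(grad, gradients(ws, X, y), rtol=1e-10)


class TestInitWeights:
    def test_weight_count(self):
        assert n_params(Topology(2, 3)) == 13
        assert n_params(Topology(2, 0)) == 3

    def test_same_seed_identical(self):
        a = init_weights(Topology(2, 2), np.random.default_rng(9))
        b = init_weights(Topology(2, 2), np.random.default_rng(9))
        np.testing.assert_array_equal(a.flat(), b.flat())

    def test_standard_normal_moments(self):
        rng = np.random.default_rng(10)
        draws = np.concatenate(
            [init_weights(Topology(2, 5), rng).flat() for _ in range(6000)]
        )
        n = len(draws)
        assert abs(draws.mean()) < 3 / np.sqrt(n)
        assert abs(draws.var() - 1) < 3 * np.sqrt(2 / n)


class TestRpropTraining:
    def test_m0_recovers_irls_coefficients(self, masking1_dataset, warm_kernels):
        import statsmodels.api as sm

        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        res = MLP(ds.status, X, m_hidden=0).fit(TrainConfig(), rng=0)
        irls = sm.GLM(
            ds.status.astype(float), np.hstack([np.ones((len(ds), 1)), X]),
            family=sm.families.Binomial(),
        ).fit(tol=1e-10)
        assert res.converged
        np.testing.assert_allclose(res.weights.output, irls.params, atol=1e-3)
        p = 3
        assert res.bic == pytest.approx(-2 * irls.llf + p * np.log(len(ds)), abs=1e-6)

    def test_descent_from_initialization(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        model = MLP(ds.status, X, m_hidden=1)
        rng = np.random.default_rng(12)
        start = init_weights(model.topology, rng)
        e0 = cross_entropy(ds.status, forward(start, X))
        res = model.fit(TrainConfig(stepmax=2000), start_weights=start)
        assert res.final_error <= e0

    def test_step_growth_while_sign_constant(self, warm_kernels):
        # one intercept-only weight, y=1: the gradient mu-1 stays negative, so
        # the step grows by x1.2 every iteration from delta_zero
        from gxemlp import _rprop

        X1 = np.ones((1, 1))
        y = np.array([1.0])
        w = np.array([-30.0])
        _rprop.rprop_train(X1, y, w, 0, 1.2, 0.5, 0.1, 50.0, 1e-9, 1e-12, 12, 1e-12)
        expected = -30.0 + 0.1 * sum(1.2**j for j in range(12))
        assert w[0] == pytest.approx(expected, rel=1e-9)

    def test_same_seed_bitwise_reproducible(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        a = MLP(ds.status, X, m_hidden=2).fit(TrainConfig(stepmax=400), rng=33)
        b = MLP(ds.status, X, m_hidden=2).fit(TrainConfig(stepmax=400), rng=33)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.final_error == b.final_error and a.bic == b.bic

    def test_single_status_rejected(self):
        with pytest.raises(ValueError):
            MLP(np.ones(5), np.zeros((5, 2)), m_hidden=0).fit(rng=0)


class TestBICAndSelection:
    def test_bic_penalty_arithmetic(self):
        # m -> m+1 adds (n+2) weights; same likelihood => BIC rises by (n+2) log N
        n_obs = 500
        p1 = n_params(Topology(2, 1))
        p2 = n_params(Topology(2, 2))
        assert (p2 - p1) == 4
        e = 100.0
        bic1 = 2 * e + p1 * np.log(n_obs)
        bic2 = 2 * e + p2 * np.log(n_obs)
        assert bic2 - bic1 == pytest.approx(4 * np.log(n_obs))

    def test_single_topology_single_restart(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        cfg = TrainConfig(stepmax=300, n_restarts=1)
        res = select_topology(ds.status, X, topologies=[1], config=cfg, rng=5)
        assert res.topology.m_hidden == 1
        assert len(res.selection_log) == 1

    def test_selection_is_deterministic(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        cfg = TrainConfig(stepmax=300, n_restarts=2)
        a = select_topology(ds.status, X, topologies=[0, 1], config=cfg, rng=6)
        b = select_topology(ds.status, X, topologies=[0, 1], config=cfg, rng=6)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.topology == b.topology

    def test_strict_mode_raises_when_nothing_converges(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        cfg = TrainConfig(stepmax=5, n_restarts=1)  # nothing can converge in 5 steps
        with pytest.raises(SelectionError):
            select_topology(
                ds.status, X, topologies=[2], config=cfg, rng=7, converged_only=True
            )

    def test_empty_topology_list_rejected(self, masking1_dataset):
        with pytest.raises(ValueError):
            select_topology(masking1_dataset.status, np.zeros((1000, 2)), topologies=[])


class TestPredictGrid:
    def test_shape_and_logistic_curves_for_m0(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        res = MLP(ds.status, X, m_hidden=0).fit(TrainConfig(), rng=0)
        surf = res.predict_grid()
        assert surf.shape == (3, 1001)
        # log-odds linear in u within each genotype
        lo = np.log(surf / (1 - surf))
        for g in range(3):
            slopes = np.diff(lo[g])
            assert np.allclose(slopes, slopes[0], atol=1e-8)

    def test_probabilities_strictly_inside_unit_interval(self, masking1_dataset, warm_kernels):
        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        res = MLP(ds.status, X, m_hidden=1).fit(TrainConfig(stepmax=200), rng=1)
        surf = res.predict_grid()
        assert np.all(surf > 0) and np.all(surf < 1)

    def test_json_roundtrip(self, tmp_path, masking1_dataset, warm_kernels):
        import json

        ds = masking1_dataset
        X = np.column_stack([ds.genotype, ds.exposure])
        res = MLP(ds.status, X, m_hidden=1).fit(TrainConfig(stepmax=100), rng=2)
        path = tmp_path / "model.json"
        res.to_json(path)
        d = json.loads(path.read_text())
        assert d["topology"]["m_hidden"] == 1
        np.testing.assert_allclose(d["output"], res.weights.output)
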