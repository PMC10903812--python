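"""The multi-input risk network: shapes, determinism, gradients, recovery."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from cmrsurv.cox import neg_log_partial_likelihood_grad
from cmrsurv.covariates import CovariateEncoder
from cmrsurv.estimators import CoxNeuralRegressor, build_network, forward_logrisk
from cmrsurv.nn import MultiInputCoxNet, NetworkConfig
from cmrsurv.nn.model import ConstructionError
from cmrsurv.simulate import SimParams, generate_cohort

TINY = dict(cine_filters=(2, 3), lge_filters=(2, 3), trunk_filters=(3, 3),
            embed_dim=4, cov_hidden=(4, 4), head_hidden=4)


def _tiny_net(seed=0, **kw):
    cfg = NetworkConfig(seed=seed, **{**TINY, **kw})
    return MultiInputCoxNet(cfg, n_cov=6, h=8, w=8, c=3, t=2)


def _tiny_batch(rng, n=5):
    return {"cine": rng.uniform(0, 1, (n, 2, 3, 8, 8)),
            "lge": rng.uniform(0, 1, (n, 3, 8, 8)),
            "cov": rng.normal(0, 1, (n, 6))}


class TestArchitecture:
    def test_output_is_a_single_scalar_per_patient(self, rng):
        net = _tiny_net()
        scores = net.forward(_tiny_batch(rng), train=False)
        assert scores.shape == (5,)
        assert np.isfinite(scores).all()

    def test_embedding_widths_are_eight_by_default(self):
        cfg = NetworkConfig(seed=0)
        net = MultiInputCoxNet(cfg, n_cov=23, h=16, w=16, c=7, t=8)
        # image-side embedding: last dense of the trunk; covariate branch:
        # last dense block — both project to width 8 before merging
        trunk_dense = [l for l in net.trunk.layers
                       if l.__class__.__name__ == "Dense"][-1]
        cov_dense = [l for l in net.cov_branch.layers
                     if l.__class__.__name__ == "Dense"][-1]
        assert trunk_dense.params["w"].shape[1] == 8
        assert cov_dense.params["w"].shape[1] == 8
        # merged width 16 feeds the head; final unit is linear, width 1
        head_first = [l for l in net.head.layers
                      if l.__class__.__name__ == "Dense"][0]
        head_last = [l for l in net.head.layers
                     if l.__class__.__name__ == "Dense"][-1]
        assert head_first.params["w"].shape[0] == 16
        assert head_last.params["w"].shape[1] == 1

    def test_parameter_count_fixed_across_seeds(self):
        assert _tiny_net(seed=1).n_parameters() == _tiny_net(seed=2).n_parameters()

    def test_parameter_count_matches_layer_arithmetic_for_linear_config(self):
        cfg = NetworkConfig(covariates_only=True, linear_covariates=True, seed=0)
        net = MultiInputCoxNet(cfg, n_cov=23)
        assert net.n_parameters() == 23 + 1  # single linear unit: w + b

    def test_dims_mismatch_raises_construction_error(self, rng):
        net = _tiny_net()
        bad = _tiny_batch(rng)
        bad["cine"] = bad["cine"][:, :, :, :6, :6]
        with pytest.raises(ConstructionError, match="homogenized"):
            net.forward(bad)


class TestForwardContract:
    def test_inference_is_deterministic(self, rng):
        net = _tiny_net()
        batch = _tiny_batch(rng)
        s1 = net.forward(batch, train=False)
        s2 = net.forward(batch, train=False)
        np.testing.assert_array_equal(s1, s2)

    def test_batch_permutation_equivariance(self, rng):
        net = _tiny_net()
        batch = _tiny_batch(rng, n=6)
        perm = np.array([3, 1, 5, 0, 4, 2])
        s = net.forward(batch, train=False)
        s_perm = net.forward({k: v[perm] for k, v in batch.items()}, train=False)
        np.testing.assert_allclose(s_perm, s[perm], atol=1e-12)

    def test_constant_input_gives_identical_scores(self):
        net = _tiny_net()
        n = 4
        batch = {"cine": np.zeros((n, 2, 3, 8, 8)), "lge": np.zeros((n, 3, 8, 8)),
                 "cov": np.zeros((n, 6))}
        scores = net.forward(batch, train=False)
        assert np.all(scores == scores[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_output_finite_under_random_unit_inputs(self, seed):
        rng = np.random.default_rng(seed)
        net = _tiny_net(seed=seed)
        batch = _tiny_batch(rng)
        assert np.isfinite(net.forward(batch, train=False)).all()
        assert np.isfinite(net.forward(batch, train=True)).all()

    def test_functional_wrappers(self, rng):
        net = build_network(NetworkConfig(seed=0, **TINY), n_cov=6, h=8, w=8, c=3, t=2)
        batch = _tiny_batch(rng)
        np.testing.assert_array_equal(
            forward_logrisk(net, batch, mode="inference"),
            net.forward(batch, train=False))
        with pytest.raises(ValueError, match="mode"):
            forward_logrisk(net, batch, mode="banana")


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Exact-gradient audit through every branch (ConvLSTM BPTT, conv
        trunk, batchnorm, dense head) at randomly probed weights."""
        net = _tiny_net(dropout=0.0, activity_l2=1e-3)
        batch = _tiny_batch(rng)
        time = rng.uniform(1, 90, 5)
        event = np.array([1, 0, 1, 1, 0])

        def loss():
            s = net.forward(batch, train=True)
            l, g = neg_log_partial_likelihood_grad(s, time, event)
            return l + net.penalty(), g

        l0, g = loss()
        net.backward(g)
        probe = np.random.default_rng(1)
        for key, layer, name in net.iter_params():
            p = layer.params[name]
            analytic = layer.grads[name]
            idx = tuple(probe.integers(0, s) for s in p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            lp, _ = loss()
            p[idx] = orig - eps
            lm, _ = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), key

    def test_one_small_step_decreases_loss(self, rng):
        net = _tiny_net(dropout=0.0, activity_l2=0.0)
        batch = _tiny_batch(rng, n=8)
        time = rng.uniform(1, 90, 8)
        event = rng.integers(0, 2, 8)
        event[0] = 1

        s = net.forward(batch, train=True)
        l0, g = neg_log_partial_likelihood_grad(s, time, event)
        net.backward(g)
        lr = 1e-3
        for _, layer, name in net.iter_params():
            layer.params[name] -= lr * layer.grads[name]
        s1 = net.forward(batch, train=True)
        l1, _ = neg_log_partial_likelihood_grad(s1, time, event)
        assert l1 < l0


class TestLinearRecovery:
    def test_degenerate_linear_model_recovers_generating_effects(self):
        """Covariate-only cohort (image betas zero), single linear unit
        trained with the Cox loss: recovers the sign of every generating
        effect and ranks patients like the true log-risk (Kendall >= 0.8)."""
        params = SimParams.strong_signal(n=400, seed=11, beta_amp=0.0, beta_scar=0.0)
        _, covariates, followup, truth = generate_cohort(params)
        enc = CovariateEncoder().fit(covariates)
        X = enc.transform(covariates)
        y = followup[["time_months", "event"]]
        model = CoxNeuralRegressor(covariates_only=True, linear_covariates=True,
                                   epochs=300, lr=5e-2, seed=11).fit(X, y)
        scores = model.predict(X)
        tau = kendalltau(scores, truth.true_log_risk).statistic
        assert tau >= 0.8

        w = model.net_.head.layers[0].params["w"][:, 0]
        names = list(enc.get_feature_names_out())
        # generating betas: age +, log NT-proBNP +, NYHA ordinal +
        assert w[names.index("age_std")] > 0
        assert w[names.index("nt_probnp_std")] > 0
        assert w[names.index("nyha_4")] > w[names.index("nyha_1")]
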