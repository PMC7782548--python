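"""Deep-LDA training, projection, cubic transform and serialisation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from watercv import (DeepLDAModel, lda_direction, make_gaussian_classes,
                     optimal_fisher_ratio, scatter_stats, train_deep_lda,
                     validation_fisher_ratio)
from watercv.deeplda import _batch_loss_grad, export_cv_table
from watercv.network import MLP

COLS2 = ["d_1", "d_2"]


@pytest.fixture(scope="module")
def gauss2d():
    return make_gaussian_classes(1500, 2, (1, 0), (-1, 0), np.eye(2), seed=10)


@pytest.fixture(scope="module")
def held2d():
    return make_gaussian_classes(1500, 2, (1, 0), (-1, 0), np.eye(2), seed=1000)


@pytest.fixture(scope="module")
def model2d(gauss2d):
    return train_deep_lda(gauss2d, hidden=(32, 16, 8), epochs=300, seed=0)


class TestLossGradient:
    def test_matches_finite_differences(self, rng):
        h_b = rng.normal(size=(10, 4)) + 0.3
        h_u = rng.normal(size=(12, 4))
        lam, eps = 0.05, 1e-6
        _, g_b, g_u = _batch_loss_grad(h_b, h_u, lam)
        for k in range(3):
            for i in range(4):
                hp, hm = h_b.copy(), h_b.copy()
                hp[k, i] += eps
                hm[k, i] -= eps
                fd = (
                    _batch_loss_grad(hp, h_u, lam)[0]
                    - _batch_loss_grad(hm, h_u, lam)[0]
                ) / (2 * eps)
                assert g_b[k, i] == pytest.approx(fd, abs=1e-7)

    def test_backprop_through_network(self, rng):
        # full dJ/dtheta against central finite differences
        net = MLP([3, 6, 4], activation="elu", seed=1)
        xb = rng.normal(size=(25, 3)) + 1
        xu = rng.normal(size=(25, 3)) - 1
        lam = 0.05

        def loss():
            return _batch_loss_grad(net.forward(xb), net.forward(xu), lam)[0]

        _, g_b, g_u = _batch_loss_grad(net.forward(xb), net.forward(xu), lam)
        net.forward(xb, cache=True)
        gwb, gbb = net.backward(g_b)
        net.forward(xu, cache=True)
        gwu, gbu = net.backward(g_u)
        grads = [a + b for a, b in zip(gwb, gwu)] + [a + b for a, b in zip(gbb, gbu)]
        params = net.get_params()
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                old = flat[idx]
                flat[idx] = old + eps
                jp = loss()
                flat[idx] = old - eps
                jm = loss()
                flat[idx] = old
                assert g.ravel()[idx] == pytest.approx(
                    (jp - jm) / (2 * eps), rel=1e-4, abs=1e-8
                )


class TestTraining:
    def test_linear_limit_recovers_plain_lda(self, gauss2d, held2d):
        """A single linear layer cannot beat plain LDA; its validation J
        matches the closed form within 1e-3 relative."""
        model = train_deep_lda(
            gauss2d, hidden=(2,), activation="linear", epochs=200, seed=3
        )
        j_deep = validation_fisher_ratio(model, held2d, lambda_reg=0.0)
        xb = held2d.loc[held2d.label == "B", COLS2].to_numpy()
        xu = held2d.loc[held2d.label == "U", COLS2].to_numpy()
        j_plain = optimal_fisher_ratio(scatter_stats(xb, xu), 0.0)
        assert j_deep == pytest.approx(j_plain, rel=1e-3)

    def test_deep_matches_or_beats_plain_lda(self, model2d, held2d):
        j_deep = validation_fisher_ratio(model2d, held2d)
        xb = held2d.loc[held2d.label == "B", COLS2].to_numpy()
        xu = held2d.loc[held2d.label == "U", COLS2].to_numpy()
        j_plain = optimal_fisher_ratio(scatter_stats(xb, xu), model2d.lambda_reg)
        assert j_deep >= 0.95 * j_plain

    def test_projection_tracks_analytic_lda(self, model2d, held2d):
        X = held2d[COLS2].to_numpy()
        xb = held2d.loc[held2d.label == "B", COLS2].to_numpy()
        xu = held2d.loc[held2d.label == "U", COLS2].to_numpy()
        w = lda_direction(scatter_stats(xb, xu), 0.0)
        lin = X @ w
        # deployed CV: strong linear correlation; raw projection: monotone
        assert abs(np.corrcoef(model2d.cv_value(X), lin)[0, 1]) >= 0.95
        assert abs(spearmanr(model2d.project(X), lin).statistic) >= 0.95

    def test_bound_class_projects_positive(self, model2d, held2d):
        sb = model2d.project(held2d.loc[held2d.label == "B", COLS2].to_numpy())
        su = model2d.project(held2d.loc[held2d.label == "U", COLS2].to_numpy())
        assert sb.mean() > su.mean()

    def test_separation_beats_best_single_descriptor(self, model2d, held2d):
        X = held2d[COLS2].to_numpy()
        lab = (held2d.label == "B").to_numpy()

        def separation(v):
            return abs(v[lab].mean() - v[~lab].mean()) / v.std()

        s = model2d.project(X)
        best_single = max(separation(X[:, i]) for i in range(X.shape[1]))
        assert separation(s) > best_single

    def test_single_class_rejected(self, gauss2d):
        with pytest.raises(ValueError):
            train_deep_lda(gauss2d[gauss2d.label == "B"], epochs=2)

    def test_replica_trainings_agree(self, gauss2d, held2d):
        """Different initial weights give CVs with strongly correlated
        held-out projections (the robustness protocol behind replica FES)."""
        X = held2d[COLS2].to_numpy()
        proj = [
            train_deep_lda(gauss2d, hidden=(16, 8), epochs=200, seed=s).cv_value(X)
            for s in (0, 1, 2)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.corrcoef(proj[i], proj[j])[0, 1]) >= 0.9


class TestProjectionAndStretch:
    def test_identity_model_projects_first_descriptor(self):
        # linear single-layer net wired to the identity, w = e_1
        net = MLP([2, 2], activation="linear", seed=0)
        net.weights[0] = np.eye(2)
        net.biases[0] = np.zeros(2)
        model = DeepLDAModel(
            net=net, w=np.array([1.0, 0.0]), s_min=-1.0, s_max=1.0,
            input_mean=np.zeros(2), input_std=np.ones(2), lambda_reg=0.0, seed=0,
        )
        d = np.array([[0.3, 9.9], [-2.0, 1.0]])
        assert np.allclose(model.project(d), d[:, 0])

    def test_size_mismatch_rejected(self, model2d):
        with pytest.raises(ValueError, match="descriptor"):
            model2d.project(np.zeros((3, 5)))

    def test_identical_inputs_identical_outputs(self, model2d):
        d = np.tile([0.2, -0.4], (5, 1))
        # identical up to BLAS batching roundoff
        assert np.ptp(model2d.project(d)) < 1e-12

    def test_forward_agrees_with_independent_recomputation(self, model2d, rng):
        # independent forward pass written from the stored weights
        d = rng.normal(size=(20, 2))
        x = (d - model2d.input_mean) / model2d.input_std
        a = x
        for W, b in zip(model2d.net.weights, model2d.net.biases):
            z = a @ W.T + b
            a = np.where(z > 0, z, np.expm1(z))
        s_ref = a @ model2d.w
        assert np.allclose(model2d.project(d), s_ref, rtol=1e-10)

    def test_stretch_fixed_points(self, model2d):
        # rescaled s = 0 -> 0; +-1 -> +-2 under u + u^3
        mid = 0.5 * (model2d.s_min + model2d.s_max)
        assert model2d.stretch(mid) == pytest.approx(0.0, abs=1e-12)
        assert model2d.stretch(model2d.s_max) == pytest.approx(2.0)
        assert model2d.stretch(model2d.s_min) == pytest.approx(-2.0)

    def test_stretch_strictly_monotone(self, model2d):
        s = np.linspace(model2d.s_min - 1, model2d.s_max + 1, 1000)
        assert np.all(np.diff(model2d.stretch(s)) > 0)

    def test_stretch_widens_distribution(self, model2d, held2d):
        s = model2d.project(held2d[COLS2].to_numpy())
        u = model2d.rescale(s)
        inside = np.abs(u) <= 1
        assert model2d.stretch(s)[inside].var() >= u[inside].var()


class TestSerialisation:
    def test_json_roundtrip_is_exact(self, model2d, tmp_path, held2d):
        path = tmp_path / "model.json"
        model2d.to_json(path)
        back = DeepLDAModel.from_json(path)
        X = held2d[COLS2].to_numpy()
        assert np.array_equal(model2d.cv_value(X), back.cv_value(X))

    def test_same_seed_training_byte_identical(self, gauss2d, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        train_deep_lda(gauss2d, hidden=(8,), epochs=30, seed=5).to_json(p1)
        train_deep_lda(gauss2d, hidden=(8,), epochs=30, seed=5).to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_export_cv_table_matches_direct_evaluation(model2d):
    grids = [np.linspace(-2, 2, 7), np.linspace(-2, 2, 5)]
    table = export_cv_table(model2d, grids)
    assert len(table) == 35
    pt = table.iloc[17]
    direct = model2d.cv_value(np.array([[pt.d_1, pt.d_2]]))[0]
    assert pt.s_w == pytest.approx(direct)
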