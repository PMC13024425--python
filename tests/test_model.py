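"""Network components: squash, routing (vs naive oracle), margin loss,
forward contracts, and finite-difference gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegroute import nn
from eegroute.model import (BiLSTMRoutingClassifier, ModelConfig, dynamic_route,
                            load_checkpoint, margin_loss, primary_vectorize,
                            save_checkpoint, squash)


# ---------------------------------------------------------------------------
# independent straight-line routing reference (the oracle)
# ---------------------------------------------------------------------------

def naive_squash(s):
    n = np.linalg.norm(s)
    if n < 1e-8:
        return np.zeros_like(s)
    return (s / n) * (n / (1.0 + n))


def naive_routing(u, W, r):
    """Per-sample scalar-loop dynamic routing, written independently of the
    vectorized implementation: softmax over lower units, weighted sum,
    squash, agreement update."""
    B, T, d = u.shape
    K, dp, _ = W.shape
    A = np.zeros((B, K, T))
    V = np.zeros((B, K, dp))
    for bi in range(B):
        u_hat = np.zeros((K, T, dp))
        for j in range(K):
            for i in range(T):
                u_hat[j, i] = W[j] @ u[bi, :, :][i]
        b = np.zeros((K, T))
        for _ in range(r):
            a = np.zeros((K, T))
            for j in range(K):
                e = np.exp(b[j] - b[j].max())
                a[j] = e / e.sum()
            v = np.zeros((K, dp))
            for j in range(K):
                s = np.zeros(dp)
                for i in range(T):
                    s += a[j, i] * u_hat[j, i]
                v[j] = naive_squash(s)
            for j in range(K):
                for i in range(T):
                    b[j, i] += u_hat[j, i] @ v[j]
        A[bi], V[bi] = a, v
    return A, V


# ---------------------------------------------------------------------------
# squash
# ---------------------------------------------------------------------------

class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(4)), np.zeros(4))

    def test_unit_norm_halves(self):
        s = np.array([1.0, 0.0, 0.0])
        assert np.linalg.norm(squash(s)) == pytest.approx(0.5)

    def test_three_four_vector(self):
        v = squash(np.array([3.0, 4.0]))
        np.testing.assert_allclose(v, [0.5, 2.0 / 3.0], rtol=1e-12)
        assert np.linalg.norm(v) == pytest.approx(5.0 / 6.0)

    def test_classic_quadratic_norm(self):
        s = np.array([3.0, 4.0])  # ||s|| = 5
        v = squash(s, "classic_quadratic")
        assert np.linalg.norm(v) == pytest.approx(25.0 / 26.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6))
    def test_range_and_direction(self, vals):
        s = np.array(vals)
        for variant in ("paper_linear", "classic_quadratic"):
            v = squash(s, variant)
            assert 0 <= np.linalg.norm(v) < 1
            if np.linalg.norm(s) > 1e-6:
                cos = np.dot(v, s) / (np.linalg.norm(v) * np.linalg.norm(s) + 1e-30)
                assert cos == pytest.approx(1.0, abs=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            squash(np.ones(3), "cubic")


# ---------------------------------------------------------------------------
# dynamic routing
# ---------------------------------------------------------------------------

class TestRouting:
    def test_single_lower_unit(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((1, 1, 3))
        W = rng.standard_normal((2, 2, 3))
        for r in (1, 2, 5):
            state = dynamic_route(u, W, r)
            np.testing.assert_allclose(state.a, 1.0)
            for j in range(2):
                np.testing.assert_allclose(state.v[0, j],
                                           naive_squash(W[j] @ u[0, 0]),
                                           atol=1e-12)

    def test_one_iteration_is_uniform_mean(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((2, 7, 3))
        W = rng.standard_normal((2, 4, 3))
        state = dynamic_route(u, W, 1)
        np.testing.assert_allclose(state.a, 1.0 / 7, atol=1e-12)
        for bi in range(2):
            for j in range(2):
                s = np.mean([W[j] @ u[bi, i] for i in range(7)], axis=0)
                np.testing.assert_allclose(state.v[bi, j], naive_squash(s),
                                           atol=1e-12)

    def test_identical_units_stay_uniform(self):
        one = np.array([0.3, -0.2, 0.5])
        u = np.tile(one, (1, 6, 1))
        W = np.random.default_rng(2).standard_normal((2, 3, 3))
        state = dynamic_route(u, W, 4)
        np.testing.assert_allclose(state.a, 1.0 / 6, atol=1e-9)
        for j in range(2):
            np.testing.assert_allclose(state.v[0, j], naive_squash(W[j] @ one),
                                       atol=1e-9)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            T = int(rng.integers(2, 9))
            d = int(rng.integers(2, 5))
            dp = int(rng.integers(2, 5))
            r = int(rng.choice([1, 3, 5]))
            u = rng.standard_normal((2, T, d))
            W = rng.standard_normal((2, dp, d))
            state = dynamic_route(u, W, r)
            A, V = naive_routing(u, W, r)
            np.testing.assert_allclose(state.a, A, atol=1e-6)
            np.testing.assert_allclose(state.v, V, atol=1e-6)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(1, 5))
    def test_coupling_conservation(self, seed, r):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((3, 6, 4))
        W = rng.standard_normal((2, 3, 4))
        state = dynamic_route(u, W, r)
        np.testing.assert_allclose(state.a.sum(axis=2), 1.0, atol=1e-6)
        assert np.all(np.linalg.norm(state.v, axis=-1) < 1)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal((1, 8, 3))
        W = rng.standard_normal((2, 3, 3))
        perm = rng.permutation(8)
        s1 = dynamic_route(u, W, 3)
        s2 = dynamic_route(u[:, perm], W, 3)
        np.testing.assert_allclose(s2.a[:, :, :], s1.a[:, :, perm], atol=1e-10)
        np.testing.assert_allclose(s2.v, s1.v, atol=1e-10)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            dynamic_route(np.zeros((1, 2, 3)), np.zeros((2, 2, 3)), 0)


# ---------------------------------------------------------------------------
# margin loss
# ---------------------------------------------------------------------------

class TestMarginLoss:
    def test_zero_when_hinges_satisfied(self):
        norms = np.array([[0.9, 0.1], [0.05, 0.95]])
        targets = np.array([0, 1])
        assert margin_loss(norms, targets, 0.9, 0.1, 0.5) == 0.0

    def test_quadratic_hinge_value(self):
        norms = np.array([[0.5, 0.1]])
        assert margin_loss(norms, np.array([0]), 0.9, 0.1, 0.5) == \
            pytest.approx(0.16)

    def test_lambda_zero_ignores_non_targets(self):
        norms = np.array([[0.9, 0.99]])  # non-target far above m-
        assert margin_loss(norms, np.array([0]), 0.9, 0.1, 0.0) == 0.0

    def test_batch_average(self):
        norms = np.array([[0.5, 0.1], [0.9, 0.1]])
        targets = np.array([0, 0])
        assert margin_loss(norms, targets, 0.9, 0.1, 0.5) == pytest.approx(0.08)

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(np.ones((1, 2)) * 0.5, np.array([0]), 0.1, 0.9, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        norms = rng.uniform(0, 1, size=(4, 2))
        targets = rng.integers(0, 2, size=4)
        assert margin_loss(norms, targets) >= 0.0


# ---------------------------------------------------------------------------
# forward pass contracts
# ---------------------------------------------------------------------------

def tiny_config(**kw):
    base = dict(hidden_size=4, vec_dim=3, out_vec_dim=3, routing_iters=2,
                in_channels=6, seed=0, dtype="float64")
    base.update(kw)
    return ModelConfig(**base)


class TestForward:
    def test_contract_shapes_and_ranges(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        x = np.random.default_rng(0).standard_normal((3, 1, 6, 10))
        out = model.forward(x)
        assert out.class_norms.shape == (3, 2)
        assert np.all((out.class_norms >= 0) & (out.class_norms < 1))
        np.testing.assert_array_equal(out.prediction,
                                      np.argmax(out.class_norms, axis=1))
        assert np.all(out.logits >= 0)

    def test_wide_allbands_style_input(self):
        model = BiLSTMRoutingClassifier(tiny_config(in_channels=30))
        x = np.random.default_rng(1).standard_normal((2, 1, 30, 8))
        out = model.forward(x)
        assert out.class_norms.shape == (2, 2)

    def test_shape_mismatch_message(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        with pytest.raises(ValueError, match="expected input"):
            model.forward(np.zeros((2, 1, 5, 10)))

    def test_nonfinite_rejected(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        x = np.zeros((1, 1, 6, 10))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            model.forward(x)

    def test_tied_norms_pick_lower_class(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        model.params["route.W"][:] = 0.0  # both class vectors collapse to 0
        x = np.random.default_rng(2).standard_normal((2, 1, 6, 10))
        out = model.forward(x)
        np.testing.assert_array_equal(out.prediction, 0)

    def test_unidirectional_halves_encoding(self):
        model = BiLSTMRoutingClassifier(tiny_config(bidirectional=False))
        xs = np.random.default_rng(3).standard_normal((2, 10, 6))
        from eegroute.model import bilstm_encode
        assert bilstm_encode(model, xs).shape == (2, 10, 4)

    def test_bidirectional_encoding_shape(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        xs = np.random.default_rng(4).standard_normal((2, 10, 6))
        from eegroute.model import bilstm_encode
        assert bilstm_encode(model, xs).shape == (2, 10, 8)

    def test_zero_weights_zero_input_gives_zero_encoding(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        for k in list(model.params):
            if k.startswith("lstm"):
                model.params[k][:] = 0.0
        from eegroute.model import bilstm_encode
        h = bilstm_encode(model, np.zeros((1, 5, 6)))
        np.testing.assert_array_equal(h, 0.0)

    def test_primary_vector_norms_below_one(self):
        model = BiLSTMRoutingClassifier(tiny_config())
        h = np.random.default_rng(5).standard_normal((10, 100, 8)) * 5
        u = primary_vectorize(model, h)
        assert np.all(np.linalg.norm(u, axis=-1) < 1.0)

    def test_variants_run(self):
        x = np.random.default_rng(6).standard_normal((2, 1, 6, 10))
        for variant in ("full", "routing_only", "bilstm_only"):
            model = BiLSTMRoutingClassifier(tiny_config(variant=variant))
            out = model.forward(x)
            assert out.class_norms.shape == (2, 2)
            assert np.all((out.class_norms >= 0) & (out.class_norms < 1))


# ---------------------------------------------------------------------------
# gradients: every analytic gradient vs central finite differences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant,squash_variant", [
    ("full", "paper_linear"),
    ("full", "classic_quadratic"),
    ("routing_only", "paper_linear"),
    ("bilstm_only", "paper_linear"),
])
def test_finite_difference_gradients(variant, squash_variant):
    cfg = tiny_config(hidden_size=3, vec_dim=2, out_vec_dim=2, routing_iters=3,
                      in_channels=4, variant=variant,
                      squash_variant=squash_variant, seed=1)
    model = BiLSTMRoutingClassifier(cfg)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 1, 4, 5))
    y = np.array([0, 1])
    _, grads, _ = model.loss_and_grads(x, y)
    eps = 1e-6
    for name, p in model.params.items():
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp, _, _ = model.loss_and_grads(x, y)
            p[idx] = orig - eps
            lm, _, _ = model.loss_and_grads(x, y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, abs=2e-7), \
                f"{variant}/{squash_variant}: {name}[{idx}]"


def test_training_step_reduces_loss():
    cfg = tiny_config(seed=3)
    model = BiLSTMRoutingClassifier(cfg)
    opt = nn.AdamW(model.params, lr=1e-2)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((8, 1, 6, 10))
    y = rng.integers(0, 2, size=8)
    losses = []
    for _ in range(30):
        loss, grads, _ = model.loss_and_grads(x, y)
        opt.step(grads)
        losses.append(loss)
    assert losses[-1] < losses[0]


def test_checkpoint_roundtrip(tmp_path):
    cfg = tiny_config(seed=5)
    model = BiLSTMRoutingClassifier(cfg)
    x = np.random.default_rng(1).standard_normal((2, 1, 6, 10))
    before = model.forward(x).class_norms
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert loaded.config == cfg
    np.testing.assert_array_equal(loaded.forward(x).class_norms, before)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(m_plus=0.1, m_minus=0.9)
    with pytest.raises(ValueError):
        ModelConfig(routing_iters=0)
    with pytest.raises(ValueError):
        ModelConfig(variant="cnn")
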