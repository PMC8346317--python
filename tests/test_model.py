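import numpy as np
import pytest

from spinemri.nn.model import (
    DenoiserSpec,
    LayerSpec,
    build_model,
    load_checkpoint,
    save_checkpoint,
)


def enumerate_parameters(depth: int, channels: int) -> int:
    """Independent count: walk the layer shapes and add up tensor sizes."""
    total = 0
    chain = [(1, channels)] + [(channels, channels)] * (depth - 2) + [(channels, 1)]
    for idx, (cin, cout) in enumerate(chain):
        total += 3 * 3 * cin * cout  # conv weights
        total += cout  # conv bias, retained in every layer
        if 0 < idx < depth - 1:  # hidden layers carry BN gamma/beta
            total += 2 * cout
    return total


def test_default_architecture_parameter_count():
    spec = DenoiserSpec(depth=15, channels=64)
    assert enumerate_parameters(15, 64) == 482_945
    assert spec.n_parameters() == 482_945
    assert build_model(spec, init_seed=0).n_parameters() == 482_945


def test_depth3_parameter_count():
    spec = DenoiserSpec(depth=3, channels=64)
    # 576+64 (input) + 36864+64+128 (hidden) + 576+1 (output)
    assert enumerate_parameters(3, 64) == 38_273
    assert spec.n_parameters() == 38_273
    assert build_model(spec, init_seed=0).n_parameters() == 38_273


def test_layer_roles_and_shapes():
    layers = DenoiserSpec(depth=15, channels=64).layers
    assert len(layers) == 15
    assert layers[0] == LayerSpec("input_conv", 1, 64, False, True)
    assert layers[-1] == LayerSpec("output_conv", 64, 1, False, False)
    assert all(
        l == LayerSpec("hidden_conv", 64, 64, True, True) for l in layers[1:-1]
    )
    assert DenoiserSpec(depth=15).hidden_layers == 13


def test_build_is_deterministic_given_seed():
    a = build_model(DenoiserSpec(depth=3), init_seed=5)
    b = build_model(DenoiserSpec(depth=3), init_seed=5)
    c = build_model(DenoiserSpec(depth=3), init_seed=6)
    for pa, pb in zip(a.params, b.params):
        for k in pa:
            np.testing.assert_array_equal(pa[k], pb[k])
    assert any(np.any(pa[k] != pc[k]) for pa, pc in zip(a.params, c.params) for k in pa)


def test_invalid_depth_rejected():
    with pytest.raises(ValueError, match="depth"):
        DenoiserSpec(depth=2)


def test_zeroed_output_layer_gives_exact_identity(phantom64):
    model = build_model(DenoiserSpec(depth=3), init_seed=1)
    model.params[-1]["weight"][:] = 0.0
    model.params[-1]["bias"][:] = 0.0
    residual, denoised = model.forward(phantom64)
    assert np.all(residual == 0.0)
    np.testing.assert_array_equal(denoised, phantom64)


def test_skip_connection_conservation(phantom64):
    # denoised + residual = noisy, elementwise to machine precision
    model = build_model(DenoiserSpec(depth=3), init_seed=2)
    residual, denoised = model.forward(phantom64)
    np.testing.assert_allclose(denoised + residual, phantom64, rtol=0, atol=1e-14)


def test_analytic_gradients_match_finite_differences():
    """MSE-loss gradients through a depth-3 model vs central differences."""
    model = build_model(DenoiserSpec(depth=3), init_seed=0, dtype=np.float64)
    rng = np.random.default_rng(1)
    x = rng.random((2, 16, 16, 1))
    t = rng.random((2, 16, 16, 1))
    pred, caches = model.forward_batch(x, train=True)
    err = pred - t
    grads = model.backward_batch((2.0 / err.size) * err, caches)

    def loss():
        p, _ = model.forward_batch(x, train=True)
        return float(np.mean((p - t) ** 2))

    eps = 1e-6
    rng2 = np.random.default_rng(2)
    for li, layer_params in enumerate(model.params):
        for key, arr in layer_params.items():
            for fi in rng2.integers(0, arr.size, size=4):
                orig = arr.flat[fi]
                arr.flat[fi] = orig + eps
                lp = loss()
                arr.flat[fi] = orig - eps
                lm = loss()
                arr.flat[fi] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[li][key].flat[fi]
                # hidden-conv biases are absorbed by BN: true gradient is 0
                if abs(num - ana) > 1e-10:
                    assert abs(num - ana) / max(abs(num), abs(ana)) < 1e-4, (
                        f"layer {li} {key}[{fi}]: analytic {ana} vs numeric {num}"
                    )


def test_checkpoint_roundtrip(tmp_path, phantom64):
    model = build_model(DenoiserSpec(depth=3), init_seed=9)
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert loaded.spec == model.spec
    res_a, den_a = model.forward(phantom64)
    res_b, den_b = loaded.forward(phantom64)
    np.testing.assert_array_equal(res_a, res_b)
    np.testing.assert_array_equal(den_a, den_b)


def test_forward_rejects_undersized_images():
    model = build_model(DenoiserSpec(depth=3), init_seed=0)
    with pytest.raises(ValueError):
        model.forward(np.zeros((8, 8)))
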