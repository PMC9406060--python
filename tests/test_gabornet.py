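"""Gabor kernel bank, backbone dimension chain, and readout heads."""

import numpy as np
import pytest

from ventralenc.gabornet import (
    BackboneSpec,
    GaborNet,
    GaborParams,
    ReadoutSpec,
    build_gabor_kernels,
    gabor_kernel_grads,
)


def reference_gabor(theta, lam, sigma, gamma, psi, size):
    """Independent pointwise evaluation of the Gabor formula."""
    half = (size - 1) // 2
    k = np.empty((size, size))
    for row in range(size):
        for col in range(size):
            x, y = col - half, row - half
            xp = x * np.cos(theta) + y * np.sin(theta)
            yp = -x * np.sin(theta) + y * np.cos(theta)
            env = np.exp(-(xp**2 + gamma**2 * yp**2) / (2 * sigma**2))
            k[row, col] = env * np.cos(2 * np.pi * xp / lam + psi)
    return k


class TestGaborKernels:
    def test_matches_pointwise_formula_on_random_tuples(self, rng):
        n = 100
        params = GaborParams(
            theta=rng.uniform(0, np.pi, n),
            lam=rng.uniform(2, 12, n),
            sigma=rng.uniform(0.5, 5, n),
            gamma=rng.uniform(0.3, 2.0, n),
            psi=rng.uniform(0, 2 * np.pi, n),
        )
        bank = build_gabor_kernels(params, 9)
        assert bank.shape == (2 * n, 1, 9, 9)
        for i in rng.choice(n, size=25, replace=False):
            even = reference_gabor(
                params.theta[i], params.lam[i], params.sigma[i], params.gamma[i], params.psi[i], 9
            )
            odd = reference_gabor(
                params.theta[i],
                params.lam[i],
                params.sigma[i],
                params.gamma[i],
                params.psi[i] + np.pi / 2,
                9,
            )
            np.testing.assert_allclose(bank[i, 0], even, atol=1e-12)
            np.testing.assert_allclose(bank[n + i, 0], odd, atol=1e-12)

    def test_quadrature_center_is_zero_at_zero_phase(self):
        p = GaborParams(theta=[0.3], lam=[5.0], sigma=[2.0], gamma=[1.0], psi=[0.0])
        bank = build_gabor_kernels(p, 9)
        assert bank[1, 0, 4, 4] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_period_pi_for_even_kernel(self):
        base = dict(lam=[4.0], sigma=[2.0], gamma=[1.3], psi=[0.0])
        k1 = build_gabor_kernels(GaborParams(theta=[0.7], **base), 9)
        k2 = build_gabor_kernels(GaborParams(theta=[0.7 + np.pi], **base), 9)
        np.testing.assert_allclose(k1[0], k2[0], atol=1e-12)

    def test_known_value_on_axis(self):
        p = GaborParams(theta=[0.0], lam=[4.0], sigma=[2.0], gamma=[1.0], psi=[0.0])
        k = build_gabor_kernels(p, 9)[0, 0]
        assert k[4, 4] == pytest.approx(1.0)
        # x=2, y=0 -> exp(-0.5) * cos(pi)
        assert k[4, 6] == pytest.approx(np.exp(-0.5) * np.cos(np.pi), abs=1e-12)

    @pytest.mark.parametrize("field", ["lam", "sigma", "gamma"])
    def test_nonpositive_parameters_rejected(self, field):
        kwargs = dict(theta=[0.0], lam=[4.0], sigma=[2.0], gamma=[1.0], psi=[0.0])
        kwargs[field] = [0.0]
        with pytest.raises(ValueError):
            GaborParams(**kwargs)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            build_gabor_kernels(GaborParams.default_bank(4), 8)

    def test_default_bank_expands_to_128_kernels(self):
        bank = build_gabor_kernels(GaborParams.default_bank(64), 9)
        assert bank.shape == (128, 1, 9, 9)

    def test_parameter_gradients_match_finite_differences(self, rng):
        params = GaborParams(
            theta=rng.uniform(0, np.pi, 3),
            lam=rng.uniform(3, 8, 3),
            sigma=rng.uniform(1, 4, 3),
            gamma=rng.uniform(0.5, 1.5, 3),
            psi=rng.uniform(0, 2 * np.pi, 3),
        )
        weights = rng.standard_normal((6, 1, 9, 9))
        grads = gabor_kernel_grads(params, 9, weights)
        eps = 1e-6
        for name in ("theta", "lam", "sigma", "gamma", "psi"):
            for i in range(3):
                for sgn, store in ((1, "hi"), (-1, "lo")):
                    arrs = {
                        f: getattr(params, "lam" if f == "lam" else f).copy()
                        for f in ("theta", "lam", "sigma", "gamma", "psi")
                    }
                    arrs[name][i] += sgn * eps
                    k = build_gabor_kernels(GaborParams(**arrs), 9)
                    if store == "hi":
                        hi = np.sum(weights * k)
                    else:
                        lo = np.sum(weights * k)
                fd = (hi - lo) / (2 * eps)
                assert grads[name][i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestBackbone:
    def test_default_dimension_chain(self):
        spec = BackboneSpec()
        assert spec.output_shapes() == ((128, 62, 62), (128, 31, 31), (128, 16, 16))
        assert spec.feature_dim == 32768

    @pytest.mark.parametrize("batch", [1, 3])
    def test_forward_shapes_reduced_any_batch(self, batch, rng):
        spec = BackboneSpec.reduced(32)
        net = GaborNet(spec, ReadoutSpec("linear", 5), rng=rng)
        x = rng.random((batch, 32, 32))
        pred, feats = net.forward(x, return_features=True)
        for tag, shape in zip(("conv1", "conv2", "conv3"), spec.output_shapes()):
            assert feats[tag].shape == (batch, *shape)
        assert pred.shape == (batch, 5)
        assert net.features(x).shape == (batch, spec.feature_dim)

    def test_wrong_input_side_raises_with_sizes(self, rng):
        net = GaborNet(BackboneSpec.reduced(32), ReadoutSpec("linear", 2), rng=rng)
        with pytest.raises(ValueError, match="64.*32|32.*64"):
            net.forward(rng.random((1, 64, 64)))

    def test_zero_input_zero_bias_gives_zero_conv3(self, rng):
        net = GaborNet(BackboneSpec.reduced(32), ReadoutSpec("linear", 2), rng=rng)
        for layer in net.net.layers:
            if "b" in layer.params:
                layer.params["b"][:] = 0
        _, feats = net.forward(np.zeros((2, 32, 32)), return_features=True)
        np.testing.assert_array_equal(feats["conv3"], 0)

    def test_forward_is_deterministic(self, rng):
        net = GaborNet(BackboneSpec.reduced(32), ReadoutSpec("nonlinear", 3), rng=rng)
        x = rng.random((2, 32, 32))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))


class TestReadout:
    def test_linear_zero_features_returns_bias(self, rng):
        from ventralenc.nn import Linear

        lin = Linear(4, 3, rng=rng, dtype=np.float64)
        lin.params["b"] = np.array([0.1, -0.2, 0.3])
        np.testing.assert_allclose(lin.forward(np.zeros((2, 4))), [[0.1, -0.2, 0.3]] * 2)

    def test_linear_hand_example(self, rng):
        from ventralenc.nn import Linear

        lin = Linear(2, 1, rng=rng, dtype=np.float64)
        lin.params["w"] = np.array([[1.0], [-1.0]])
        lin.params["b"] = np.array([0.5])
        assert lin.forward(np.array([[2.0, 1.0]]))[0, 0] == pytest.approx(1.5)

    def test_width_mismatch_raises(self, rng):
        from ventralenc.nn import Linear

        lin = Linear(4, 3, rng=rng)
        with pytest.raises(ValueError, match="width"):
            lin.forward(np.zeros((2, 5), dtype=np.float32))

    def test_nonlinear_defaults_latent_to_voxel_count(self):
        spec = ReadoutSpec("nonlinear", n_voxels=1535)
        assert spec.latent == 1535
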