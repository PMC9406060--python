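"""Source-voxel selection, representation extraction, readout, weight rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventralenc.evaluation import AccuracyVector
from ventralenc.gabornet import BackboneSpec, GaborNet, ReadoutSpec
from ventralenc.hierarchy import (
    HierReadout,
    RepresentationSpace,
    apply_squared_weight_rule,
    extract_representation,
    select_effective_voxels,
)
from ventralenc.nn import Adam, mse_loss


class TestSelection:
    def test_strictly_above_threshold(self):
        acc = AccuracyVector(np.array([0.5, 0.1, 0.28]), threshold=0.27)
        np.testing.assert_array_equal(select_effective_voxels(acc), [0, 2])

    def test_exact_threshold_excluded(self):
        acc = AccuracyVector(np.array([0.27]), threshold=0.27)
        with pytest.raises(ValueError, match="threshold"):
            select_effective_voxels(acc)

    def test_empty_selection_raises(self):
        acc = AccuracyVector(np.array([0.1, 0.2]), threshold=0.27)
        with pytest.raises(ValueError):
            select_effective_voxels(acc)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5), st.floats(0.0, 0.4))
    def test_raising_threshold_never_adds_voxels(self, seed, thr, bump):
        rho = np.random.default_rng(seed).uniform(-1, 1, 50)
        acc = AccuracyVector(rho)
        try:
            low = set(select_effective_voxels(acc, thr))
        except ValueError:
            low = set()
        try:
            high = set(select_effective_voxels(acc, thr + bump))
        except ValueError:
            high = set()
        assert high <= low


class TestSquaredWeightRule:
    def test_elementwise_gating(self):
        g = np.array([[0.1, -0.2], [0.3, 0.0]])
        w = np.array([[2.0, -1.0], [0.0, 5.0]])
        out = apply_squared_weight_rule(g, w)
        np.testing.assert_allclose(out, [[0.4, -0.2], [0.0, 0.0]])

    def test_zero_weight_suppresses(self):
        assert apply_squared_weight_rule(np.array([0.7]), np.array([0.0]))[0] == 0.0

    def test_unit_weights_identity(self, rng):
        g = rng.standard_normal((4, 5))
        w = rng.choice([-1.0, 1.0], (4, 5))
        np.testing.assert_array_equal(apply_squared_weight_rule(g, w), g)

    def test_sign_preserved_and_monotone_in_weight_magnitude(self, rng):
        g = np.full(10, 0.3)
        w = np.linspace(0.1, 2.0, 10)
        out = apply_squared_weight_rule(g, w)
        assert (np.sign(out) == np.sign(g)).all()
        assert (np.diff(np.abs(out)) > 0).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_squared_weight_rule(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_unit_weight_step_matches_plain_descent(self, rng):
        """From a +-1 first-layer init, one gated update equals the plain one."""
        x = rng.standard_normal((12, 6))
        y = rng.standard_normal((12, 3))
        readouts = []
        for _ in range(2):
            r = HierReadout(6, 3, rng=np.random.default_rng(99), dtype=np.float64)
            r.first_affine.params["w"] = np.sign(
                np.random.default_rng(5).standard_normal((6, 3))
            ).astype(np.float64)
            readouts.append(r)
        for r, rule in zip(readouts, (True, False)):
            opt = Adam(r.parameters(), lr=1e-3)
            _, grad = mse_loss(r.forward(x), y)
            r.backward(grad, weight_rule=rule)
            opt.step()
        for (k, a), (_, b) in zip(
            readouts[0].state_dict().items(), readouts[1].state_dict().items()
        ):
            np.testing.assert_allclose(a, b, atol=1e-10, err_msg=k)


class TestHierReadout:
    def test_hand_evaluated_forward(self):
        r = HierReadout(2, 1, rng=np.random.default_rng(0), dtype=np.float64, latent=1)
        r.net.layers[0].params["w"] = np.array([[1.0], [1.0]])
        r.net.layers[0].params["b"] = np.array([-1.0])
        r.net.layers[2].params["w"] = np.array([[2.0]])
        r.net.layers[2].params["b"] = np.array([0.0])
        assert r.forward(np.array([[2.0, 1.0]]))[0, 0] == pytest.approx(4.0)
        assert r.forward(np.array([[0.0, 0.0]]))[0, 0] == pytest.approx(0.0)

    def test_zero_weights_output_bias(self):
        r = HierReadout(3, 2, rng=np.random.default_rng(0), dtype=np.float64)
        for layer in (r.net.layers[0], r.net.layers[2]):
            layer.params["w"][:] = 0
            layer.params["b"][:] = 0
        r.net.layers[2].params["b"] = np.array([0.5, -0.5])
        np.testing.assert_allclose(r.forward(np.ones((4, 3))), [[0.5, -0.5]] * 4)

    def test_latent_defaults_to_target_voxel_count(self):
        r = HierReadout(10, 7, rng=np.random.default_rng(0))
        assert r.first_affine.params["w"].shape == (10, 7)

    def test_width_mismatch_raises(self):
        r = HierReadout(4, 2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="width"):
            r.forward(np.zeros((2, 5)))


@pytest.fixture(scope="module")
def stage1():
    rng = np.random.default_rng(42)
    spec = BackboneSpec.reduced(32)
    return GaborNet(spec, ReadoutSpec("linear", 12), rng=rng), spec


class TestExtraction:
    def test_feature_mode_width(self, stage1, rng):
        net, spec = stage1
        train, val = rng.random((6, 32, 32)), rng.random((3, 32, 32))
        rep = extract_representation(net, train, val, "feature", source_roi="V2")
        assert rep.dim == spec.feature_dim
        assert rep.train.shape == (6, spec.feature_dim)

    def test_voxel_mode_restricts_columns(self, stage1, rng):
        net, _ = stage1
        train, val = rng.random((6, 32, 32)), rng.random((3, 32, 32))
        sel = np.array([0, 3, 7])
        rep = extract_representation(net, train, val, "voxel", sel, source_roi="V1")
        assert rep.dim == 3
        full = net.forward(val)
        np.testing.assert_allclose(rep.val, full[:, sel], rtol=1e-6)

    def test_voxel_mode_without_selection_raises(self, stage1, rng):
        net, _ = stage1
        with pytest.raises(ValueError, match="selection"):
            extract_representation(net, rng.random((2, 32, 32)), rng.random((2, 32, 32)), "voxel")

    def test_repeated_extraction_identical_and_weights_untouched(self, stage1, rng):
        net, _ = stage1
        before = net.state_dict()
        train, val = rng.random((4, 32, 32)), rng.random((2, 32, 32))
        r1 = extract_representation(net, train, val, "feature")
        r2 = extract_representation(net, train, val, "feature")
        np.testing.assert_array_equal(r1.train, r2.train)
        for k, v in net.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_representation_space_invariants(self):
        with pytest.raises(ValueError):
            RepresentationSpace(np.zeros((3, 2)), np.zeros((3, 2)), "voxel", "V1")
        with pytest.raises(ValueError):
            RepresentationSpace(np.zeros((3, 2)), np.zeros((3, 2)), "pixel", "V1")
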