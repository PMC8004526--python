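from types import SimpleNamespace

import numpy as np
import pytest
from scipy import ndimage

from patchreg.deform import zero_field
from patchreg.network import NetworkConfig, build_model
from patchreg.predict import (
    pad_amount,
    predict_field,
    register,
    superposition_counts,
)
from patchreg.volumes_io import Volume3D

from .conftest import smooth_random_field


class ConstantStub:
    """Predicts the same displacement vector for every window."""

    def __init__(self, w, o, vec):
        self.w, self.o, self.vec = w, o, np.asarray(vec, dtype=np.float64)
        self.cfg = SimpleNamespace(window=w, output=o)

    def forward(self, fb, mb, train=False):
        B = fb.shape[0]
        out = np.zeros((B, 3, self.o, self.o, self.o))
        for c in range(3):
            out[:, c] = self.vec[c]
        return out


class GroundTruthStub:
    """Returns the true central block per window (assembly oracle)."""

    def __init__(self, w, o, gt_field):
        self.w, self.o = w, o
        self.cfg = SimpleNamespace(window=w, output=o)
        pad = pad_amount(w, o)
        self.padded = np.pad(gt_field.vectors, ((pad, pad),) * 3 + ((0, 0),), mode="edge")
        self.pad = pad

    def predict_blocks(self, fb, mb, centers):
        o = self.o
        out = []
        for c in centers:
            lo = [ci + self.pad - o // 2 for ci in c]
            block = self.padded[lo[0]:lo[0] + o, lo[1]:lo[1] + o, lo[2]:lo[2] + o]
            out.append(np.moveaxis(block, -1, 0))
        return np.stack(out)


class ZeroStub(ConstantStub):
    def __init__(self, w=16, o=9):
        super().__init__(w, o, (0.0, 0.0, 0.0))


class TestPredictField:
    def _pair(self, shape=(24, 24, 24)):
        gen = np.random.default_rng(0)
        data = ndimage.gaussian_filter(gen.random(shape), 1.5)
        return Volume3D(data=data), Volume3D(data=data.copy())

    def test_constant_stub_exact(self):
        fixed, moving = self._pair()
        stub = ConstantStub(16, 9, (1.5, -0.5, 2.0))
        field = predict_field(stub, fixed, moving, w=16, o=9, smooth_radius=0)
        np.testing.assert_allclose(field.vectors[..., 0], 1.5, atol=1e-12)
        np.testing.assert_allclose(field.vectors[..., 1], -0.5, atol=1e-12)
        np.testing.assert_allclose(field.vectors[..., 2], 2.0, atol=1e-12)

    def test_gt_stub_reassembles_exactly(self):
        fixed, moving = self._pair()
        gt = smooth_random_field((24, 24, 24), 3.0, seed=7)
        stub = GroundTruthStub(16, 9, gt)
        field = predict_field(stub, fixed, moving, w=16, o=9, smooth_radius=0)
        np.testing.assert_allclose(field.vectors, gt.vectors, atol=1e-9)

    def test_overlap_averaging_hand_case(self):
        # 16^3 volume, w=16, o=9: padded to 24^3, two windows per axis
        # (starts 0 and end-aligned 8), eight windows total whose central
        # blocks overlap.  A stub numbering windows 1..8 in traversal
        # order gives hand-computable averages.
        fixed = Volume3D(data=np.zeros((16, 16, 16)))

        class NumberingStub:
            def __init__(self):
                self.calls = 0

            def forward(self, fb, mb, train=False):
                B = fb.shape[0]
                out = np.zeros((B, 3, 9, 9, 9))
                for i in range(B):
                    out[i] = float(self.calls + i + 1)
                self.calls += B
                return out

        field = predict_field(NumberingStub(), fixed, fixed, w=16, o=9,
                              smooth_radius=0, batch_size=64)
        W = superposition_counts((16, 16, 16), 16, 9)
        # corner voxel (1,1,1): only window (0,0,0) -> value 1, W=1
        assert W[1, 1, 1] == 1
        assert field.vectors[1, 1, 1, 0] == pytest.approx(1.0)
        # voxel (8,1,1): windows 1 (start z=0) and 5 (start z=8) -> (1+5)/2
        assert W[8, 1, 1] == 2
        assert field.vectors[8, 1, 1, 0] == pytest.approx(3.0)
        # center voxel (8,8,8): all eight windows -> mean(1..8) = 4.5
        assert W[8, 8, 8] == 8
        assert field.vectors[8, 8, 8, 0] == pytest.approx(4.5)

    def test_full_coverage_and_W_geometry(self):
        W = superposition_counts((24, 24, 24), 16, 9)
        assert (W >= 1).all()
        # model-independent: equals the counter of a real prediction run
        fixed, moving = self._pair()
        stub = ConstantStub(16, 9, (1.0, 1.0, 1.0))
        field, report = predict_field(stub, fixed, moving, w=16, o=9, smooth_radius=0,
                                      with_report=True)
        assert report["coverage"] == 1.0
        assert report["W_min"] >= 1

    def test_brute_force_accumulation(self):
        # field * W == sum of contributing blocks, checked by re-accumulating
        shape = (20, 20, 20)
        gt = smooth_random_field(shape, 2.0, seed=11)
        fixed = Volume3D(data=np.zeros(shape))
        stub = GroundTruthStub(16, 9, gt)
        field = predict_field(stub, fixed, fixed, w=16, o=9, smooth_radius=0)
        W = superposition_counts(shape, 16, 9)
        # every voxel covered, and all contributions equal the GT value
        np.testing.assert_allclose(field.vectors * W[..., None],
                                   gt.vectors * W[..., None], atol=1e-9)

    def test_deterministic(self):
        fixed, moving = self._pair()
        model = build_model(NetworkConfig(window=16, output=9, base_features=2,
                                          n_encoders=2, seed=0))
        a = predict_field(model, fixed, moving)
        b = predict_field(model, fixed, moving)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_batch_size_invariance(self):
        fixed, moving = self._pair()
        model = build_model(NetworkConfig(window=16, output=9, base_features=2,
                                          n_encoders=2, seed=0))
        a = predict_field(model, fixed, moving, batch_size=64)
        b = predict_field(model, fixed, moving, batch_size=7)
        np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-5)

    def test_window_mismatch_rejected(self):
        fixed, moving = self._pair()
        model = build_model(NetworkConfig(window=16, output=9, base_features=2,
                                          n_encoders=2, seed=0))
        with pytest.raises(ValueError):
            predict_field(model, fixed, moving, w=32, o=9)

    def test_shape_mismatch_rejected(self):
        fixed, _ = self._pair()
        moving = Volume3D(data=np.zeros((16, 16, 16)))
        with pytest.raises(ValueError):
            predict_field(ZeroStub(), fixed, moving, w=16, o=9)


class TestRegister:
    class Models:
        def __init__(self, level1, level2):
            self.level1, self.level2 = level1, level2

    def test_zero_stubs_identity(self):
        gen = np.random.default_rng(1)
        vol = Volume3D(data=ndimage.gaussian_filter(gen.random((20, 20, 20)), 1.0))
        fixed = Volume3D(data=vol.data.copy())
        models = self.Models(ZeroStub(), ZeroStub())
        result = register(models, vol, fixed, smooth_radius=0)
        np.testing.assert_allclose(result.warped.data, vol.data, atol=1e-9)

    def test_gt_level1_zero_level2(self):
        from patchreg.deform import warp

        gen = np.random.default_rng(2)
        shape = (20, 20, 20)
        moving = Volume3D(data=ndimage.gaussian_filter(gen.random(shape), 1.5))
        gt = smooth_random_field(shape, 2.0, seed=3)
        fixed = warp(moving, gt)
        models = self.Models(GroundTruthStub(16, 9, gt), ZeroStub())
        result = register(models, moving, fixed, smooth_radius=0)
        np.testing.assert_allclose(result.warped.data, fixed.data, atol=1e-9)
        np.testing.assert_allclose(result.field_level1.vectors, gt.vectors, atol=1e-9)
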