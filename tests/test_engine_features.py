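"""Whole-vector extraction: cardinality, binary equivalence against the
independent classic implementation, weight-scaling classes, morphology."""

import numpy as np
import pytest

from fuzzyrad import EngineConfig, FuzzyMask, VoxelVolume, extract_features
from fuzzyrad.errors import MaskError
from fuzzyrad.manifest import default_manifest
from fuzzyrad.morphology import compute_morphology

from conftest import make_random_lesion
from reference_classic import classic_features

ENGINE = EngineConfig(min_voxels=32)  # small test lesions


class TestVectorContract:
    def test_manifest_names_and_order(self, lesion_factory):
        v, m = lesion_factory()
        fv = extract_features(v, m, ENGINE)
        assert fv.names == [fd.name for fd in default_manifest()]
        assert len(fv) == 153

    def test_min_voxel_gate_enforced(self):
        v = VoxelVolume(np.ones((6, 6, 6)), (2, 2, 2))
        w = np.zeros((6, 6, 6))
        w[2, 2, 2] = 1.0
        with pytest.raises(MaskError):
            extract_features(v, FuzzyMask(w, (2, 2, 2)), EngineConfig(min_voxels=64))

    def test_degenerate_lesion_flags_instead_of_dropping(self, rng):
        """A constant-intensity lesion has one grey level; undefined
        features come back flagged, not silently removed."""
        v, m = make_random_lesion(rng, n_levels_hint=1)
        v = VoxelVolume(np.full(v.shape, 4.0), v.spacing)
        fv = extract_features(v, m, ENGINE)
        assert len(fv) == 153
        assert "PET_cm_corr_3d_avg" in fv.invalid
        assert fv.no_variation


class TestBinaryEquivalence:
    def test_fuzzy_path_reproduces_classic_radiomics(self, rng):
        """With a {0,1} mask every feature from the weighted path equals
        the independent unweighted implementation to 1e-10 relative."""
        for _ in range(3):
            v, m = make_random_lesion(rng)
            fv = extract_features(v, m, ENGINE)
            ref = classic_features(v.values, m.weights, v.spacing, ENGINE.bin_width)
            for name, got in fv.values.items():
                want = ref[name]
                if np.isnan(want):
                    assert name in fv.invalid
                    continue
                assert got == pytest.approx(want, rel=1e-10, abs=1e-12), name


class TestWeightScaling:
    def test_declared_scaling_classes_hold(self, rng):
        """Scaling all memberships by 0.7 leaves intensive features
        unchanged and scales extensive ones by exactly 0.7."""
        v, m = make_random_lesion(rng, fuzzy=True)
        scaled = FuzzyMask(m.weights * 0.7, m.spacing)
        a = extract_features(v, m, ENGINE)
        b = extract_features(v, scaled, ENGINE)
        for fd in default_manifest():
            x, y = a.values[fd.name], b.values[fd.name]
            if np.isnan(x) or np.isnan(y):
                continue
            if fd.scaling == "intensive":
                assert y == pytest.approx(x, rel=1e-9), fd.name
            elif fd.scaling == "extensive":
                assert y == pytest.approx(0.7 * x, rel=1e-9), fd.name

    def test_continuity_in_a_single_weight(self, rng):
        """Perturbing one voxel's membership by a tiny delta moves
        normalized features only by a comparably tiny amount."""
        v, m = make_random_lesion(rng, fuzzy=True)
        w2 = m.weights.copy()
        target = tuple(np.argwhere(w2 > 0.3)[0])
        w2[target] += 1e-6
        a = extract_features(v, m, ENGINE)
        b = extract_features(v, FuzzyMask(w2, m.spacing), ENGINE)
        for fd in default_manifest():
            if fd.scaling == "geometric":
                continue
            x, y = a.values[fd.name], b.values[fd.name]
            if np.isnan(x) or np.isnan(y):
                continue
            scale = max(1.0, abs(x))
            assert abs(y - x) / scale < 1e-3, fd.name


class TestMorphology:
    def test_weighted_volume_is_linear_in_weights(self):
        w = np.zeros((8, 8, 8))
        w.ravel()[:100] = 1.0
        full = compute_morphology(FuzzyMask(w, (2, 2, 2)))
        half = compute_morphology(FuzzyMask(w * 0.5, (2, 2, 2)))
        assert full["morph_vol_count"] == pytest.approx(800.0)
        assert half["morph_vol_count"] == pytest.approx(400.0)

    def test_digital_sphere_sphericity(self):
        grids = np.meshgrid(*[(np.arange(16) - 7.5) * 2.0] * 3, indexing="ij")
        sphere = sum(g**2 for g in grids) <= 10.0**2
        f = compute_morphology(FuzzyMask(sphere.astype(float), (2, 2, 2)))
        assert 0.97 <= f["morph_sphericity"] <= 1.0

    def test_sub_half_fuzzy_mask_has_no_mesh(self):
        w = np.zeros((8, 8, 8))
        w[2:6, 2:6, 2:6] = 0.4
        f = compute_morphology(FuzzyMask(w, (2, 2, 2)))
        assert np.isnan(f["morph_vol_mesh"])
        assert f["morph_vol_count"] == pytest.approx(0.4 * 64 * 8)
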