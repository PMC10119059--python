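"""Discretization, weighted statistics and the fuzzy texture matrices
against hand-computed oracles."""

import numpy as np
import pytest

from fuzzyrad import FuzzyMask, VoxelVolume, discretize_intensities
from fuzzyrad.discretize import DiscretizedLesion
from fuzzyrad.errors import DiscretizationError
from fuzzyrad.intensity import weighted_intensity_statistics
from fuzzyrad.texture import (
    build_fuzzy_glcm,
    build_fuzzy_glrlm,
    build_fuzzy_glszm,
    build_fuzzy_ngtdm,
    glcm_features,
    ngtdm_features,
)


def _line_lesion(values, weights, bin_width=0.5):
    """A 1xNx1-shaped lesion embedded in 3D for hand calculations."""
    n = len(values)
    vals = np.zeros((1, n, 1))
    vals[0, :, 0] = values
    w = np.zeros((1, n, 1))
    w[0, :, 0] = weights
    v = VoxelVolume(vals, (2, 2, 2))
    m = FuzzyMask(w, (2, 2, 2))
    return discretize_intensities(v, m, bin_width=bin_width, epsilon=1e-3)


def _lesion_from_levels(levels, weights):
    """Build a DiscretizedLesion directly from level/weight arrays."""
    levels = np.asarray(levels, dtype=np.int32)
    weights = np.asarray(weights, dtype=float)
    inc = levels > 0
    return DiscretizedLesion(
        levels=levels,
        weights=np.where(inc, weights, 0.0),
        values=levels[inc].astype(float),
        flat_weights=weights[inc],
        n_levels=int(levels.max()),
        bin_width=1.0,
        spacing=(2.0, 2.0, 2.0),
        no_variation=int(levels.max()) == 1,
    )


class TestDiscretization:
    def test_floor_binning(self):
        d = _line_lesion([1.0, 1.2, 1.9], [1, 1, 1], bin_width=0.5)
        assert list(d.levels[0, :, 0]) == [1, 1, 2]
        assert d.n_levels == 2 and not d.no_variation

    def test_constant_lesion_flags_no_variation(self):
        d = _line_lesion([2.0, 2.0, 2.0], [1, 1, 1])
        assert d.n_levels == 1 and d.no_variation

    def test_epsilon_threshold_excludes_low_weights(self):
        vals = np.zeros((1, 2, 1))
        vals[0, :, 0] = [1.0, 9.0]
        w = np.zeros((1, 2, 1))
        w[0, :, 0] = [0.4, 0.6]
        d = discretize_intensities(
            VoxelVolume(vals, (2, 2, 2)), FuzzyMask(w, (2, 2, 2)),
            bin_width=0.5, epsilon=0.5,
        )
        assert len(d.values) == 1 and d.values[0] == 9.0

    def test_empty_inclusion_rejected(self):
        v = VoxelVolume(np.ones((3, 3, 3)), (2, 2, 2))
        m = FuzzyMask(np.zeros((3, 3, 3)), (2, 2, 2))
        with pytest.raises(DiscretizationError):
            discretize_intensities(v, m)


class TestWeightedStatistics:
    @pytest.mark.parametrize(
        "values,weights,mean",
        [([2, 4], [1, 1], 3.0), ([2, 4], [1, 0.0000001], 2.0)],
    )
    def test_weighted_mean(self, values, weights, mean):
        f = weighted_intensity_statistics(values, weights)
        assert f["stat_mean"] == pytest.approx(mean, abs=1e-6)

    def test_hand_computed_variance(self):
        f = weighted_intensity_statistics([1, 2, 3], [0.5, 1, 0.5])
        assert f["stat_mean"] == pytest.approx(2.0)
        assert f["stat_var"] == pytest.approx(0.5)

    def test_unit_weights_match_numpy(self, rng):
        x = rng.normal(3, 1, 40)
        f = weighted_intensity_statistics(x, np.ones(40))
        assert f["stat_mean"] == pytest.approx(x.mean())
        assert f["stat_var"] == pytest.approx(x.var())
        assert f["stat_median"] == pytest.approx(
            np.percentile(x, 50, method="inverted_cdf")
        )
        assert f["stat_energy"] == pytest.approx((x**2).sum())


class TestFuzzyGlcm:
    def test_hand_computed_weighted_pairs(self):
        """Collinear levels [1,2,2] with weights [1, .5, .8]: pair
        products .5 and .4 symmetrized give p(1,2)=p(2,1)=.5/1.8 and
        p(2,2)=.8/1.8."""
        d = _lesion_from_levels(
            np.array([[[1], [2], [2]]]), np.array([[[1.0], [0.5], [0.8]]])
        )
        tm = build_fuzzy_glcm(d, directions=[(0, 1, 0)], symmetric=True)
        np.testing.assert_allclose(
            tm.p, np.array([[0.0, 0.5], [0.5, 0.8]]) / 1.8, atol=1e-12
        )

    def test_unit_weights_reduce_to_classic_counts(self):
        d = _lesion_from_levels(
            np.array([[[1], [2], [2]]]), np.array([[[1.0], [1.0], [1.0]]])
        )
        tm = build_fuzzy_glcm(d, directions=[(0, 1, 0)], symmetric=True)
        np.testing.assert_allclose(
            tm.p, np.array([[0.0, 0.25], [0.25, 0.5]]), atol=1e-12
        )

    def test_single_level_has_zero_contrast(self):
        d = _lesion_from_levels(np.ones((3, 3, 3), dtype=int), np.ones((3, 3, 3)))
        tm = build_fuzzy_glcm(d)
        feats = glcm_features(tm)
        assert tm.p[0, 0] == pytest.approx(1.0)
        assert feats["contrast"] == 0.0

    def test_normalized_matrix_sums_to_one(self, lesion_factory):
        v, m = lesion_factory(fuzzy=True)
        d = discretize_intensities(v, m)
        for agg in ("avg", "mrg"):
            tm = build_fuzzy_glcm(d, aggregation=agg)
            assert tm.p.sum() == pytest.approx(1.0, abs=1e-12)


class TestFuzzyGlrlm:
    def test_classic_single_run(self):
        d = _lesion_from_levels(
            np.array([[[2], [2], [2]]]), np.ones((1, 3, 1))
        )
        tm = build_fuzzy_glrlm(d, directions=[(0, 1, 0)])
        assert tm.p[1, 2] == pytest.approx(1.0)

    def test_run_weight_is_mean_membership(self):
        d = _lesion_from_levels(
            np.array([[[2], [2], [2]]]), np.array([[[0.5], [1.0], [0.5]]])
        )
        tm = build_fuzzy_glrlm(d, directions=[(0, 1, 0)])
        assert tm.ns == pytest.approx(2.0 / 3.0)
        assert tm.p[1, 2] == pytest.approx(1.0)

    def test_alternating_levels_make_unit_runs(self):
        d = _lesion_from_levels(
            np.array([[[1], [2], [1]]]), np.ones((1, 3, 1))
        )
        tm = build_fuzzy_glrlm(d, directions=[(0, 1, 0)])
        assert tm.ns == pytest.approx(3.0)  # three runs of length 1
        assert tm.p.shape[1] == 1

    def test_normalized_matrix_sums_to_one(self, lesion_factory):
        v, m = lesion_factory(fuzzy=True)
        d = discretize_intensities(v, m)
        for agg in ("avg", "mrg"):
            assert build_fuzzy_glrlm(d, aggregation=agg).p.sum() == pytest.approx(
                1.0, abs=1e-12
            )


class TestFuzzyGlszm:
    def test_single_zone_unit_weights(self):
        levels = np.zeros((1, 4, 1), dtype=int)
        levels[0, :, 0] = 3
        d = _lesion_from_levels(levels, np.ones((1, 4, 1)))
        tm = build_fuzzy_glszm(d)
        assert tm.ns == pytest.approx(1.0)
        assert tm.p[2, 3] == pytest.approx(1.0)

    def test_zone_weight_is_mean_membership(self):
        levels = np.zeros((1, 4, 1), dtype=int)
        levels[0, :, 0] = 3
        w = np.zeros((1, 4, 1))
        w[0, :, 0] = [1, 1, 0.5, 0.5]
        d = _lesion_from_levels(levels, w)
        tm = build_fuzzy_glszm(d)
        assert tm.ns == pytest.approx(0.75)

    def test_separated_voxels_make_two_zones(self):
        levels = np.zeros((1, 5, 1), dtype=int)
        levels[0, 0, 0] = levels[0, 4, 0] = 2
        d = _lesion_from_levels(levels, np.ones((1, 5, 1)))
        tm = build_fuzzy_glszm(d)
        assert tm.ns == pytest.approx(2.0)
        assert tm.p[1, 0] == pytest.approx(1.0)


class TestFuzzyNgtdm:
    def test_uniform_volume_caps_coarseness(self):
        d = _lesion_from_levels(np.ones((3, 3, 3), dtype=int), np.ones((3, 3, 3)))
        s, n = build_fuzzy_ngtdm(d)
        assert s.sum() == 0.0
        assert ngtdm_features(s, n)["coarseness"] == 1e6

    def test_hand_computed_deviation(self):
        """Center voxel of [1,2,1] sees neighbor mean 1, adding |2-1|=1
        to the level-2 deviation sum."""
        d = _lesion_from_levels(
            np.array([[[1], [2], [1]]]), np.ones((1, 3, 1))
        )
        s, n = build_fuzzy_ngtdm(d)
        assert s[1] == pytest.approx(1.0)
        # edge voxels each see the single neighbor at level 2
        assert s[0] == pytest.approx(2.0)
        np.testing.assert_allclose(n, [2.0, 1.0])

    def test_ratio_features_invariant_under_weight_halving(self, lesion_factory):
        v, m = lesion_factory(fuzzy=True)
        d1 = discretize_intensities(v, m)
        half = FuzzyMask(m.weights * 0.5, m.spacing)
        d2 = discretize_intensities(v, half)
        f1 = ngtdm_features(*build_fuzzy_ngtdm(d1))
        f2 = ngtdm_features(*build_fuzzy_ngtdm(d2))
        for key in ("busyness", "complexity", "contrast", "coarseness", "strength"):
            assert f1[key] == pytest.approx(f2[key], rel=1e-9), key
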