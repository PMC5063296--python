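"""Texture matrices and the 27 parameters against hand values and oracles."""

import numpy as np
import pytest
from oracles import (
    all_features_oracle,
    glcm_features_oracle,
    glcm_oracle,
    rlm_features_oracle,
    runs_oracle,
    szm_features_oracle,
    zones_oracle,
)

from conftest import random_masked_grey
from phantex.texture import (
    MATRIX_PARAMETERS,
    PARAMETERS,
    GreyLevelImage,
    coefficient_of_variation,
    compute_all_features,
    compute_cooccurrence,
    compute_runlength,
    compute_sizezone,
    cooccurrence_features,
    intensity_variability,
    resample_grey_levels,
    runlength_features,
    sizezone_features,
)


def _grey(levels, n_levels=64):
    levels = np.asarray(levels, dtype=np.int32)
    return GreyLevelImage(levels, levels > 0, n_levels, 0.0, 1.0)


class TestResampling:
    def test_hand_example_three_values(self):
        vals = np.array([10.0, 20.0, 30.0]).reshape(3, 1, 1)
        g = resample_grey_levels(vals, np.ones((3, 1, 1), bool), 64)
        assert g.levels.ravel().tolist() == [1, 33, 64]

    def test_minimum_maps_to_one_and_max_clipped(self):
        vals = np.linspace(3.0, 9.0, 11).reshape(11, 1, 1)
        g = resample_grey_levels(vals, np.ones((11, 1, 1), bool), 64)
        assert g.levels.ravel()[0] == 1
        assert g.levels.ravel()[-1] == 64
        assert g.levels.max() <= 64

    def test_constant_region_maps_to_level_one(self):
        vals = np.full((3, 3, 3), 7.0)
        g = resample_grey_levels(vals, np.ones((3, 3, 3), bool), 64)
        assert (g.levels == 1).all()

    def test_out_of_mask_is_sentinel_zero(self, rng):
        vals = rng.random((4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.5
        mask.flat[0] = True
        g = resample_grey_levels(vals, mask, 16)
        assert (g.levels[~mask] == 0).all()
        assert (g.levels[mask] >= 1).all()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            resample_grey_levels(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool), 64)


class TestCooccurrence:
    def test_strip_hand_values(self, strip):
        m = compute_cooccurrence(strip)
        assert m.n_directions == 1
        assert m.p[0, 0] == pytest.approx(0.5)
        assert m.p[0, 1] == pytest.approx(0.25)
        assert m.p[1, 0] == pytest.approx(0.25)
        f = cooccurrence_features(m)
        assert f["ENT"] == pytest.approx(1.5)
        assert f["CON"] == pytest.approx(0.5)
        assert f["HOM"] == pytest.approx(0.75)
        assert f["COR"] == pytest.approx(-1.0 / 3.0)

    def test_constant_region_degenerate_values(self):
        g = _grey(np.ones((3, 3, 3)))
        f = cooccurrence_features(compute_cooccurrence(g))
        assert f["ENT"] == 0.0
        assert f["CON"] == 0.0
        assert f["HOM"] == 1.0
        assert f["COR"] == 0.0  # sigma^2 = 0 sentinel

    def test_matrix_symmetric_and_normalised(self, rng):
        for _ in range(20):
            g = random_masked_grey(rng)
            m = compute_cooccurrence(g)
            assert np.allclose(m.p, m.p.T)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (m.p >= 0).all()

    def test_grey_reversal_invariance(self, rng):
        g = random_masked_grey(rng, n_levels=6)
        rev_levels = np.where(g.levels > 0, 7 - g.levels, 0).astype(np.int32)
        grev = GreyLevelImage(rev_levels, g.mask, 6, 0.0, 1.0)
        f = cooccurrence_features(compute_cooccurrence(g))
        fr = cooccurrence_features(compute_cooccurrence(grev))
        for k in ("ENT", "CON", "HOM"):
            assert f[k] == pytest.approx(fr[k], rel=1e-12)

    def test_isolated_voxels_raise(self):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        levels[0, 0, 0] = 3
        with pytest.raises(ValueError, match="no neighbour pairs"):
            compute_cooccurrence(_grey(levels))


class TestRunLength:
    def test_strip_single_direction_hand_values(self):
        g = _grey(np.array([1, 1, 2, 2, 2]).reshape(5, 1, 1))
        r = compute_runlength(g, directions=[(1, 0, 0)])
        assert r.n_runs == 2
        assert r.counts[0, 1] == 1  # grey 1, length 2
        assert r.counts[1, 2] == 1  # grey 2, length 3
        f = runlength_features(r)
        assert f["SRE"] == pytest.approx(13.0 / 72.0)
        assert f["LRE"] == pytest.approx(6.5)
        assert f["RP"] == pytest.approx(2.0 / 5.0)

    def test_constant_strip_single_run(self):
        n = 7
        g = _grey(np.ones((n, 1, 1)))
        r = compute_runlength(g, directions=[(1, 0, 0)])
        f = runlength_features(r)
        assert r.n_runs == 1
        assert f["LRE"] == pytest.approx(n**2)
        assert f["SRE"] == pytest.approx(1.0 / n**2)
        assert f["RP"] == pytest.approx(1.0 / n)

    def test_runs_partition_the_mask_per_direction(self, rng):
        for _ in range(10):
            g = random_masked_grey(rng, shape=(5, 4, 3))
            for d in [(1, 0, 0), (0, 1, -1), (1, 1, 1)]:
                r = compute_runlength(g, directions=[d])
                l = np.arange(1, r.counts.shape[1] + 1)
                assert (r.counts * l).sum() == g.n_voxels

    def test_matches_oracle_all_13_directions(self, rng):
        for _ in range(25):
            g = random_masked_grey(rng)
            r = compute_runlength(g)
            runs = runs_oracle(np.asarray(g.levels))
            expect = np.zeros_like(r.counts)
            for grey_val, length in runs:
                expect[grey_val - 1, length - 1] += 1
            assert (r.counts == expect).all()
            f = runlength_features(r)
            fo = rlm_features_oracle(runs, g.n_voxels, 13)
            for k, v in fo.items():
                assert f[k] == pytest.approx(v, rel=1e-10)

    def test_sre_lre_cauchy_schwarz(self, rng):
        for _ in range(30):
            g = random_masked_grey(rng, shape=(5, 5, 4))
            f = runlength_features(compute_runlength(g))
            assert f["SRE"] * f["LRE"] >= 1.0 - 1e-12


class TestSizeZone:
    def test_three_by_three_slice_hand_values(self):
        sl = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]]).reshape(3, 3, 1)
        z = compute_sizezone(_grey(sl))
        assert z.n_zones == 3
        f = sizezone_features(z)
        assert f["SZE"] == pytest.approx(1.0 / 9.0)
        assert f["LZE"] == pytest.approx(9.0)
        assert f["ZP"] == pytest.approx(1.0 / 3.0)

    def test_constant_region_single_zone(self):
        g = _grey(np.ones((3, 4, 2)))
        z = compute_sizezone(g)
        f = sizezone_features(z)
        nv = 24
        assert z.n_zones == 1
        assert f["LZE"] == pytest.approx(nv**2)
        assert f["ZP"] == pytest.approx(1.0 / nv)

    def test_intensity_variability_hand_cases(self):
        # two zones of different greys -> 1; two zones of the same grey -> 2
        g = _grey(np.array([1, 1, 2]).reshape(3, 1, 1))
        assert intensity_variability(compute_sizezone(g)) == pytest.approx(1.0)
        # same grey twice, separated by an out-of-mask gap
        g = _grey(np.array([1, 0, 1]).reshape(3, 1, 1))
        assert intensity_variability(compute_sizezone(g)) == pytest.approx(2.0)

    def test_zones_partition_mask_and_match_oracle(self, rng):
        for _ in range(25):
            g = random_masked_grey(rng)
            z = compute_sizezone(g)
            s = np.arange(1, z.counts.shape[1] + 1)
            assert (z.counts * s).sum() == g.n_voxels
            zones = zones_oracle(np.asarray(g.levels))
            expect = np.zeros_like(z.counts)
            for grey_val, size in zones:
                expect[grey_val - 1, size - 1] += 1
            assert (z.counts == expect).all()

    def test_sze_lze_bracket_one(self, rng):
        for _ in range(30):
            g = random_masked_grey(rng, shape=(4, 5, 4))
            f = sizezone_features(compute_sizezone(g))
            assert f["SZE"] <= 1.0 + 1e-12 <= f["LZE"] + 1e-12


class TestCoV:
    def test_hand_value_and_scale_invariance(self):
        vals = np.array([4.0, 6.0]).reshape(2, 1, 1)
        mask = np.ones((2, 1, 1), bool)
        cov = coefficient_of_variation(vals, mask)
        assert cov == pytest.approx(np.sqrt(2.0) / 5.0)
        assert coefficient_of_variation(3.7 * vals, mask) == pytest.approx(cov)

    def test_constant_region_zero(self):
        assert coefficient_of_variation(np.full((3, 3, 3), 5.0), np.ones((3, 3, 3), bool)) == 0.0

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValueError, match="mean"):
            coefficient_of_variation(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool))


class TestAllFeatures:
    def test_exactly_27_named_parameters(self, rng):
        vals = rng.random((6, 6, 6)) + 1.0
        fv = compute_all_features(vals, np.ones((6, 6, 6), bool), n_levels=8)
        assert len(fv.values) == 27
        assert tuple(fv.values) == PARAMETERS

    def test_matrix_features_affine_invariant_cov_not(self, rng):
        vals = rng.random((5, 5, 5)) + 2.0
        mask = np.ones((5, 5, 5), bool)
        a, b = 3.0, 10.0
        f1 = compute_all_features(vals, mask, n_levels=8)
        f2 = compute_all_features(a * vals + b, mask, n_levels=8)
        for p in MATRIX_PARAMETERS:
            assert f1[p] == pytest.approx(f2[p], rel=1e-12), p
        assert f1["CoV"] != pytest.approx(f2["CoV"], rel=1e-3)

    def test_constant_region_degenerate_values(self):
        mask = np.ones((4, 4, 4), bool)
        fv = compute_all_features(np.full((4, 4, 4), 5.0), mask, n_levels=64)
        nv = 64
        assert fv["ENT"] == 0.0
        assert fv["CON"] == 0.0
        assert fv["HOM"] == 1.0
        assert fv["CoV"] == 0.0
        assert fv["LZE"] == pytest.approx(nv**2)
        assert fv["ZP"] == pytest.approx(1.0 / nv)

    def test_oracle_equivalence_random_grids(self, rng):
        """Full 27-parameter vectors equal the naive enumeration (1e-10 rel)."""
        for _ in range(30):
            shape = (4, 4, 4)
            vals = rng.random(shape) + 0.5
            mask = rng.random(shape) < 0.85
            if mask.sum() < 8:
                continue
            fv = compute_all_features(vals, mask, n_levels=4)
            ref = all_features_oracle(vals, mask, 4)
            for p in PARAMETERS:
                assert fv[p] == pytest.approx(ref[p], rel=1e-10, abs=1e-12), p

    def test_feature_range_invariants(self, rng):
        for _ in range(20):
            vals = rng.random((5, 5, 5)) + 1.0
            fv = compute_all_features(vals, np.ones((5, 5, 5), bool), n_levels=8)
            assert 0 < fv["HOM"] <= 1
            assert -1 <= fv["COR"] <= 1
            assert fv["ENT"] >= 0
            assert fv["CON"] >= 0
            assert 0 < fv["SRE"] <= 1 and 0 < fv["SZE"] <= 1
            assert fv["LRE"] >= 1 and fv["LZE"] >= 1
            assert 0 < fv["RP"] <= 1 and 0 < fv["ZP"] <= 1
            assert fv["CoV"] >= 0
            assert all(np.isfinite(v) for v in fv.values.values())

    def test_determinism(self, rng):
        vals = rng.random((5, 5, 5)) + 1.0
        mask = np.ones((5, 5, 5), bool)
        f1 = compute_all_features(vals, mask, n_levels=16)
        f2 = compute_all_features(vals.copy(order="F"), mask, n_levels=16)
        for p in PARAMETERS:
            assert f1[p] == f2[p]
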