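"""Seed definition, correlation mapping, t conversion, and whole-brain
standardization, with naive-loop and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedconn as sc
from seedconn.types import SeedPlacementError, ValidationError


class TestDefineSeed:
    def test_block_construction(self, small_mask):
        seed = sc.define_seed((4, 4, 3), small_mask)
        got = {tuple(v) for v in seed.voxel_indices}
        expected = {(x, y, 3) for x in (3, 4, 5) for y in (3, 4, 5)}
        assert got == expected

    def test_corner_center_raises_bounds_error(self, small_mask):
        with pytest.raises(SeedPlacementError):
            sc.define_seed((0, 0, 0), small_mask)

    def test_off_mask_voxel_listed_in_error(self):
        mask_arr = np.ones((8, 8, 8), bool)
        mask_arr[3, 3, 3] = False
        with pytest.raises(SeedPlacementError, match=r"\(3, 3, 3\)"):
            sc.define_seed((4, 4, 3), sc.BrainMask(mask_arr))


class TestReferenceTimeseries:
    def test_identical_series_detrended(self, small_mask, rng):
        s = rng.normal(size=40)
        data = np.tile(s, (8, 8, 8, 1))
        img = sc.Image4D(data=data, tr_s=2.8)
        seed = sc.define_seed((4, 4, 3), small_mask)
        ref = sc.reference_timeseries(img, seed)
        np.testing.assert_allclose(ref.values, sc.linear_detrend(s), atol=1e-12)

    def test_pure_lines_give_zero_reference(self, small_mask, rng):
        t = np.arange(40.0)
        data = np.zeros((8, 8, 8, 40))
        slopes = rng.normal(size=(8, 8, 8))
        data[:] = slopes[..., None] * t
        img = sc.Image4D(data=data, tr_s=2.8)
        ref = sc.reference_timeseries(img, sc.define_seed((4, 4, 3), small_mask))
        np.testing.assert_allclose(ref.values, np.zeros(40), atol=1e-8)

    def test_matches_naive_loop_oracle(self, small_mask, small_image):
        seed = sc.define_seed((4, 4, 3), small_mask)
        ref = sc.reference_timeseries(small_image, seed)
        acc = np.zeros(40)
        for v in seed.voxel_indices:  # naive re-computation
            acc += small_image.data[v[0], v[1], v[2], :]
        np.testing.assert_allclose(ref.values, sc.linear_detrend(acc / 9), atol=1e-10)

    def test_reference_orthogonal_to_line(self, small_mask, small_image):
        ref = sc.reference_timeseries(small_image,
                                      sc.define_seed((4, 4, 3), small_mask))
        t = np.arange(40)
        scale = max(np.abs(ref.values).max(), 1e-30) * 40
        assert abs(ref.values.sum()) < 1e-8 * scale
        assert abs(ref.values @ t) < 1e-8 * scale * 40


class TestCorrelationMap:
    def test_self_and_negated_correlation(self, rng):
        T = 40
        refv = sc.linear_detrend(rng.normal(size=T))
        data = np.zeros((2, 1, 1, T))
        data[0, 0, 0] = refv
        data[1, 0, 0] = -refv
        img = sc.Image4D(data=data, tr_s=2.8)
        mask = sc.BrainMask(np.ones((2, 1, 1), bool))
        rmap = sc.correlation_map(img, sc.ReferenceTimeSeries(values=refv), mask)
        assert rmap.data[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert rmap.data[1, 0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_pearson_value(self):
        # ref (1,2,3,4), voxel (1,3,2,4): cov-sum 4, each dev-sum-sq 5 -> r = 0.8
        ref = sc.ReferenceTimeSeries(values=np.array([1.0, 2.0, 3.0, 4.0]))
        data = np.array([1.0, 3.0, 2.0, 4.0]).reshape(1, 1, 1, 4)
        img = sc.Image4D(data=data, tr_s=1.0)
        mask = sc.BrainMask(np.ones((1, 1, 1), bool))
        rmap = sc.correlation_map(img, ref, mask)
        assert rmap.data[0, 0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_matches_naive_two_loop_oracle(self, small_image, small_mask, rng):
        refv = rng.normal(size=40)
        rmap = sc.correlation_map(small_image, sc.ReferenceTimeSeries(values=refv),
                                  small_mask)
        rc = refv - refv.mean()
        for x in range(0, 8, 3):  # spot-check a lattice of voxels
            for y in range(0, 8, 3):
                for z in range(0, 8, 3):
                    v = small_image.data[x, y, z]
                    vc = v - v.mean()
                    expected = (vc @ rc) / np.sqrt((vc @ vc) * (rc @ rc))
                    assert rmap.data[x, y, z] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_voxel_gets_r0_and_qc_count(self, rng):
        data = rng.normal(size=(3, 3, 3, 20))
        data[0, 0, 0, :] = 5.0  # flat series
        img = sc.Image4D(data=data, tr_s=2.8)
        mask = sc.BrainMask(np.ones((3, 3, 3), bool))
        qc = sc.QCLog()
        rmap = sc.correlation_map(img, sc.ReferenceTimeSeries(values=rng.normal(size=20)),
                                  mask, qc=qc)
        assert rmap.data[0, 0, 0] == 0.0
        assert qc.zero_variance_voxels == 1

    def test_zero_variance_reference_rejected(self, small_image, small_mask):
        with pytest.raises(ValidationError):
            sc.correlation_map(small_image,
                               sc.ReferenceTimeSeries(values=np.zeros(40)),
                               small_mask)

    def test_off_mask_is_nan(self, small_image, rng):
        mask_arr = np.ones((8, 8, 8), bool)
        mask_arr[0, 0, 0] = False
        rmap = sc.correlation_map(small_image,
                                  sc.ReferenceTimeSeries(values=rng.normal(size=40)),
                                  sc.BrainMask(mask_arr))
        assert np.isnan(rmap.data[0, 0, 0])


class TestRToT:
    def _rmap(self, values):
        return sc.StatMap(data=np.asarray(values, float).reshape(-1, 1, 1), kind="r")

    def test_zero_maps_to_zero(self):
        tmap = sc.r_to_t(self._rmap([0.0]), dof=17)
        assert tmap.data[0, 0, 0] == 0.0

    def test_direct_formula_oracle(self):
        tmap = sc.r_to_t(self._rmap([0.8]), dof=130)
        expected = 0.8 * np.sqrt(130 / 0.36)  # ~= 15.20
        assert tmap.data[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(15.2023, abs=5e-4)

    def test_r_of_one_finite_via_clipping(self):
        tmap = sc.r_to_t(self._rmap([1.0, -1.0]), dof=130)
        assert np.all(np.isfinite(tmap.data))
        assert tmap.data[0, 0, 0] > 1e5
        assert tmap.data[1, 0, 0] < -1e5

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0),
           st.integers(min_value=1, max_value=500))
    def test_strictly_increasing_and_odd(self, r1, r2, dof):
        t = sc.r_to_t(self._rmap([r1, r2, -r1]), dof=dof).data.ravel()
        if r1 < r2:
            assert t[0] < t[1]
        elif r1 > r2:
            assert t[0] > t[1]
        assert t[2] == pytest.approx(-t[0], rel=1e-12, abs=1e-300)


class TestStandardizeWholeBrain:
    def test_in_mask_mean_zero_variance_one(self, small_image, small_mask):
        tmap = sc.StatMap(data=small_image.data[..., 0] * 3 + 1, kind="t")
        z = sc.standardize_whole_brain(tmap, small_mask)
        vals = z.data[small_mask.data]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.var() - 1.0) < 1e-10

    def test_idempotent(self, small_image, small_mask):
        tmap = sc.StatMap(data=small_image.data[..., 0], kind="t")
        z1 = sc.standardize_whole_brain(tmap, small_mask)
        z2 = sc.standardize_whole_brain(
            sc.StatMap(data=z1.data, kind="t", mask_applied=True), small_mask)
        np.testing.assert_allclose(z2.data[small_mask.data],
                                   z1.data[small_mask.data], atol=1e-10)

    def test_population_sd_convention_on_three_values(self):
        tmap = sc.StatMap(data=np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), kind="t")
        mask = sc.BrainMask(np.ones((3, 1, 1), bool))
        z = sc.standardize_whole_brain(tmap, mask, sd_mode="population")
        np.testing.assert_allclose(z.data.ravel(), [-1.2247, 0.0, 1.2247], atol=5e-5)

    def test_affine_invariance(self, small_image, small_mask, rng):
        t = small_image.data[..., 0]
        z1 = sc.standardize_whole_brain(sc.StatMap(data=t, kind="t"), small_mask)
        z2 = sc.standardize_whole_brain(sc.StatMap(data=3.5 * t - 2.0, kind="t"),
                                        small_mask)
        np.testing.assert_allclose(z2.data[small_mask.data],
                                   z1.data[small_mask.data], atol=1e-10)

    def test_rank_order_preserved(self, small_image, small_mask):
        t = small_image.data[..., 0]
        z = sc.standardize_whole_brain(sc.StatMap(data=t, kind="t"), small_mask)
        tv, zv = t[small_mask.data], z.data[small_mask.data]
        np.testing.assert_array_equal(np.argsort(tv), np.argsort(zv))

    def test_constant_map_rejected(self, small_mask):
        with pytest.raises(ValidationError):
            sc.standardize_whole_brain(sc.StatMap(data=np.full((8, 8, 8), 2.0),
                                                  kind="t"), small_mask)


class TestSubjectZmap:
    def test_peak_falls_in_planted_node(self, default_config):
        img, physio, truth = sc.generate_subject(default_config,
                                                 "no-head-trauma", 77)
        mask = sc.BrainMask(np.ones(default_config.grid_dims, bool))
        z = sc.subject_zmap(img, physio, (12, 12, 8), mask)
        peak = np.unravel_index(np.nanargmax(z.data), z.shape)
        assert truth.any_node_mask()[peak]

    def test_zero_amplitude_map_is_standardized_noise(self):
        cfg = sc.SimulationConfig(amp_by_group={"null": 0.0, "x": 0.5})
        img, physio, _ = sc.generate_subject(cfg, "null", 31)
        mask = sc.BrainMask(np.ones(cfg.grid_dims, bool))
        z = sc.subject_zmap(img, physio, (12, 12, 8), mask)
        vals = z.data[mask.data]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.var() - 1.0) < 1e-10
        # the seed voxels correlate with their own average even for pure
        # noise, so exclude the seed's immediate neighbourhood; elsewhere
        # max |z| of ~9k standardized values follows Gaussian order
        # statistics (~3.7); allow a generous band
        idx = np.indices(cfg.grid_dims)
        cheb = np.max(np.abs(idx - np.array([12, 12, 8]).reshape(3, 1, 1, 1)), axis=0)
        away = np.abs(z.data[cheb > 2])
        assert 2.5 < away.max() < 6.0

    def test_deterministic(self, default_config):
        img, physio, _ = sc.generate_subject(default_config, "head-trauma", 13)
        mask = sc.BrainMask(np.ones(default_config.grid_dims, bool))
        z1 = sc.subject_zmap(img, physio, (12, 12, 8), mask)
        z2 = sc.subject_zmap(img, physio, (12, 12, 8), mask)
        np.testing.assert_array_equal(z1.data, z2.data)
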