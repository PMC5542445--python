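"""Signal model, per-voxel fitting and ΔR1 map construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaquer1.phantom import build_ground_truth, simulate_sr_series
from plaquer1.relaxometry import (
    SaturationRecoveryT1Mapper,
    SRSignalParams,
    delta_r1,
    fit_map,
    fit_voxel,
    fit_voxels,
    model_signal,
    r1_from_t1,
    roi_mean_delta_r1,
    sr_signal,
)
from plaquer1.volumetry import ROISet

from conftest import CANONICAL_TR


class TestModelSignal:
    @pytest.mark.parametrize(
        "params, t, tr, expected",
        [
            # perfect saturation at t = T1: S0 (1 - 1/e)
            (SRSignalParams(s0=1000, t1=800, b=0.0), 800, 1500, 632.120559),
            # imperfect saturation, frozen from an independent high-precision
            # evaluation of the closed-form expression
            (SRSignalParams(s0=1000, t1=800, b=0.2), 1200, 1500, 722.756815),
        ],
    )
    def test_known_values(self, params, t, tr, expected):
        assert model_signal(params, t, tr) == pytest.approx(expected, abs=1e-4)

    def test_plateau_at_long_delay(self):
        p = SRSignalParams(s0=1000, t1=800, b=0.15)
        val = model_signal(p, t=2e4, tr=1500)
        assert val == pytest.approx(1000, rel=1e-4)

    @given(
        t=st.floats(10, 3000),
        t1=st.floats(100, 3000),
        s0=st.floats(0.1, 2000),
    )
    def test_reduces_to_textbook_form_at_b0(self, t, t1, s0):
        expected = s0 * (1 - np.exp(-t / t1))
        got = sr_signal(s0, t1, 0.0, t, CANONICAL_TR)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_rejects_nonpositive_delay(self):
        with pytest.raises(ValueError):
            sr_signal(1.0, 1000.0, 0.1, 0.0, 1500.0)

    def test_signal_decreases_with_t1_at_fixed_delay(self):
        t1s = np.linspace(200, 3000, 50)
        vals = sr_signal(1.0, t1s, 0.1, 500.0, 1500.0)
        assert np.all(np.diff(vals) < 0)


class TestFitVoxel:
    def test_recovers_noiseless_generator(self, delays, tr):
        clean = sr_signal(1000.0, 1200.0, 0.0, delays, tr)
        res = fit_voxel(clean, delays, tr)
        assert res.converged
        assert res.params.t1 == pytest.approx(1200.0, rel=1e-3)

    @pytest.mark.parametrize(
        "s0, t1, b", [(800, 600, 0.25), (1.0, 357.1, 0.1), (0.5, 2000, 0.05)]
    )
    def test_exact_on_noiseless_curves(self, delays, tr, s0, t1, b):
        clean = sr_signal(s0, t1, b, delays, tr)
        res = fit_voxel(clean, delays, tr)
        assert res.params.t1 == pytest.approx(t1, rel=1e-6)
        assert res.params.b == pytest.approx(b, abs=1e-6)
        assert res.params.s0 == pytest.approx(s0, rel=1e-6)

    def test_b_fixed_excludes_b_from_free_set(self, delays, tr):
        clean = sr_signal(900.0, 750.0, 0.12, delays, tr)
        res = fit_voxel(clean, delays, tr, b_fixed=0.12)
        assert res.params.b == 0.12
        assert res.params.t1 == pytest.approx(750.0, rel=1e-6)

    def test_matches_independent_optimizer(self, delays, tr):
        """Cross-check the in-house LM solver against scipy's bounded
        trust-region least squares on noisy curves."""
        from scipy.optimize import least_squares

        rng = np.random.default_rng(42)
        for _ in range(10):
            t1, b, s0 = rng.uniform(300, 2000), rng.uniform(0, 0.15), rng.uniform(0.5, 1.2)
            sig = sr_signal(s0, t1, b, delays, tr) + rng.normal(0, 0.01, delays.size)
            sig = np.abs(sig)
            mine = fit_voxel(sig, delays, tr)

            best = None
            for t1_0, b_0 in ((1000.0, 0.1), (400.0, 0.05), (1500.0, 0.35)):
                ref = least_squares(
                    lambda p: sr_signal(p[0], p[1], p[2], delays, tr) - sig,
                    [sig.max(), t1_0, b_0],
                    bounds=([0, 1, 0], [np.inf, 10000, 0.99]),
                )
                if best is None or ref.cost < best.cost:
                    best = ref
            assert 0.5 * mine.residual_norm**2 <= best.cost * (1 + 1e-3) + 1e-12

    def test_rejects_nonfinite_signal(self, delays, tr):
        sig = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="finite"):
            fit_voxel(sig, delays, tr)

    def test_requires_enough_points(self, tr):
        with pytest.raises(ValueError, match="at least"):
            fit_voxel(np.array([1.0, 2.0]), np.array([100.0, 500.0]), tr)
        # two points suffice when B is fixed
        clean = sr_signal(1.0, 500.0, 0.0, np.array([200.0, 1200.0]), tr)
        res = fit_voxel(clean, np.array([200.0, 1200.0]), tr, b_fixed=0.0)
        assert res.params.t1 == pytest.approx(500.0, rel=1e-6)

    def test_batch_and_scalar_paths_agree(self, delays, tr):
        rng = np.random.default_rng(3)
        sigs = np.abs(
            sr_signal(0.9, 800.0, 0.1, delays, tr) + rng.normal(0, 0.01, (4, delays.size))
        )
        batch = fit_voxels(sigs, delays, tr)
        for i in range(4):
            single = fit_voxel(sigs[i], delays, tr)
            assert single.params.t1 == pytest.approx(batch["t1"][i])


class TestFitMap:
    def test_constant_b_smoothing_is_noop(self, flat_b_spec, delays, tr):
        truth = build_ground_truth(flat_b_spec)
        series = simulate_sr_series(truth, delays, tr, noise_sigma=0.0, seed=0)
        mask = truth.labels > 0
        one = fit_map(series, passes=1, mask=mask)
        three = fit_map(series, passes=3, mask=mask)
        np.testing.assert_allclose(
            three.t1_map[mask], one.t1_map[mask], rtol=1e-6
        )

    def test_all_background_mask_fits_nothing(self, plaque_truth, delays, tr):
        series = simulate_sr_series(plaque_truth, delays, tr, noise_sigma=0.0, seed=0)
        rmap = fit_map(series, mask=np.zeros(series.grid.shape, dtype=bool))
        assert not rmap.mask.any()
        assert np.isnan(rmap.t1_map).all()

    def test_requires_three_delays(self, plaque_truth, tr):
        short = simulate_sr_series(
            plaque_truth, delays_ms=[100.0, 900.0], tr_ms=tr, noise_sigma=0.0, seed=0
        )
        with pytest.raises(ValueError, match="3 saturation delays"):
            fit_map(short)

    def test_estimator_api_round_trip(self, plaque_truth, delays, tr):
        mapper = SaturationRecoveryT1Mapper(passes=2, smooth_radius=1)
        assert mapper.get_params()["passes"] == 2
        mapper.set_params(passes=1)
        series = simulate_sr_series(plaque_truth, delays, tr, noise_sigma=0.0, seed=0)
        mask = plaque_truth.labels > 0
        mapper.fit(series, mask=mask)
        rmap = mapper.to_relaxation_map()
        assert rmap.t1_map.shape == series.grid.shape
        sel = mask & np.isfinite(rmap.t1_map)
        np.testing.assert_allclose(
            rmap.t1_map[sel], plaque_truth.t1_pre[sel], rtol=1e-4
        )


class TestRates:
    @pytest.mark.parametrize("t1, r1", [(1000.0, 1.0), (500.0, 2.0), (357.1, 2.8003)])
    def test_r1_from_t1_values(self, t1, r1):
        assert r1_from_t1(np.array([t1]))[0] == pytest.approx(r1, abs=1e-3)

    def test_nonpositive_t1_masked_out(self, caplog):
        t1 = np.array([1000.0, -5.0, 0.0])
        r1 = r1_from_t1(t1, mask=np.ones(3, dtype=bool))
        assert np.isnan(r1[1]) and np.isnan(r1[2])
        assert r1[0] == 1.0

    def test_self_consistency_r1_times_t1(self, plaque_truth, delays, tr):
        series = simulate_sr_series(plaque_truth, delays, tr, noise_sigma=0.01, seed=4)
        rmap = fit_map(series, passes=1, mask=plaque_truth.labels > 0)
        sel = rmap.mask & np.isfinite(rmap.t1_map)
        np.testing.assert_allclose(
            rmap.r1_map[sel] * rmap.t1_map[sel], 1000.0, rtol=1e-12
        )


class TestDeltaR1:
    def _map_pair(self, truth, delays, tr, noise=0.0):
        mask = truth.labels > 0
        pre = fit_map(
            simulate_sr_series(truth, delays, tr, noise_sigma=noise, seed=1), mask=mask
        )
        post = fit_map(
            simulate_sr_series(truth, delays, tr, noise_sigma=noise, seed=2, contrast="post"),
            mask=mask,
        )
        return pre, post

    def test_identical_maps_give_zero(self, plaque_truth, delays, tr):
        pre, _ = self._map_pair(plaque_truth, delays, tr)
        dmap = delta_r1(pre, pre)
        assert np.allclose(dmap.delta_r1[dmap.mask], 0.0)

    def test_grid_mismatch_raises(self, plaque_truth, delays, tr):
        from dataclasses import replace
        from plaquer1.grid import Grid

        pre, post = self._map_pair(plaque_truth, delays, tr)
        shifted = replace(
            post, grid=Grid(post.grid.shape, post.grid.voxel_size, (1.0, 0.0, 0.0))
        )
        with pytest.raises(ValueError, match="resample"):
            delta_r1(pre, shifted)

    def test_plaque_delta_r1_matches_forward_relation(self, plaque_truth, delays, tr):
        """Noiseless phantom with plaque C_Gd = 0.1 mmol/L and r1 = 18 must
        return ΔR1 = 1.8 s^-1 in the plaque ROI."""
        pre, post = self._map_pair(plaque_truth, delays, tr)
        dmap = delta_r1(pre, post)
        roi = ROISet(plaque_truth.plaque_mask(), plaque_truth.grid)
        assert roi_mean_delta_r1(dmap, roi) == pytest.approx(1.8, rel=0.01)

    def test_null_compartment_stays_null(self, plaque_truth, delays, tr):
        pre, post = self._map_pair(plaque_truth, delays, tr, noise=0.005)
        dmap = delta_r1(pre, post)
        wall = (plaque_truth.labels == 2) & dmap.mask
        vals = dmap.delta_r1[wall]
        # the wall received no agent: its mean ΔR1 is zero within noise
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(vals.size)

    def test_uniform_roi_mean(self, plaque_truth):
        from plaquer1.relaxometry import DeltaR1Map

        shape = plaque_truth.grid.shape
        dmap = DeltaR1Map(
            delta_r1=np.full(shape, 2.0),
            mask=np.ones(shape, dtype=bool),
            grid=plaque_truth.grid,
        )
        roi = ROISet(plaque_truth.plaque_mask(), plaque_truth.grid)
        assert roi_mean_delta_r1(dmap, roi) == pytest.approx(2.0)

    def test_empty_roi_raises(self, plaque_truth):
        from plaquer1.relaxometry import DeltaR1Map

        shape = plaque_truth.grid.shape
        dmap = DeltaR1Map(
            delta_r1=np.zeros(shape), mask=np.ones(shape, dtype=bool), grid=plaque_truth.grid
        )
        roi = ROISet(np.zeros(shape, dtype=bool), plaque_truth.grid)
        with pytest.raises(ValueError, match="empty ROI"):
            roi_mean_delta_r1(dmap, roi)
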