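"""Preprocessing operators against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import gliomaconn as gc
from gliomaconn.preprocess_qc import CONFOUND_COLUMNS

from conftest import make_run


class TestDropInitialVolumes:
    def test_acquisition_trim(self, rng):
        run = make_run(rng.standard_normal((4, 4, 2, 500)))
        assert gc.drop_initial_volumes(run, 5).n_volumes == 495

    def test_zero_is_identity(self, rng):
        run = make_run(rng.standard_normal((3, 3, 2, 10)))
        assert np.array_equal(gc.drop_initial_volumes(run, 0).data, run.data)

    def test_dropping_too_many_fails(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 4)))
        with pytest.raises(ValueError):
            gc.drop_initial_volumes(run, 5)


class TestFramewiseDisplacement:
    def test_still_head_gives_zero(self):
        fd = gc.framewise_displacement(np.zeros((20, 6)))
        assert fd.shape == (19,) and np.all(fd == 0)

    def test_single_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.1  # +0.1 mm in x from frame 5 on
        fd = gc.framewise_displacement(motion)
        expected = np.zeros(9)
        expected[4] = 0.1
        assert np.allclose(fd, expected)

    def test_matches_direct_formula(self, rng):
        motion = rng.normal(0, 0.05, (50, 6))
        fd = gc.framewise_displacement(motion, radius_mm=50)
        oracle = np.array([
            sum(abs(motion[t, j] - motion[t - 1, j]) for j in range(3))
            + 50 * sum(abs(motion[t, j] - motion[t - 1, j]) for j in range(3, 6))
            for t in range(1, 50)
        ])
        assert np.allclose(fd, oracle, atol=1e-12)

    def test_time_reversed_series_is_reversed(self, rng):
        motion = rng.normal(0, 0.05, (30, 6))
        assert np.allclose(gc.framewise_displacement(motion[::-1])[::-1],
                           gc.framewise_displacement(motion))

    def test_wrong_columns_rejected(self):
        with pytest.raises(ValueError):
            gc.framewise_displacement(np.zeros((10, 5)))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (8, 6),
                      elements=st.floats(-1.0, 1.0, allow_nan=False)))
    def test_nonnegative_and_translation_offset_invariant(self, motion):
        fd = gc.framewise_displacement(motion)
        assert (fd >= 0).all()
        shifted = motion + np.array([5.0, -3.0, 2.0, 0.0, 0.0, 0.0])
        assert np.allclose(gc.framewise_displacement(shifted), fd, atol=1e-9)


class TestDvars:
    def test_static_run_is_zero(self):
        run = make_run(np.ones((3, 3, 2, 10)) * 7.0)
        assert np.all(gc.dvars(run, np.ones((3, 3, 2), bool)) == 0)

    def test_single_voxel_step_closed_form(self):
        data = np.zeros((4, 4, 2, 10))
        data[0, 0, 0, 5:] = 3.0
        run = make_run(data)
        mask = np.ones((4, 4, 2), bool)
        dv = gc.dvars(run, mask)
        expected = np.zeros(9)
        expected[4] = 3.0 / np.sqrt(mask.sum())
        assert np.allclose(dv, expected)

    def test_matches_voxel_loop_oracle(self, rng):
        data = rng.standard_normal((3, 4, 2, 12))
        mask = rng.random((3, 4, 2)) > 0.3
        run = make_run(data)
        dv = gc.dvars(run, mask)
        vox = [data[i, j, k] for i, j, k in np.argwhere(mask)]
        oracle = [np.sqrt(np.mean([(v[t] - v[t - 1]) ** 2 for v in vox]))
                  for t in range(1, 12)]
        assert np.allclose(dv, oracle, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 5)))
        with pytest.raises(ValueError):
            gc.dvars(run, np.zeros((2, 2, 2), bool))


class TestQcGate:
    def test_double_breach_excludes(self):
        assert gc.qc_gate(0.25, 25.0).excluded

    def test_clean_subject_included(self):
        assert not gc.qc_gate(0.0, 0.0).excluded

    def test_single_breach_warns_but_includes(self):
        with pytest.warns(UserWarning, match="single-threshold"):
            decision = gc.qc_gate(0.25, 10.0)
        assert not decision.excluded

    def test_or_rule_excludes_single_breach(self):
        assert gc.qc_gate(0.25, 10.0, rule="or").excluded


class TestRegressNuisance:
    def _confounds(self, rng, t):
        return pd.DataFrame(rng.standard_normal((t, 8)), columns=list(CONFOUND_COLUMNS))

    def test_confound_signal_fully_removed(self, rng):
        conf = self._confounds(rng, 50)
        data = np.tile(conf["wm"].to_numpy(), (2, 2, 2, 1))
        out = gc.regress_nuisance(make_run(data), conf)
        assert np.abs(out.data).max() < 1e-8

    def test_orthogonal_signal_preserved_up_to_mean(self, rng):
        t = 64
        conf = pd.DataFrame(np.zeros((t, 8)), columns=list(CONFOUND_COLUMNS))
        sig = np.sin(2 * np.pi * np.arange(t) / 8) + 5.0
        data = np.tile(sig, (2, 2, 2, 1))
        out = gc.regress_nuisance(make_run(data), conf)
        assert np.allclose(out.data, data - 5.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        conf = self._confounds(rng, 40)
        data = rng.standard_normal((2, 3, 2, 40))
        out = gc.regress_nuisance(make_run(data), conf)
        X = np.column_stack([np.ones(40), conf.to_numpy()])
        for idx in np.ndindex(2, 3, 2):
            y = data[idx]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(out.data[idx], y - X @ beta, atol=1e-8)

    def test_rank_deficient_warns(self, rng):
        conf = self._confounds(rng, 30)
        conf["csf"] = conf["wm"]
        with pytest.warns(UserWarning, match="rank-deficient"):
            gc.regress_nuisance(make_run(rng.standard_normal((2, 2, 2, 30))), conf)


class TestBandpass:
    def _tone(self, freq, t=200, tr=1.6):
        return np.sin(2 * np.pi * freq * np.arange(t) * tr)

    def test_in_band_tone_preserved(self):
        # 0.05 Hz falls on a DFT bin at T=200, TR=1.6 (bin 16)
        data = np.tile(self._tone(0.05), (2, 2, 2, 1))
        out = gc.bandpass(make_run(data))
        assert np.abs(out.data - data).max() < 0.01 * np.abs(data).max()

    def test_out_of_band_tone_removed(self):
        data = np.tile(self._tone(0.2), (2, 2, 2, 1))
        out = gc.bandpass(make_run(data))
        assert np.abs(out.data).max() < 0.01 * np.abs(data).max()

    def test_dc_removed(self):
        data = np.full((2, 2, 2, 100), 42.0)
        out = gc.bandpass(make_run(data))
        assert np.abs(out.data).max() < 1e-10

    def test_band_above_nyquist_rejected(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 50)))
        with pytest.raises(ValueError, match="Nyquist"):
            gc.bandpass(run, 0.01, 0.4)  # Nyquist at TR 1.6 s is 0.3125 Hz


class TestSmooth:
    def test_tiny_kernel_is_identity(self, rng):
        run = make_run(rng.standard_normal((6, 6, 6, 3)))
        out = gc.smooth(run, fwhm_mm=1.0)  # below half a 3 mm voxel
        assert np.abs(out.data - run.data).max() < 1e-6

    def test_delta_response_has_requested_fwhm(self):
        data = np.zeros((41, 41, 41, 2))
        data[20, 20, 20, 0] = 1.0
        out = gc.smooth(make_run(data, voxel_mm=1.0), fwhm_mm=6.0)
        profile = out.data[:, 20, 20, 0]
        half = profile.max() / 2.0
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the half-max crossings
        lo, hi = above[0], above[-1]
        left = lo - 1 + (half - profile[lo - 1]) / (profile[lo] - profile[lo - 1])
        right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        assert (right - left) == pytest.approx(6.0, rel=0.05)

    def test_sum_conserved(self):
        data = np.zeros((21, 21, 21, 2))
        data[10, 10, 10, 0] = 1.0
        out = gc.smooth(make_run(data, voxel_mm=1.0), fwhm_mm=4.0)
        assert out.data[..., 0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            gc.smooth(make_run(rng.standard_normal((4, 4, 4, 2))), fwhm_mm=0.0)


class TestTsnr:
    def test_hand_computed_vector(self):
        assert gc.tsnr([2, 4, 4, 4, 5, 5, 7, 9]) == pytest.approx(5.0 / 2.138, abs=1e-3)

    def test_noisy_baseline(self, rng):
        series = 100.0 + rng.normal(0, 10.0, 495)
        assert gc.tsnr(series) == pytest.approx(10.0, rel=0.10)

    def test_zero_mean_series_near_zero(self, rng):
        series = rng.standard_normal(500)
        assert abs(gc.tsnr(series)) < 0.2

    def test_scale_invariance(self, rng):
        series = 50 + rng.standard_normal(100)
        assert gc.tsnr(series * 3.7) == pytest.approx(gc.tsnr(series), rel=1e-12)

    def test_constant_series_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="zero temporal SD"):
            assert gc.tsnr(np.full(10, 5.0)) == np.inf


class TestNetworkCount:
    def test_mask_inside_one_parcel(self, small_atlas):
        mask = small_atlas.labels == 1
        assert gc.count_intersected_networks(mask, small_atlas) >= 1
        single = np.zeros_like(mask)
        single[tuple(np.argwhere(mask)[0])] = True
        assert gc.count_intersected_networks(single, small_atlas) == 1

    def test_whole_brain_hits_all_networks(self, desk_atlas):
        assert gc.count_intersected_networks(desk_atlas.brain_mask, desk_atlas) == 7

    def test_networks_counted_distinctly(self, desk_atlas):
        # union of all parcels from exactly two networks
        parcels = [p for p, n in desk_atlas.network_of.items() if n in (1, 3)]
        mask = np.isin(desk_atlas.labels, parcels)
        assert gc.count_intersected_networks(mask, desk_atlas) == 2

    def test_empty_overlap_warns_zero(self, small_atlas):
        mask = np.zeros_like(small_atlas.labels, bool)
        mask[0, 0, 0] = True  # background corner
        with pytest.warns(UserWarning):
            assert gc.count_intersected_networks(mask, small_atlas) == 0


class TestPreprocessPipeline:
    def test_stage_order_and_qc(self, desk_atlas, rng):
        p = gc.SimulationParams.desk_scale(n_volumes=80)
        subj = gc.simulate_subject(desk_atlas, p, 3)
        brain = desk_atlas.brain_mask
        pre = gc.preprocess(subj.bold, subj.confounds, brain, n_drop=5)
        assert pre.trimmed.n_volumes == 75
        assert len(pre.confounds) == 75
        assert pre.qc.fd_series.shape == (74,)
        assert pre.qc.dvars_series.shape == (74,)
        assert not pre.qc.excluded
        assert np.isfinite(pre.filtered.data).all()
        # band-pass removed the baseline/DC
        assert abs(pre.filtered.data[brain].mean()) < 1e-6
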