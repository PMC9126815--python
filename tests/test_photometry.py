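"""ΔF/F, demultiplexing, PETH construction and z-score summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socialphys import (DffTrace, PhotometrySession, build_peth, compute_dff,
                        demultiplex, isosbestic_correct, peth_zscore_summary)
from socialphys.synth import (SyntheticSessionTruth, simulate_photometry,
                              transient_kernel)


def _session(fluor, led, rate=1000.0):
    t = np.arange(len(fluor)) / rate
    return PhotometrySession(t=t, fluor=np.asarray(fluor, float),
                             led_state=np.asarray(led), raw_rate=rate,
                             habituation_interval=(0.0, t[-1] / 2),
                             test_interval=(t[-1] / 2, t[-1]))


def _events(times, stimulus="social"):
    return pd.DataFrame({"stimulus": stimulus, "t_entry": times,
                         "t_exit": np.asarray(times) + 1.0, "included": True,
                         "reason": None})


class TestDemultiplex:
    def test_constant_channel_recovered_exactly(self):
        led = np.tile(["465"] * 10 + ["405"] * 10, 20)
        out = demultiplex(_session(np.full(led.size, 5.0), led))
        assert np.all(out["465"]["f"] == 5.0)
        assert np.all(out["405"]["f"] == 5.0)

    def test_channels_separate_without_crosstalk(self):
        led = np.tile(["465"] * 10 + ["405"] * 10, 20)
        fluor = np.where(led == "465", 7.0, 3.0)
        out = demultiplex(_session(fluor, led))
        assert np.all(out["465"]["f"] == 7.0)
        assert np.all(out["405"]["f"] == 3.0)

    def test_matches_pulse_mean_oracle(self):
        """Demuxed values equal direct per-pulse means after settling."""
        rng = np.random.default_rng(0)
        led = np.tile(["465"] * 10 + ["405"] * 10, 50)
        fluor = rng.normal(10, 1, led.size)
        out = demultiplex(_session(fluor, led), settle_discard=0.2)
        # brute-force oracle on the first 465 pulse: samples 2..9
        assert out["465"]["f"].iloc[0] == pytest.approx(fluor[2:10].mean())
        assert out["405"]["f"].iloc[0] == pytest.approx(fluor[12:20].mean())

    def test_off_samples_ignored(self):
        led = np.tile(["465"] * 8 + ["off"] * 4 + ["405"] * 8, 10)
        fluor = np.where(led == "off", 1e6, 2.0)
        out = demultiplex(_session(fluor, led))
        assert np.all(out["465"]["f"] == 2.0)
        assert np.all(out["405"]["f"] == 2.0)


class TestDff:
    def _trace(self, f):
        return pd.DataFrame({"t": np.arange(len(f)) / 10.0, "f": f})

    def test_f_equal_f0_gives_zero(self):
        dff = compute_dff(self._trace(np.full(100, 4.0)), f0_window=(0, 5))
        assert np.all(dff.dff == 0.0)

    def test_doubling_gives_one(self):
        f = np.concatenate([np.full(50, 3.0), np.full(50, 6.0)])
        dff = compute_dff(self._trace(f), f0_window=(0, 4.9))
        assert dff.dff[-1] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30)
    @given(gain=st.floats(0.01, 100.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(5)
        f = rng.uniform(5, 10, 200)
        base = compute_dff(self._trace(f), f0_window=(0, 10))
        scaled = compute_dff(self._trace(gain * f), f0_window=(0, 10))
        np.testing.assert_allclose(scaled.dff, base.dff, rtol=1e-9, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(self._trace(np.full(100, -1.0)), f0_window=(0, 5))


class TestIsosbesticCorrection:
    def test_identical_channels_give_zero(self):
        t = np.arange(200) / 10.0
        f = pd.DataFrame({"t": t, "f": 5 + np.sin(t)})
        out = isosbestic_correct(f, f.copy())
        np.testing.assert_allclose(out.dff, 0.0, atol=1e-12)
        assert out.correction_mode == "isosbestic"

    def test_shared_artifact_suppressed(self):
        truth = SyntheticSessionTruth(seed=0)
        sess = simulate_photometry(truth, 20.0, raw_rate=1000,
                                   motion_times=[12.0], motion_amplitude=20.0,
                                   motion_duration=2.0)
        ch = demultiplex(sess)
        raw = compute_dff(ch["465"], f0_window=(0, 10))
        corr = isosbestic_correct(ch["465"], ch["405"])
        # the channels sample the bump half a pulse apart, so suppression
        # is strong but not perfect
        assert np.max(np.abs(corr.dff)) < 0.05 * np.max(np.abs(raw.dff))

    def test_event_only_trace_unchanged_by_correction(self):
        truth = SyntheticSessionTruth(true_entry_times_social=[10.0],
                                      event_response_amplitude=0.1,
                                      noise_sd=0.002, seed=1)
        sess = simulate_photometry(truth, 30.0, raw_rate=1000)
        ch = demultiplex(sess)
        raw = compute_dff(ch["465"], f0_window=(0, 8))
        corr = isosbestic_correct(ch["465"], ch["405"])
        # no shared artifact: corrected peak ≈ uncorrected peak within noise
        assert corr.dff.max() == pytest.approx(raw.dff.max(), abs=0.02)


class TestPeth:
    def _flat_dff(self, value=0.0, duration=100.0, rate=20.0):
        t = np.arange(int(duration * rate)) / rate
        return DffTrace(t=t, dff=np.full(t.size, float(value)), f0=1.0)

    def test_zero_dff_gives_zero_bins(self):
        peth = build_peth(self._flat_dff(0.0), _events([30.0, 60.0]))
        assert np.all(peth.rows == 0.0)
        assert peth.n_events == 2

    def test_grid_contains_zero(self):
        peth = build_peth(self._flat_dff(), _events([50.0]), window=(-5, 10))
        assert 0.0 in peth.grid
        assert peth.grid[0] >= -5 - 1e-9 and peth.grid[-1] <= 10 + 1e-9

    def test_event_near_edge_dropped_and_logged(self):
        peth = build_peth(self._flat_dff(duration=100), _events([2.0, 50.0]),
                          window=(-5, 10))
        assert peth.n_events == 1
        assert len(peth.dropped) == 1

    def test_excluded_events_not_used(self):
        ev = _events([30.0, 60.0])
        ev.loc[1, "included"] = False
        peth = build_peth(self._flat_dff(), ev)
        assert peth.n_events == 1

    def test_no_usable_events_is_error(self):
        with pytest.raises(ValueError, match="no usable events"):
            build_peth(self._flat_dff(duration=8.0), _events([1.0]))

    def test_single_noiseless_transient_recovers_kernel(self):
        """A PETH row around a planted event equals the planted kernel."""
        truth = SyntheticSessionTruth(true_entry_times_social=[30.0],
                                      event_response_amplitude=0.1, seed=0)
        sess = simulate_photometry(truth, 60.0, raw_rate=2000)
        ch = demultiplex(sess)
        dff = compute_dff(ch["465"], f0_window=(0, 25))
        peth = build_peth(dff, _events([30.0]), window=(-5, 10))
        expected = 0.1 * transient_kernel(peth.grid, decay_tau=truth.decay_tau)
        # demultiplexing averages over 12.5 ms pulses, smoothing the sharp
        # onset: allow a few percent of the amplitude around t = 0
        np.testing.assert_allclose(peth.rows[0], expected, atol=5e-3)

    def test_mean_permutation_invariant(self):
        rng = np.random.default_rng(2)
        t = np.arange(4000) / 20.0
        dff = DffTrace(t=t, dff=rng.normal(0, 1, t.size), f0=1.0)
        times = rng.uniform(20, 180, 30)
        p1 = build_peth(dff, _events(times))
        p2 = build_peth(dff, _events(times[::-1]))
        np.testing.assert_allclose(np.sort(p1.rows, 0), np.sort(p2.rows, 0))
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-12)


class TestZscoreSummary:
    def _dff_and_peth(self, dff_values, event_times, rate=20.0):
        t = np.arange(len(dff_values)) / rate
        dff = DffTrace(t=t, dff=np.asarray(dff_values, float), f0=1.0)
        return dff, build_peth(dff, _events(event_times))

    def test_session_self_z_is_standard(self):
        """z-normalizing the session by its own µ, σ gives mean 0, SD 1."""
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 0.5, 10_000)
        z = (x - x.mean()) / x.std()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_peth_at_session_mean_gives_zero(self):
        dff, peth = self._dff_and_peth(np.full(4000, 0.7), [50.0, 100.0])
        # constant trace has zero variance: perturb one far-away sample
        dff.dff[0] = 0.7 + 1.0
        ws = peth_zscore_summary(peth, dff)
        mu = dff.dff.mean()
        assert ws.mean_z["social"] == pytest.approx((0.7 - mu) / dff.dff.std())

    def test_one_sigma_offset_gives_mean_z_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 8000)
        t = np.arange(x.size) / 20.0
        dff = DffTrace(t=t, dff=x, f0=1.0)
        mu, sd = x.mean(), x.std()
        peth_rows = np.full((3, 11), mu + sd)
        from socialphys.photometry import Peth
        peth = Peth(grid=np.linspace(0, 5, 11), rows=peth_rows,
                    event_ids=[0, 1, 2], stimuli=["social"] * 3)
        ws = peth_zscore_summary(peth, dff)
        assert ws.mean_z["social"] == pytest.approx(1.0)

    def test_zero_variance_is_error(self):
        dff, peth = self._dff_and_peth(np.full(4000, 0.5), [50.0])
        with pytest.raises(ValueError, match="variance"):
            peth_zscore_summary(peth, dff)

    def test_mean_z_reproducible_from_rows(self):
        rng = np.random.default_rng(6)
        dff, peth = self._dff_and_peth(rng.normal(0, 1, 6000),
                                       [60.0, 120.0, 180.0])
        ws = peth_zscore_summary(peth, dff)
        sel = (peth.grid >= 0) & (peth.grid <= 5)
        manual = (peth.rows[:, sel].mean(axis=1) - ws.mu) / ws.sigma
        assert ws.mean_z["social"] == pytest.approx(manual.mean())

    def test_null_events_mean_z_within_3se(self):
        """Random events on stationary noise: |mean z| < 3 SE (≥100 events)."""
        rng = np.random.default_rng(7)
        n = 40_000
        t = np.arange(n) / 20.0
        dff = DffTrace(t=t, dff=rng.normal(0, 1, n), f0=1.0)
        times = np.sort(rng.uniform(50, t[-1] - 50, 120))
        peth = build_peth(dff, _events(times))
        ws = peth_zscore_summary(peth, dff)
        se = ws.per_event["z"].std(ddof=1) / np.sqrt(len(ws.per_event))
        assert abs(ws.mean_z["social"]) < 3 * se
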