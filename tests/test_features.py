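import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ethogram as eg
from ethogram.features import (static_acceleration, pitch, dynamic_and_odba,
                               wbf, extended_metrics, candidate_columns)
from ethogram.io import AccelTrace, DataError

RATE = 25.0


def make_trace(z, x=None, y=None, depth=None):
    z = np.asarray(z, dtype=float)
    n = z.size
    x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    return AccelTrace("t", np.arange(n) / RATE, x, y, z, depth=depth)


class TestStatic:
    def test_constant_trace_identity(self):
        trace = make_trace(np.ones(250))
        s_x, s_y, s_z = static_acceleration(trace)
        np.testing.assert_allclose(s_x, 0.0)
        np.testing.assert_allclose(s_z, 1.0)

    def test_sine_averages_out(self):
        t = np.arange(500) / RATE
        trace = make_trace(np.sin(2 * np.pi * 8.0 * t))
        _, _, s_z = static_acceleration(trace)
        assert np.max(np.abs(s_z[50:-50])) < 0.05

    def test_subsample_window_rejected(self):
        trace = make_trace(np.ones(100))
        with pytest.raises(ValueError):
            static_acceleration(trace, window=0.01)

    def test_empty_trace_rejected(self):
        with pytest.raises(DataError):
            static_acceleration(make_trace(np.empty(0)))


class TestPitch:
    @pytest.mark.parametrize("sx,sy,sz,expected", [
        (0.0, 0.0, 1.0, 0.0),
        (1.0, 0.0, 0.0, 90.0),
        (1.0, 0.0, 1.0, 45.0),
        (-1.0, 0.0, 1.0, -45.0),
    ])
    def test_worked_values(self, sx, sy, sz, expected):
        assert pitch(sx, sy, sz) == pytest.approx(expected)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = pitch(0.3, 0.1, 0.9)
        assert pitch(0.3 * scale, 0.1 * scale, 0.9 * scale) == \
            pytest.approx(float(base))

    def test_zero_vector_is_missing(self):
        assert np.isnan(pitch(0.0, 0.0, 0.0))


class TestDynamic:
    def test_decomposition_exact(self):
        rng = np.random.default_rng(1)
        trace = make_trace(rng.normal(size=500), x=rng.normal(size=500),
                           y=rng.normal(size=500))
        statics = static_acceleration(trace)
        d = dynamic_and_odba(trace, statics)
        np.testing.assert_allclose(statics[0] + d["D_X"], trace.X)
        np.testing.assert_allclose(statics[2] + d["D_Z"], trace.Z)

    def test_odba_absolute_sum(self):
        # D = (0.1, -0.2, 0.3) -> ODBA = 0.6
        n = 250
        trace = make_trace(np.zeros(n))
        statics = (np.zeros(n), np.zeros(n), np.zeros(n))
        trace.X[:] = 0.1
        trace.Y[:] = -0.2
        trace.Z[:] = 0.3
        d = dynamic_and_odba(trace, statics)
        np.testing.assert_allclose(d["ODBA"], 0.6)

    def test_constant_trace_zero_odba_and_sd(self):
        trace = make_trace(np.full(250, 0.7))
        d = dynamic_and_odba(trace, static_acceleration(trace))
        np.testing.assert_allclose(d["ODBA"], 0.0, atol=1e-12)
        np.testing.assert_allclose(d["SD_ODBA"], 0.0, atol=1e-12)

    def test_sd_uses_population_denominator(self):
        # a full window of known values: SD must match ddof=0 exactly
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        ser = pd.Series(vals).rolling(4, center=True, min_periods=1).std(ddof=0)
        assert ser.iloc[2] == pytest.approx(np.std(vals, ddof=0))

    def test_gaussian_noise_sd_recovered(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 0.2, 25_000)
        trace = make_trace(z)
        d = dynamic_and_odba(trace, static_acceleration(trace))
        # moving-mean removal eats some variance in a 50-sample window
        assert d["SD_Z"][100:-100].mean() == pytest.approx(0.2, rel=0.05)


def dense_dft_peak(z, rate, pad=64):
    """Oracle: argmax of a heavily zero-padded DFT."""
    z = z - z.mean()
    spec = np.abs(np.fft.rfft(z, n=pad * z.size))
    freqs = np.fft.rfftfreq(pad * z.size, d=1.0 / rate)
    keep = freqs > 0.05
    return freqs[keep][np.argmax(spec[keep])]


class TestWbf:
    def test_exact_bin_sine(self):
        t = np.arange(500) / RATE
        z = np.sin(2 * np.pi * 8.0 * t)
        out = wbf(z, RATE, at=np.array([250]))
        assert out[0] == pytest.approx(8.0, abs=1e-6)

    def test_constant_signal_zero(self):
        out = wbf(np.ones(500), RATE, at=np.array([250]))
        assert out[0] == 0.0

    def test_offbin_sine_vs_dense_dft_oracle(self):
        t = np.arange(125) / RATE
        z = np.sin(2 * np.pi * 8.1 * t + 0.3)
        est = wbf(np.tile(z, 4), RATE, at=np.array([250]))[0]
        oracle = dense_dft_peak(z, RATE)
        assert est == pytest.approx(oracle, abs=0.05)
        assert est == pytest.approx(8.1, abs=0.05)

    @pytest.mark.parametrize("freq", np.arange(0.7, 12.0, 0.9))
    def test_sine_sweep_within_half_bin(self, freq):
        t = np.arange(1000) / RATE
        z = np.sin(2 * np.pi * freq * t + 1.1)
        est = wbf(z, RATE, at=np.array([500]))[0]
        assert abs(est - freq) < 0.1    # half of the 0.2 Hz bin width

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(DataError):
            wbf(np.ones(50), RATE)


class TestCalibration:
    def _flight_features(self, offset_deg, murre_config, seconds=600):
        from helpers import single_behavior_states
        from ethogram.simulate import default_params, simulate_accel
        params = default_params(murre_config)
        params.mounting_offset_range = 0.0
        states = single_behavior_states("flying", seconds)
        trace = simulate_accel(states, murre_config, params, seed=3)
        # impose a known mounting offset by rotating the static frame
        rad = np.radians(offset_deg)
        x, z = trace.X.copy(), trace.Z.copy()
        trace.X = x * np.cos(rad) + z * np.sin(rad)
        trace.Z = -x * np.sin(rad) + z * np.cos(rad)
        return eg.compute_features(trace, murre_config)

    def test_known_offset_recovered(self, murre_config):
        feats = self._flight_features(9.0, murre_config)
        cal = eg.calibrate_pitch(feats, murre_config)
        assert cal.attrs["pitch_offset"] == pytest.approx(9.0, abs=1.0)
        lo, hi = murre_config.flight_wbf_band
        flight = (cal["WBF"] >= lo) & (cal["WBF"] <= hi)
        assert abs(cal.loc[flight, "pitch"].mean()) < 1e-9

    def test_offset_definition(self, murre_config):
        feats = self._flight_features(12.0, murre_config)
        cal = eg.calibrate_pitch(feats, murre_config)
        np.testing.assert_allclose(cal["pitch"],
                                   feats["pitch"] - cal.attrs["pitch_offset"])

    def test_no_flight_warns_and_leaves_unchanged(self, murre_config):
        n = 300
        feats = pd.DataFrame({"t": np.arange(n, dtype=float),
                              "pitch": np.full(n, 30.0),
                              "WBF": np.zeros(n)})
        with pytest.warns(UserWarning):
            cal = eg.calibrate_pitch(feats, murre_config)
        np.testing.assert_array_equal(cal["pitch"], feats["pitch"])
        assert cal.attrs["pitch_offset"] == 0.0


class TestExtendedMetrics:
    def test_column_count(self, murre_config, kitti_config):
        assert len(candidate_columns(kitti_config)) == 42
        assert len(candidate_columns(murre_config)) == 43

    def test_ramp_trend_and_acf(self):
        t = np.arange(250) / RATE
        trace = make_trace(t)               # Z = t: slope 1 g/s
        ext = extended_metrics(trace)
        mid = len(ext) // 2
        assert ext["trend_Z"].iloc[mid] == pytest.approx(1.0, rel=1e-3)
        assert ext["acf_Z"].iloc[mid] > 0.95

    def test_symmetric_window_zero_skew(self):
        z = np.tile([1.0, -1.0], 125)
        ext = extended_metrics(make_trace(z))
        assert abs(ext["skew_Z"].iloc[len(ext) // 2]) < 1e-8

    def test_white_noise_acf_small(self):
        rng = np.random.default_rng(4)
        ext = extended_metrics(make_trace(rng.normal(size=2500)))
        mid = ext["acf_Z"].iloc[2:-2].to_numpy()
        assert np.mean(np.abs(mid) < 0.3) > 0.9

    def test_range_nonnegative_and_consistent(self):
        rng = np.random.default_rng(5)
        trace = make_trace(rng.normal(size=1000), x=rng.normal(size=1000))
        ext = extended_metrics(trace)
        for ax in "XYZ":
            r = ext[f"range_{ax}"].to_numpy()
            assert np.all(r >= 0)
            np.testing.assert_allclose(
                r, ext[f"max_{ax}"].to_numpy() - ext[f"min_{ax}"].to_numpy())

    def test_zero_variance_window_missing_values(self):
        ext = extended_metrics(make_trace(np.ones(250)))
        assert ext["skew_Z"].isna().all()
        assert ext["acf_Z"].isna().all()


class TestParameterRecovery:
    def test_behavior_means_recovered_on_simulator_output(self, murre_cohort,
                                                          murre_config):
        # pooled per-behavior feature means across a small cohort recover
        # the generator's class parameters within Monte-Carlo tolerance
        feats = pd.concat(
            [f.assign(true=t[:len(f)]) for f, t in
             zip(murre_cohort["features"].values(),
                 murre_cohort["truth"].values())], ignore_index=True)
        g = feats.groupby("true")
        assert g["pitch"].mean()["colony"] == pytest.approx(37.6, abs=4.0)
        assert g["pitch"].mean()["swimming"] == pytest.approx(-7.4, abs=2.5)
        assert g["SD_ODBA"].mean()["colony"] == pytest.approx(0.05, abs=0.015)
        assert g["SD_ODBA"].mean()["swimming"] == pytest.approx(0.28, abs=0.05)
        fly = feats[feats["true"] == "flying"]
        assert fly["WBF"].mean() == pytest.approx(8.1, abs=0.15)
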