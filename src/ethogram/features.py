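"""Accelerometer-derived movement metrics.

Static acceleration is a 2-s centered moving mean per axis (the gravity
component, encoding posture); the dynamic component is the residual.
Pitch is the vertical body angle from the static vector,
``atan(S_X / sqrt(S_Y^2 + S_Z^2))`` in degrees.  ODBA sums the absolute
dynamic components of the three axes; SD_Z and SD_ODBA are 2-s moving
standard deviations (population denominator ``N``).  The wing-beat
frequency (WBF) is the dominant frequency of the heave (Z) axis in a
5-s moving window, with sub-bin quadratic peak interpolation and a
noise floor below which windows report 0 Hz.

All moving windows are centered and truncated at the track edges.  The
full metric set is computed at the accelerometer rate and subsampled to
a 1-s grid, which is the resolution every classifier consumes.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .config import SpeciesConfig
from .io import AccelTrace, DataError

__all__ = [
    "static_acceleration", "pitch", "dynamic_and_odba", "wbf",
    "compute_features", "calibrate_pitch", "extended_metrics",
    "candidate_columns",
]

_WBF_NOISE_FLOOR = 3.0   # peak power must exceed this multiple of the median


def _window_samples(window: float, rate: float) -> int:
    n = int(round(window * rate))
    if n < 2:
        raise ValueError(
            f"window of {window} s spans fewer than two samples at {rate} Hz")
    return n


def _roll_mean(x: np.ndarray, n: int) -> np.ndarray:
    return pd.Series(x).rolling(n, center=True, min_periods=1).mean().to_numpy()


def _roll_std(x: np.ndarray, n: int) -> np.ndarray:
    # population denominator N, per the metric definition
    return pd.Series(x).rolling(n, center=True, min_periods=1).std(ddof=0).to_numpy()


def static_acceleration(trace: AccelTrace, window: float = 2.0):
    """Centered moving-mean gravity estimate per axis (S_X, S_Y, S_Z)."""
    if len(trace) == 0:
        raise DataError("empty trace")
    n = _window_samples(window, trace.sampling_rate)
    return (_roll_mean(trace.X, n), _roll_mean(trace.Y, n), _roll_mean(trace.Z, n))


def pitch(s_x, s_y, s_z) -> np.ndarray:
    """Vertical body angle in degrees, in [-90, 90].

    Undefined (NaN) where the static vector vanishes.  Invariant under
    overall scaling of the static vector.
    """
    s_x = np.asarray(s_x, dtype=float)
    s_y = np.asarray(s_y, dtype=float)
    s_z = np.asarray(s_z, dtype=float)
    norm = np.hypot(s_y, s_z)
    with np.errstate(invalid="ignore"):
        out = np.degrees(np.arctan2(s_x, norm))
    out = np.where((norm == 0) & (s_x == 0), np.nan, out)
    return out


def dynamic_and_odba(trace: AccelTrace, statics, window: float = 2.0) -> dict:
    """Dynamic components, ODBA and the 2-s moving activity SDs."""
    s_x, s_y, s_z = statics
    if any(s.shape != trace.t.shape for s in (s_x, s_y, s_z)):
        raise DataError("static series not on the trace grid")
    n = _window_samples(window, trace.sampling_rate)
    d_x = trace.X - s_x
    d_y = trace.Y - s_y
    d_z = trace.Z - s_z
    odba = np.abs(d_x) + np.abs(d_y) + np.abs(d_z)
    return {
        "D_X": d_x, "D_Y": d_y, "D_Z": d_z, "ODBA": odba,
        "SD_Z": _roll_std(d_z, n), "SD_ODBA": _roll_std(odba, n),
    }


def _dominant_freq_batch(windows: np.ndarray, rate: float,
                         noise_floor: float) -> np.ndarray:
    """Dominant frequency for each row of a (n_windows, width) array."""
    width = windows.shape[1]
    demeaned = windows - windows.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(demeaned, axis=1)) ** 2
    power = power[:, 1:]                         # DC excluded
    peak = np.argmax(power, axis=1)
    rows = np.arange(power.shape[0])
    peak_power = power[rows, peak]
    med = np.median(power, axis=1)
    freq = (peak + 1).astype(float)
    # quadratic (parabolic) sub-bin refinement where the peak has neighbors
    interior = (peak > 0) & (peak < power.shape[1] - 1)
    r = rows[interior]
    k = peak[interior]
    p_l, p_c, p_r = power[r, k - 1], power[r, k], power[r, k + 1]
    denom = p_l - 2 * p_c + p_r
    delta = np.where(np.abs(denom) > 0, 0.5 * (p_l - p_r) / denom, 0.0)
    freq[interior] += np.clip(delta, -0.5, 0.5)
    freq *= rate / width
    silent = (peak_power <= noise_floor * med) | (peak_power <= 1e-12)
    return np.where(silent, 0.0, freq)


def wbf(z: np.ndarray, rate: float, window: float = 5.0,
        at: Optional[np.ndarray] = None,
        noise_floor: float = _WBF_NOISE_FLOOR) -> np.ndarray:
    """Dominant heave-axis frequency (Hz) in a centered moving window.

    ``at`` selects the sample indices to evaluate (default: every
    sample).  Windows whose spectral peak does not rise above
    ``noise_floor`` times the window's median power report 0 Hz.
    """
    z = np.asarray(z, dtype=float)
    width = _window_samples(window, rate)
    if width > z.size:
        raise DataError("window exceeds trace length")
    if width < 8:
        raise ValueError("window too short for a meaningful spectrum")
    if at is None:
        at = np.arange(z.size)
    at = np.asarray(at, dtype=int)
    half = width // 2
    out = np.zeros(at.size)

    full = (at >= half) & (at + width - half <= z.size)
    if np.any(full):
        starts = at[full] - half
        idx = starts[:, None] + np.arange(width)[None, :]
        out[full] = _dominant_freq_batch(z[idx], rate, noise_floor)
    for j in np.nonzero(~full)[0]:
        lo = max(at[j] - half, 0)
        hi = min(at[j] - half + width, z.size)
        seg = z[lo:hi]
        if seg.size >= 8:
            out[j] = _dominant_freq_batch(seg[None, :], rate, noise_floor)[0]
    return out


def compute_features(trace: AccelTrace, config: SpeciesConfig,
                     extended: bool = False) -> pd.DataFrame:
    """Per-second feature frame for one deployment.

    Returns a DataFrame on the 1-s grid with the classification metrics
    (pitch, dynamic summaries, WBF, depth where available); with
    ``extended=True`` the full windowed statistic library is appended.
    """
    rate = trace.sampling_rate
    s_x, s_y, s_z = static_acceleration(trace)
    dyn = dynamic_and_odba(trace, (s_x, s_y, s_z))
    pit = pitch(s_x, s_y, s_z)

    t0 = trace.t[0]
    duration = trace.t[-1] - t0
    grid_t = t0 + np.arange(int(np.floor(duration)) + 1.0)
    gi = np.clip(np.round((grid_t - t0) * rate).astype(int), 0, len(trace) - 1)

    out = pd.DataFrame({
        "t": trace.t[gi],
        "S_X": s_x[gi], "S_Y": s_y[gi], "S_Z": s_z[gi],
        "pitch": pit[gi],
        "D_X": dyn["D_X"][gi], "D_Y": dyn["D_Y"][gi], "D_Z": dyn["D_Z"][gi],
        "ODBA": dyn["ODBA"][gi],
        "SD_Z": dyn["SD_Z"][gi], "SD_ODBA": dyn["SD_ODBA"][gi],
        "WBF": wbf(trace.Z, rate, at=gi),
    })
    if trace.depth is not None:
        out["depth"] = trace.depth[gi]
    if extended:
        ext = extended_metrics(trace, grid_index=gi)
        for col in ext.columns:
            if col not in out.columns:
                out[col] = ext[col].to_numpy()
    out.attrs["bird_id"] = trace.bird_id
    out.attrs["sampling_rate"] = rate
    return out


def calibrate_pitch(features: pd.DataFrame, config: SpeciesConfig,
                    min_flight: float = 60.0) -> pd.DataFrame:
    """Standardize pitch to 0 degrees during presumed flapping flight.

    Presumed flight is every timestamp whose WBF lies in the species
    flight band; the mean pitch over those timestamps (the mounting
    offset of the logger) is subtracted from the whole deployment.  With
    under ``min_flight`` seconds of presumed flight the frame is
    returned unchanged with a warning.
    """
    lo, hi = config.flight_wbf_band
    mask = (features["WBF"] >= lo) & (features["WBF"] <= hi)
    native = float(np.median(np.diff(features["t"]))) if len(features) > 1 else 1.0
    out = features.copy()
    if mask.sum() * native < min_flight:
        warnings.warn("under %.0f s of presumed flight; pitch left "
                      "uncalibrated" % min_flight)
        out.attrs["pitch_offset"] = 0.0
        return out
    offset = float(features.loc[mask, "pitch"].mean())
    out["pitch"] = features["pitch"] - offset
    out.attrs["pitch_offset"] = offset
    return out


def extended_metrics(trace: AccelTrace, window: float = 2.0,
                     freq_window: float = 5.0,
                     grid_index: Optional[np.ndarray] = None) -> pd.DataFrame:
    """The 42-metric windowed statistic library.

    Twelve statistics per axis (raw value, static, dynamic, windowed SD,
    min, max, range, skew, kurtosis, regression trend, lag-1
    autocorrelation, dominant frequency -- the heave-axis dominant
    frequency is the WBF), plus pitch, roll, ODBA, its windowed mean and
    SD (SD_ODBA) and range.  Depth is appended when the trace carries a
    depth channel, giving 43 candidates for divers.

    Statistics are computed over the 2-s window centered on each
    evaluation point (``grid_index``; default the 1-s grid), with the
    window clamped inside the track at the edges.  Skew and kurtosis
    are moment estimators (kurtosis reported as excess); zero-variance
    windows yield missing values for skew, kurtosis and autocorrelation.
    """
    rate = trace.sampling_rate
    if trace.duration < freq_window:
        raise DataError("trace shorter than the frequency window")
    width = _window_samples(window, rate)
    n = len(trace)
    if grid_index is None:
        t0 = trace.t[0]
        grid_t = t0 + np.arange(int(np.floor(trace.t[-1] - t0)) + 1.0)
        grid_index = np.clip(np.round((grid_t - t0) * rate).astype(int),
                             0, n - 1)
    gi = np.asarray(grid_index, dtype=int)
    starts = np.clip(gi - width // 2, 0, n - width)
    win = starts[:, None] + np.arange(width)[None, :]

    t_rel = np.arange(width) / rate
    tc = t_rel - t_rel.mean()
    tt = float(tc @ tc)

    cols: dict[str, np.ndarray] = {"t": trace.t[gi]}
    statics = {}
    for ax in ("X", "Y", "Z"):
        x = getattr(trace, ax)
        W = x[win]
        mean = W.mean(axis=1)
        C = W - mean[:, None]
        m2 = np.mean(C ** 2, axis=1)
        m3 = np.mean(C ** 3, axis=1)
        m4 = np.mean(C ** 4, axis=1)
        ok = m2 > 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            skew = np.where(ok, m3 / m2 ** 1.5, np.nan)
            kurt = np.where(ok, m4 / m2 ** 2 - 3.0, np.nan)
            a, b = C[:, 1:], C[:, :-1]
            am = a - a.mean(axis=1, keepdims=True)
            bm = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((am ** 2).sum(axis=1) * (bm ** 2).sum(axis=1))
            acf = np.where(denom > 1e-14,
                           (am * bm).sum(axis=1) / denom, np.nan)
        statics[ax] = mean
        cols[ax] = x[gi]
        cols[f"static_{ax}"] = mean
        cols[f"dyn_{ax}"] = x[gi] - mean
        cols[f"sd_{ax}"] = np.sqrt(m2)
        cols[f"min_{ax}"] = W.min(axis=1)
        cols[f"max_{ax}"] = W.max(axis=1)
        cols[f"range_{ax}"] = cols[f"max_{ax}"] - cols[f"min_{ax}"]
        cols[f"skew_{ax}"] = skew
        cols[f"kurt_{ax}"] = kurt
        cols[f"trend_{ax}"] = (C @ tc) / tt
        cols[f"acf_{ax}"] = np.clip(acf, -1.0, 1.0)
        name = "WBF" if ax == "Z" else f"f_{ax}"
        cols[name] = wbf(x, rate, freq_window, at=gi)

    # ODBA within each window: dynamic = deviation from the window mean
    O = np.zeros_like(trace.X[win])
    for ax in ("X", "Y", "Z"):
        W = getattr(trace, ax)[win]
        O += np.abs(W - W.mean(axis=1, keepdims=True))
    cols["pitch"] = pitch(statics["X"], statics["Y"], statics["Z"])
    cols["roll"] = np.degrees(np.arctan2(statics["Y"], statics["Z"]))
    mid = gi - starts
    cols["ODBA"] = O[np.arange(len(gi)), mid]
    cols["ODBA_mean"] = O.mean(axis=1)
    cols["SD_ODBA"] = O.std(axis=1)
    cols["ODBA_range"] = np.ptp(O, axis=1)
    if trace.depth is not None:
        cols["depth"] = trace.depth[gi]
    return pd.DataFrame(cols)


def candidate_columns(config: SpeciesConfig) -> list[str]:
    """Variable-selection candidate names (42; 43 with depth for divers)."""
    cols: list[str] = []
    for ax in ("X", "Y", "Z"):
        cols += [ax, f"static_{ax}", f"dyn_{ax}", f"sd_{ax}", f"min_{ax}",
                 f"max_{ax}", f"range_{ax}", f"skew_{ax}", f"kurt_{ax}",
                 f"trend_{ax}", f"acf_{ax}"]
        cols.append("WBF" if ax == "Z" else f"f_{ax}")
    cols += ["pitch", "roll", "ODBA", "ODBA_mean", "SD_ODBA", "ODBA_range"]
    if config.has_depth:
        cols.append("depth")
    return cols
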