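"""Histogram segregation: stepwise thresholds at density valleys.

The distribution of each metric is examined in turn and a break point
is placed at the density minimum between the two dominant modes; once a
behavior has been assigned those records leave the pool.  Murres:
diving by depth, flying by WBF, then segment-level activity and pitch
split swimming from colony.  Kittiwakes: flying by WBF, colony by low
SD_Z, then pitch assigns the remaining segments.  Thresholds are
per-track; pooled fallback thresholds cover tracks whose own
distribution shows no valley.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ..config import SpeciesConfig
from ..segmentation import first_pass, enforce_min_bout, build_segments, \
    expand_segment_labels
from .common import make_ethogram, _UPRIGHT_PITCH_DEG

__all__ = ["BreakpointError", "hs_breakpoints", "classify_hs",
           "pooled_hs_fallbacks"]


class BreakpointError(ValueError):
    """No interior density valley: the sample is effectively unimodal."""


_KDE_MAX_N = 20_000
_KDE_GRID = 512


def hs_breakpoints(values, n_classes: int = 2) -> float:
    """Break point between the two dominant modes of a 1-D sample.

    A Gaussian kernel density estimate (Silverman bandwidth) is scanned
    for local maxima; the threshold is the density minimum between the
    two highest peaks.  Raises :class:`BreakpointError` when the
    density has no interior valley.
    """
    if n_classes != 2:
        raise NotImplementedError("only two-class break points are used")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) <= 0:
        raise BreakpointError("sample has no spread")
    if x.size > _KDE_MAX_N:
        x = x[:: x.size // _KDE_MAX_N + 1]
    try:
        kde = gaussian_kde(x, bw_method="silverman")
    except np.linalg.LinAlgError as err:
        raise BreakpointError("degenerate sample") from err
    # extend past the data range so modes at the extremes are detected
    bw = float(kde.factor * x.std())
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, _KDE_GRID)
    dens = kde(grid)
    interior = np.nonzero((dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
    if interior.size < 2:
        raise BreakpointError("density is unimodal")
    top2 = interior[np.argsort(dens[interior])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def _flight_threshold(wbf_values: np.ndarray, config: SpeciesConfig) -> float:
    """WBF break point for flight, with the flight-band fallback.

    The valley must actually separate a flapping mode: if the values
    above the candidate threshold do not average inside or above the
    flight band, the lower band edge is used instead (e.g. a track with
    no flight at all).
    """
    band_lo = config.flight_wbf_band[0]
    try:
        thr = hs_breakpoints(wbf_values)
    except BreakpointError:
        return band_lo
    above = wbf_values[wbf_values > thr]
    if above.size == 0 or np.mean(above) < band_lo:
        return band_lo
    return thr


def pooled_hs_fallbacks(features_list, config: SpeciesConfig) -> dict:
    """Population-level activity/pitch break points for per-track fallback."""
    act = np.concatenate([f[config.activity_metric].to_numpy() for f in features_list])
    pit = np.concatenate([f["pitch"].to_numpy() for f in features_list])
    out = {}
    thr = _activity_threshold(act, None)
    if thr is not None:
        out["activity"] = thr
    thr = _pitch_threshold(pit, None)
    if thr is not None:
        out["pitch"] = thr
    return out


def classify_hs(features: pd.DataFrame, config: SpeciesConfig,
                fallback: Optional[dict] = None) -> pd.DataFrame:
    """Histogram-segregation ethogram for one track."""
    fallback = fallback or {}
    wbf_v = features["WBF"].to_numpy()
    thr_wbf = _flight_threshold(wbf_v, config)
    labels = first_pass(features, config, flight_mask=wbf_v > thr_wbf)
    labels = enforce_min_bout(labels)
    segments = build_segments(labels, features, config)

    unknown = segments[segments["behavior_hint"] == "unknown"]
    behavior = segments["behavior_hint"].to_numpy().copy()
    if len(unknown):
        if config.species == "murre":
            behavior[unknown.index] = _split_murre(unknown, fallback)
        else:
            behavior[unknown.index] = _split_kittiwake(unknown, fallback)
    segments = segments.assign(behavior=behavior)
    out = expand_segment_labels(segments, labels, len(features))
    return make_ethogram(features, out, "HS")


def _threshold_or(values: np.ndarray, fallback: Optional[float]):
    try:
        return hs_breakpoints(values)
    except BreakpointError:
        return fallback


def _activity_threshold(act: np.ndarray, fallback: Optional[float]):
    """Activity valley, accepted only if the two sides differ in kind.

    Activity classes are separated multiplicatively (quiet nest
    attendance versus active swimming), so a valley whose sides differ
    by less than a factor of two is an intra-class artifact.
    """
    thr = _threshold_or(act, None)
    if thr is not None:
        lo, hi = act[act <= thr], act[act > thr]
        if lo.size and hi.size and hi.mean() > 2.0 * max(lo.mean(), 1e-6):
            return thr
    return fallback


def _pitch_threshold(pit: np.ndarray, fallback: Optional[float]):
    """Pitch valley, accepted only if it separates upright from prone.

    A valley between two modes on the same side of the upright cutoff
    is within-class structure (e.g. different nest postures), not a
    colony/water boundary.
    """
    thr = _threshold_or(pit, None)
    if thr is not None:
        lo, hi = pit[pit <= thr], pit[pit > thr]
        if (lo.size and hi.size and lo.mean() < _UPRIGHT_PITCH_DEG
                and hi.mean() > _UPRIGHT_PITCH_DEG):
            return thr
    return fallback


def _split_murre(unknown: pd.DataFrame, fallback: dict) -> np.ndarray:
    """Swimming by high activity, then colony by high pitch."""
    act = unknown["mean_activity"].to_numpy()
    pit = unknown["mean_pitch"].to_numpy()
    out = np.full(len(unknown), "", dtype="<U8")
    thr_act = _activity_threshold(act, fallback.get("activity"))
    if thr_act is not None:
        out[act > thr_act] = "swimming"
    rest = out == ""
    thr_pitch = _pitch_threshold(pit[rest], fallback.get("pitch"))
    if thr_pitch is not None:
        out[rest & (pit > thr_pitch)] = "colony"
        out[rest & (pit <= thr_pitch)] = "swimming"
    else:
        out[rest] = np.where(pit[rest] > _UPRIGHT_PITCH_DEG, "colony", "swimming")
    return out


def _split_kittiwake(unknown: pd.DataFrame, fallback: dict) -> np.ndarray:
    """Colony by low activity, then swimming by low pitch."""
    act = unknown["mean_activity"].to_numpy()
    pit = unknown["mean_pitch"].to_numpy()
    out = np.full(len(unknown), "", dtype="<U8")
    thr_act = _activity_threshold(act, fallback.get("activity"))
    if thr_act is not None:
        out[act < thr_act] = "colony"
    rest = out == ""
    thr_pitch = _pitch_threshold(pit[rest], fallback.get("pitch"))
    if thr_pitch is not None:
        out[rest & (pit < thr_pitch)] = "swimming"
        out[rest & (pit >= thr_pitch)] = "colony"
    else:
        out[rest] = np.where(pit[rest] > _UPRIGHT_PITCH_DEG, "colony", "swimming")
    return out
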