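"""Track segmentation into bounded constant-behavior segments.

Classification of colony versus swimming operates on *segments* rather
than individual seconds: diving (murres) and flying are identified first
on the 1-s grid, runs shorter than 3 s are re-assigned to the preceding
behavior, and every maximal constant-label run is split into chunks of
at most 120 s.  The cap stops a missed transition from contaminating
more than two minutes of data and keeps long incubation bouts from
dominating the segment population.  Per-segment means of pitch, the
species activity metric, WBF and depth are the classification inputs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import SpeciesConfig
from .io import DataError

__all__ = ["first_pass", "enforce_min_bout", "build_segments",
           "runs_of", "expand_segment_labels"]


def runs_of(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal constant runs as (start, end, label) with half-open ends."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    return [(int(bounds[i]), int(bounds[i + 1]), str(labels[bounds[i]]))
            for i in range(len(bounds) - 1)]


def first_pass(features: pd.DataFrame, config: SpeciesConfig,
               flight_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-second {diving, flying, unknown} labels.

    Diving is every second with depth below the dive threshold (murres;
    depth must be present).  ``flight_mask`` carries the method-specific
    flight criterion (a histogram threshold for HS, a cluster assignment
    for KM/EM); diving takes precedence over flying.
    """
    n = len(features)
    labels = np.full(n, "unknown", dtype="<U8")
    if flight_mask is not None:
        labels[np.asarray(flight_mask, dtype=bool)] = "flying"
    if config.has_depth:
        if "depth" not in features.columns:
            raise DataError("depth channel required for a diving species")
        labels[features["depth"].to_numpy() < config.dive_depth_threshold] = "diving"
    return labels


def enforce_min_bout(labels: np.ndarray, min_bout: float = 3.0,
                     step: float = 1.0) -> np.ndarray:
    """Re-assign runs shorter than ``min_bout`` to the preceding behavior.

    A single left-to-right pass: each too-short run takes the label of
    the run before it (after that run's own possible re-assignment);
    leading short runs, which have no predecessor, absorb into the first
    following run that survives.
    """
    labels = np.asarray(labels).copy()
    min_len = int(np.ceil(min_bout / step))
    out = labels.copy()
    current: Optional[str] = None
    pending_start = 0   # start of the yet-unlabelled leading stretch
    for start, end, lab in runs_of(labels):
        if end - start >= min_len:
            if current is None:
                out[pending_start:start] = lab   # leading short runs
            current = lab
            out[start:end] = lab
        elif current is not None:
            out[start:end] = current
    # if no run reaches min_len at all, the labels are returned unchanged
    return out


def build_segments(labels: np.ndarray, features: pd.DataFrame,
                   config: SpeciesConfig, max_len: float = 120.0,
                   step: float = 1.0) -> pd.DataFrame:
    """Split constant-label runs into segments of at most ``max_len`` s.

    Runs are cut left to right with the remainder last, so only a track
    tail (or a clipped final chunk) may be shorter than the minimum
    bout.  Per-segment means of pitch, the species activity metric, WBF
    and depth are computed over the member seconds.  Segment bounds are
    half-open ``[start, end)`` row indices on the 1-s grid.
    """
    labels = np.asarray(labels)
    if labels.size != len(features):
        raise DataError("labels not aligned with the feature grid")
    cap = max(int(round(max_len / step)), 1)
    activity_col = config.activity_metric
    pitch_v = features["pitch"].to_numpy()
    act_v = features[activity_col].to_numpy()
    wbf_v = features["WBF"].to_numpy()
    depth_v = (features["depth"].to_numpy() if "depth" in features.columns
               else np.full(len(features), np.nan))

    rows = []
    seg_id = 0
    for start, end, lab in runs_of(labels):
        for s in range(start, end, cap):
            e = min(s + cap, end)
            rows.append({
                "segment_id": seg_id,
                "behavior_hint": lab,
                "start": s, "end": e,
                "mean_pitch": float(np.nanmean(pitch_v[s:e])),
                "mean_activity": float(np.nanmean(act_v[s:e])),
                "mean_WBF": float(np.nanmean(wbf_v[s:e])),
                "mean_depth": float(np.nanmean(depth_v[s:e]))
                if np.any(np.isfinite(depth_v[s:e])) else np.nan,
            })
            seg_id += 1
    out = pd.DataFrame(rows)
    out.attrs["bird_id"] = features.attrs.get("bird_id", "")
    return out


def expand_segment_labels(segments: pd.DataFrame, labels: np.ndarray,
                          n: int) -> np.ndarray:
    """Per-second behavior labels from per-segment assignments.

    ``segments`` must carry a ``behavior`` column; rows without one keep
    their ``behavior_hint``.
    """
    out = np.empty(n, dtype="<U8")
    col = "behavior" if "behavior" in segments.columns else "behavior_hint"
    for row in segments.itertuples(index=False):
        out[row.start:row.end] = getattr(row, col)
    return out
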