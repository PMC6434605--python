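"""Shared helpers for the classification methods."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SpeciesConfig

__all__ = ["make_ethogram", "classifier_feature_columns",
           "map_clusters_by_pitch", "apply_depth_override"]

# a segment population whose pitch shows no internal valley is assigned
# wholesale by posture: above this angle the bird is assumed upright at
# the nest, below it horizontal on the water
_UPRIGHT_PITCH_DEG = 15.0


def make_ethogram(features: pd.DataFrame, labels: np.ndarray,
                  method: str) -> pd.DataFrame:
    """Package per-second labels as an ethogram frame."""
    if len(labels) != len(features):
        raise ValueError("labels not aligned with feature grid")
    return pd.DataFrame({
        "bird_id": features.attrs.get("bird_id", ""),
        "t": features["t"].to_numpy(),
        "behavior": labels,
        "method": method,
    })


def classifier_feature_columns(config: SpeciesConfig) -> list[str]:
    """Default input variables for the supervised methods."""
    cols = ["pitch", config.activity_metric, "WBF"]
    if config.has_depth:
        cols.append("depth")
    return cols


def map_clusters_by_pitch(cluster_mean_pitch: np.ndarray,
                          cluster_mean_activity=None) -> np.ndarray:
    """Assign clusters to colony/swimming from their feature means.

    High pitch means an upright bird at the nest and low activity means
    quiet nest attendance, so clusters are scored by (scaled activity -
    scaled pitch): swimming clusters score high, colony clusters low.
    The sorted scores are split at their largest gap.  The mapping is a
    pure function of cluster statistics -- invariant to cluster index
    permutation and robust to either behavior being covered by more
    than one cluster.  Without activity means, pitch alone is scored.
    When the score gap is negligible (a single-behavior pool) each
    cluster falls back to the upright-posture rule on its mean pitch.
    """
    pitch = np.asarray(cluster_mean_pitch, dtype=float)
    posture = np.where(pitch > _UPRIGHT_PITCH_DEG, "colony", "swimming")
    if pitch.size == 1:
        return posture

    def scaled(v):
        rng = np.ptp(v)
        return (v - v.min()) / rng if rng > 1e-9 else np.zeros_like(v)

    # absolute-scale degeneracy guard: a pool drawn from one behavior has
    # neither a large postural spread nor a multiplicative activity
    # contrast, and must not be split by the (scale-free) gap rule
    if cluster_mean_activity is not None:
        act = np.asarray(cluster_mean_activity, dtype=float)
        ratio = act.max() / max(act.min(), 1e-6)
        if ratio < 2.0 and np.ptp(pitch) < 25.0:
            return posture
        score = scaled(act) - scaled(pitch)
    else:
        if np.ptp(pitch) < 10.0:
            return posture
        score = -scaled(pitch)
    order = np.argsort(score)
    gaps = np.diff(score[order])
    cut = int(np.argmax(gaps))
    if gaps[cut] < 0.15:       # no usable separation between behaviors
        return posture
    labels = np.empty(pitch.size, dtype="<U8")
    labels[order[:cut + 1]] = "colony"
    labels[order[cut + 1:]] = "swimming"
    return labels


def apply_depth_override(labels: np.ndarray, features: pd.DataFrame,
                         config: SpeciesConfig) -> np.ndarray:
    """Force the diving label wherever depth is below the dive threshold."""
    if config.has_depth and "depth" in features.columns:
        labels = labels.copy()
        labels[features["depth"].to_numpy() < config.dive_depth_threshold] = "diving"
    return labels
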