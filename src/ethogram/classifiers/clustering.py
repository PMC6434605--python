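"""Unsupervised two-step clustering methods (k-means and mixture EM).

Both methods share the structure used for the seabird data: dives are
taken straight from the depth rule (murres), a first clustering of the
per-second WBF pooled over all tracks separates flapping flight (the
cluster with the higher WBF), and a second clustering of the remaining
segments on [pitch, ln(activity)] -- both min-max scaled to their range
-- separates colony from swimming.  Three classes are used at the
second step (two colony plus one swimming); mixture EM instead selects
the class count in 3..6 by BIC.  Clusters map to behaviors through
their mean pitch, never their index.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from ..config import SpeciesConfig
from ..segmentation import first_pass, enforce_min_bout, build_segments, \
    expand_segment_labels
from .common import make_ethogram, map_clusters_by_pitch

__all__ = ["classify_km", "classify_em"]

_ACT_FLOOR = 1e-4   # g, floor before taking ln(activity)


def _pooled_wbf(features_map: Mapping[str, pd.DataFrame],
                config: SpeciesConfig):
    """Per-second WBF pooled over tracks, excluding diving seconds."""
    keys = sorted(features_map.keys())
    parts, masks = [], {}
    for bird in keys:
        f = features_map[bird]
        keep = np.ones(len(f), dtype=bool)
        if config.has_depth and "depth" in f.columns:
            keep = ~(f["depth"].to_numpy() < config.dive_depth_threshold)
        masks[bird] = keep
        parts.append(f["WBF"].to_numpy()[keep])
    return keys, np.concatenate(parts), masks


def _flight_from_clusters(values: np.ndarray, assign: np.ndarray,
                          centers: np.ndarray) -> np.ndarray:
    return assign == int(np.argmax(centers))


def _segment_step(features_map, config, flight_flags):
    """Min-bout smoothing and segmentation per track; returns segment pools."""
    seg_map, label_map = {}, {}
    for bird, f in features_map.items():
        labels = first_pass(f, config, flight_mask=flight_flags[bird])
        labels = enforce_min_bout(labels)
        seg_map[bird] = build_segments(labels, f, config)
        label_map[bird] = labels
    return seg_map, label_map


def _scale_unknown(segs: pd.DataFrame):
    pitch = segs["mean_pitch"].to_numpy(dtype=float)
    ln_act = np.log(np.maximum(segs["mean_activity"].to_numpy(dtype=float),
                               _ACT_FLOOR))
    X = np.column_stack([pitch, ln_act])
    lo = X.min(axis=0)
    rng = np.ptp(X, axis=0)
    span = np.where(rng > 0, rng, 1.0)
    return (X - lo) / span, pitch


def _finalize(features_map, seg_map, label_map, unknown_all, assign,
              cluster_behaviors, method):
    out = {}
    offset = 0
    for bird in sorted(features_map.keys()):
        segs = seg_map[bird]
        behavior = segs["behavior_hint"].to_numpy().copy()
        mask = behavior == "unknown"
        k = int(mask.sum())
        if k:
            behavior[mask] = cluster_behaviors[assign[offset:offset + k]]
            offset += k
        segs = segs.assign(behavior=behavior)
        labels = expand_segment_labels(segs, label_map[bird],
                                       len(features_map[bird]))
        out[bird] = make_ethogram(features_map[bird], labels, method)
    return out


def _run_two_step(features_map, config, step1, step2, method):
    keys, wbf_pool, masks = _pooled_wbf(features_map, config)
    flight_pool = step1(wbf_pool)
    flight_flags = {}
    offset = 0
    for bird in keys:
        keep = masks[bird]
        flags = np.zeros(keep.size, dtype=bool)
        flags[keep] = flight_pool[offset:offset + int(keep.sum())]
        offset += int(keep.sum())
        flight_flags[bird] = flags
    seg_map, label_map = _segment_step(features_map, config, flight_flags)

    unknown_all = pd.concat(
        [seg_map[bird][seg_map[bird]["behavior_hint"] == "unknown"]
         for bird in keys], ignore_index=True)
    if len(unknown_all) == 0:
        assign = np.zeros(0, dtype=int)
        cluster_behaviors = np.array(["colony"])
    else:
        X, pitch = _scale_unknown(unknown_all)
        act = unknown_all["mean_activity"].to_numpy(dtype=float)
        assign = step2(X)
        k = int(assign.max()) + 1
        p_means, a_means = [], []
        for c in range(k):
            sel = assign == c
            p_means.append(pitch[sel].mean() if np.any(sel) else -90.0)
            a_means.append(act[sel].mean() if np.any(sel) else 1e-6)
        cluster_behaviors = map_clusters_by_pitch(np.array(p_means),
                                                  np.array(a_means))
    return _finalize(features_map, seg_map, label_map, unknown_all, assign,
                     cluster_behaviors, method)


def classify_km(features_map: Mapping[str, pd.DataFrame],
                config: SpeciesConfig, seed=0) -> dict:
    """Two-step k-means ethograms for a pooled set of tracks."""
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))

    def step1(wbf_pool):
        km = KMeans(n_clusters=2, n_init=10, random_state=rs)
        assign = km.fit_predict(wbf_pool.reshape(-1, 1))
        return _flight_from_clusters(wbf_pool, assign,
                                     km.cluster_centers_.ravel())

    def step2(X):
        k = min(3, len(X))
        km = KMeans(n_clusters=k, n_init=10, random_state=rs)
        return km.fit_predict(X)

    return _run_two_step(features_map, config, step1, step2, "KM")


def classify_em(features_map: Mapping[str, pd.DataFrame],
                config: SpeciesConfig, seed=0, k_range=(3, 6),
                max_fit: int = 200_000) -> dict:
    """Two-step Gaussian-mixture ethograms; step-2 class count by BIC."""
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))

    def step1(wbf_pool):
        Xw = wbf_pool.reshape(-1, 1)
        fit_X = Xw if len(Xw) <= max_fit else Xw[:: len(Xw) // max_fit + 1]
        gm = GaussianMixture(n_components=2, random_state=rs, n_init=2)
        gm.fit(fit_X)
        assign = gm.predict(Xw)
        return _flight_from_clusters(wbf_pool, assign, gm.means_.ravel())

    def step2(X):
        best, best_bic = None, np.inf
        for k in range(k_range[0], k_range[1] + 1):
            if k >= len(X):
                break
            ok = False
            for attempt in range(5):
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     random_state=rs + attempt, n_init=1,
                                     reg_covar=1e-6)
                try:
                    gm.fit(X)
                    ok = gm.converged_ or True
                    break
                except ValueError:
                    continue
            if not ok:
                continue
            bic = gm.bic(X)
            if bic < best_bic:
                best, best_bic = gm, bic
        if best is None:   # degenerate pool: fall back to k-means labels
            km = KMeans(n_clusters=min(3, len(X)), n_init=10, random_state=rs)
            return km.fit_predict(X)
        return best.predict(X)

    return _run_two_step(features_map, config, step1, step2, "EM")
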