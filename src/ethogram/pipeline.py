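"""End-to-end drivers: simulate a cohort, classify it six ways, score.

These are the entry points the command line and the benchmark scripts
use.  A cohort is a set of simulated deployments (one per bird); the
driver computes calibrated features, runs every classification method,
builds GPS-rule reference labels and reports per-bird and pooled
accuracies.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SpeciesConfig
from .features import compute_features, calibrate_pitch
from .simulate import BehaviorParams, default_params, simulate_deployment
from .validation import (label_gps_murre, label_gps_kittiwake,
                         mark_transitions, score, forward_selection)
from .classifiers import (classify_hs, classify_nn, classify_rf, classify_km,
                          classify_em, classify_hmm, build_training_set,
                          pooled_hs_fallbacks, classifier_feature_columns)

__all__ = ["simulate_cohort", "prepare_features", "reference_labels",
           "run_all_methods", "benchmark", "selection_benchmark",
           "METHODS"]

METHODS = ("HS", "KM", "EM", "NN", "RF", "HMM")


def simulate_cohort(config: SpeciesConfig, n_birds: int, hours: float,
                    seed: int, params: Optional[BehaviorParams] = None) -> dict:
    """Simulate ``n_birds`` deployments with seeds ``seed .. seed+n-1``."""
    if params is None:
        params = default_params(config)
    out = {}
    for i in range(n_birds):
        states, trace, gps = simulate_deployment(config, hours, seed + i, params)
        out[trace.bird_id] = {"states": states, "trace": trace, "gps": gps}
    return out


def prepare_features(trace, config: SpeciesConfig,
                     extended: bool = False) -> pd.DataFrame:
    """Feature frame on the 1-s grid with flight-calibrated pitch."""
    feats = compute_features(trace, config, extended=extended)
    return calibrate_pitch(feats, config)


def reference_labels(gps, features: pd.DataFrame,
                     config: SpeciesConfig) -> pd.DataFrame:
    """GPS-rule labels with transition exclusions applied."""
    if config.species == "murre":
        ft = features["t"].to_numpy()
        idx = np.clip(np.searchsorted(ft, gps.t), 0, len(ft) - 1)
        depth_at_fix = features["depth"].to_numpy()[idx]
        labels = label_gps_murre(gps, depth_at_fix, nest=(0.0, 0.0),
                                 config=config)
    else:
        labels = label_gps_kittiwake(gps, config)
    return mark_transitions(labels, config.transition_window)


def expand_gps_labels(gps_labels: pd.DataFrame, features: pd.DataFrame,
                      config: SpeciesConfig) -> np.ndarray:
    """GPS-rule labels carried onto the 1-s feature grid.

    Each usable fix labels the seconds within half a fix interval of it
    (a fix is the only behavioral information available at that time).
    For divers the 1 Hz depth channel then resolves dive boundaries
    exactly: seconds below the dive threshold become diving, and
    seconds a diving fix covered that are actually at the surface
    become swimming.  Unlabeled seconds return the empty string.
    """
    t = features["t"].to_numpy()
    out = np.full(len(features), "", dtype="<U8")
    half = config.fix_interval / 2.0
    usable = gps_labels[gps_labels["behavior"] != "excluded"]
    for ft, beh in zip(usable["t"].to_numpy(),
                       usable["behavior"].to_numpy()):
        lo, hi = np.searchsorted(t, [ft - half, ft + half])
        out[lo:hi] = beh
    if config.has_depth and "depth" in features.columns:
        deep = features["depth"].to_numpy() < config.dive_depth_threshold
        out[deep & (out != "")] = "diving"
        out[~deep & (out == "diving")] = "swimming"
    return out


def run_all_methods(features_map: Mapping[str, pd.DataFrame],
                    config: SpeciesConfig, seed: int = 0,
                    methods: Sequence[str] = METHODS,
                    n_train_tracks: int = 10) -> dict:
    """Run the requested classification methods over a cohort.

    Returns ``{method: {bird: ethogram}}``.  The NN and RF methods are
    trained on histogram-segregation labels, so HS runs whenever either
    is requested.
    """
    methods = [m.upper() for m in methods]
    out: dict[str, dict] = {}
    need_hs = bool({"HS", "NN", "RF"} & set(methods))
    if need_hs:
        fallback = pooled_hs_fallbacks(list(features_map.values()), config)
        hs = {bird: classify_hs(f, config, fallback=fallback)
              for bird, f in features_map.items()}
        if "HS" in methods:
            out["HS"] = hs
    if {"NN", "RF"} & set(methods):
        cols = classifier_feature_columns(config)
        training = build_training_set(
            {b: e["behavior"].to_numpy() for b, e in hs.items()},
            features_map, cols,
            n_tracks=min(n_train_tracks, len(features_map)), seed=seed)
        if "NN" in methods:
            out["NN"] = classify_nn(training, features_map, config, seed=seed)
        if "RF" in methods:
            out["RF"] = classify_rf(training, features_map, config, seed=seed)
    if "KM" in methods:
        out["KM"] = classify_km(features_map, config, seed=seed)
    if "EM" in methods:
        out["EM"] = classify_em(features_map, config, seed=seed)
    if "HMM" in methods:
        out["HMM"] = classify_hmm(features_map, config)
    return {m: out[m] for m in methods if m in out}


def benchmark(config: SpeciesConfig, n_birds: int = 10, hours: float = 48.0,
              seed: int = 1, params: Optional[BehaviorParams] = None,
              methods: Sequence[str] = METHODS,
              extended: bool = False) -> dict:
    """Simulate a cohort, classify it with every method and score it.

    Returns a dict with an ``accuracies`` frame (method, bird, overall
    accuracy), summary statistics, the reference labels, and -- with
    ``extended=True`` -- fix-resolution extended metrics and labels
    ready for variable selection.
    """
    from .features import extended_metrics
    if params is None:
        params = default_params(config)
    features_map, gps_ref, truth = {}, {}, {}
    sel_metrics, sel_labels = {}, {}
    for i in range(n_birds):
        # one bird at a time so only one 25 Hz trace is alive at once
        states, trace, gps = simulate_deployment(config, hours, seed + i,
                                                 params)
        bird = trace.bird_id
        feats = prepare_features(trace, config)
        features_map[bird] = feats
        gps_ref[bird] = reference_labels(gps, feats, config)
        truth[bird] = states.states
        if extended:
            sec_labels = expand_gps_labels(gps_ref[bird], feats, config)
            keep = np.nonzero(sec_labels != "")[0]
            rate = config.sampling_rate
            idx = np.clip(np.round(feats["t"].to_numpy()[keep] * rate)
                          .astype(int), 0, len(trace) - 1)
            ext = extended_metrics(trace, grid_index=idx)
            ext["pitch"] -= feats.attrs.get("pitch_offset", 0.0)
            sel_metrics[bird] = ext.reset_index(drop=True)
            sel_labels[bird] = sec_labels[keep]
        del trace

    ethograms = run_all_methods(features_map, config, seed=seed,
                                methods=methods)
    rows = []
    summaries = {}
    for method, per_bird in ethograms.items():
        for bird, eth in per_bird.items():
            s = score(eth, gps_ref[bird], config)
            summaries[(method, bird)] = s
            rows.append({"method": method, "bird": bird,
                         "accuracy": s.overall_accuracy})
    acc = pd.DataFrame(rows, columns=["method", "bird", "accuracy"])
    out = {
        "accuracies": acc,
        "mean_accuracy": float(acc["accuracy"].mean()),
        "min_accuracy": float(acc["accuracy"].min()),
        "summaries": summaries,
        "ethograms": ethograms,
        "features": features_map,
        "gps_labels": gps_ref,
        "true_states": truth,
    }
    if extended:
        out["selection_metrics"] = sel_metrics
        out["selection_labels"] = sel_labels
    return out


def selection_benchmark(config: SpeciesConfig, n_birds: int = 10,
                        hours: float = 48.0, seed: int = 1,
                        n_steps: int = 3, n_sim: int = 20,
                        bench: Optional[dict] = None) -> pd.DataFrame:
    """Forward variable selection on a simulated cohort.

    Reuses a :func:`benchmark` result run with ``extended=True`` when
    provided, otherwise simulates the cohort afresh.
    """
    if bench is None or "selection_metrics" not in bench:
        bench = benchmark(config, n_birds=n_birds, hours=hours, seed=seed,
                          methods=(), extended=True)
    return forward_selection(bench["selection_metrics"],
                             bench["selection_labels"], config,
                             n_steps=n_steps, n_sim=n_sim, seed=seed)
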