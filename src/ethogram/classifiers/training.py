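"""Training-set construction and the NN / RF supervised methods.

Both models are trained on labels produced by the histogram-segregation
method (no GPS information), from ten randomly chosen tracks with at
most 1,000 rows per behavior per track, and then predict every second
of every track.  The murre depth rule (below -1 m means diving) is
enforced on the predictions.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from ..config import SpeciesConfig
from .common import (make_ethogram, classifier_feature_columns,
                     apply_depth_override)

__all__ = ["build_training_set", "classify_nn", "classify_rf"]


def _labels_of(ethogram) -> np.ndarray:
    if isinstance(ethogram, pd.DataFrame):
        return ethogram["behavior"].to_numpy()
    return np.asarray(ethogram)


def build_training_set(ethograms: Mapping[str, object],
                       features: Mapping[str, pd.DataFrame],
                       feature_cols: Sequence[str],
                       n_tracks: int = 10, per_class: int = 1000,
                       seed=0) -> pd.DataFrame:
    """Sample a labeled training table from classified tracks.

    ``n_tracks`` tracks are chosen uniformly at random; within each
    track and behavior class up to ``per_class`` rows are sampled
    without replacement.  Returns a frame with the feature columns plus
    ``behavior`` and ``bird_id``; the chosen tracks and seed are kept in
    ``attrs`` for provenance.
    """
    birds = sorted(ethograms.keys())
    if len(birds) < n_tracks:
        raise ValueError(f"need at least {n_tracks} labeled tracks, "
                         f"got {len(birds)}")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(birds, size=n_tracks, replace=False))
    parts = []
    for bird in chosen:
        feats = features[bird]
        labels = _labels_of(ethograms[bird])
        finite = np.isfinite(feats[list(feature_cols)].to_numpy()).all(axis=1)
        for behavior in np.unique(labels):
            idx = np.nonzero((labels == behavior) & finite)[0]
            if idx.size > per_class:
                idx = rng.choice(idx, size=per_class, replace=False)
            part = feats.iloc[idx][list(feature_cols)].copy()
            part["behavior"] = behavior
            part["bird_id"] = bird
            part["row"] = idx
            parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out.attrs["tracks"] = chosen
    out.attrs["seed"] = seed
    out.attrs["feature_cols"] = list(feature_cols)
    return out


def _predict_tracks(model, scaler, feature_cols, features, config, method):
    single = isinstance(features, pd.DataFrame)
    items = {"": features} if single else features
    out = {}
    for bird, feats in items.items():
        X = feats[list(feature_cols)].to_numpy(dtype=float)
        X = np.nan_to_num(X, nan=0.0)
        if scaler is not None:
            mu, sd = scaler
            X = (X - mu) / sd
        labels = model.predict(X).astype("<U8")
        labels = apply_depth_override(labels, feats, config)
        out[bird] = make_ethogram(feats, labels, method)
    return out[""] if single else out


def classify_nn(training: pd.DataFrame, features, config: SpeciesConfig,
                seed=0, max_retries: int = 5):
    """Single-hidden-layer (5 node) neural network ethograms.

    Inputs are standardized by the training means and SDs.  On
    non-convergence the fit is retried with a fresh initialization, up
    to ``max_retries`` times.
    """
    feature_cols = training.attrs.get("feature_cols") or \
        classifier_feature_columns(config)
    X = training[list(feature_cols)].to_numpy(dtype=float)
    y = training["behavior"].to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    model = None
    for attempt in range(max_retries):
        cand = MLPClassifier(hidden_layer_sizes=(5,), activation="logistic",
                             max_iter=1000, random_state=(base + attempt) % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cand.fit(Xs, y)
        model = cand
        if cand.n_iter_ < cand.max_iter:
            break
    return _predict_tracks(model, (mu, sd), feature_cols, features, config, "NN")


def classify_rf(training: pd.DataFrame, features, config: SpeciesConfig,
                seed=0, n_estimators: int = 500):
    """Random-forest ethograms (500 trees, sqrt(p) features per split)."""
    feature_cols = training.attrs.get("feature_cols") or \
        classifier_feature_columns(config)
    X = training[list(feature_cols)].to_numpy(dtype=float)
    y = training["behavior"].to_numpy()
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    model = RandomForestClassifier(n_estimators=n_estimators,
                                   max_features="sqrt", random_state=rs,
                                   n_jobs=1)
    model.fit(X, y)
    return _predict_tracks(model, None, feature_cols, features, config, "RF")
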