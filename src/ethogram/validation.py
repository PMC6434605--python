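"""GPS-rule reference labels, accuracy scoring, energetics and
variable selection.

Concurrent GPS tracks provide an independent behavioral reference:
ground speed above the species flight threshold means flying, fixes at
the nest mean colony (murres), depth below -1 m means diving (murres),
and the remainder is swimming.  Fixes with implausible speeds, long
gaps (kittiwakes), near-island ambiguity (kittiwakes) or within a
window of a behavior change are excluded before scoring, because a GPS
fix interval cannot resolve the exact moment of a transition.

Accuracy is summarised by the confusion matrix: overall accuracy plus
one-vs-rest balanced accuracy per behavior.  Activity budgets convert
an ethogram to hours per behavior per day, and daily energy expenditure
is the linear combination of those hours with behavior-specific
metabolic coefficients (kJ/h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import SpeciesConfig
from .features import candidate_columns
from .io import GpsTrack, DataError, ground_speed


__all__ = [
    "label_gps_murre", "label_gps_kittiwake", "mark_transitions",
    "ConfusionSummary", "score", "pooled_score",
    "activity_budget", "daily_energy", "forward_selection",
]

EXCLUDED = "excluded"


def _base_frame(gps: GpsTrack) -> pd.DataFrame:
    return pd.DataFrame({
        "t": gps.t,
        "speed": ground_speed(gps),
        "behavior": np.full(len(gps), "swimming", dtype="<U8"),
        "exclusion_reason": np.full(len(gps), "none", dtype="<U12"),
    })


def label_gps_murre(gps: GpsTrack, depth_at_fix: np.ndarray,
                    nest: Sequence[float],
                    config: SpeciesConfig) -> pd.DataFrame:
    """Murre GPS reference labels.

    Precedence: speed-error exclusion, then diving (depth below -1 m),
    flying (speed above 2 m/s), colony (within 250 m of the nest),
    swimming.  All thresholds are strict inequalities.
    """
    if nest is None:
        raise ValueError("nest location is required for murre GPS labels")
    depth_at_fix = np.asarray(depth_at_fix, dtype=float)
    if depth_at_fix.shape != gps.t.shape:
        raise DataError("depth not synchronized to fix times")
    out = _base_frame(gps)
    dist = np.hypot(gps.x - nest[0], gps.y - nest[1])
    beh = out["behavior"].to_numpy()
    beh[dist < config.colony_radius] = "colony"
    beh[out["speed"].to_numpy() > config.gps_flight_speed] = "flying"
    beh[depth_at_fix < config.dive_depth_threshold] = "diving"
    err = out["speed"].to_numpy() > config.gps_speed_error_cutoff
    beh[err] = EXCLUDED
    out["behavior"] = beh
    reasons = out["exclusion_reason"].to_numpy()
    reasons[err] = "speed_error"
    out["exclusion_reason"] = reasons
    return out


def label_gps_kittiwake(gps: GpsTrack, config: SpeciesConfig,
                        island: Sequence[float] = (0.0, 0.0)) -> pd.DataFrame:
    """Kittiwake GPS reference labels.

    Precedence: speed-error or fix-gap exclusion, then near-island
    exclusion (fixes within the island buffer cannot distinguish
    loafing from swimming), then flying (speed above 3 m/s), swimming.
    """
    out = _base_frame(gps)
    beh = out["behavior"].to_numpy()
    reasons = out["exclusion_reason"].to_numpy()
    beh[out["speed"].to_numpy() > config.gps_flight_speed] = "flying"
    near = np.hypot(gps.x - island[0], gps.y - island[1]) < config.colony_radius
    beh[near] = EXCLUDED
    reasons[near] = "near_island"
    if config.gps_max_gap is not None:
        gap = np.zeros(len(gps), dtype=bool)
        gap[1:] = np.diff(gps.t) > config.gps_max_gap
        beh[gap] = EXCLUDED
        reasons[gap] = "gap"
    err = out["speed"].to_numpy() > config.gps_speed_error_cutoff
    beh[err] = EXCLUDED
    reasons[err] = "speed_error"
    out["behavior"] = beh
    out["exclusion_reason"] = reasons
    return out


def mark_transitions(labels: pd.DataFrame, window: float) -> pd.DataFrame:
    """Exclude fixes near a colony/flying/swimming behavior change.

    The change time is only known to fix resolution, so every usable
    fix within ``window`` seconds of the midpoint between two
    consecutive differently-labeled fixes is excluded.  Changes between
    diving and swimming are exempt (depth is sampled at 1 Hz, so dive
    boundaries are sharp).
    """
    out = labels.copy()
    beh = out["behavior"].to_numpy().copy()
    reasons = out["exclusion_reason"].to_numpy().copy()
    usable = beh != EXCLUDED
    t = out["t"].to_numpy()[usable]
    lab = beh[usable]
    mark = np.zeros(t.size, dtype=bool)
    for i in range(t.size - 1):
        a, b = lab[i], lab[i + 1]
        if a == b or {a, b} == {"diving", "swimming"}:
            continue
        mid = 0.5 * (t[i] + t[i + 1])
        mark |= np.abs(t - mid) <= window
    idx = np.nonzero(usable)[0][mark]
    beh[idx] = EXCLUDED
    reasons[idx] = "transition"
    out["behavior"] = beh
    out["exclusion_reason"] = reasons
    return out


@dataclass
class ConfusionSummary:
    """Confusion matrix plus overall and per-behavior balanced accuracy."""

    matrix: pd.DataFrame            # reference rows x predicted columns
    overall_accuracy: float
    balanced_accuracy: dict
    n_used: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
        }


def score(ethogram: pd.DataFrame, gps_labels: pd.DataFrame,
          config: SpeciesConfig) -> ConfusionSummary:
    """Score an ethogram against GPS reference labels at fix resolution.

    The per-second ethogram is subsampled to the fix grid (nearest
    second); excluded fixes are dropped.
    """
    used = gps_labels[gps_labels["behavior"] != EXCLUDED]
    n_excluded = len(gps_labels) - len(used)
    if len(used) == 0:
        raise DataError("no usable GPS fixes to score against")
    et = ethogram["t"].to_numpy()
    idx = np.clip(np.searchsorted(et, used["t"].to_numpy()), 0, len(et) - 1)
    left = np.clip(idx - 1, 0, len(et) - 1)
    take = np.where(np.abs(et[left] - used["t"].to_numpy())
                    < np.abs(et[idx] - used["t"].to_numpy()), left, idx)
    in_range = np.abs(et[take] - used["t"].to_numpy()) <= config.fix_interval
    ref = used["behavior"].to_numpy()[in_range]
    pred = ethogram["behavior"].to_numpy()[take[in_range]]
    if ref.size == 0:
        raise DataError("no overlapping coverage between ethogram and GPS")
    classes = sorted(set(ref) | set(pred))
    matrix = pd.crosstab(pd.Series(ref, name="reference"),
                         pd.Series(pred, name="predicted")) \
        .reindex(index=classes, columns=classes, fill_value=0)
    overall = float(np.trace(matrix.to_numpy()) / matrix.to_numpy().sum())
    balanced = {}
    for c in sorted(set(ref)):
        tp = np.sum((ref == c) & (pred == c))
        fn = np.sum((ref == c) & (pred != c))
        tn = np.sum((ref != c) & (pred != c))
        fp = np.sum((ref != c) & (pred == c))
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        balanced[c] = float(0.5 * (sens + spec))
    return ConfusionSummary(matrix=matrix, overall_accuracy=overall,
                            balanced_accuracy=balanced,
                            n_used=int(ref.size), n_excluded=int(n_excluded))


def pooled_score(ethograms: Mapping[str, pd.DataFrame],
                 gps_labels: Mapping[str, pd.DataFrame],
                 config: SpeciesConfig) -> dict:
    """Per-bird summaries plus a pooled confusion summary."""
    per_bird = {b: score(ethograms[b], gps_labels[b], config)
                for b in sorted(ethograms.keys())}
    mats = [s.matrix for s in per_bird.values()]
    classes = sorted({c for m in mats for c in m.index}
                     | {c for m in mats for c in m.columns})
    total = sum(m.reindex(index=classes, columns=classes, fill_value=0)
                for m in mats)
    arr = total.to_numpy()
    pooled = float(np.trace(arr) / arr.sum())
    return {"per_bird": per_bird, "pooled_matrix": total,
            "pooled_accuracy": pooled}


def activity_budget(ethogram: pd.DataFrame,
                    step: float = 1.0) -> pd.DataFrame:
    """Hours per behavior per bird-day (day = successive 24 h block)."""
    day = (ethogram["t"].to_numpy() // 86400).astype(int)
    tab = pd.crosstab(day, ethogram["behavior"]) * step / 3600.0
    tab.index.name = "day"
    return tab


def daily_energy(budget, config: SpeciesConfig):
    """Daily energy expenditure (kJ/day) from an activity budget.

    ``budget`` maps behaviors to hours (or is a budget DataFrame, one
    row per day).  Hours for a behavior the species cannot perform are
    an error.
    """
    coeff = config.dee_coefficients
    if isinstance(budget, pd.DataFrame):
        unknown = [c for c in budget.columns if c not in coeff]
        if any(budget[c].to_numpy().sum() > 0 for c in unknown):
            raise ValueError(f"behavior(s) {unknown} have no DEE coefficient "
                             f"for {config.species}")
        out = sum(coeff[c] * budget[c] for c in budget.columns if c in coeff)
        return out.rename("DEE_kJ")
    total = 0.0
    for behavior, hours in dict(budget).items():
        if hours < 0:
            raise ValueError("negative hours in activity budget")
        if behavior not in coeff:
            if hours > 0:
                raise ValueError(f"behavior {behavior!r} has no DEE "
                                 f"coefficient for {config.species}")
            continue
        total += coeff[behavior] * hours
    return float(total)


def forward_selection(metrics_map: Mapping[str, pd.DataFrame],
                      labels_map: Mapping[str, np.ndarray],
                      config: SpeciesConfig,
                      n_steps: int = 10, n_sim: int = 100, seed=0,
                      top_k: int = 20, n_tracks: int = 10,
                      per_class: int = 1000, select_trees: int = 10,
                      global_trees: int = 200,
                      max_eval: int = 10_000) -> pd.DataFrame:
    """Forward variable selection with random-forest accuracy.

    A global forest on every candidate variable ranks importance and
    keeps the ``top_k`` candidates.  At each step, ``n_sim`` training
    sets are resampled (shared across the step's candidates, making the
    comparison paired); for every candidate a forest is fitted on the
    already-chosen variables plus the candidate and evaluated on the
    rows not sampled into that simulation's training set.  The variable
    with the highest median held-out accuracy is added.  Training sets
    follow the supervised-method recipe: ``n_tracks`` random tracks, up
    to ``per_class`` rows per behavior per track.  The evaluation
    forests use ``select_trees`` trees with a 64-leaf cap per tree --
    an accuracy estimate over one to a handful of variables does not
    need the full production ensemble, and uncapped trees grown on a
    single weakly-informative candidate can be enormous.

    Returns one row per step (chosen variable, median accuracy and
    2.5/97.5 percentiles); the global-model accuracy distribution is in
    ``attrs``.
    """
    rng = np.random.default_rng(seed)
    cand = [c for c in candidate_columns(config)
            if all(c in m.columns for m in metrics_map.values())]
    birds = sorted(metrics_map.keys())
    if len(birds) < min(n_tracks, 2):
        raise ValueError("too few labeled tracks for selection")
    n_tracks = min(n_tracks, len(birds))

    X = {b: metrics_map[b][cand].to_numpy(dtype=np.float32) for b in birds}
    y = {b: np.asarray(labels_map[b]) for b in birds}
    finite = {b: np.isfinite(X[b]).all(axis=1) for b in birds}
    class_rows = {
        b: {c: np.nonzero((y[b] == c) & finite[b])[0]
            for c in np.unique(y[b])}
        for b in birds}

    def draw_split():
        tracks = rng.choice(birds, size=n_tracks, replace=False)
        tr_parts, te_parts = [], []
        for b in tracks:
            taken = []
            for c, idx in class_rows[b].items():
                if idx.size > per_class:
                    taken.append(rng.choice(idx, size=per_class,
                                            replace=False))
                else:
                    taken.append(idx)
            taken = np.concatenate(taken)
            tr_parts.append((b, taken))
            mask = finite[b].copy()
            mask[taken] = False
            rest = np.flatnonzero(mask)
            cap = max(max_eval // n_tracks, 100)
            if rest.size > cap:
                rest = rng.choice(rest, size=cap, replace=False)
            te_parts.append((b, rest))
        Xtr = np.vstack([X[b][r] for b, r in tr_parts])
        ytr = np.concatenate([y[b][r] for b, r in tr_parts])
        Xte = np.vstack([X[b][r] for b, r in te_parts])
        yte = np.concatenate([y[b][r] for b, r in te_parts])
        return Xtr, ytr, Xte, yte

    def fit_acc(Xtr, ytr, Xte, yte, cols_idx, trees):
        m = RandomForestClassifier(n_estimators=trees, max_features="sqrt",
                                   max_leaf_nodes=64,
                                   random_state=int(rng.integers(2 ** 31)),
                                   n_jobs=1)
        m.fit(Xtr[:, cols_idx], ytr)
        return float(np.mean(m.predict(Xte[:, cols_idx]) == yte))

    # global model: importance prefilter + reference accuracy
    Xtr, ytr, Xte, yte = draw_split()
    rf = RandomForestClassifier(n_estimators=global_trees, max_features="sqrt",
                                max_leaf_nodes=512,
                                random_state=int(rng.integers(2 ** 31)),
                                n_jobs=1)
    rf.fit(Xtr, ytr)
    order = np.argsort(rf.feature_importances_)[::-1]
    candidates = [cand[i] for i in order[:top_k]]

    if n_steps > len(candidates):
        import warnings
        warnings.warn("n_steps exceeds candidate count; clipping")
        n_steps = len(candidates)

    all_idx = np.arange(len(cand))
    global_accs = []
    for _ in range(n_sim):
        global_accs.append(fit_acc(*draw_split(), all_idx, select_trees))

    chosen: list[str] = []
    rows = []
    for step in range(1, n_steps + 1):
        splits = [draw_split() for _ in range(n_sim)]
        results = {}
        for c in candidates:
            cols_idx = np.array([cand.index(v) for v in chosen + [c]])
            results[c] = np.array([fit_acc(*sp, cols_idx, select_trees)
                                   for sp in splits])
        best = max(results, key=lambda c: np.median(results[c]))
        accs = results[best]
        rows.append({
            "step": step, "chosen_variable": best,
            "median_accuracy": float(np.median(accs)),
            "q025": float(np.percentile(accs, 2.5)),
            "q975": float(np.percentile(accs, 97.5)),
        })
        chosen.append(best)
        candidates.remove(best)
    path = pd.DataFrame(rows)
    path.attrs["global_accuracy"] = np.array(global_accs)
    path.attrs["global_median"] = float(np.median(global_accs))
    path.attrs["global_q025"] = float(np.percentile(global_accs, 2.5))
    path.attrs["global_q975"] = float(np.percentile(global_accs, 97.5))
    path.attrs["chosen"] = chosen
    return path
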