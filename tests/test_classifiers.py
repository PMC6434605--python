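import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

import ethogram as eg
from ethogram.classifiers import (hs_breakpoints, BreakpointError, classify_hs,
                                  build_training_set, classify_nn, classify_rf,
                                  classify_km, classify_em, classify_hmm,
                                  HmmSpec, fit_hmm, map_clusters_by_pitch,
                                  classifier_feature_columns)
from ethogram.classifiers.hmm import bin_features, decode
from helpers import per_second_accuracy


class TestBreakpoints:
    def test_bimodal_threshold_matches_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.5, 0.2, 500), rng.normal(8, 0.3, 500)])
        thr = hs_breakpoints(x)
        assert 2 < thr < 6
        # oracle: exhaustive grid search of the KDE minimum between modes
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), 10_001)
        dens = kde(grid)
        inner = (grid > 2) & (grid < 6)
        oracle = grid[inner][np.argmin(dens[inner])]
        assert thr == pytest.approx(oracle, abs=0.1)

    def test_two_point_masses(self):
        x = np.concatenate([np.zeros(100), np.ones(100)])
        thr = hs_breakpoints(x)
        assert 0 < thr < 1

    def test_constant_sample_is_error(self):
        with pytest.raises(BreakpointError):
            hs_breakpoints(np.full(200, 3.0))


class TestClusterMapping:
    def test_mapping_depends_on_means_not_indices(self):
        means = np.array([37.0, -7.0, 30.0])
        labels = map_clusters_by_pitch(means)
        assert list(labels) == ["colony", "swimming", "colony"]
        # permuting cluster order permutes labels identically
        perm = [2, 0, 1]
        permuted = map_clusters_by_pitch(means[perm])
        assert list(permuted) == [labels[i] for i in perm]

    def test_split_survives_swimming_split_in_two(self):
        labels = map_clusters_by_pitch(np.array([-9.0, -5.0, 36.0]))
        assert list(labels) == ["swimming", "swimming", "colony"]


class TestHS:
    def test_recall_on_synthetic_murre(self, murre_cohort, murre_config):
        bird, feats = next(iter(murre_cohort["features"].items()))
        truth = murre_cohort["truth"][bird]
        eth = classify_hs(feats, murre_config)
        pred = eth["behavior"].to_numpy()
        for behavior in np.unique(truth):
            mask = truth == behavior
            recall = np.mean(pred[mask] == behavior)
            assert recall >= 0.95, (behavior, recall)

    def test_all_colony_track_has_no_flying(self, murre_config):
        from helpers import single_behavior_states
        from ethogram.simulate import simulate_accel, default_params
        params = default_params(murre_config)
        states = single_behavior_states("colony", 1800)
        trace = simulate_accel(states, murre_config, params, seed=2)
        feats = eg.compute_features(trace, murre_config)
        eth = classify_hs(feats, murre_config)
        assert "flying" not in set(eth["behavior"])
        assert (eth["behavior"] == "colony").mean() > 0.99

    def test_depth_dominates_all_other_features(self, murre_cohort,
                                                murre_config):
        bird, feats = next(iter(murre_cohort["features"].items()))
        eth = classify_hs(feats, murre_config)
        deep = feats["depth"].to_numpy() < -1
        assert np.all(eth["behavior"].to_numpy()[deep] == "diving")


@pytest.fixture(scope="module")
def separable_tracks(murre_config):
    """Ten synthetic tracks with well-separated class features."""
    rng = np.random.default_rng(7)
    features, labels = {}, {}
    spec = {
        "colony": dict(pitch=37.0, act=0.05, wbf=0.4, depth=0.0),
        "flying": dict(pitch=0.0, act=0.33, wbf=8.1, depth=0.0),
        "swimming": dict(pitch=-7.0, act=0.28, wbf=0.4, depth=0.0),
        "diving": dict(pitch=-5.0, act=0.2, wbf=0.3, depth=-15.0),
    }
    for b in range(10):
        rows = []
        for behavior, p in spec.items():
            n = 400 if behavior != "swimming" else 500
            rows.append(pd.DataFrame({
                "pitch": rng.normal(p["pitch"], 2.0, n),
                "SD_ODBA": np.maximum(rng.normal(p["act"], 0.02, n), 1e-3),
                "WBF": np.maximum(rng.normal(p["wbf"], 0.1, n), 0.0),
                "depth": p["depth"] + rng.normal(0, 0.05, n),
                "behavior": behavior,
            }))
        df = pd.concat(rows, ignore_index=True)
        df.insert(0, "t", np.arange(len(df), dtype=float))
        df.attrs["bird_id"] = f"t{b}"
        features[f"t{b}"] = df.drop(columns="behavior")
        features[f"t{b}"].attrs["bird_id"] = f"t{b}"
        labels[f"t{b}"] = df["behavior"].to_numpy()
    return features, labels


class TestTrainingSet:
    def test_row_counts_follow_sampling_rule(self, separable_tracks,
                                             murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        tr = build_training_set(labels, features, cols, n_tracks=10,
                                per_class=1000, seed=1)
        # every class has fewer than 1,000 rows per track: all are taken
        assert len(tr) == sum(len(v) for v in labels.values())
        tr2 = build_training_set(labels, features, cols, n_tracks=10,
                                 per_class=300, seed=1)
        assert len(tr2) == 10 * 4 * 300

    def test_min_rule_takes_all_available(self, separable_tracks, murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        tr = build_training_set(labels, features, cols, n_tracks=10,
                                per_class=450, seed=0)
        counts = tr.groupby(["bird_id", "behavior"]).size()
        assert counts.loc[("t0", "colony")] == 400      # all 400 taken
        assert counts.loc[("t0", "swimming")] == 450    # capped

    def test_deterministic_under_seed(self, separable_tracks, murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        a = build_training_set(labels, features, cols, seed=5)
        b = build_training_set(labels, features, cols, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_tracks_is_error(self, separable_tracks, murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        few = {k: labels[k] for k in list(labels)[:3]}
        with pytest.raises(ValueError):
            build_training_set(few, features, cols, n_tracks=10)


class TestSupervised:
    def test_nn_separable_accuracy(self, separable_tracks, murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        tr = build_training_set(labels, features, cols, seed=2)
        ethos = classify_nn(tr, features, murre_config, seed=2)
        accs = [np.mean(ethos[b]["behavior"].to_numpy() == labels[b])
                for b in features]
        assert np.mean(accs) >= 0.99

    def test_nn_constant_features_no_crash(self, murre_config):
        n = 200
        feats = pd.DataFrame({"t": np.arange(n, dtype=float),
                              "pitch": np.ones(n), "SD_ODBA": np.ones(n),
                              "WBF": np.ones(n), "depth": np.zeros(n)})
        tr = feats.iloc[:50].copy()
        tr["behavior"] = "colony"
        tr.attrs["feature_cols"] = ["pitch", "SD_ODBA", "WBF", "depth"]
        eth = classify_nn(tr, feats, murre_config, seed=0)
        assert set(eth["behavior"]) == {"colony"}

    def test_rf_separable_and_deterministic(self, separable_tracks,
                                            murre_config):
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        tr = build_training_set(labels, features, cols, seed=3)
        a = classify_rf(tr, features, murre_config, seed=3)
        b = classify_rf(tr, features, murre_config, seed=3)
        accs = [np.mean(a[x]["behavior"].to_numpy() == labels[x])
                for x in features]
        assert np.mean(accs) >= 0.99
        for x in features:
            np.testing.assert_array_equal(a[x]["behavior"], b[x]["behavior"])

    def test_rf_importance_ranks_wbf_or_depth_top2(self, separable_tracks,
                                                   murre_config):
        from sklearn.ensemble import RandomForestClassifier
        features, labels = separable_tracks
        cols = classifier_feature_columns(murre_config)
        tr = build_training_set(labels, features, cols, seed=4)
        rf = RandomForestClassifier(n_estimators=200, random_state=0)
        rf.fit(tr[cols].to_numpy(), tr["behavior"].to_numpy())
        top2 = [cols[i] for i in np.argsort(rf.feature_importances_)[-2:]]
        assert {"WBF", "depth"} & set(top2)


class TestUnsupervised:
    def test_km_wbf_step_labels_higher_cluster_flying(self, murre_config):
        rng = np.random.default_rng(5)
        n = 600
        feats = pd.DataFrame({
            "t": np.arange(n, dtype=float),
            "pitch": np.concatenate([rng.normal(37, 2, n // 2),
                                     rng.normal(0, 2, n // 2)]),
            "SD_ODBA": np.concatenate([rng.normal(0.05, 0.01, n // 2),
                                       rng.normal(0.3, 0.02, n // 2)]),
            "WBF": np.concatenate([rng.normal(0.3, 0.05, n // 2),
                                   rng.normal(8.1, 0.1, n // 2)]),
            "depth": np.zeros(n),
        })
        feats.attrs["bird_id"] = "x"
        ethos = classify_km({"x": feats}, murre_config, seed=0)
        pred = ethos["x"]["behavior"].to_numpy()
        assert np.all(pred[n // 2 + 5: n - 5] == "flying")
        assert "flying" not in set(pred[5:n // 2 - 5])

    def test_km_accuracy_on_cohort(self, murre_cohort, murre_config):
        ethos = classify_km(murre_cohort["features"], murre_config, seed=0)
        accs = [per_second_accuracy(ethos[b], murre_cohort["truth"][b])
                for b in ethos]
        assert np.mean(accs) >= 0.98

    def test_em_accuracy_on_cohort(self, kitti_cohort, kitti_config):
        ethos = classify_em(kitti_cohort["features"], kitti_config, seed=0)
        accs = [per_second_accuracy(ethos[b], kitti_cohort["truth"][b])
                for b in ethos]
        assert np.mean(accs) >= 0.89


class TestHMM:
    def test_forbidden_transitions_never_decoded(self, murre_cohort,
                                                 murre_config):
        ethos = classify_hmm(murre_cohort["features"], murre_config)
        forbidden = {("colony", "swimming"), ("swimming", "colony"),
                     ("colony", "diving"), ("diving", "colony"),
                     ("diving", "flying"), ("flying", "diving")}
        for eth in ethos.values():
            s = eth["behavior"].to_numpy()
            change = np.nonzero(s[1:] != s[:-1])[0]
            pairs = {(s[i], s[i + 1]) for i in change}
            assert pairs & forbidden == set()

    def test_accuracy_on_cohort(self, murre_cohort, murre_config):
        ethos = classify_hmm(murre_cohort["features"], murre_config)
        accs = [per_second_accuracy(ethos[b], murre_cohort["truth"][b])
                for b in ethos]
        assert np.mean(accs) >= 0.95

    def test_two_state_toy_viterbi_exact(self):
        spec = HmmSpec(
            states=["low", "high"],
            variables={"pitch": {"family": "normal",
                                 "mean": {"low": -20.0, "high": 30.0},
                                 "sd": {"low": 2.0, "high": 2.0}}},
            forbidden=[], state_map={"low": "low", "high": "high"},
            bin_s=1.0)
        truth = np.array(["low"] * 30 + ["high"] * 40 + ["low"] * 30)
        obs = pd.DataFrame({"pitch": np.where(truth == "low", -20.0, 30.0)})
        params = spec.param_arrays()
        A = spec.initial_transitions()
        pi0 = np.array([0.5, 0.5])
        path = decode(obs, params, A, pi0, spec)
        np.testing.assert_array_equal(path, truth)

    def test_emission_parameter_recovery(self):
        # sample a chain from known emissions and refit from the presets
        rng = np.random.default_rng(11)
        spec = HmmSpec(
            states=["a", "b"],
            variables={"pitch": {"family": "normal",
                                 "mean": {"a": 30.0, "b": -5.0},
                                 "sd": {"a": 8.0, "b": 4.0}}},
            forbidden=[], state_map={"a": "a", "b": "b"}, bin_s=1.0)
        T = 4000
        state = np.zeros(T, dtype=int)
        for t in range(1, T):
            stay = 0.98
            state[t] = state[t - 1] if rng.random() < stay \
                else 1 - state[t - 1]
        true_mean = np.array([30.0, -5.0])
        true_sd = np.array([8.0, 4.0])
        obs = pd.DataFrame({"pitch": rng.normal(true_mean[state],
                                                true_sd[state])})
        params, A, pi0, hist = fit_hmm([obs], spec, max_iter=20)
        got = np.sort(params["pitch"]["mean"])
        np.testing.assert_allclose(got, np.sort(true_mean), rtol=0.10)
        assert hist[-1] >= hist[0]

    def test_transition_rows_sum_to_one_and_zeros_stay(self, murre_cohort,
                                                       murre_config):
        spec = HmmSpec.preset(murre_config)
        obs = [bin_features(f, murre_config)
               for f in murre_cohort["features"].values()]
        params, A, pi0, _ = fit_hmm(obs, spec, max_iter=5)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-9)
        mask = spec.transition_mask()
        assert np.all(A[~mask] == 0.0)
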