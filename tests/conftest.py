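import numpy as np
import pandas as pd
import pytest

import ethogram as eg


@pytest.fixture(scope="session")
def murre_config():
    return eg.get_config("murre", "chick")


@pytest.fixture(scope="session")
def kitti_config():
    return eg.get_config("kittiwake", "chick")


@pytest.fixture(scope="session")
def murre_cohort(murre_config):
    """Small simulated murre cohort shared by classifier/validation tests."""
    cohort = eg.simulate_cohort(murre_config, n_birds=4, hours=4, seed=11)
    features = {b: eg.prepare_features(d["trace"], murre_config)
                for b, d in cohort.items()}
    truth = {b: d["states"].states for b, d in cohort.items()}
    gps = {b: d["gps"] for b, d in cohort.items()}
    return {"features": features, "truth": truth, "gps": gps,
            "states": {b: d["states"] for b, d in cohort.items()}}


@pytest.fixture(scope="session")
def kitti_cohort(kitti_config):
    cohort = eg.simulate_cohort(kitti_config, n_birds=3, hours=4, seed=21)
    features = {b: eg.prepare_features(d["trace"], kitti_config)
                for b, d in cohort.items()}
    truth = {b: d["states"].states for b, d in cohort.items()}
    gps = {b: d["gps"] for b, d in cohort.items()}
    return {"features": features, "truth": truth, "gps": gps}


def per_second_accuracy(ethogram: pd.DataFrame, truth: np.ndarray) -> float:
    pred = ethogram["behavior"].to_numpy()
    n = min(len(pred), len(truth))
    return float(np.mean(pred[:n] == truth[:n]))
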