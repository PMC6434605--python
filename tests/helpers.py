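"""Shared test utilities."""

import numpy as np
import pandas as pd

import ethogram as eg


def single_behavior_states(behavior, seconds, bout_len=90):
    """A StateSequence of one behavior, split into bouts."""
    rows, t = [], 0
    while t < seconds:
        end = min(t + bout_len, seconds)
        rows.append((behavior, t, end, np.nan))
        t = end
    table = pd.DataFrame(rows, columns=["behavior", "start", "end", "dive_depth"])
    states = np.full(seconds, behavior, dtype="<U8")
    return eg.StateSequence("unit", states, table)


def per_second_accuracy(ethogram, truth):
    pred = ethogram["behavior"].to_numpy()
    n = min(len(pred), len(truth))
    return float(np.mean(pred[:n] == truth[:n]))
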