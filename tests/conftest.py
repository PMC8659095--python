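import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from screenaudit.io_model import Benchmark, ScoreChannel, ScreenTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_screen_table(
    target_id="T0",
    pose_scores=None,
    labels=None,
    channel="score",
    extra_channels=None,
):
    """Build a small ScreenTable from {compound: [(receptor, score), ...]}."""
    pose_scores = pose_scores or {
        "a1": [("r0", 0.9), ("r0", 0.4)],
        "d1": [("r0", 0.3)],
        "d2": [("r0", 0.1), ("r0", 0.05)],
    }
    labels = labels or {"a1": "active", "d1": "inactive", "d2": "inactive"}
    rows = []
    for comp, poses in pose_scores.items():
        by_receptor = {}
        for rec, s in poses:
            by_receptor[rec] = by_receptor.get(rec, 0) + 1
            rows.append({"compound": comp, "receptor": rec,
                         "pose_rank": by_receptor[rec], channel: s})
    df = pd.DataFrame(rows)
    channels = [ScoreChannel(channel)]
    if extra_channels:
        for name, values in extra_channels.items():
            df[name] = values
            channels.append(ScoreChannel(name))
    return ScreenTable(target_id, df, labels, channels)


@pytest.fixture
def small_table():
    return make_screen_table()


@pytest.fixture
def score_csv(tmp_path):
    """A minimal on-disk score table: one target, one channel, three compounds."""
    path = tmp_path / "scores.csv"
    path.write_text(
        "target,compound,label,vina\n"
        "T0,c1,1,-9.1\n"
        "T0,c2,0,-7.2\n"
        "T0,c3,0,-8.0\n"
    )
    return path
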