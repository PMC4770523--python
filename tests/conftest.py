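import numpy as np
import pytest

from acpsim import preset


@pytest.fixture
def sim1_params():
    return preset("sim1")


@pytest.fixture
def sim2_params():
    return preset("sim2")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def brute_force_update(stage, score, delta, thresholds, baselines):
    """Independent reference for one point-award-then-evaluate cycle.

    Deliberately written as a direct transcription of the rules, separate from
    the implementation: clamp the score to [0, 100]; a raw sum below zero
    backslides one stage (never below the bottom) onto the destination
    baseline; otherwise advance while the score meets the next entry
    threshold, taking each destination baseline in turn.
    """
    thr = (thresholds.enter_contemplation, thresholds.enter_preparation, thresholds.enter_action)
    base = baselines.as_tuple()
    raw = score + delta
    if raw < 0:
        if stage > 0:
            return stage - 1, base[stage - 1]
        return 0, 0
    raw = min(raw, 100)
    s = stage
    while s < 3 and raw >= thr[s]:
        s += 1
        raw = base[s]
    return s, raw
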