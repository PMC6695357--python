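"""Shared fixtures: hand-built sessions and small synthetic cohorts."""

import numpy as np
import pytest

from pefmri.cohort import CohortConfig, make_schedule, simulate_behavior
from pefmri.qlearning import QParams, TrialRecord


def make_trial(i, valence="reward", choice=0, outcome=1.0, rt=0.8):
    """Trial on the canonical 6.5 s grid with feedback at cue + rt + 3."""
    return TrialRecord(
        index=i,
        valence=valence,
        cue_onset_s=i * 6.5,
        feedback_onset_s=i * 6.5 + rt + 3.0,
        choice=choice,
        outcome=outcome,
        rt_s=rt,
    )


@pytest.fixture
def six_trial_session():
    """Six reward trials whose likelihood/trace were worked out by hand.

    With alpha=0.5, beta=1 and zero-initialized values the stepwise table
    gives deltas [1, -0.5, 1, 0.75, -0.5, 0.375] and
    nll = -(ln .5 + ln .622459 + ln .437823 + ln .437823 + ln .468791
    + ln .592667) ~= 4.09983.
    """
    spec = [  # (choice, outcome)
        (0, 1.0),
        (0, 0.0),
        (1, 1.0),
        (0, 1.0),
        (1, 0.0),
        (0, 1.0),
    ]
    return [make_trial(i, choice=c, outcome=o) for i, (c, o) in enumerate(spec)]


@pytest.fixture
def six_trial_params():
    return QParams(alpha=0.5, beta=1.0)


@pytest.fixture
def session_120():
    """One 120-trial task session from a mid-range agent."""
    cfg = CohortConfig(n_per_group=2, seed=1)
    schedule = make_schedule(cfg, 42)
    return simulate_behavior(schedule, QParams(0.3, 4.0), 7)


@pytest.fixture
def tiny_config():
    """Desk-scale cohort: 4/group, 20 trials per valence, short runs."""
    return CohortConfig(
        n_per_group=4, trials_per_valence=20, n_volumes=200, seed=9
    )


def naive_replay(trials, alpha, beta):
    """Independent spreadsheet-style recursion: one value dict per stimulus
    pair, plain floats, explicit softmax. Returns (nll, deltas list).

    Deliberately un-vectorized so it shares no code with the package path.
    """
    import math

    q = {"reward": [0.0, 0.0], "punish": [0.0, 0.0], "neutral": [0.0, 0.0]}
    nll = 0.0
    deltas = []
    for t in trials:
        if t.choice is None:
            deltas.append(float("nan"))
            continue
        qs = q[t.valence]
        exps = [math.exp(beta * v) for v in qs]
        p_choice = exps[t.choice] / (exps[0] + exps[1])
        nll -= math.log(p_choice)
        delta = t.outcome - qs[t.choice]
        deltas.append(delta)
        qs[t.choice] += alpha * delta
    return nll, deltas


def random_session(rng, n_trials=60):
    """Random trials (not from any agent) for likelihood-oracle checks."""
    trials = []
    for i in range(n_trials):
        valence = rng.choice(["reward", "punish", "neutral"])
        outcome = {
            "reward": rng.choice([1.0, 0.0]),
            "punish": rng.choice([-1.0, 0.0]),
            "neutral": 0.0,
        }[valence]
        trials.append(
            make_trial(i, valence=valence, choice=int(rng.integers(2)), outcome=outcome)
        )
    return trials
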