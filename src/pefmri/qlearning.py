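"""Q-learning model of probabilistic two-choice learning.

Implements the delta-rule value update ``Q <- Q + alpha * (outcome - Q)``
with softmax (inverse-temperature ``beta``) choice, the session likelihood,
maximum-likelihood fitting, and extraction of trial-by-trial expected
values and signed reward prediction errors (PEs) — the quantities used
downstream as fMRI parametric modulators.

Each stimulus pair (reward / punish / neutral) carries its own pair of
action values; a single ``(alpha, beta)`` is shared across pairs within a
session. Values initialize at zero, outcomes are coded +1 (win), 0
(nothing), -1 (loss), so values and PEs are dimensionless and bounded in
[-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "VALENCES",
    "TrialRecord",
    "QParams",
    "LatentTrace",
    "FitResult",
    "q_update",
    "choice_prob",
    "session_nll",
    "fit_session",
    "pe_trace",
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
]

VALENCES = ("reward", "punish", "neutral")

#: Fit-time parameter bounds.
ALPHA_BOUNDS = (0.001, 0.999)
BETA_BOUNDS = (0.01, 20.0)


@dataclass(frozen=True)
class TrialRecord:
    """One task trial.

    ``choice`` and ``rt_s`` are ``None`` on missed-response trials; such
    trials contribute nothing to learning or likelihood.
    """

    index: int
    valence: str
    cue_onset_s: float
    feedback_onset_s: float
    choice: Optional[int]
    outcome: float
    rt_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.feedback_onset_s <= self.cue_onset_s:
            raise ValueError("feedback must follow the cue")
        if self.choice is not None and self.choice not in (0, 1):
            raise ValueError("choice must be 0, 1 or None")
        if self.outcome not in (-1.0, 0.0, 1.0):
            raise ValueError("outcome must be -1, 0 or +1")
        if self.rt_s is not None and not (0.0 < self.rt_s <= 2.0):
            raise ValueError("rt_s must lie in (0, 2] seconds")

    @property
    def responded(self) -> bool:
        return self.choice is not None


@dataclass(frozen=True)
class QParams:
    """Learning rate ``alpha`` in [0, 1] and inverse temperature ``beta`` >= 0."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")


@dataclass
class LatentTrace:
    """Per-trial latent variables implied by a parameter pair.

    ``q_values[t]`` are the two action values *before* trial ``t``'s update
    (the values that generated that trial's choice); ``chosen_value`` and
    ``delta`` are NaN on missed trials. ``pe_pos``/``pe_neg`` partition the
    responded reward-trial deltas by whether the reward was delivered
    (outcome +1) or omitted (outcome 0).
    """

    q_values: np.ndarray  # (n_trials, 2)
    chosen_value: np.ndarray  # (n_trials,)
    delta: np.ndarray  # (n_trials,)
    is_pe_pos: np.ndarray  # (n_trials,) bool: reward trial, responded, outcome +1
    is_pe_neg: np.ndarray  # (n_trials,) bool: reward trial, responded, outcome 0

    @property
    def pe_pos(self) -> np.ndarray:
        return self.delta[self.is_pe_pos]

    @property
    def pe_neg(self) -> np.ndarray:
        return self.delta[self.is_pe_neg]


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one subject-session."""

    params: QParams
    nll: float
    n_trials: int
    convergence_flag: bool


def q_update(
    q_pair: Sequence[float], choice: int, outcome: float, alpha: float
) -> tuple[np.ndarray, float]:
    """Delta-rule update of the chosen option's value.

    Returns the updated value pair and the signed prediction error
    ``delta = outcome - q_pair[choice]``. The unchosen value is untouched.
    """
    if choice not in (0, 1):
        raise ValueError("choice must be 0 or 1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    q = np.asarray(q_pair, dtype=float).copy()
    if q.shape != (2,):
        raise ValueError("q_pair must have exactly two entries")
    delta = float(outcome - q[choice])
    q[choice] += alpha * delta
    return q, delta


def choice_prob(q_pair: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities over a value pair at inverse temperature beta.

    ``beta = 0`` yields uniform (pure exploration); large beta approaches
    greedy exploitation of the higher-valued option.
    """
    if beta < 0.0:
        raise ValueError("beta must be non-negative")
    q = np.asarray(q_pair, dtype=float)
    z = beta * (q - q.max())  # subtract max for numerical stability
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Session arrays: columns extracted once, shared by likelihood and replay.
# ---------------------------------------------------------------------------


def _session_arrays(trials: Sequence[TrialRecord]):
    pair = np.array([VALENCES.index(t.valence) for t in trials], dtype=np.int64)
    resp = np.array([t.responded for t in trials], dtype=bool)
    choice = np.array([t.choice if t.responded else 0 for t in trials], dtype=np.int64)
    outcome = np.array([t.outcome for t in trials], dtype=float)
    return pair, resp, choice, outcome


def _replay_dq(pair, resp, choice, outcome, alphas: np.ndarray):
    """Replay the update recursion for a vector of alphas.

    Returns ``(chosen_q, dq)`` of shape ``(n_alpha, n_trials)`` where
    ``chosen_q`` is the pre-update value of the chosen option and ``dq``
    is chosen-minus-unchosen. Missed trials leave values untouched and
    their columns are NaN.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    n_a, n_t = alphas.size, len(pair)
    q = np.zeros((n_a, len(VALENCES), 2))
    chosen_q = np.full((n_a, n_t), np.nan)
    dq = np.full((n_a, n_t), np.nan)
    rows = np.arange(n_a)
    for t in range(n_t):
        if not resp[t]:
            continue
        p, c = pair[t], choice[t]
        qc = q[rows, p, c]
        chosen_q[:, t] = qc
        dq[:, t] = qc - q[rows, p, 1 - c]
        q[rows, p, c] = qc + alphas * (outcome[t] - qc)
    return chosen_q, dq


def _replay_dq_scalar(pair, resp, choice, outcome, alpha: float):
    """Scalar-path replay: chosen-minus-unchosen value gaps for responded
    trials only. Pure-python floats — called inside optimizer loops."""
    q = [[0.0, 0.0] for _ in VALENCES]
    dq = []
    for t in range(len(pair)):
        if not resp[t]:
            continue
        p, c = pair[t], choice[t]
        qc = q[p][c]
        dq.append(qc - q[p][1 - c])
        q[p][c] = qc + alpha * (outcome[t] - qc)
    return np.array(dq)


def session_nll(params: QParams, trials: Sequence[TrialRecord]) -> float:
    """Negative log-likelihood of the responded choices in a session.

    ``-sum_t log P(choice_t | Q-state before t)`` under softmax choice,
    replaying the value recursion in trial order with an independent value
    pair per stimulus pair. Missed-response trials are skipped (no choice
    to explain, no update).
    """
    if len(trials) == 0:
        raise ValueError("empty trial sequence")
    pair, resp, choice, outcome = _session_arrays(trials)
    d = _replay_dq_scalar(pair, resp, choice, outcome, params.alpha)
    # -log sigmoid(beta * dq) summed, in a numerically safe form
    return float(np.logaddexp(0.0, -params.beta * d).sum())


def _nll_grid(pair, resp, choice, outcome, alphas, betas):
    """NLL on the (alpha, beta) product grid, shape (n_alpha, n_beta)."""
    _, dq = _replay_dq(pair, resp, choice, outcome, alphas)
    d = dq[:, resp]  # (A, T_resp)
    return np.logaddexp(0.0, -betas[None, :, None] * d[:, None, :]).sum(axis=2)


def fit_session(
    trials: Sequence[TrialRecord],
    grid_size: int = 50,
) -> FitResult:
    """Maximum-likelihood (alpha, beta) for one subject-session.

    A ``grid_size x grid_size`` log-spaced grid over the parameter bounds
    is scanned first; Nelder-Mead then refines from the best grid point
    with parameters clipped to bounds. Deterministic given the trials —
    no random restarts.

    Sessions with no responded trials return a flagged failure rather than
    raising (degenerate data, nothing to fit).
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials to fit")
    pair, resp, choice, outcome = _session_arrays(trials)
    n_resp = int(resp.sum())
    if n_resp == 0:
        return FitResult(QParams(0.5, 0.0), float("nan"), 0, False)

    alphas = np.geomspace(*ALPHA_BOUNDS, grid_size)
    betas = np.geomspace(*BETA_BOUNDS, grid_size)
    grid = _nll_grid(pair, resp, choice, outcome, alphas, betas)
    ia, ib = np.unravel_index(np.argmin(grid), grid.shape)

    def objective(x):
        a = float(np.clip(x[0], *ALPHA_BOUNDS))
        b = float(np.clip(x[1], *BETA_BOUNDS))
        d = _replay_dq_scalar(pair, resp, choice, outcome, a)
        return float(np.logaddexp(0.0, -b * d).sum())

    res = minimize(
        objective,
        x0=[alphas[ia], betas[ib]],
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500},
    )
    best_x, best_nll = res.x, float(res.fun)
    if grid[ia, ib] < best_nll:  # refinement should never lose to the grid
        best_x, best_nll = [alphas[ia], betas[ib]], float(grid[ia, ib])
    params = QParams(
        float(np.clip(best_x[0], *ALPHA_BOUNDS)),
        float(np.clip(best_x[1], *BETA_BOUNDS)),
    )
    return FitResult(params, best_nll, n_resp, bool(res.success))


def pe_trace(trials: Sequence[TrialRecord], params: QParams) -> LatentTrace:
    """Replay a session under ``params`` and emit per-trial latents.

    ``q_values`` holds the pre-update pair for each trial's own stimulus
    pair; ``delta`` is the signed PE at feedback; reward-trial deltas are
    partitioned into delivered (``pe_pos``) and omitted (``pe_neg``).
    """
    pair, resp, choice, outcome = _session_arrays(trials)
    n_t = len(trials)
    q = np.zeros((len(VALENCES), 2))
    q_values = np.zeros((n_t, 2))
    chosen_value = np.full(n_t, np.nan)
    delta = np.full(n_t, np.nan)
    for t in range(n_t):
        q_values[t] = q[pair[t]]
        if not resp[t]:
            continue
        c = choice[t]
        chosen_value[t] = q[pair[t], c]
        delta[t] = outcome[t] - chosen_value[t]
        q[pair[t], c] += params.alpha * delta[t]
    is_reward = np.array([t.valence == "reward" for t in trials])
    is_pe_pos = is_reward & resp & (outcome == 1.0)
    is_pe_neg = is_reward & resp & (outcome == 0.0)
    return LatentTrace(q_values, chosen_value, delta, is_pe_pos, is_pe_neg)
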