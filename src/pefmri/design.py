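"""First-level GLM design: events, HRF convolution, high-pass filter, OLS.

Builds the eight-regressor design used for model-based prediction-error
analysis — reward/punishment expected value at cue, signed positive and
negative PEs at feedback, plus unmodulated feedback and cue events — each
with a temporal-derivative column, convolved with a canonical double-gamma
HRF on a 0.1 s grid, high-pass filtered with a discrete-cosine basis
(60 s cutoff), and fit by ordinary least squares with +1 contrasts on the
PE regressors.

Modulator heights are the raw (signed) model estimates by default, the
three-column-file idiom: the negative-PE regressor carries negative
heights, so a positive COPE on it means BOLD *fell* when an expected
reward was omitted. A ``demean`` flag mean-centers heights per regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .qlearning import LatentTrace, TrialRecord

__all__ = [
    "EV_NAMES",
    "EventSpec",
    "DesignMatrix",
    "GlmResult",
    "build_events",
    "hrf",
    "convolve_design",
    "highpass",
    "drift_basis",
    "fit_glm",
    "write_fsl_ev",
    "read_fsl_ev",
]

#: Regressor classes in canonical order.
EV_NAMES = (
    "reward_ev",
    "pe_pos",
    "pe_neg",
    "punish_ev",
    "pun_pe_pos",
    "pun_pe_neg",
    "feedback",
    "cue",
)

EVENT_DURATION_S = 2.0  # every event is modeled with a 2 s boxcar
FINE_DT_S = 0.1  # oversampled grid for convolution


@dataclass
class EventSpec:
    """One regressor class: onsets, durations and modulation heights."""

    name: str
    onsets_s: np.ndarray
    durations_s: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if not (len(self.onsets_s) == len(self.durations_s) == len(self.heights)):
            raise ValueError("onsets, durations and heights must align")


@dataclass
class DesignMatrix:
    """Sampled design: one column per EV plus its temporal derivative."""

    columns: list  # column names
    matrix: np.ndarray  # (n_volumes, n_columns)
    frame_times: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]


@dataclass
class GlmResult:
    betas: Dict[str, float]
    residual_variance: float
    copes: Dict[str, float]
    dof: int


#: Event classes whose heights are model-based parametric modulators.
MODULATED_EVS = frozenset(
    ("reward_ev", "pe_pos", "pe_neg", "punish_ev", "pun_pe_pos", "pun_pe_neg")
)


def build_events(
    trace: LatentTrace,
    trials: Sequence[TrialRecord],
    demean: bool = False,
    normalize: Optional[str] = "rms",
) -> Dict[str, EventSpec]:
    """Assemble the eight event classes from a session and its latent trace.

    Expected-value regressors sit at cue onsets with the chosen option's
    pre-choice value as height; PE regressors sit at feedback onsets with
    the signed delta. ``feedback`` and ``cue`` are unmodulated (height 1)
    over all responded trials. Event classes empty in this session (e.g.
    no reward omissions) are dropped with a warning.

    ``normalize="rms"`` (default) rescales each parametric modulator's
    heights to unit root-mean-square, preserving sign. Fitted-parameter
    traces can otherwise carry an arbitrary amplitude (a near-zero
    learning rate shrinks every modeled value toward zero), which turns
    the per-unit-modulation COPE into an ill-conditioned ratio;
    standardizing the modulator makes COPEs comparable across subjects.
    ``normalize=None`` keeps raw model units. A modulator whose heights
    are all (near) zero is degenerate and is dropped like an empty class.
    """
    if len(trials) != len(trace.delta):
        raise ValueError("trace is not aligned to trials")
    cue = np.array([t.cue_onset_s for t in trials])
    fb = np.array([t.feedback_onset_s for t in trials])
    resp = np.array([t.responded for t in trials])
    val = np.array([t.valence for t in trials])
    out = np.array([t.outcome for t in trials])

    def spec(name, mask, onsets, heights):
        return EventSpec(
            name,
            onsets[mask],
            np.full(int(mask.sum()), EVENT_DURATION_S),
            heights[mask] if np.ndim(heights) else np.full(int(mask.sum()), heights),
        )

    rew = (val == "reward") & resp
    pun = (val == "punish") & resp
    events = {
        "reward_ev": spec("reward_ev", rew, cue, trace.chosen_value),
        "pe_pos": spec("pe_pos", trace.is_pe_pos, fb, trace.delta),
        "pe_neg": spec("pe_neg", trace.is_pe_neg, fb, trace.delta),
        "punish_ev": spec("punish_ev", pun, cue, trace.chosen_value),
        "pun_pe_pos": spec("pun_pe_pos", pun & (out == 0.0), fb, trace.delta),
        "pun_pe_neg": spec("pun_pe_neg", pun & (out == -1.0), fb, trace.delta),
        "feedback": spec("feedback", resp, fb, 1.0),
        "cue": spec("cue", resp, cue, 1.0),
    }
    if normalize not in (None, "rms"):
        raise ValueError("normalize must be None or 'rms'")
    for name in list(events):
        ev = events[name]
        if len(ev.onsets_s) == 0:
            warnings.warn(f"event class {name!r} is empty; column dropped")
            del events[name]
            continue
        if demean and name in MODULATED_EVS:
            ev.heights = ev.heights - ev.heights.mean()
        if normalize == "rms" and name in MODULATED_EVS:
            rms = float(np.sqrt(np.mean(ev.heights**2)))
            if rms < 1e-8:
                warnings.warn(
                    f"event class {name!r} has (near-)zero modulation; dropped"
                )
                del events[name]
                continue
            ev.heights = ev.heights / rms
    return events


def hrf(t_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak.

    Response gamma peaks at 6 s, undershoot gamma at 16 s, undershoot
    amplitude ratio 1/6; normalized so the kernel maximum is 1.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    from scipy.stats import gamma as gamma_dist

    # shape a, scale 1: mode at (a-1); peaks at 6 s and 16 s
    peak = gamma_dist.pdf(t, a=7.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=17.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _fine_grid(tr_s: float, n_volumes: int) -> np.ndarray:
    return np.arange(0.0, n_volumes * tr_s, FINE_DT_S)


def convolve_design(
    events: Mapping[str, EventSpec],
    tr_s: float,
    n_volumes: int,
) -> DesignMatrix:
    """Render events as height-scaled boxcars, convolve with the HRF,
    sample at frame times, and append finite-difference temporal
    derivatives as their own columns.
    """
    fine_t = _fine_grid(tr_s, n_volumes)
    kernel = hrf(np.arange(0.0, 32.0, FINE_DT_S))
    frame_times = np.arange(n_volumes) * tr_s
    frame_idx = np.round(frame_times / FINE_DT_S).astype(int)
    run_end = n_volumes * tr_s

    names, cols = [], []
    for name, ev in events.items():
        if np.any(ev.onsets_s >= run_end) or np.any(ev.onsets_s < 0):
            raise ValueError(f"event onset outside run for {name!r}")
        box = np.zeros_like(fine_t)
        for onset, dur, h in zip(ev.onsets_s, ev.durations_s, ev.heights):
            i0 = int(np.round(onset / FINE_DT_S))
            i1 = min(int(np.round((onset + dur) / FINE_DT_S)), len(box))
            box[i0:i1] += h
        conv = np.convolve(box, kernel)[: len(fine_t)] * FINE_DT_S
        sampled = conv[frame_idx]
        names.append(name)
        cols.append(sampled)
    # temporal derivatives appended after the main block, one per EV
    for name, col in list(zip(names, cols)):
        names.append(name + "_td")
        cols.append(np.gradient(col, tr_s))
    return DesignMatrix(names, np.column_stack(cols), frame_times)


def drift_basis(n_volumes: int, tr_s: float, cutoff_s: float = 60.0) -> np.ndarray:
    """Low-frequency drift basis: intercept plus cosine/sine pairs.

    Harmonic k contributes ``cos(2 pi k t / T)`` and ``sin(2 pi k t / T)``
    over the run length ``T = n_volumes * tr``; harmonics with period
    ``T / k >= cutoff_s`` are retained. Including both quadratures makes
    removal exact for a slow cosine of any phase.
    """
    n = n_volumes
    t = np.arange(n) * tr_s
    T = n * tr_s
    k_max = int(np.floor(T / cutoff_s))
    cols = [np.ones(n)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(2.0 * np.pi * k * t / T))
        cols.append(np.sin(2.0 * np.pi * k * t / T))
    return np.column_stack(cols)


def highpass(
    data: np.ndarray, tr_s: float, cutoff_s: float = 60.0
) -> np.ndarray:
    """Remove slow drift by projecting out the drift basis (plus intercept).

    Applied identically to BOLD data and design columns so filtering
    commutes with the GLM fit. Accepts a 1-D series or a 2-D
    (time x columns) matrix.
    """
    x = np.asarray(data, dtype=float)
    series = x[:, None] if x.ndim == 1 else x
    basis = drift_basis(series.shape[0], tr_s, cutoff_s)
    coef, *_ = np.linalg.lstsq(basis, series, rcond=None)
    filtered = series - basis @ coef
    return filtered[:, 0] if x.ndim == 1 else filtered


def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    contrasts: Optional[Mapping[str, Mapping[str, float]]] = None,
    tr_s: Optional[float] = None,
    cutoff_s: Optional[float] = 60.0,
) -> GlmResult:
    """Ordinary least squares fit with named contrasts.

    If ``tr_s`` is given, data and design are both high-pass filtered
    first. Contrasts map a name to ``{column: weight}``; by default the
    +1 contrasts on the positive and negative reward-PE regressors
    (derivative columns are never weighted). A contrast naming a column
    absent from this session's design yields a NaN COPE with a warning.
    """
    y = np.asarray(bold, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("BOLD and design length mismatch")
    if tr_s is not None and cutoff_s is not None:
        y = highpass(y, tr_s, cutoff_s)
        X = highpass(X, tr_s, cutoff_s)
    X = np.column_stack([X, np.ones(X.shape[0])])  # intercept
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("design is rank deficient; using pseudoinverse")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.shape[0] - rank
    resid_var = float(resid @ resid / dof) if dof > 0 else float("nan")
    betas = {name: float(b) for name, b in zip(design.columns, beta)}

    if contrasts is None:
        contrasts = {
            "pe_pos": {"pe_pos": 1.0},
            "pe_neg": {"pe_neg": 1.0},
        }
    copes = {}
    for cname, weights in contrasts.items():
        missing = [c for c in weights if c not in betas]
        if missing:
            warnings.warn(f"contrast {cname!r}: columns {missing} absent; COPE is NaN")
            copes[cname] = float("nan")
        else:
            copes[cname] = float(sum(w * betas[c] for c, w in weights.items()))
    return GlmResult(betas, resid_var, copes, dof)


# ---------------------------------------------------------------------------
# FSL-style three-column EV files (onset  duration  height).
# ---------------------------------------------------------------------------


def write_fsl_ev(path, ev: EventSpec) -> None:
    """Write a three-column (onset duration height) whitespace text file."""
    arr = np.column_stack([ev.onsets_s, ev.durations_s, ev.heights])
    np.savetxt(path, arr, fmt="%.6f")


def read_fsl_ev(path, name: str) -> EventSpec:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 3:
        raise ValueError("expected three columns: onset duration height")
    return EventSpec(name, arr[:, 0], arr[:, 1], arr[:, 2])
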