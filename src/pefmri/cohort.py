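"""Synthetic two-group, three-session pharmacological fMRI cohorts.

Generates complete studies — probabilistic-learning task schedules,
Q-learning agent behavior, trait questionnaires, and ROI BOLD series with
configurable coupling of prediction-error regressors — so the whole
downstream pipeline (fitting, first-level GLM, ROI extraction, group
statistics) can be exercised without any external data.

The default configuration encodes the study design this package targets:
two groups (control, OCD; 18 per group) scanned under placebo,
amisulpride and pramipexole; 40 trials each of reward, punishment and
neutral stimulus pairs with 70/30 outcome contingencies; group-specific
learning rates (0.27 vs 0.22); cingulate negative-PE coupling elevated
only in OCD under placebo; accumbens positive-PE coupling elevated in OCD
under every drug; and a trait self-regulation (SRQ) score negatively
rank-correlated with the OCD-placebo cingulate coupling.

All randomness flows from the single config seed through a spawned
``numpy.random.SeedSequence`` tree (cohort -> subject -> session), so
identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import design as dg
from .qlearning import QParams, TrialRecord, VALENCES, choice_prob, pe_trace

__all__ = [
    "TRIAL_LENGTH_S",
    "ROIS",
    "CohortConfig",
    "ScheduleTrial",
    "SessionData",
    "SubjectData",
    "default_coupling_matrix",
    "make_schedule",
    "simulate_behavior",
    "simulate_roi_bold",
    "generate_cohort",
]

#: Fixed trial length implied by the task timing: response window counts
#: toward the fixation (0.5 s + (2 s - RT)), so every trial spans
#: RT + 3 (choice display) + 1 (feedback) + 0.5 + (2 - RT) = 6.5 s.
TRIAL_LENGTH_S = 6.5

#: The two regions of interest carried through the pipeline.
ROIS = ("cingulate", "accumbens")

#: Per-group trait-score distributions (mean, SD).
TRAIT_DISTRIBUTIONS = {
    "srq_total": {"control": (225.7, 16.2), "OCD": (199.9, 21.6)},
    "srq_searching_options": {"control": (31.9, 4.0), "OCD": (29.7, 5.0)},
    "srq_implementing_plan": {"control": (34.7, 3.0), "OCD": (26.9, 5.1)},
    "srq_triggering_change": {"control": (31.1, 2.1), "OCD": (28.5, 3.1)},
    "ybocs": {"OCD": (24.1, 6.8)},
}


def default_coupling_matrix() -> Dict[Tuple[str, str, str, str], float]:
    """Generative BOLD coupling weights, (group, session, roi, pe-sign) -> weight.

    Magnitudes are chosen so standardized group effects land near the
    effect sizes the design targets (partial eta^2 ~ 0.2-0.3 for the
    cingulate placebo group contrast and the accumbens group main
    effect) given the default between-subject coupling SD (0.4), session
    jitter (0.25) and COPE estimation noise (~0.1): a 0.5 group contrast
    is d ~ 1.06 between subjects.
    """
    m: Dict[Tuple[str, str, str, str], float] = {}
    for group in ("control", "OCD"):
        for session in ("placebo", "amisulpride", "pramipexole"):
            # cingulate: negative-PE coupling high only in OCD on placebo
            cing_neg = 0.5 if (group == "OCD" and session == "placebo") else 0.0
            m[(group, session, "cingulate", "pe_neg")] = cing_neg
            m[(group, session, "cingulate", "pe_pos")] = 0.1
            # accumbens: positive-PE coupling elevated in OCD across drugs
            m[(group, session, "accumbens", "pe_pos")] = (
                0.65 if group == "OCD" else 0.15
            )
            m[(group, session, "accumbens", "pe_neg")] = 0.0
    return m


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of one synthetic study."""

    n_per_group: int = 18
    sessions: Tuple[str, ...] = ("placebo", "amisulpride", "pramipexole")
    trials_per_valence: int = 40
    p_win_good: float = 0.7
    p_win_bad: float = 0.3
    alpha_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.27, "OCD": 0.22}
    )
    alpha_sd: float = 0.085  # SE 0.02 at n=18
    beta_mean: float = 3.0
    beta_sd: float = 1.0
    coupling_matrix: Optional[Mapping[Tuple[str, str, str, str], float]] = None
    coupling_subject_sd: float = 0.4  # stable between-subject coupling offset
    coupling_session_sd: float = 0.25  # per-session coupling jitter
    noise_sd: float = 0.5  # white BOLD noise, signal units
    drift_sd: float = 0.8  # amplitude of sub-1/60 Hz cosine drift
    srq_coupling_rho: float = -0.7  # target Spearman rho, OCD placebo cingulate
    rt_median_by_session: Mapping[str, float] = field(
        default_factory=lambda: {
            "placebo": 0.75,
            "amisulpride": 0.74,
            "pramipexole": 0.83,  # pramipexole slows reward-trial responses
        }
    )
    rt_sigma: float = 0.3
    p_miss: float = 0.0
    tr_s: float = 2.0
    n_volumes: Optional[int] = None  # None: derived from the schedule length
    n_outlier_subjects: int = 0  # spiked couplings to exercise exclusion
    outlier_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_win_good, self.p_win_bad):
            if not (0.0 <= p <= 1.0):
                raise ValueError("contingency probabilities must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")

    @property
    def n_trials(self) -> int:
        return 3 * self.trials_per_valence

    def resolved_n_volumes(self) -> int:
        if self.n_volumes is not None:
            return self.n_volumes
        run_s = self.n_trials * TRIAL_LENGTH_S + 16.0  # washout after last trial
        return int(math.ceil(run_s / self.tr_s))

    def resolved_coupling(self) -> Mapping[Tuple[str, str, str, str], float]:
        return (
            default_coupling_matrix()
            if self.coupling_matrix is None
            else self.coupling_matrix
        )


@dataclass(frozen=True)
class ScheduleTrial:
    """One planned trial: valence, timing slot, and pre-drawn outcomes.

    Option 0 is always the advantageous option (high win probability on
    reward pairs, low loss probability on punish pairs, designated
    "correct" on neutral pairs); agents cannot observe this labeling.
    ``outcome_if_choice`` pre-draws the feedback for either choice so a
    schedule is fully determined by its seed.
    """

    index: int
    valence: str
    cue_onset_s: float
    outcome_if_choice: Tuple[float, float]


@dataclass
class SessionData:
    """One subject-session: behavior, per-ROI BOLD, and ground truth."""

    trials: List[TrialRecord]
    bold: Dict[str, np.ndarray]
    params_true: QParams
    coupling: Dict[str, Dict[str, float]]  # roi -> {pe_pos, pe_neg} realized


@dataclass
class SubjectData:
    subject_id: str
    group: str
    session_order: Tuple[str, ...]
    sessions: Dict[str, SessionData]
    traits: Dict[str, float]
    med_class: Optional[str] = None  # OCD only: "high" | "not_high" SSRI dose


def make_schedule(config: CohortConfig, seed) -> List[ScheduleTrial]:
    """Seeded random interleave of the three valence pairs with outcomes.

    Cue onsets sit on a fixed 6.5 s trial grid (the task timing makes
    trial length independent of RT). Outcomes are Bernoulli draws per
    option: reward pair wins with p_win_good (option 0) / p_win_bad
    (option 1), punish pair loses with p_win_bad / p_win_good, neutral
    never pays.
    """
    rng = np.random.default_rng(seed)
    valences = np.repeat(np.arange(3), config.trials_per_valence)
    rng.shuffle(valences)
    trials = []
    for i, v in enumerate(valences):
        valence = VALENCES[v]
        if valence == "reward":
            outcomes = (
                1.0 if rng.random() < config.p_win_good else 0.0,
                1.0 if rng.random() < config.p_win_bad else 0.0,
            )
        elif valence == "punish":
            outcomes = (
                -1.0 if rng.random() < config.p_win_bad else 0.0,
                -1.0 if rng.random() < config.p_win_good else 0.0,
            )
        else:
            outcomes = (0.0, 0.0)
        trials.append(ScheduleTrial(i, valence, i * TRIAL_LENGTH_S, outcomes))
    return trials


def simulate_behavior(
    schedule: Sequence[ScheduleTrial],
    params: QParams,
    seed,
    rt_median_s: float = 0.75,
    rt_sigma: float = 0.3,
    p_miss: float = 0.0,
) -> List[TrialRecord]:
    """Forward-run a Q-learning agent over a schedule.

    Choices are sampled from the softmax of the current values (explicit
    seeded RNG); RTs from a lognormal with the given median, truncated to
    (0.15, 2] by resampling; feedback appears 3 s after the response
    (choice display). Missed trials (probability ``p_miss``) record no
    choice, no outcome and a nominal feedback slot.
    """
    rng = np.random.default_rng(seed)
    q = np.zeros((len(VALENCES), 2))
    records: List[TrialRecord] = []
    for st in schedule:
        v = VALENCES.index(st.valence)
        if p_miss > 0.0 and rng.random() < p_miss:
            records.append(
                TrialRecord(
                    st.index, st.valence, st.cue_onset_s, st.cue_onset_s + 5.0,
                    None, 0.0, None,
                )
            )
            continue
        probs = choice_prob(q[v], params.beta)
        choice = int(rng.random() < probs[1])
        outcome = st.outcome_if_choice[choice]
        rt = float(rng.lognormal(np.log(rt_median_s), rt_sigma))
        while not (0.15 < rt <= 2.0):
            rt = float(rng.lognormal(np.log(rt_median_s), rt_sigma))
        q[v, choice] += params.alpha * (outcome - q[v, choice])
        records.append(
            TrialRecord(
                st.index, st.valence, st.cue_onset_s,
                st.cue_onset_s + rt + 3.0, choice, outcome, rt,
            )
        )
    return records


def simulate_roi_bold(
    trace,
    trials: Sequence[TrialRecord],
    coupling: Mapping[str, float],
    tr_s: float = 2.0,
    n_volumes: Optional[int] = None,
    noise_sd: float = 0.5,
    drift_sd: float = 0.8,
    cutoff_s: float = 60.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One ROI BOLD series: coupled regressors + slow drift + white noise.

    The regressors are built by the *analysis* design code
    (:func:`pefmri.design.build_events` / :func:`~pefmri.design.convolve_design`),
    so generation and analysis share a single code path and a noise-free
    series is exactly explained by the GLM. Drift is a random combination
    of the discrete-cosine basis below 1/cutoff Hz — the same basis the
    high-pass filter removes.
    """
    unknown = set(coupling) - set(dg.EV_NAMES)
    if unknown:
        raise ValueError(f"coupling for unknown regressor(s): {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(0)
    if n_volumes is None:
        n_volumes = int(math.ceil((trials[-1].feedback_onset_s + 16.0) / tr_s))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # empty event classes are fine here
        events = dg.build_events(trace, trials)
        X = dg.convolve_design(events, tr_s, n_volumes)
    signal = np.zeros(n_volumes)
    for name, w in coupling.items():
        if name in X.columns and w != 0.0:
            signal += w * X.column(name)
    basis = dg.drift_basis(n_volumes, tr_s, cutoff_s)[:, 1:]
    if basis.shape[1] and drift_sd > 0.0:
        signal += basis @ (rng.normal(0.0, drift_sd, basis.shape[1]))
    if noise_sd > 0.0:
        signal = signal + rng.normal(0.0, noise_sd, n_volumes)
    return signal


def _truncnorm(rng, mean, sd, lo, hi):
    x = rng.normal(mean, sd)
    while not (lo <= x <= hi):
        x = rng.normal(mean, sd)
    return float(x)


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving a target Spearman rho under a
    Gaussian copula: rho_p = 2 sin(pi rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_cohort(config: CohortConfig) -> List[SubjectData]:
    """Draw a complete synthetic study from the configuration.

    Per subject: a truncated-normal learning rate around the group mean, a
    shared inverse temperature, a counterbalanced session order, stable
    per-ROI coupling offsets plus per-session jitter around the group x
    session coupling matrix, behavior and BOLD per session, and trait
    scores. OCD SRQ totals are generated by Gaussian copula against the
    subject's realized placebo cingulate negative-PE coupling to hit the
    configured Spearman correlation.
    """
    coupling_m = config.resolved_coupling()
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_subjects = root.spawn(2)
    rng = np.random.default_rng(ss_cohort)
    n_vol = config.resolved_n_volumes()

    orders = list(itertools.permutations(config.sessions))
    subjects: List[SubjectData] = []
    groups = ["control"] * config.n_per_group + ["OCD"] * config.n_per_group
    subj_seeds = ss_subjects.spawn(len(groups))

    # stable subject-level coupling offsets, one per roi x sign
    signs = ("pe_pos", "pe_neg")
    offsets = rng.normal(0.0, config.coupling_subject_sd, (len(groups), 2, 2))
    # counterbalanced session order within each group
    order_idx = np.concatenate(
        [
            rng.permutation(
                np.resize(np.arange(len(orders)), config.n_per_group)
            )
            for _ in range(2)
        ]
    )
    # optional outlier spikes on the cingulate negative-PE coupling
    outlier_rows = (
        rng.choice(len(groups), size=config.n_outlier_subjects, replace=False)
        if config.n_outlier_subjects
        else np.array([], dtype=int)
    )

    placebo_cing_neg: Dict[int, float] = {}
    for i, (group, sseed) in enumerate(zip(groups, subj_seeds)):
        srng = np.random.default_rng(sseed)
        sid = f"{'con' if group == 'control' else 'ocd'}{i % config.n_per_group + 1:02d}"
        alpha = _truncnorm(
            srng, config.alpha_mean_by_group[group], config.alpha_sd, 0.02, 0.95
        )
        beta = _truncnorm(srng, config.beta_mean, config.beta_sd, 0.5, 15.0)
        params = QParams(alpha, beta)

        sessions: Dict[str, SessionData] = {}
        ses_seeds = sseed.spawn(len(config.sessions))
        for session, ses_seed in zip(config.sessions, ses_seeds):
            schedule_seed, behavior_seed, bold_seed = ses_seed.spawn(3)
            schedule = make_schedule(config, schedule_seed)
            trials = simulate_behavior(
                schedule,
                params,
                behavior_seed,
                rt_median_s=config.rt_median_by_session.get(session, 0.75),
                rt_sigma=config.rt_sigma,
                p_miss=config.p_miss,
            )
            trace = pe_trace(trials, params)
            brng = np.random.default_rng(bold_seed)
            coupling_realized: Dict[str, Dict[str, float]] = {}
            bold: Dict[str, np.ndarray] = {}
            for ri, roi in enumerate(ROIS):
                cw = {}
                for si, sign in enumerate(signs):
                    w = (
                        coupling_m[(group, session, roi, sign)]
                        + offsets[i, ri, si]
                        + brng.normal(0.0, config.coupling_session_sd)
                    )
                    if (
                        i in outlier_rows
                        and roi == "cingulate"
                        and sign == "pe_neg"
                    ):
                        w += config.outlier_shift
                    cw[sign] = float(w)
                coupling_realized[roi] = cw
                # common unmodulated task responses shared by everyone
                full = {"feedback": 0.3, "cue": 0.2, **cw}
                bold[roi] = simulate_roi_bold(
                    trace,
                    trials,
                    full,
                    tr_s=config.tr_s,
                    n_volumes=n_vol,
                    noise_sd=config.noise_sd,
                    drift_sd=config.drift_sd,
                    rng=brng,
                )
            sessions[session] = SessionData(trials, bold, params, coupling_realized)
            if session == "placebo":
                placebo_cing_neg[i] = coupling_realized["cingulate"]["pe_neg"]

        subjects.append(
            SubjectData(
                subject_id=sid,
                group=group,
                session_order=orders[order_idx[i]],
                sessions=sessions,
                traits={},
                med_class=None,
            )
        )

    _assign_traits(subjects, placebo_cing_neg, config, rng)
    return subjects


def _assign_traits(subjects, placebo_cing_neg, config, rng) -> None:
    """Trait questionnaires; OCD SRQ tied to cingulate coupling by copula."""
    rho_p = _spearman_to_pearson(config.srq_coupling_rho)
    sd_c = math.hypot(config.coupling_subject_sd, config.coupling_session_sd)
    mu_c = config.resolved_coupling()[("OCD", "placebo", "cingulate", "pe_neg")]
    med_pool = None
    for i, sub in enumerate(subjects):
        g = sub.group
        if g == "OCD":
            z_c = (placebo_cing_neg[i] - mu_c) / sd_c
            z = rho_p * z_c + math.sqrt(1.0 - rho_p**2) * rng.normal()
        else:
            z = rng.normal()
        traits = {}
        m, s = TRAIT_DISTRIBUTIONS["srq_total"][g]
        traits["srq_total"] = m + s * z
        for sub_name in (
            "srq_searching_options",
            "srq_implementing_plan",
            "srq_triggering_change",
        ):
            m, s = TRAIT_DISTRIBUTIONS[sub_name][g]
            traits[sub_name] = m + s * (0.7 * z + math.sqrt(1 - 0.49) * rng.normal())
        if g == "OCD":
            m, s = TRAIT_DISTRIBUTIONS["ybocs"]["OCD"]
            traits["ybocs"] = _truncnorm(rng, m, s, 8.0, 40.0)
            if med_pool is None or not med_pool:
                # 16 of 18 medicated; dichotomized high vs not-high dose,
                # the latter absorbing the two unmedicated patients
                n_ocd = sum(1 for x in subjects if x.group == "OCD")
                n_high = max(1, round(n_ocd * 10 / 18))
                med_pool = ["high"] * n_high + ["not_high"] * (n_ocd - n_high)
                med_pool = list(rng.permutation(med_pool))
            sub.med_class = med_pool.pop()
        sub.traits = traits
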