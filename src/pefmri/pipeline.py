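"""End-to-end orchestration: simulate -> fit -> first-level -> extract -> stats.

The in-memory functions (:func:`fit_cohort`, :func:`first_level`,
:func:`group_battery`, :func:`run_study`) form the library pipeline;
:func:`run_all` wraps them with a validated YAML config, a versioned run
directory, logging and a manifest for command-line use.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import CohortConfig, SubjectData, generate_cohort
from .design import build_events, convolve_design, fit_glm
from .qlearning import QParams, fit_session, pe_trace
from . import stats as gs

logger = logging.getLogger("pefmri")

__all__ = [
    "RunConfig",
    "fit_cohort",
    "first_level",
    "accuracy_table",
    "group_battery",
    "run_study",
    "run_all",
]


# ---------------------------------------------------------------------------
# Config schema (unknown keys rejected).
# ---------------------------------------------------------------------------


class GlmBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_s: float = 60.0
    demean_modulators: bool = False
    use_true_params: bool = False


class StatsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_sd: float = 3.0
    sphericity_correction: bool = False


class CohortBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 18
    trials_per_valence: int = 40
    p_win_good: float = 0.7
    p_win_bad: float = 0.3
    alpha_sd: float = 0.085
    beta_mean: float = 3.0
    beta_sd: float = 1.0
    coupling_subject_sd: float = 0.4
    coupling_session_sd: float = 0.25
    noise_sd: float = 0.5
    drift_sd: float = 0.8
    srq_coupling_rho: float = -0.7
    p_miss: float = 0.0
    tr_s: float = 2.0
    n_volumes: Optional[int] = None
    n_outlier_subjects: int = 0
    outlier_shift: float = 3.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    out_dir: str = "pefmri_run"
    seed: int = 0
    volume_mode: bool = False
    log_level: str = "INFO"
    figures: bool = False
    cohort: CohortBlock = CohortBlock()
    glm: GlmBlock = GlmBlock()
    stats: StatsBlock = StatsBlock()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(seed=self.seed, **self.cohort.model_dump())


# ---------------------------------------------------------------------------
# In-memory pipeline stages.
# ---------------------------------------------------------------------------


def fit_cohort(subjects: Sequence[SubjectData]) -> pd.DataFrame:
    """Maximum-likelihood Q-learning fit per subject-session."""
    rows = []
    for sub in subjects:
        for session, ses in sub.sessions.items():
            fit = fit_session(ses.trials)
            rows.append(
                {
                    "subject_id": sub.subject_id,
                    "group": sub.group,
                    "session": session,
                    "alpha": fit.params.alpha,
                    "beta": fit.params.beta,
                    "nll": fit.nll,
                    "n_trials": fit.n_trials,
                    "converged": fit.convergence_flag,
                    "alpha_true": ses.params_true.alpha,
                    "beta_true": ses.params_true.beta,
                }
            )
    return pd.DataFrame(rows)


def first_level(
    subjects: Sequence[SubjectData],
    fits: Optional[pd.DataFrame] = None,
    use_true_params: bool = False,
    demean: bool = False,
    cutoff_s: float = 60.0,
    tr_s: float = 2.0,
) -> pd.DataFrame:
    """First-level GLM per subject-session-ROI; returns tidy COPE records.

    Parametric modulators come from the fitted parameters (the standard
    procedure) or, with ``use_true_params``, from the generating ones
    (exact-recovery checks). One row per subject x session x ROI x
    contrast, plus the realized generating coupling for recovery tests.
    """
    if not use_true_params and fits is None:
        fits = fit_cohort(subjects)
    if fits is not None:
        fit_idx = fits.set_index(["subject_id", "session"])
    rows = []
    for sub in subjects:
        for session, ses in sub.sessions.items():
            if use_true_params:
                params = ses.params_true
            else:
                f = fit_idx.loc[(sub.subject_id, session)]
                params = QParams(float(f["alpha"]), float(f["beta"]))
            trace = pe_trace(ses.trials, params)
            n_vol = len(next(iter(ses.bold.values())))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                events = build_events(trace, ses.trials, demean=demean)
                X = convolve_design(events, tr_s, n_vol)
                for roi in ses.bold:
                    res = fit_glm(ses.bold[roi], X, tr_s=tr_s, cutoff_s=cutoff_s)
                    for contrast, value in res.copes.items():
                        rows.append(
                            {
                                "subject_id": sub.subject_id,
                                "group": sub.group,
                                "session": session,
                                "roi": roi,
                                "contrast": contrast,
                                "value": value,
                                "coupling_true": ses.coupling[roi][contrast],
                            }
                        )
    return pd.DataFrame(rows)


def first_level_volume(
    bold_img,
    trials,
    params: QParams,
    roi_masks: Mapping[str, np.ndarray],
    tr_s: float = 2.0,
    cutoff_s: float = 60.0,
) -> Dict[str, Dict[str, float]]:
    """Voxelwise GLM on a small 4D volume, then ROI-mean COPE extraction.

    Fits every voxel's time series against the shared design in one
    least-squares solve, forms the +1 PE contrasts per voxel, and returns
    ``{roi: {contrast: mean COPE}}`` via :func:`pefmri.roi.extract_mean`.
    """
    from .design import highpass
    from .roi import extract_mean

    data = np.asarray(bold_img.dataobj, dtype=float)
    n_vol = data.shape[-1]
    trace = pe_trace(trials, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        events = build_events(trace, trials)
        X = convolve_design(events, tr_s, n_vol)
    Y = highpass(data.reshape(-1, n_vol).T, tr_s, cutoff_s)
    Xf = np.column_stack([highpass(X.matrix, tr_s, cutoff_s), np.ones(n_vol)])
    beta, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    out: Dict[str, Dict[str, float]] = {}
    for roi, mask in roi_masks.items():
        out[roi] = {}
        for contrast in ("pe_pos", "pe_neg"):
            if contrast in X.columns:
                cope_map = beta[X.columns.index(contrast)].reshape(data.shape[:3])
                out[roi][contrast], _ = extract_mean(cope_map, mask)
            else:
                out[roi][contrast] = float("nan")
    return out


def accuracy_table(subjects: Sequence[SubjectData]) -> pd.DataFrame:
    """Per subject-session behavioral summaries (option 0 is 'correct')."""
    rows = []
    for sub in subjects:
        for session, ses in sub.sessions.items():
            for valence in ("reward", "punish", "neutral"):
                tt = [t for t in ses.trials if t.valence == valence and t.responded]
                if not tt:
                    continue
                rows.append(
                    {
                        "subject_id": sub.subject_id,
                        "group": sub.group,
                        "session": session,
                        "valence": valence,
                        "accuracy": float(np.mean([t.choice == 0 for t in tt])),
                        "mean_rt_s": float(np.mean([t.rt_s for t in tt])),
                    }
                )
    return pd.DataFrame(rows)


def _battery_for(records: pd.DataFrame, roi: str, contrast: str, k_sd: float,
                 correction: bool) -> Dict:
    """Exclusion + ANOVA battery for one ROI x contrast."""
    sel = records[(records["roi"] == roi) & (records["contrast"] == contrast)]
    kept, reports = gs.exclude_outliers(sel, k=k_sd)
    report = reports[(roi, contrast)]
    out: Dict = {"excluded": report.excluded}
    out["mixed"] = {
        r.effect: r for r in gs.mixed_anova(kept, correction=correction)
    }
    out["univariate"] = {
        s: gs.univariate_by_session(kept, s) for s in kept["session"].unique()
    }
    out["posthoc"] = {}
    for group, part in kept.groupby("group"):
        omnibus, pairs = gs.posthoc_within(part)
        out["posthoc"][group] = {"omnibus": omnibus, "pairs": pairs}
    out["kept"] = kept
    return out


def group_battery(
    records: pd.DataFrame,
    subjects: Sequence[SubjectData],
    k_sd: float = 3.0,
    sphericity_correction: bool = False,
) -> Dict:
    """The full group-level battery on first-level COPE records.

    Runs, for the two hypothesis-carrying measures (cingulate negative PE
    and accumbens positive PE): pooled outlier exclusion, the mixed
    group x drug ANOVA, per-session univariate group ANOVAs, within-group
    Bonferroni post-hocs, the dichotomized-medication factor within the
    patient group, and Spearman correlations of the OCD placebo cingulate
    signal with trait scales.
    """
    results: Dict = {}
    for roi, contrast in (("cingulate", "pe_neg"), ("accumbens", "pe_pos")):
        results[f"{roi}_{contrast}"] = _battery_for(
            records, roi, contrast, k_sd, sphericity_correction
        )

    med_class = pd.Series(
        {s.subject_id: s.med_class for s in subjects if s.group == "OCD"}
    )
    cing = results["cingulate_pe_neg"]["kept"]
    ocd_cing = cing[cing["group"] == "OCD"]
    if med_class.notna().all() and len(ocd_cing):
        results["medication_anova"] = {
            r.effect: r
            for r in gs.medication_factor_anova(ocd_cing, med_class)
        }

    # trait correlations against the OCD placebo cingulate negative-PE COPE
    traits = {s.subject_id: s.traits for s in subjects}
    results["correlations"] = {}
    for label, kept_only in (("including_outliers", False), ("excluding_outliers", True)):
        table = results["cingulate_pe_neg"]["kept"] if kept_only else records[
            (records["roi"] == "cingulate") & (records["contrast"] == "pe_neg")
        ]
        part = table[(table["group"] == "OCD") & (table["session"] == "placebo")]
        for scale in ("srq_total", "ybocs"):
            x = [traits[s].get(scale) for s in part["subject_id"]]
            y = part["value"].tolist()
            pairs = [(a, b) for a, b in zip(x, y) if a is not None]
            if len(pairs) >= 5:
                rho, p = gs.spearman_corr(*zip(*pairs))
                results["correlations"][f"{scale}_{label}"] = {"rho": rho, "p": p}
    return results


def run_study(
    config: CohortConfig,
    use_true_params: bool = False,
    demean: bool = False,
    cutoff_s: float = 60.0,
    k_sd: float = 3.0,
) -> Tuple[List[SubjectData], pd.DataFrame, pd.DataFrame, Dict]:
    """Simulate one cohort and run the full analysis pipeline on it."""
    subjects = generate_cohort(config)
    fits = None if use_true_params else fit_cohort(subjects)
    records = first_level(
        subjects, fits, use_true_params=use_true_params, demean=demean,
        cutoff_s=cutoff_s, tr_s=config.tr_s,
    )
    results = group_battery(records, subjects, k_sd=k_sd)
    return subjects, fits, records, results


# ---------------------------------------------------------------------------
# File-based orchestration (CLI backend).
# ---------------------------------------------------------------------------

STAGES = ("simulate", "fit", "firstlevel", "extract", "groupstats", "report")


def _anova_row(name: str, r: gs.AnovaResult) -> Dict:
    return {
        "effect": name,
        "F": r.F,
        "df_num": r.df_num,
        "df_den": r.df_den,
        "p": r.p,
        "partial_eta_sq": r.partial_eta_sq,
    }


def results_table(results: Mapping) -> pd.DataFrame:
    """Flatten the battery output into a tidy effects table."""
    rows = []
    for key in ("cingulate_pe_neg", "accumbens_pe_pos"):
        bat = results[key]
        for effect, r in bat["mixed"].items():
            rows.append({"measure": key, "analysis": "mixed", **_anova_row(effect, r)})
        for session, r in bat["univariate"].items():
            rows.append(
                {"measure": key, "analysis": f"univariate_{session}", **_anova_row("group", r)}
            )
        for group, ph in bat["posthoc"].items():
            rows.append(
                {"measure": key, "analysis": f"posthoc_{group}",
                 **_anova_row("session", ph["omnibus"])}
            )
            for pr in ph["pairs"]:
                rows.append(
                    {
                        "measure": key,
                        "analysis": f"posthoc_{group}",
                        "effect": f"{pr.pair[0]}_vs_{pr.pair[1]}",
                        "F": pr.t**2,
                        "p": pr.p_adj,
                    }
                )
    for effect, r in results.get("medication_anova", {}).items():
        rows.append({"measure": "cingulate_pe_neg", "analysis": "medication", **_anova_row(effect, r)})
    for name, c in results.get("correlations", {}).items():
        rows.append(
            {"measure": "cingulate_pe_neg", "analysis": "spearman", "effect": name,
             "F": np.nan, "p": c["p"], "rho": c["rho"]}
        )
    return pd.DataFrame(rows)


def render_report(results: Mapping, exclusion_k: float) -> str:
    lines = ["pefmri group-level report", "=" * 40]
    for key in ("cingulate_pe_neg", "accumbens_pe_pos"):
        bat = results[key]
        lines.append(f"\n[{key}]  excluded (> {exclusion_k} SD pooled): "
                     f"{', '.join(bat['excluded']) or 'none'}")
        for effect, r in bat["mixed"].items():
            lines.append(
                f"  mixed {effect:<12} F({r.df_num:.0f},{r.df_den:.0f}) = {r.F:6.2f}"
                f"  p = {r.p:.4f}  partial eta^2 = {r.partial_eta_sq:.3f}"
            )
        for session, r in bat["univariate"].items():
            lines.append(
                f"  group @ {session:<12} F({r.df_num:.0f},{r.df_den:.0f}) = {r.F:6.2f}"
                f"  p = {r.p:.4f}  partial eta^2 = {r.partial_eta_sq:.3f}"
            )
        for group, ph in bat["posthoc"].items():
            o = ph["omnibus"]
            lines.append(
                f"  drug effect in {group:<8} F({o.df_num:.0f},{o.df_den:.0f}) ="
                f" {o.F:6.2f}  p = {o.p:.4f}"
            )
            for pr in ph["pairs"]:
                lines.append(
                    f"    {pr.pair[0]} vs {pr.pair[1]}: means {pr.mean_a:.2f} /"
                    f" {pr.mean_b:.2f}, adj p = {pr.p_adj:.4f}"
                )
    for name, c in results.get("correlations", {}).items():
        lines.append(f"  {name}: rho = {c['rho']:.3f}, p = {c['p']:.4f}")
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Execute the pipeline stages, writing artifacts and a manifest."""
    from . import io as pio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "stages_completed": [],
    }
    stages = list(stages or STAGES)
    ccfg = config.cohort_config()
    subjects = fits = records = results = None
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            logger.info("stage %s ...", stage)
            if stage == "simulate":
                subjects = generate_cohort(ccfg)
                pio.write_cohort_tree(subjects, out / "cohort", ccfg.tr_s)
                if config.volume_mode:
                    pio.write_volume_mode(subjects, out / "cohort", seed=config.seed)
            elif stage == "fit":
                subjects = subjects or pio.read_cohort_tree(out / "cohort")
                fits = fit_cohort(subjects)
                fits.to_csv(out / "fits.csv", index=False)
            elif stage == "firstlevel":
                subjects = subjects or pio.read_cohort_tree(out / "cohort")
                if fits is None and (out / "fits.csv").exists():
                    fits = pd.read_csv(out / "fits.csv")
                records = first_level(
                    subjects,
                    fits,
                    use_true_params=config.glm.use_true_params,
                    demean=config.glm.demean_modulators,
                    cutoff_s=config.glm.cutoff_s,
                    tr_s=ccfg.tr_s,
                )
                records.to_csv(out / "copes.csv", index=False)
            elif stage == "extract":
                if records is None:
                    records = pd.read_csv(out / "copes.csv")
                records.to_csv(out / "cope_records.csv", index=False)
                accuracy_table(subjects or pio.read_cohort_tree(out / "cohort")).to_csv(
                    out / "behavior.csv", index=False
                )
            elif stage == "groupstats":
                subjects = subjects or pio.read_cohort_tree(out / "cohort")
                if records is None:
                    records = pd.read_csv(out / "cope_records.csv")
                results = group_battery(
                    records,
                    subjects,
                    k_sd=config.stats.k_sd,
                    sphericity_correction=config.stats.sphericity_correction,
                )
                results_table(results).to_csv(out / "results.csv", index=False)
                (out / "report.txt").write_text(
                    render_report(results, config.stats.k_sd)
                )
            elif stage == "report":
                if config.figures and results is not None:
                    from .figures import cope_bar_chart

                    for key in ("cingulate_pe_neg", "accumbens_pe_pos"):
                        cope_bar_chart(
                            results[key]["kept"], out / f"{key}_bars.png"
                        )
            manifest["stages_completed"].append(
                {"stage": stage, "seconds": round(time.time() - t0, 2)}
            )
    except Exception as exc:  # partial-results manifest, then re-raise
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
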