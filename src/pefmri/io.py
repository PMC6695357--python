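"""File interchange: BIDS-style events, ROI series, cohort trees, NIfTI.

ROI-mode cohorts are written as a BIDS-like tree of plain-text files::

    <root>/participants.tsv
    <root>/sub-<id>/ses-<session>/sub-<id>_ses-<session>_events.tsv
    <root>/sub-<id>/ses-<session>/sub-<id>_ses-<session>_roi-bold.csv
    <root>/sub-<id>/ses-<session>/sub-<id>_ses-<session>_truth.json

Volume mode additionally renders each session as a small 4D NIfTI with
the cingulate sphere and a synthetic accumbens mask embedded in a
12x12x12 grid (4 mm voxels), plus the mask file itself.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SessionData, SubjectData
from .qlearning import QParams, TrialRecord

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_cohort_tree",
    "read_cohort_tree",
    "VOLUME_SHAPE",
    "VOLUME_AFFINE",
    "accumbens_synthetic_mask",
    "render_session_volume",
]

_NA = "n/a"


def write_events_tsv(trials: Sequence[TrialRecord], path) -> None:
    """BIDS-style events table: onset, duration, trial_type, choice,
    outcome, response_time. Onset is cue onset; the feedback onset is
    implied by the task timing (onset + RT + 3 s choice display)."""
    rows = []
    for t in trials:
        rows.append(
            {
                "onset": t.cue_onset_s,
                "duration": 2.0,
                "trial_type": t.valence,
                "choice": t.choice if t.responded else _NA,
                "outcome": t.outcome,
                "response_time": t.rt_s if t.rt_s is not None else _NA,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_events_tsv(path) -> List[TrialRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    trials = []
    for i, row in df.iterrows():
        responded = not pd.isna(row["choice"])
        rt = None if pd.isna(row["response_time"]) else float(row["response_time"])
        fb = row["onset"] + (rt + 3.0 if rt is not None else 5.0)
        trials.append(
            TrialRecord(
                index=int(i),
                valence=str(row["trial_type"]),
                cue_onset_s=float(row["onset"]),
                feedback_onset_s=float(fb),
                choice=int(row["choice"]) if responded else None,
                outcome=float(row["outcome"]),
                rt_s=rt,
            )
        )
    return trials


def _session_dir(root: Path, sid: str, session: str) -> Path:
    d = Path(root) / f"sub-{sid}" / f"ses-{session}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_cohort_tree(subjects: Sequence[SubjectData], root, tr_s: float) -> None:
    """Write a full ROI-mode cohort as plain-text files (see module docs)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    prows = []
    for sub in subjects:
        prows.append(
            {
                "participant_id": sub.subject_id,
                "group": sub.group,
                "med_class": sub.med_class or _NA,
                "session_order": "-".join(sub.session_order),
                **{k: round(v, 4) for k, v in sub.traits.items()},
            }
        )
        for session, ses in sub.sessions.items():
            d = _session_dir(root, sub.subject_id, session)
            stem = f"sub-{sub.subject_id}_ses-{session}"
            write_events_tsv(ses.trials, d / f"{stem}_events.tsv")
            pd.DataFrame(ses.bold).to_csv(d / f"{stem}_roi-bold.csv", index=False)
            truth = {
                "alpha": ses.params_true.alpha,
                "beta": ses.params_true.beta,
                "coupling": ses.coupling,
                "tr_s": tr_s,
            }
            (d / f"{stem}_truth.json").write_text(json.dumps(truth, indent=1))
    pd.DataFrame(prows).to_csv(root / "participants.tsv", sep="\t", index=False)


def read_cohort_tree(root) -> List[SubjectData]:
    """Reload a ROI-mode cohort tree written by :func:`write_cohort_tree`."""
    root = Path(root)
    participants = pd.read_csv(root / "participants.tsv", sep="\t", na_values=[_NA])
    subjects = []
    for _, prow in participants.iterrows():
        sid = prow["participant_id"]
        sessions: Dict[str, SessionData] = {}
        for ses_dir in sorted((root / f"sub-{sid}").glob("ses-*")):
            session = ses_dir.name.split("-", 1)[1]
            stem = f"sub-{sid}_ses-{session}"
            trials = read_events_tsv(ses_dir / f"{stem}_events.tsv")
            bold_df = pd.read_csv(ses_dir / f"{stem}_roi-bold.csv")
            truth = json.loads((ses_dir / f"{stem}_truth.json").read_text())
            sessions[session] = SessionData(
                trials,
                {c: bold_df[c].to_numpy() for c in bold_df.columns},
                QParams(truth["alpha"], truth["beta"]),
                truth["coupling"],
            )
        traits = {
            k: float(prow[k])
            for k in prow.index
            if k.startswith(("srq", "ybocs")) and not pd.isna(prow[k])
        }
        subjects.append(
            SubjectData(
                subject_id=sid,
                group=prow["group"],
                session_order=tuple(prow["session_order"].split("-")),
                sessions=sessions,
                traits=traits,
                med_class=None if pd.isna(prow["med_class"]) else prow["med_class"],
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Volume mode: a desk-scale 4D rendering with embedded ground-truth ROIs.
# ---------------------------------------------------------------------------

VOLUME_SHAPE = (12, 12, 12)
#: 4 mm isotropic grid positioned so the anterior-cingulate sphere
#: (MNI 0, 42, 18; radius 14 mm) lies fully inside the field of view.
VOLUME_AFFINE = np.array(
    [
        [4.0, 0.0, 0.0, -22.0],
        [0.0, 4.0, 0.0, 20.0],
        [0.0, 0.0, 4.0, -4.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def accumbens_synthetic_mask() -> np.ndarray:
    """Synthetic stand-in for an atlas accumbens mask on the toy grid.

    A 3x3x3 voxel block in a corner of the field of view, disjoint from
    the cingulate sphere. Purely synthetic geometry — it exercises the
    mask-ROI code path, it does not approximate real anatomy.
    """
    m = np.zeros(VOLUME_SHAPE, dtype=bool)
    m[0:3, 0:3, 0:3] = True
    return m


def render_session_volume(
    ses: SessionData,
    sphere: np.ndarray,
    voxel_noise_sd: float = 0.1,
    rng: Optional[np.random.Generator] = None,
) -> nib.Nifti1Image:
    """Embed the per-ROI series into a 4D volume with voxel-level noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    n_vol = len(next(iter(ses.bold.values())))
    data = rng.normal(0.0, max(voxel_noise_sd, 1e-12), (*VOLUME_SHAPE, n_vol))
    acc = accumbens_synthetic_mask()
    data[sphere, :] += ses.bold["cingulate"]
    data[acc, :] += ses.bold["accumbens"]
    return nib.Nifti1Image(data.astype(np.float32), VOLUME_AFFINE)


def write_volume_mode(
    subjects: Sequence[SubjectData], root, seed: int = 0, voxel_noise_sd: float = 0.1
) -> None:
    """Write per-session 4D NIfTIs plus the synthetic accumbens mask."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    mask_img = nib.Nifti1Image(
        accumbens_synthetic_mask().astype(np.float32), VOLUME_AFFINE
    )
    nib.save(mask_img, root / "accumbens_synthetic_mask.nii")
    from .roi import RoiSpec, sphere_mask

    sphere = sphere_mask(
        RoiSpec("cingulate", "sphere", (0.0, 42.0, 18.0), 14.0),
        VOLUME_AFFINE,
        VOLUME_SHAPE,
    )
    ss = np.random.SeedSequence(seed)
    for sub, sub_ss in zip(subjects, ss.spawn(len(subjects))):
        for session, ses_ss in zip(sub.sessions, sub_ss.spawn(len(sub.sessions))):
            d = _session_dir(root, sub.subject_id, session)
            img = render_session_volume(
                sub.sessions[session],
                sphere,
                voxel_noise_sd,
                np.random.default_rng(ses_ss),
            )
            nib.save(img, d / f"sub-{sub.subject_id}_ses-{session}_bold.nii")
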