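"""Plain-text readers and writers for cohorts, time-courses and motion files.

Cohort directory layout:

* ``<subject>_timecourses.tsv`` — T rows x C columns, header row of component
  ids;
* ``rp_<subject>.txt`` — SPM-dialect realignment parameters, 6
  whitespace-separated columns (translations mm, rotations radians);
* ``<subject>_states.txt`` — ground-truth latent state labels (one per TR);
* ``cp_<pid>.tsv`` — ground-truth CP correlation matrices;
* ``manifest.json`` — subject ids, groups, genders, seed, file paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, CohortConfig, GroundTruthCP, StateSequence, SubjectRecord

__all__ = [
    "write_timecourses",
    "read_timecourses",
    "write_motion",
    "read_motion",
    "write_cohort",
    "read_cohort",
]


def write_timecourses(tc: np.ndarray, path: str | Path, component_ids=None) -> None:
    tc = np.asarray(tc)
    if component_ids is None:
        component_ids = [f"comp_{i:02d}" for i in range(tc.shape[1])]
    pd.DataFrame(tc, columns=component_ids).to_csv(path, sep="\t", index=False)


def read_timecourses(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=None, engine="python")
    return df.to_numpy(dtype=float), list(df.columns)


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(motion), fmt="%.10e")


def read_motion(path: str | Path, rotations_degrees: bool = False) -> np.ndarray:
    """Read an SPM-style rp_*.txt file; optionally convert degree rotations."""
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise ValueError(f"realignment file must have 6 columns, got {motion.shape[1]}")
    if rotations_degrees:
        motion = motion.copy()
        motion[:, 3:] = np.radians(motion[:, 3:])
    return motion


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cohort.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cohort.config).items()},
        "ground_truth_cps": [],
        "subjects": [],
    }
    for cp in cohort.cps:
        cp_path = out_dir / f"cp_{cp.pattern_id}.tsv"
        np.savetxt(cp_path, cp.correlation_matrix, fmt="%.10e", delimiter="\t")
        manifest["ground_truth_cps"].append(cp_path.name)
    for sub in cohort.subjects:
        tc_path = out_dir / f"{sub.subject_id}_timecourses.tsv"
        rp_path = out_dir / f"rp_{sub.subject_id}.txt"
        st_path = out_dir / f"{sub.subject_id}_states.txt"
        write_timecourses(sub.tc, tc_path)
        write_motion(sub.motion, rp_path)
        np.savetxt(st_path, sub.states.labels, fmt="%d")
        manifest["subjects"].append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "gender": sub.gender,
                "TR": sub.TR,
                "timecourses": tc_path.name,
                "motion": rp_path.name,
                "states": st_path.name,
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    if "group_names" in cfg_dict:
        cfg_dict["group_names"] = tuple(cfg_dict["group_names"])
    config = CohortConfig(**cfg_dict)
    cps = []
    for i, name in enumerate(manifest["ground_truth_cps"], start=1):
        R = np.loadtxt(in_dir / name, delimiter="\t")
        cps.append(GroundTruthCP(pattern_id=i, correlation_matrix=R))
    cohort = Cohort(config=config, cps=cps)
    for s in manifest["subjects"]:
        tc, _ = read_timecourses(in_dir / s["timecourses"])
        motion = read_motion(in_dir / s["motion"])
        labels = np.loadtxt(in_dir / s["states"], dtype=int)
        cohort.subjects.append(
            SubjectRecord(
                subject_id=s["subject_id"],
                group=s["group"],
                gender=s["gender"],
                tc=tc,
                motion=motion,
                TR=s["TR"],
                states=StateSequence(labels=np.atleast_1d(labels)),
            )
        )
    return cohort
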