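"""Simulate the two-group study cohort with known switching dynamics.

Generates the default synthetic design — 18 "expert" vs 20 "novice"
subjects, 37 network components, 200 volumes at TR = 2 s, five latent
connectivity patterns, per-TR switch rates 0.10 vs 0.02, Table-style motion
(mean FD 0.14 vs 0.16 mm) — writes the raw cohort (time-course tables,
realignment files, ground truth) under scratch/cohort/ and a per-subject
summary table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

import chronnectome as cn
from chronnectome.io import write_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]

cohort = cn.generate_cohort(cn.CohortConfig(seed=SEED))
write_cohort(cohort, ROOT / "scratch" / "cohort")

rows = []
for sub in cohort.subjects:
    summary = cn.compute_fd_power(sub.motion)
    rows.append({
        "subject_id": sub.subject_id,
        "group": sub.group,
        "gender": sub.gender,
        "mean_fd_mm": round(summary.mean_fd, 4),
        "n_latent_states_visited": len(set(sub.states.labels)),
        "n_latent_transitions": int((sub.states.labels[1:] != sub.states.labels[:-1]).sum()),
    })
df = pd.DataFrame(rows)
out = ROOT / "results"
out.mkdir(exist_ok=True)
df.to_csv(out / "cohort_summary.csv", index=False)

print(f"simulated {len(df)} subjects (seed {SEED}); raw data in scratch/cohort/")
print(df.groupby("group")[["mean_fd_mm", "n_latent_transitions"]].mean().round(3))
print("expert subjects switch latent connectivity patterns ~5x more often, by design")
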