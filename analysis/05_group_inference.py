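"""Group comparison of the meta-state fluidity metrics.

Fits the GLM (group + gender + mean FD) for each of the four metrics,
corrects the four group p-values together with Benjamini-Hochberg FDR, and
writes the inference report. The same comparison is repeated at every model
order of the 4..8 sweep (uncorrected, robustness view).
"""

from pathlib import Path

import pandas as pd

from chronnectome.stats import run_inference, write_report

ROOT = Path(__file__).resolve().parents[1]
metrics = pd.read_csv(ROOT / "results" / "metrics.csv")
report = run_inference(metrics)
write_report(report, ROOT / "results")

print("k=5 group GLM (gender and mean FD as nuisance covariates):")
for r in report["glm"]:
    means = {g: f"{m:.1f} ± {s:.1f}" for g, (m, s) in r["group_means_sds"].items()}
    print(f"  {r['metric']:15s} {means}  p={r['p_raw']:.4f}  p_fdr={r['p_fdr']:.4f}")

sweep = pd.read_csv(ROOT / "results" / "metrics_sweep.csv")
print("\nmodel-order sweep, expert-minus-novice mean differences:")
for k, sub in sweep.groupby("k"):
    g = sub.groupby("group")[["n_states", "n_changes", "total_distance"]].mean()
    d = g.loc["expert"] - g.loc["novice"]
    print(f"  k={k}: n_states {d['n_states']:+.1f}  n_changes {d['n_changes']:+.1f}  "
          f"total_distance {d['total_distance']:+.1f}")
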