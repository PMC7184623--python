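"""Group-level inference on the meta-state fluidity metrics.

A general linear model (OLS) tests the group effect on each of the four
metrics with gender and mean framewise displacement as nuisance covariates;
the four group p-values are corrected together with the Benjamini-Hochberg
step-up FDR procedure. Partial Pearson correlations relate the metrics to
training time (within the trained group) and education (whole cohort),
residualizing both variables on the nuisance covariates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .metastates import METRIC_NAMES

__all__ = [
    "GroupTestResult",
    "fit_group_glm",
    "bh_fdr",
    "partial_pearson",
    "run_inference",
    "write_report",
]


@dataclass
class GroupTestResult:
    metric: str
    beta_group: float
    t_stat: float
    p_raw: float
    p_fdr: float | None
    group_means_sds: dict[str, tuple[float, float]]


def _encode_binary(series: pd.Series, treatment: str | None = None) -> tuple[np.ndarray, str]:
    """0/1-encode a two-level column; returns the code and the level coded 1."""
    levels = sorted(series.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 levels, got {levels}")
    if treatment is None:
        # "expert" (or the expert-like level) coded 1 so positive betas mean
        # "experts higher"; otherwise the lexicographically later level
        treatment = "expert" if "expert" in levels else levels[1]
    return (series.astype(str) == treatment).to_numpy(dtype=float), treatment


def _covariate_matrix(table: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in covariates:
        col = table[name]
        if col.dtype == object or str(col.dtype) == "category":
            if col.astype(str).nunique() < 2:  # constant factor: no information
                cols.append(np.zeros(len(table)))
            else:
                enc, _ = _encode_binary(col)
                cols.append(enc)
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def fit_group_glm(
    table: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("gender", "mean_fd"),
    group_col: str = "group",
    treatment: str | None = None,
) -> GroupTestResult:
    """OLS of one metric on [intercept, group, covariates].

    Returns the group coefficient with its two-sided t-test, plus raw
    per-group means and SDs of the metric. With constant covariates the group
    t statistic reduces to the classical pooled-variance two-sample t.
    """
    y = table[metric].to_numpy(dtype=float)
    group, treat_level = _encode_binary(table[group_col], treatment)
    Z = _covariate_matrix(table, covariates)
    X = np.column_stack([np.ones(len(y)), group, Z])
    # drop constant covariate columns (they alias the intercept)
    keep = [0, 1] + [2 + j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
    X = X[:, keep]
    if len(y) <= X.shape[1]:
        raise ValueError("not enough subjects for the design")
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"collinear design (condition number {cond:.2e})")
    fit = sm.OLS(y, X).fit()
    means = {}
    for level, sub in table.groupby(group_col, observed=True)[metric]:
        vals = sub.to_numpy(dtype=float)
        means[str(level)] = (float(vals.mean()), float(vals.std(ddof=1)))
    return GroupTestResult(
        metric=metric,
        beta_group=float(fit.params[1]),
        t_stat=float(fit.tvalues[1]),
        p_raw=float(fit.pvalues[1]),
        p_fdr=None,
        group_means_sds=means,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by OLS; the
    Pearson correlation of the residuals is tested against the t distribution
    with n - k_cov - 2 degrees of freedom. With no covariates this is the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > covariate count + 2")
    design = np.column_stack([np.ones(n), Z])
    proj = design @ np.linalg.pinv(design)
    rx = x - proj @ x
    ry = y - proj @ y
    # a variable fully explained by the covariates leaves only float noise
    if (rx**2).sum() <= 1e-24 * max((x**2).sum(), 1e-300) or (ry**2).sum() <= 1e-24 * max(
        (y**2).sum(), 1e-300
    ):
        raise ValueError("zero residual variance")
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float(rx @ ry / denom)
    df = n - k - 2
    r_clip = min(max(r, -0.999999999), 0.999999999)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sstats.t.sf(abs(t), df))
    return r, p


def run_inference(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_NAMES,
    covariates: tuple[str, ...] = ("gender", "mean_fd"),
    group_col: str = "group",
    treatment: str | None = None,
) -> dict:
    """Full group inference: per-metric GLM, family-wise BH-FDR, correlations.

    The FDR family is exactly the listed metrics (default: the four fluidity
    indexes). If ``training_hours`` exists, each metric is partially
    correlated with it within the treatment group (covariates: gender, FD);
    if ``education_years`` exists, across the whole cohort (covariates:
    gender, group, FD). Missing optional covariates skip the corresponding
    correlations with a notice.
    """
    results = [
        fit_group_glm(table, m, covariates=covariates, group_col=group_col, treatment=treatment)
        for m in metrics
    ]
    p_fdr = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, p_fdr):
        r.p_fdr = float(q)
    report: dict = {
        "glm": [asdict(r) for r in results],
        "fdr_family_size": len(results),
        "correlations": {},
        "notices": [],
    }
    _, treat_level = _encode_binary(table[group_col], treatment)
    if "training_hours" in table.columns:
        sub = table[table[group_col].astype(str) == treat_level]
        Z = _covariate_matrix(sub, ("gender", "mean_fd"))
        report["correlations"]["training_hours"] = {
            m: dict(zip(("r", "p"), partial_pearson(
                sub[m].to_numpy(dtype=float), sub["training_hours"].to_numpy(dtype=float), Z
            )))
            for m in metrics
        }
    else:
        report["notices"].append("training_hours absent: training correlations skipped")
    if "education_years" in table.columns:
        genc, _ = _encode_binary(table[group_col], treatment)
        Z = np.column_stack([_covariate_matrix(table, ("gender", "mean_fd")), genc])
        report["correlations"]["education_years"] = {
            m: dict(zip(("r", "p"), partial_pearson(
                table[m].to_numpy(dtype=float), table["education_years"].to_numpy(dtype=float), Z
            )))
            for m in metrics
        }
    else:
        report["notices"].append("education_years absent: education correlations skipped")
    return report


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the inference report as JSON plus a Markdown summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "inference_report.json"
    json_path.write_text(json.dumps(report, indent=2, default=float))
    lines = [
        "| Metric | " + " | ".join(
            f"{g} mean ± sd" for g in sorted(report["glm"][0]["group_means_sds"])
        ) + " | p | p (FDR) |",
        "|---|" + "---|" * (len(report["glm"][0]["group_means_sds"]) + 2),
    ]
    for r in report["glm"]:
        cells = [
            f"{m:.1f} ± {s:.1f}"
            for _, (m, s) in sorted(r["group_means_sds"].items())
        ]
        lines.append(
            f"| {r['metric']} | " + " | ".join(cells)
            + f" | {r['p_raw']:.4f} | {r['p_fdr']:.4f} |"
        )
    md_path = out_dir / "inference_report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return json_path, md_path
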