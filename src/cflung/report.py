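"""Cohort-level report: the study-style summary tables from a cohort CSV.

Emits group-characteristic, MBW-index and MRI-metric summaries, the
mFLD-vs-MBW correlation matrix, and the two hierarchical regressions
(Scond* on central mFLD metrics; LCI on the regional mFLD metrics), as
CSV files plus a plain-text report.  All outputs are deterministic
functions of the input table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import PipelineConfig, load_cohort_csv
from .stats import compare_groups, hierarchical_regression, pearson

def plot_association(
    cohort: pd.DataFrame,
    x: str,
    y: str,
    out_path,
    group_col: str = "group",
) -> None:
    """Scatter of ``y`` vs ``x`` by group with the pooled OLS line and a
    95% confidence band on the mean prediction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import statsmodels.api as sm

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for group, marker in (("control", "o"), ("CF", "s")):
        sub = cohort[cohort[group_col] == group]
        ax.scatter(sub[x], sub[y], marker=marker, label=group, alpha=0.8)
    xs = cohort[x].to_numpy(float)
    ys = cohort[y].to_numpy(float)
    model = sm.OLS(ys, sm.add_constant(xs)).fit()
    grid = np.linspace(xs.min(), xs.max(), 100)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    ax.plot(grid, pred["mean"], color="k", lw=1)
    ax.fill_between(grid, pred["mean_ci_lower"], pred["mean_ci_upper"],
                    color="k", alpha=0.15, lw=0)
    r = pearson(xs, ys)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(f"R = {r['R']:.2f}, p = {r['p']:.3g}", fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


_CHARACTERISTIC_VARS = (
    "age_yr",
    "weight_kg",
    "height_cm",
    "bmi",
    "fev1_pct",
    "fvc_pct",
    "fef2575_pct",
)
_MBW_VARS = ("lci", "scond_star", "sacin_star")
_MRI_VARS = (
    "central_mfld_frc",
    "central_mfld_tlc",
    "central_mfld_ratio",
    "peripheral_mfld_frc",
    "peripheral_mfld_tlc",
    "peripheral_mfld_ratio",
)
_CORR_PREDICTORS = _MRI_VARS
_CORR_OUTCOMES = ("fev1_pct", "scond_star", "sacin_star", "lci")


def _group_summary(df: pd.DataFrame, variables: Sequence[str], welch: bool) -> pd.DataFrame:
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        cmp = compare_groups(df, var, welch=welch)
        rows.append(
            {
                "variable": var,
                "control_mean": cmp.means["control"],
                "control_sd": cmp.sds["control"],
                "cf_mean": cmp.means["CF"],
                "cf_sd": cmp.sds["CF"],
                "t": cmp.t,
                "p": cmp.p,
            }
        )
    return pd.DataFrame(rows)


def _correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    subsets = {"all": df, "cf_only": df[df["group"] == "CF"]}
    for subset_name, sub in subsets.items():
        for pred in _CORR_PREDICTORS:
            for out in _CORR_OUTCOMES:
                if pred not in sub.columns or out not in sub.columns:
                    continue
                pair = sub[[pred, out]].dropna()
                res = pearson(pair[pred], pair[out])
                rows.append(
                    {
                        "subset": subset_name,
                        "mri_metric": pred,
                        "outcome": out,
                        "R": res["R"],
                        "p": res["p"],
                        "n": res["n"],
                    }
                )
    return pd.DataFrame(rows)


def _regression_frames(df: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    cf = df[df["group"] == "CF"]
    out = {}
    for name, dependent, blocks in (
        (
            "regression_scond",
            "scond_star",
            [["central_mfld_tlc"], ["central_mfld_ratio"]],
        ),
        (
            "regression_lci",
            "lci",
            [["central_mfld_ratio"], ["peripheral_mfld_frc"], ["peripheral_mfld_ratio"]],
        ),
    ):
        res = hierarchical_regression(cf, dependent, blocks)
        rows = []
        for k, step in enumerate(res.steps, start=1):
            rows.append(
                {
                    "step": k,
                    "predictor": "(step)",
                    "b": np.nan,
                    "beta": np.nan,
                    "t": np.nan,
                    "sr2": np.nan,
                    "R": step.R,
                    "R2": step.R2,
                    "dR2": step.dR2,
                    "F_change": step.F_change,
                    "p_change": step.p_change,
                }
            )
            for pred, c in step.coefficients.iterrows():
                rows.append(
                    {
                        "step": k,
                        "predictor": pred,
                        "b": c["b"],
                        "beta": c["beta"],
                        "t": c["t"],
                        "sr2": c["sr2"],
                        "R": np.nan,
                        "R2": np.nan,
                        "dR2": np.nan,
                        "F_change": np.nan,
                        "p_change": np.nan,
                    }
                )
        out[name] = pd.DataFrame(rows)
    return out


def reproduce_tables(
    cohort_csv,
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> Dict[str, pd.DataFrame]:
    """Build all summary tables from a cohort CSV and write them to disk.

    Returns the tables as DataFrames keyed by name; writes one CSV per
    table plus ``report.txt``.  Byte-identical across reruns on the same
    input.
    """
    config = config or PipelineConfig()
    df = load_cohort_csv(cohort_csv)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables: Dict[str, pd.DataFrame] = {}
    tables["characteristics"] = _group_summary(df, _CHARACTERISTIC_VARS, config.welch)
    tables["mbw_indices"] = _group_summary(df, _MBW_VARS, config.welch)
    tables["mri_metrics"] = _group_summary(df, _MRI_VARS, config.welch)
    tables["correlations"] = _correlation_table(df)
    tables.update(_regression_frames(df))

    lines = [f"Cohort report  (n = {len(df)}; input = {Path(cohort_csv).name})", ""]
    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g")
        lines.append(f"== {name} ==")
        lines.append(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    (out_dir / "report.txt").write_text("\n".join(lines))
    return tables
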