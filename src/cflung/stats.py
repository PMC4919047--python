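"""Cohort statistics: group comparisons, mixed-design repeated-measures
ANOVA, Pearson correlations, and hierarchical multiple regression.

The hierarchical regression reports, per step, R, R^2, the R^2 change
over the previous step with its F test, and per predictor the
unstandardised (b) and standardised (beta) coefficients, t statistics,
squared semi-partial correlations (sr^2, the unique variance share) and
variance inflation factors (VIF, collinearity diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

import statsmodels.api as sm

__all__ = [
    "compare_groups",
    "rm_anova",
    "pearson",
    "HierarchicalRegression",
    "hierarchical_regression",
    "RegressionResult",
]


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p: float
    means: Dict[str, float]
    sds: Dict[str, float]
    ns: Dict[str, int]


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided Student's t-test (pooled variance) between the two groups.

    ``welch=True`` switches to the unequal-variance form.
    """
    if variable not in cohort.columns:
        raise ValueError(f"unknown variable {variable!r}")
    levels = list(pd.unique(cohort[group_col]))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    samples = {
        g: cohort.loc[cohort[group_col] == g, variable].dropna().to_numpy()
        for g in levels
    }
    for g, x in samples.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing values")
    a, b = (samples[g] for g in levels)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = (
        len(a) + len(b) - 2
        if not welch
        else float(res.df) if hasattr(res, "df") else np.nan
    )
    return GroupComparison(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        means={g: float(np.mean(x)) for g, x in samples.items()},
        sds={g: float(np.std(x, ddof=1)) for g, x in samples.items()},
        ns={g: int(len(x)) for g, x in samples.items()},
    )


def _score_anova(x: np.ndarray, g: np.ndarray, test_mean: bool):
    """F tests on a per-subject contrast score: the score's grand mean
    (within-factor main effect) and its group differences (interaction),
    both against the within-group score variance."""
    levels = pd.unique(g)
    n = len(x)
    a = len(levels)
    group_means = np.array([x[g == lv].mean() for lv in levels])
    group_ns = np.array([(g == lv).sum() for lv in levels])
    ss_err = float(sum(((x[g == lv] - x[g == lv].mean()) ** 2).sum() for lv in levels))
    df_err = n - a
    ms_err = ss_err / df_err
    out = {}
    if test_mean:
        ss_mean = n * x.mean() ** 2
        f = ss_mean / ms_err if ms_err > 0 else (0.0 if ss_mean == 0 else np.inf)
        out["main"] = (f, 1, df_err, float(sps.f.sf(f, 1, df_err)))
    ss_group = float(np.sum(group_ns * group_means**2) - n * x.mean() ** 2)
    dfg = a - 1
    f = (ss_group / dfg) / ms_err if ms_err > 0 else (0.0 if ss_group == 0 else np.inf)
    out["group"] = (f, dfg, df_err, float(sps.f.sf(f, dfg, df_err)))
    return out


def rm_anova(
    long: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "subject",
    group_col: str = "group",
    within: Tuple[str, str] = ("volume", "region"),
) -> pd.DataFrame:
    """Mixed-design ANOVA: two 2-level within factors, one between factor.

    Expects a long table with one row per subject x within-cell.
    Subjects missing any of the four within cells are dropped with a
    warning.  Each within effect is tested on the corresponding
    per-subject difference score against its own subject-by-factor error
    term (the standard univariate decomposition; with two levels per
    factor sphericity holds trivially).  Returns a table of F, df and p
    per effect.
    """
    w1, w2 = within
    for col in (value_col, subject_col, group_col, w1, w2):
        if col not in long.columns:
            raise ValueError(f"missing column {col!r}")
    lv1 = sorted(pd.unique(long[w1]))
    lv2 = sorted(pd.unique(long[w2]))
    if len(lv1) != 2 or len(lv2) != 2:
        raise ValueError("each within factor must have exactly 2 levels")

    wide = long.pivot_table(
        index=[subject_col, group_col], columns=[w1, w2], values=value_col
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} subject(s) with incomplete cells")
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete subjects")
    g = complete.index.get_level_values(group_col).to_numpy()

    y = {
        (i, j): complete[(lv1[i], lv2[j])].to_numpy() for i in (0, 1) for j in (0, 1)
    }
    m = (y[0, 0] + y[0, 1] + y[1, 0] + y[1, 1]) / 4.0
    d1 = ((y[1, 0] + y[1, 1]) - (y[0, 0] + y[0, 1])) / 2.0
    d2 = ((y[0, 1] + y[1, 1]) - (y[0, 0] + y[1, 0])) / 2.0
    d12 = (y[1, 1] - y[1, 0]) - (y[0, 1] - y[0, 0])

    rows = []
    between = _score_anova(m, g, test_mean=False)["group"]
    rows.append((group_col, *between))
    for name, score in ((w1, d1), (w2, d2), (f"{w1}:{w2}", d12)):
        res = _score_anova(score, g, test_mean=True)
        rows.append((name, *res["main"]))
        rows.append((f"{group_col}:{name}", *res["group"]))
    return pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "p"]
    ).set_index("effect")


def pearson(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Sample Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return {"R": float(r), "p": float(p), "n": int(len(x))}


@dataclass
class StepResult:
    predictors: List[str]
    added: List[str]
    R: float
    R2: float
    dR2: float
    F_change: float
    df_num: int
    df_den: int
    p_change: float
    coefficients: pd.DataFrame  # index: predictor; columns: b, beta, t, p, sr2, vif


@dataclass
class RegressionResult:
    dependent: str
    n: int
    steps: List[StepResult]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.steps, start=1):
            rows.append(
                {
                    "step": k,
                    "predictors": " + ".join(s.predictors),
                    "R": s.R,
                    "R2": s.R2,
                    "dR2": s.dR2,
                    "F_change": s.F_change,
                    "df": f"({s.df_num}, {s.df_den})",
                    "p_change": s.p_change,
                }
            )
        return pd.DataFrame(rows)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared)


class HierarchicalRegression(BaseEstimator, RegressorMixin):
    """Blockwise (hierarchical) OLS regression.

    Predictor blocks are entered cumulatively; each step reports the
    variance newly explained (dR2) with its F-change test, and per
    predictor b, standardised beta, t, sr^2 (the R^2 drop when that
    predictor alone is removed from the step's model) and VIF.

    Parameters
    ----------
    blocks : sequence of sequence of str
        Ordered predictor blocks (column names).
    vif_threshold : float
        Collinearity flag threshold; VIFs above it are reported in
        ``vif_flags_``.

    Attributes
    ----------
    result_ : RegressionResult
    coef_ : ndarray
        Final-step coefficients (excluding intercept).
    intercept_ : float
    """

    def __init__(
        self, blocks: Sequence[Sequence[str]], vif_threshold: float = 5.0
    ) -> None:
        self.blocks = blocks
        self.vif_threshold = vif_threshold

    def fit(self, X: pd.DataFrame, y, dependent_name: str = "y") -> "HierarchicalRegression":
        blocks = [list(b) for b in self.blocks]
        if not blocks or any(len(b) == 0 for b in blocks):
            raise ValueError("blocks must be non-empty lists of column names")
        cols = [c for b in blocks for c in b]
        if len(set(cols)) != len(cols):
            raise ValueError(f"duplicate predictor across blocks in {cols}")
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"unknown predictor column(s): {missing}")
        y = np.asarray(y, dtype=float)
        data = X[cols].to_numpy(dtype=float)
        keep = np.isfinite(data).all(axis=1) & np.isfinite(y)
        data, y = data[keep], y[keep]
        n = len(y)
        if n <= len(cols) + 1:
            raise ValueError(f"n = {n} too small for {len(cols)} predictors")
        sd_y = y.std(ddof=1)
        if sd_y == 0:
            raise ValueError("dependent variable has zero variance")

        steps: List[StepResult] = []
        vif_flags: List[Tuple[int, str, float]] = []
        r2_prev = 0.0
        used: List[str] = []
        for block in blocks:
            used = used + block
            idx = [cols.index(c) for c in used]
            Xs = data[:, idx]
            if np.linalg.matrix_rank(sm.add_constant(Xs)) < Xs.shape[1] + 1:
                raise ValueError(f"singular design matrix with predictors {used}")
            model = sm.OLS(y, sm.add_constant(Xs)).fit()
            r2 = float(model.rsquared)
            k = Xs.shape[1]
            q = len(block)
            df_den = n - k - 1
            dr2 = r2 - r2_prev
            denom = (1 - r2) / df_den
            f_change = (dr2 / q) / denom if denom > 0 else np.inf
            p_change = float(sps.f.sf(f_change, q, df_den))

            coef_rows = {}
            for j, name in enumerate(used):
                b = float(model.params[j + 1])
                t = float(model.tvalues[j + 1])
                p = float(model.pvalues[j + 1])
                beta = b * data[:, cols.index(name)].std(ddof=1) / sd_y
                others = [jj for jj in idx if jj != cols.index(name)]
                r2_wo = _ols_r2(data[:, others], y) if others else 0.0
                sr2 = r2 - r2_wo
                if k > 1:
                    r2_j = _ols_r2(
                        data[:, others], data[:, cols.index(name)]
                    )
                    vif = 1.0 / (1.0 - r2_j) if r2_j < 1 else np.inf
                else:
                    vif = 1.0
                if vif > self.vif_threshold:
                    vif_flags.append((len(steps) + 1, name, vif))
                coef_rows[name] = {
                    "b": b, "beta": float(beta), "t": t, "p": p,
                    "sr2": float(sr2), "vif": float(vif),
                }
            steps.append(
                StepResult(
                    predictors=list(used),
                    added=list(block),
                    R=float(np.sqrt(max(r2, 0.0))),
                    R2=r2,
                    dR2=float(dr2),
                    F_change=float(f_change),
                    df_num=q,
                    df_den=df_den,
                    p_change=p_change,
                    coefficients=pd.DataFrame(coef_rows).T,
                )
            )
            r2_prev = r2

        self.result_ = RegressionResult(dependent=dependent_name, n=n, steps=steps)
        self.vif_flags_ = vif_flags
        self.coef_ = model.params[1:]
        self.intercept_ = float(model.params[0])
        self._cols = cols
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit before predict")
        return self.intercept_ + X[self._cols].to_numpy(dtype=float) @ self.coef_


def hierarchical_regression(
    cohort: pd.DataFrame,
    dependent: str,
    blocks: Sequence[Sequence[str]],
    vif_threshold: float = 5.0,
) -> RegressionResult:
    """Functional wrapper over :class:`HierarchicalRegression`."""
    hr = HierarchicalRegression(blocks=blocks, vif_threshold=vif_threshold)
    hr.fit(cohort, cohort[dependent], dependent_name=dependent)
    return hr.result_
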