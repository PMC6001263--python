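"""Derived model-parameter summaries and cohort statistics.

Summarizes the tuned inhibitory weights J_i per subject (whole-brain, tumor,
and non-tumor medians — medians because the J_i distribution is heavily
skewed), removes the confounding effect of region size on J_i, residualizes
outcomes on nuisance covariates with control-referenced z-scoring, and runs
the group comparisons (ANOVA / Kruskal-Wallis / Levene with an automatic
normality gate) and covariate-adjusted association models with classical
eta-squared effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "JSummary",
    "median_j",
    "size_correct_j",
    "residualize_to_z",
    "group_compare",
    "association",
    "GroupTestReport",
]

GROUPS = ("CON", "MEN", "GLI")


@dataclass(frozen=True)
class JSummary:
    """Per-subject medians of the local inhibitory weights (nA)."""

    j_brain: float
    j_tumor: float | None
    j_nontumor: float


@dataclass(frozen=True)
class GroupTestReport:
    family: str        # test actually run: anova | kruskal | levene
    statistic: float
    df: tuple
    p_value: float
    posthoc: pd.DataFrame | None = None


def median_j(j: np.ndarray, region_table: pd.DataFrame,
             group: str = "CON") -> JSummary:
    """Median J_i over the whole brain, tumor nodes, and non-tumor nodes.

    For controls (no tumor nodes) the non-tumor median equals the whole-brain
    median and the tumor median is absent.  A patient subject whose region
    table flags no tumor node is inconsistent and raises.
    """
    j = np.asarray(j, dtype=float)
    if len(j) != len(region_table):
        raise ValueError("j and region_table must be conformable")
    tumor = region_table["is_tumor"].to_numpy(dtype=bool)
    j_brain = float(np.median(j))
    if group == "CON":
        if tumor.any():
            raise ValueError("control subject has tumor-flagged regions")
        return JSummary(j_brain=j_brain, j_tumor=None, j_nontumor=j_brain)
    if not tumor.any():
        raise ValueError(f"{group} subject has no tumor-flagged regions")
    return JSummary(
        j_brain=j_brain,
        j_tumor=float(np.median(j[tumor])),
        j_nontumor=float(np.median(j[~tumor])),
    )


def size_correct_j(j_values, sizes, subject_ids=None) -> np.ndarray:
    """Residuals of J_i after regressing out region size (OLS with intercept).

    By default observations are pooled across all supplied regions/subjects in
    a single fit.  Passing ``subject_ids`` fits the regression within each
    subject instead, which removes subject-level scale offsets (e.g. from
    different fitted couplings) before regional contrasts.  Residuals come
    back in input order.
    """
    j = np.asarray(j_values, dtype=float)
    s = np.asarray(sizes, dtype=float)
    if j.shape != s.shape or j.ndim != 1:
        raise ValueError("j_values and sizes must be 1-D and conformable")
    if subject_ids is not None:
        ids = np.asarray(subject_ids)
        if ids.shape != j.shape:
            raise ValueError("subject_ids must be conformable with j_values")
        out = np.empty_like(j)
        for uid in pd.unique(ids):
            m = ids == uid
            out[m] = size_correct_j(j[m], s[m])
        return out
    if len(j) < 3:
        raise ValueError("need at least 3 observations")
    if s.std() == 0:
        raise ValueError("region sizes have zero variance")
    X = np.column_stack([np.ones_like(s), s])
    beta, *_ = np.linalg.lstsq(X, j, rcond=None)
    return j - X @ beta


def residualize_to_z(outcome, covariates, control_mask) -> np.ndarray:
    """Confound-corrected outcome expressed in control-referenced z units.

    Fits outcome ~ covariates (main effects + intercept) over all subjects,
    then standardizes the residuals by the mean and SD of the residuals of
    control subjects, so a control population scores 0 +/- 1 by construction.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates).to_numpy(dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 control subjects")
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few subjects for the covariate design")
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        cols = pd.DataFrame(covariates).columns.tolist()
        raise ValueError(f"rank-deficient covariate design (columns {cols})")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    mu = resid[mask].mean()
    sd = resid[mask].std(ddof=1)
    if sd == 0:
        raise ValueError("control residuals have zero variance")
    return (resid - mu) / sd


def _anova_df(values_by_group):
    k = len(values_by_group)
    n = sum(len(v) for v in values_by_group)
    return (k - 1, n - k)


def group_compare(values, groups, family: str = "auto",
                  alpha_normality: float = 0.05) -> GroupTestReport:
    """Compare a per-subject quantity across groups.

    family 'anova' runs one-way ANOVA with Tukey HSD post-hoc, 'kruskal' the
    Kruskal-Wallis rank sum test, 'levene' the equality-of-variances test, and
    'auto' picks Kruskal-Wallis whenever a Shapiro-Wilk check rejects
    normality (at ``alpha_normality``) in any group, ANOVA otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    by_group = [values[groups == g] for g in labels]
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in by_group):
        raise ValueError("every group needs at least 2 members")
    if family == "auto":
        normal = all(
            len(v) < 3 or sps.shapiro(v).pvalue >= alpha_normality for v in by_group
        )
        family = "anova" if normal else "kruskal"
    if family == "anova":
        res = sps.f_oneway(*by_group)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey = pairwise_tukeyhsd(values, groups)
        posthoc = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return GroupTestReport("anova", float(res.statistic), _anova_df(by_group),
                               float(res.pvalue), posthoc)
    if family == "kruskal":
        res = sps.kruskal(*by_group)
        return GroupTestReport("kruskal", float(res.statistic),
                               (len(by_group) - 1,), float(res.pvalue))
    if family == "levene":
        res = sps.levene(*by_group, center="median")
        return GroupTestReport("levene", float(res.statistic),
                               _anova_df(by_group), float(res.pvalue))
    raise ValueError(f"unknown family {family!r}")


def association(outcome, predictor, covariates=None) -> dict:
    """Linear association between an outcome and a predictor, with covariates.

    Ordinary least squares of outcome on predictor (+ covariate main effects).
    Returns the predictor's t statistic, two-sided p value, slope, and the
    classical eta-squared SS_predictor / SS_total, where SS_predictor is the
    extra sum of squares explained by the predictor on top of the covariates.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        Z = np.empty((len(y), 0))
    else:
        Z = pd.DataFrame(covariates).to_numpy(dtype=float)
    if len(y) < Z.shape[1] + 3:
        raise ValueError("too few subjects for the design")
    X_full = sm.add_constant(np.column_stack([x, Z]))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("collinear design matrix")
    fit_full = sm.OLS(y, X_full).fit()
    X_red = sm.add_constant(Z) if Z.shape[1] else np.ones((len(y), 1))
    fit_red = sm.OLS(y, X_red).fit()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_pred = float(fit_red.ssr - fit_full.ssr)
    return {
        "slope": float(fit_full.params[1]),
        "t": float(fit_full.tvalues[1]),
        "p": float(fit_full.pvalues[1]),
        "eta_squared": 0.0 if ss_total == 0 else ss_pred / ss_total,
        "df_resid": int(fit_full.df_resid),
    }
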