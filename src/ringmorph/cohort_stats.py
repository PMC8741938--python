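"""Cohort-level statistics on slide summaries joined to clinical covariates.

The battery mirrors common practice for slide-level morphometry cohorts:

* two-group comparisons by Welch/pooled t-test and Mann-Whitney U;
* multi-group comparisons by Kruskal-Wallis (tie-corrected) with optional
  Tukey-HSD pairwise post-hoc tests;
* dichotomization of continuous markers at the Youden-index-optimal ROC
  cutoff (J = sensitivity + specificity - 1);
* binary logistic regression for effect sizes on a binary outcome
  (e.g. lymph-node involvement) and proportional-odds ordinal logistic
  regression for ordered outcomes (e.g. T stage 1-4).

A note on naming: clinical reports in this setting often label the
logistic effect size "HR"; the quantity computed by a logistic model is
an odds ratio, ``exp(coefficient)``, with Wald 95% CIs
``exp(coef ± 1.96·SE)``.  We keep the ``hr`` column name for continuity
with such reports but document it as an odds ratio.  No survival model
is involved.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "YoudenResult",
    "MultiGroupResult",
    "two_group_test",
    "multi_group_test",
    "youden_cutoff",
    "binary_logit_hr",
    "ordinal_logit",
    "forest_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EffectEstimate:
    """One model effect: odds ratio (reported as ``hr``), Wald 95% CI, p."""

    variable: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float = np.nan
    se: float = np.nan
    cutoff: Optional[float] = None
    n: int = 0
    note: str = ""


@dataclass
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    j: float


@dataclass
class MultiGroupResult:
    statistic: float
    p: float
    posthoc: Optional[pd.DataFrame] = None


def _clean_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return a, b


def two_group_test(
    values_a, values_b, method: str = "t", *, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample test; ``method`` is ``"t"`` (Welch by default,
    pooled with ``equal_var=True``) or ``"mannwhitney"``."""
    a, b = _clean_pair(values_a, values_b)
    if method == "t":
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            return 0.0, 1.0  # degenerate: identical constant groups
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; expected 't' or 'mannwhitney'")


def multi_group_test(groups: Sequence, posthoc: bool = False) -> MultiGroupResult:
    """Kruskal-Wallis H (tie-corrected) over >=3 groups, with optional
    Tukey-HSD pairwise adjusted p-values."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use two_group_test for two groups")
    arrays = []
    for g in groups:
        g = np.asarray(g, float)
        g = g[~np.isnan(g)]
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
        arrays.append(g)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        result = MultiGroupResult(0.0, 1.0)
    else:
        h, p = stats.kruskal(*arrays)
        result = MultiGroupResult(float(h), float(p))
    if posthoc:
        labels = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)])
        tuk = pairwise_tukeyhsd(pooled, labels)
        result.posthoc = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        )
    return result


def youden_cutoff(scores, labels) -> YoudenResult:
    """Cutoff maximising Youden's J under the rule "positive if score >= cutoff".

    Candidate cutoffs are the midpoints between consecutive distinct
    sorted scores plus the all-positive cutoff (the minimum score), so J
    is never negative; ties resolve to the smallest cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    distinct = np.unique(scores)
    candidates = np.concatenate([[distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0])
    # sensitivity/specificity at each candidate, vectorised
    pred = scores[None, :] >= candidates[:, None]
    sens = (pred & pos[None, :]).sum(axis=1) / n_pos
    spec = (~pred & neg[None, :]).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    idx = int(np.flatnonzero(j >= best_j - 1e-12).min())  # smallest cutoff among ties
    return YoudenResult(float(candidates[idx]), float(sens[idx]), float(spec[idx]), float(j[idx]))


def _as_design(predictors, names: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(float), list(predictors.columns)
    arr = np.asarray(predictors, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{i + 1}" for i in range(arr.shape[1])]
    return arr, list(names)


def _wald_estimates(
    names: list[str], params: np.ndarray, bse: np.ndarray, pvalues: np.ndarray, n: int
) -> list[EffectEstimate]:
    out = []
    for name, coef, se, p in zip(names, params, bse, pvalues):
        out.append(
            EffectEstimate(
                variable=name,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                p=float(p),
                coef=float(coef),
                se=float(se),
                n=n,
            )
        )
    return out


def _separation_estimates(names: list[str], coefs: np.ndarray, n: int) -> list[EffectEstimate]:
    out = []
    for name, coef in zip(names, coefs):
        out.append(
            EffectEstimate(
                variable=name,
                hr=float(np.inf if coef >= 0 else 0.0),
                ci_low=np.nan,
                ci_high=np.nan,
                p=np.nan,
                coef=float(coef),
                n=n,
                note="perfect separation",
            )
        )
    return out


def binary_logit_hr(
    outcome, predictors, names: Sequence[str] | None = None
) -> list[EffectEstimate]:
    """Binary logistic regression; effect sizes as odds ratios with Wald CIs.

    Supports univariate and multivariable designs.  Perfect separation is
    flagged on the returned estimates (infinite or zero odds ratio, NaN
    CI/p) with a warning rather than raising.
    """
    y = np.asarray(outcome, float)
    X, names = _as_design(predictors, names)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("both outcome classes must be present")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant")
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # refit without the separation check to recover coefficient signs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design)
            model.raise_on_perfect_prediction = False
            fit = model.fit(disp=0, maxiter=50, method="bfgs")
        warnings.warn("perfect separation: odds ratios are unbounded", stacklevel=2)
        return _separation_estimates(names, fit.params[1:], len(y))
    if np.abs(fit.params[1:]).max(initial=0.0) > 15:
        warnings.warn("quasi-separation: odds ratios are unstable", stacklevel=2)
        return _separation_estimates(names, fit.params[1:], len(y))
    return _wald_estimates(names, fit.params[1:], fit.bse[1:], fit.pvalues[1:], len(y))


def ordinal_logit(
    outcome, predictors, names: Sequence[str] | None = None
) -> tuple[list[EffectEstimate], np.ndarray]:
    """Proportional-odds (cumulative logit) regression for ordered outcomes.

    Returns per-predictor odds ratios with Wald CIs and p-values, plus the
    fitted cutpoint thresholds.  With exactly two outcome levels the model
    reduces to binary logistic regression (identical coefficients up to
    optimiser tolerance).
    """
    y = np.asarray(outcome)
    X, names = _as_design(predictors, names)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("ordinal outcome needs >= 2 observed levels")
    if not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("outcome must be numerically ordered (e.g. T stage 1..4)")
    y_cat = pd.Series(pd.Categorical(y, categories=levels, ordered=True))
    model = OrderedModel(y_cat, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", disp=0, maxiter=1000, gtol=1e-10)
    k = X.shape[1]
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    pvals = np.asarray(fit.pvalues)
    if np.abs(params[:k]).max(initial=0.0) > 15:
        warnings.warn("quasi-separation in ordinal fit", stacklevel=2)
        estimates = _separation_estimates(names, params[:k], len(y))
    else:
        estimates = _wald_estimates(names, params[:k], bse[:k], pvals[:k], len(y))
    thresholds = model.transform_threshold_params(params[k:])[1:-1]
    return estimates, np.asarray(thresholds)


def _corrected_2x2_estimate(name: str, y: np.ndarray, pred: np.ndarray) -> EffectEstimate:
    """Haldane-Anscombe continuity-corrected odds ratio for a 2x2 with an
    empty cell (the standard zero-cell remedy in forest plots): 0.5 is
    added to every cell, giving a finite OR, Wald CI and p."""
    a = float(((pred == 1) & (y == 1)).sum()) + 0.5
    b = float(((pred == 1) & (y == 0)).sum()) + 0.5
    c = float(((pred == 0) & (y == 1)).sum()) + 0.5
    d = float(((pred == 0) & (y == 0)).sum()) + 0.5
    coef = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(
        variable=name,
        hr=math.exp(coef),
        ci_low=math.exp(coef - Z_95 * se),
        ci_high=math.exp(coef + Z_95 * se),
        p=float(p),
        coef=coef,
        se=se,
        n=int(len(y)),
        note="continuity-corrected (0.5/cell)",
    )


def forest_table(
    cohort: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    dichotomize: bool = True,
) -> pd.DataFrame:
    """Univariate logistic effect sizes per variable, forest-plot ready.

    With ``dichotomize=True`` each variable is first cut at its
    Youden-optimal cutoff against the outcome and entered as a binary
    predictor, as in cutoff-based forest plots; otherwise the continuous
    variable is entered directly.  A dichotomized 2x2 with an empty cell
    (in-sample optimal cutoffs produce these routinely on small cohorts)
    uses the Haldane-Anscombe continuity-corrected odds ratio, noted on
    the row.  Zero-variance variables are excluded with a logged reason.
    Output rows follow the order of ``variables`` and carry log-scale
    columns for plotting.
    """
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not in cohort table")
    y_all = cohort[outcome]
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise ValueError(f"variable {var!r} not in cohort table")
        sub = cohort[[var, outcome]].dropna()
        values = sub[var].to_numpy(float)
        y = sub[outcome].to_numpy(float)
        if values.size == 0 or np.ptp(values) == 0:
            logger.info("forest_table: excluding %r (zero variance)", var)
            continue
        cutoff = None
        est = None
        if dichotomize:
            yr = youden_cutoff(values, y)
            cutoff = yr.cutoff
            predictor = (values >= cutoff).astype(float)
            if np.ptp(predictor) == 0:
                logger.info("forest_table: excluding %r (degenerate cutoff)", var)
                continue
            cells_ok = all(
                ((predictor == i) & (y == j)).any() for i in (0, 1) for j in (0, 1)
            )
            if not cells_ok:
                est = _corrected_2x2_estimate(var, y, predictor)
        else:
            predictor = values
        if est is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = binary_logit_hr(y, predictor, names=[var])[0]
        est.cutoff = cutoff
        rows.append(
            {
                "variable": var,
                "cutoff": cutoff,
                "hr": est.hr,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                "n": est.n,
                "log_hr": np.log(est.hr) if est.hr > 0 else -np.inf,
                "log_ci_low": np.log(est.ci_low) if est.ci_low > 0 else np.nan,
                "log_ci_high": np.log(est.ci_high) if est.ci_high > 0 else np.nan,
                "note": est.note,
            }
        )
    return pd.DataFrame(rows)
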