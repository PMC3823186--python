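"""Cohort-level statistical analysis plan.

Implements the test battery used to compare limb-use strategies and
region-of-interest activation between congenital, acquired and control
groups:

* normality-gated two-sample tests — Shapiro–Wilk at 0.05 on each group;
  Student's *t* (pooled variance) when both pass, Mann–Whitney *U*
  otherwise;
* one-sample *t*-tests against zero (e.g. laterality index vs. balance);
* mixed group × limb ANOVA (between factor: group; 2-level within factor:
  limb), interaction tested via the classical split-plot decomposition;
* covariate-adjusted group contrasts (univariate GLM, group effect *F*);
* Pearson and one-tailed partial correlations with nuisance covariates;
* Fisher r-to-z comparison of two independent correlations;
* planned comparisons run at a corrected α = 0.025, exploratory contrasts
  at 0.05.

Every operation returns a :class:`StatResult` recording the test actually
used, its statistic, degrees of freedom, p-value, tails, the α applied and
the decision, so a full analysis run is auditable from its output table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .io import ValidationError

__all__ = [
    "StatResult",
    "DegenerateInputError",
    "gated_two_sample",
    "one_sample_vs_zero",
    "mixed_anova",
    "covariate_adjusted_contrast",
    "pearson_corr",
    "partial_corr",
    "fisher_compare",
    "planned_comparisons",
    "PLANNED_ALPHA",
    "EXPLORATORY_ALPHA",
]

logger = logging.getLogger(__name__)

#: α for hypothesis-driven planned comparisons (two per limb), corrected
#: for multiple comparisons; and for everything else.
PLANNED_ALPHA = 0.025
EXPLORATORY_ALPHA = 0.05
_SHAPIRO_ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Input admits no meaningful test (zero variance, |r| = 1, ...)."""


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    tails: str  # "one" | "two"
    alpha_used: float
    decision: str = field(init=False)
    n: int | tuple[int, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        if self.tails not in ("one", "two"):
            raise ValidationError(f"tails must be 'one' or 'two', got {self.tails!r}")
        decision = "significant" if self.p_value <= self.alpha_used else "not_significant"
        object.__setattr__(self, "decision", decision)


def _clean(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def gated_two_sample(
    group_a,
    group_b,
    alpha: float = EXPLORATORY_ALPHA,
    force_branch: str | None = None,
    equal_var: bool = True,
) -> StatResult:
    """Two-sample comparison gated on Shapiro–Wilk normality of each group.

    Both groups normal (Shapiro–Wilk p > 0.05 each) → independent Student's
    *t*-test (pooled variance; Welch available via ``equal_var=False``);
    otherwise Mann–Whitney *U*.  ``force_branch`` ("parametric" /
    "nonparametric") bypasses the gate, for testing and for deliberate
    overrides; the branch taken and both Shapiro p-values are recorded.

    Mann–Whitney p-values are exact for combined n ≤ 20 without ties, and
    use the tie-corrected normal approximation otherwise.
    """
    a = _clean(group_a, "group_a")
    b = _clean(group_b, "group_b")
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    sw_a = float(sps.shapiro(a).pvalue)
    sw_b = float(sps.shapiro(b).pvalue)
    if force_branch is None:
        branch = "parametric" if (sw_a > _SHAPIRO_ALPHA and sw_b > _SHAPIRO_ALPHA) else "nonparametric"
    elif force_branch in ("parametric", "nonparametric"):
        branch = force_branch
    else:
        raise ValidationError(f"force_branch must be 'parametric' or 'nonparametric', got {force_branch!r}")
    logger.info("gated_two_sample: shapiro p=(%.4g, %.4g) -> %s branch", sw_a, sw_b, branch)
    extra = {"shapiro_p_a": sw_a, "shapiro_p_b": sw_b, "branch": branch}
    if branch == "parametric":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise DegenerateInputError("zero-variance groups; t-test undefined")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        if not math.isfinite(res.statistic):
            raise DegenerateInputError("degenerate t-test (zero variance)")
        name = "t_independent" if equal_var else "t_welch"
        return StatResult(name, float(res.statistic), float(res.df), float(res.pvalue),
                          "two", alpha, n=(len(a), len(b)), extra=extra)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    extra["mw_method"] = method
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult("mann_whitney_u", float(res.statistic), float("nan"), float(res.pvalue),
                      "two", alpha, n=(len(a), len(b)), extra=extra)


def one_sample_vs_zero(values, tails: str = "two", alpha: float = EXPLORATORY_ALPHA) -> StatResult:
    """One-sample t-test of mean = 0 (e.g. laterality index vs. balanced use)."""
    x = _clean(values, "values")
    n = len(x)
    if n < 3:
        raise ValidationError("one-sample test needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance sample; one-sample t-test undefined")
    alternative = "two-sided" if tails == "two" else "greater"
    res = sps.ttest_1samp(x, popmean=0.0, alternative=alternative)
    return StatResult("t_one_sample", float(res.statistic), float(n - 1), float(res.pvalue),
                      tails, alpha, n=n)


def mixed_anova(
    groups,
    y_level1,
    y_level2,
    alpha: float = EXPLORATORY_ALPHA,
    participant_ids: Sequence | None = None,
) -> StatResult:
    """Group × limb interaction from a mixed (split-plot) ANOVA.

    ``groups`` labels the between-subjects factor; ``y_level1`` /
    ``y_level2`` hold each subject's value at the two within-subject
    levels (e.g. β during residual-arm and intact-hand movements).  With a
    two-level within factor the classical univariate sums-of-squares
    decomposition reduces exactly to a one-way ANOVA on the per-subject
    difference scores: SS_interaction/2 and the within-subject error map
    onto the between-group and residual SS of ``d = y1 − y2``.  Sphericity
    is moot with two levels.  Returns the interaction F with df
    ``(a − 1, N − a)``.
    """
    g = np.asarray(groups)
    y1 = np.asarray(y_level1, dtype=float)
    y2 = np.asarray(y_level2, dtype=float)
    if not (len(g) == len(y1) == len(y2)):
        raise ValidationError("groups, y_level1, y_level2 must have equal length")
    bad = ~(np.isfinite(y1) & np.isfinite(y2))
    if bad.any():
        ids = (np.asarray(participant_ids)[bad].tolist() if participant_ids is not None
               else np.flatnonzero(bad).tolist())
        raise ValidationError(f"missing within-cell values for participants {ids}")
    levels = pd.unique(g)
    a = len(levels)
    if a < 2:
        raise ValidationError("mixed ANOVA needs at least 2 groups")
    d = y1 - y2
    N = len(d)
    grand = d.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lv in levels:
        dg = d[g == lv]
        if len(dg) < 2:
            raise ValidationError(f"group {lv!r} has fewer than 2 complete subjects")
        ss_between += len(dg) * (dg.mean() - grand) ** 2
        ss_within += ((dg - dg.mean()) ** 2).sum()
    df1, df2 = a - 1, N - a
    if ss_within == 0:
        raise DegenerateInputError("zero within-group variance of difference scores")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return StatResult("mixed_anova_interaction", float(f), (float(df1), float(df2)), p,
                      "two", alpha, n=N, extra={"groups": list(map(str, levels))})


def covariate_adjusted_contrast(
    y,
    groups,
    covariates: pd.DataFrame | None = None,
    alpha: float = EXPLORATORY_ALPHA,
) -> StatResult:
    """Group effect F from the linear model ``y ~ group + covariates``.

    ``groups`` must have exactly two levels.  The F statistic compares the
    full model against the nested model without the group term, with df
    ``(1, n − k − 1)`` where k counts the group dummy plus covariates.
    With an empty covariate set this reproduces the unadjusted one-way
    contrast (F = t²) exactly.
    """
    y = _clean(y, "y")
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValidationError(f"group factor must have 2 levels, got {list(levels)}")
    dummy = (g == levels[1]).astype(float)
    n = len(y)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        cov = np.empty((n, 0))
        cov_names: list[str] = []
    else:
        cov_df = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov_df.columns]
        cov = cov_df.to_numpy(dtype=float)
        if not np.isfinite(cov).all():
            raise ValidationError("covariates contain missing or non-finite values")
    x_red = np.column_stack([np.ones(n), cov])
    x_full = np.column_stack([x_red, dummy])
    if np.linalg.matrix_rank(x_red) < x_red.shape[1]:
        rank_ok = [c for i, c in enumerate(cov_names)
                   if np.linalg.matrix_rank(np.column_stack([np.ones(n), cov[:, : i + 1]])) == i + 2]
        collinear = sorted(set(cov_names) - set(rank_ok))
        raise ValidationError(f"collinear covariates: {collinear or cov_names}")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValidationError("group indicator is collinear with the covariates")
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df2 = float(full.df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if full.ssr <= 1e-12 * (1.0 + tss):
        # perfect covariate fit leaves zero residual variance; if the group
        # term adds nothing either, its effect is exactly null
        if red.ssr - full.ssr <= 1e-12 * (1.0 + tss):
            f, p, df_num = 0.0, 1.0, 1.0
        else:
            raise DegenerateInputError("zero residual variance in the full model")
    else:
        f, p, df_num = full.compare_f_test(red)
    return StatResult("glm_group_contrast", float(f), (float(df_num), df2), float(p),
                      "two", alpha, n=n, extra={"covariates": cov_names,
                                                "group_levels": list(map(str, levels))})


def pearson_corr(x, y, tails: str = "two", direction: str | None = None,
                 alpha: float = EXPLORATORY_ALPHA) -> StatResult:
    """Pearson correlation with t-based p-value, df = n − 2."""
    xv = _clean(x, "x")
    yv = _clean(y, "y")
    if len(xv) != len(yv):
        raise ValidationError("x and y must have equal length")
    n = len(xv)
    if n < 3:
        raise ValidationError("correlation needs n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("zero variance input; correlation undefined")
    alternative = _alternative(tails, direction)
    res = sps.pearsonr(xv, yv, alternative=alternative)
    return StatResult("pearson_r", float(res.statistic), float(n - 2), float(res.pvalue),
                      tails, alpha, n=n)


def partial_corr(x, y, nuisance, tails: str = "one", direction: str | None = None,
                 alpha: float = EXPLORATORY_ALPHA) -> StatResult:
    """Partial correlation of x and y given nuisance covariates.

    Both variables are residualised on the nuisance columns (with
    intercept) by least squares; the Pearson correlation of the residuals
    is tested on df = n − 2 − k.  Directional hypotheses are one-tailed in
    the declared ``direction`` ("negative"/"positive"); a one-tailed
    request without a declared direction falls back to two-tailed with a
    logged warning.
    """
    xv = _clean(x, "x")
    yv = _clean(y, "y")
    z = np.asarray(nuisance, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n = len(xv)
    if len(yv) != n or z.shape[0] != n:
        raise ValidationError("x, y and nuisance must have equal length")
    k = z.shape[1]
    if not np.isfinite(z).all():
        raise ValidationError("nuisance contains non-finite values")
    if n <= k + 2:
        raise ValidationError(f"need n > k + 2 (n={n}, k={k})")
    for j in range(k):
        for v, name in ((xv, "x"), (yv, "y")):
            if np.ptp(v) > 0 and np.ptp(z[:, j]) > 0:
                c = np.corrcoef(v, z[:, j])[0, 1]
                if abs(c) > 1 - 1e-12:
                    raise ValidationError(f"nuisance column {j} coincides with {name}")
    if tails == "one" and direction is None:
        logger.warning("partial_corr: one-tailed requested without a declared direction; "
                       "reporting two-tailed p")
        tails = "two"
    design = np.column_stack([np.ones(n), z])
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("a variable is fully explained by the nuisance columns")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r * r))
        if tails == "two":
            p = 2 * float(sps.t.sf(abs(t), df))
        elif direction == "negative":
            p = float(sps.t.cdf(t, df))
        else:
            p = float(sps.t.sf(t, df))
    return StatResult("partial_r", r, float(df), p, tails, alpha, n=n,
                      extra={"k_nuisance": k, "direction": direction})


def fisher_compare(r1: float, n1: int, r2: float, n2: int,
                   alpha: float = EXPLORATORY_ALPHA) -> StatResult:
    """Compare two independent correlations via Fisher's r-to-z transform.

    ``z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3))``, two-tailed
    normal p-value.
    """
    for r, n, tag in ((r1, n1, "r1"), (r2, n2, "r2")):
        if abs(r) >= 1:
            raise DegenerateInputError(f"|{tag}| must be < 1 (atanh undefined at ±1)")
        if n < 4:
            raise ValidationError(f"n for {tag} must be >= 4")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * float(sps.norm.sf(abs(z)))
    return StatResult("fisher_r_to_z", z, float("inf"), p, "two", alpha, n=(n1, n2))


def planned_comparisons(data: pd.DataFrame, plan: Sequence[Mapping],
                        group_col: str = "group") -> list[StatResult]:
    """Run a list of two-sample contrasts with planned-vs-exploratory α.

    Each plan entry is a mapping with keys ``name``, ``column``,
    ``group_a``, ``group_b`` and ``planned`` (bool).  Planned contrasts are
    tested at α = 0.025, exploratory ones at 0.05; both run through the
    normality gate.  Participants missing the dependent value are excluded
    from that contrast only, with the exclusion logged.
    """
    results = []
    known = set(map(str, pd.unique(data[group_col])))
    for entry in plan:
        col = entry["column"]
        ga, gb = str(entry["group_a"]), str(entry["group_b"])
        for gname in (ga, gb):
            if gname not in known:
                raise ValidationError(f"contrast {entry.get('name', col)!r}: unknown group {gname!r}")
        if col not in data.columns:
            raise ValidationError(f"contrast {entry.get('name', col)!r}: unknown column {col!r}")
        alpha = PLANNED_ALPHA if entry.get("planned", False) else EXPLORATORY_ALPHA
        va = data.loc[data[group_col].astype(str) == ga, col]
        vb = data.loc[data[group_col].astype(str) == gb, col]
        n_drop = int(va.isna().sum() + vb.isna().sum())
        if n_drop:
            logger.info("contrast %r: excluded %d participants with missing %s",
                        entry.get("name", col), n_drop, col)
        res = gated_two_sample(va.dropna(), vb.dropna(), alpha=alpha)
        res.extra["contrast"] = entry.get("name", f"{ga}_vs_{gb}_{col}")
        res.extra["planned"] = bool(entry.get("planned", False))
        res.extra["n_excluded"] = n_drop
        results.append(res)
    return results


def _alternative(tails: str, direction: str | None) -> str:
    if tails == "two":
        return "two-sided"
    if direction == "negative":
        return "less"
    if direction == "positive":
        return "greater"
    raise ValidationError("one-tailed test requires direction 'negative' or 'positive'")
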