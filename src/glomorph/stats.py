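"""Cohort statistics battery.

Mirrors the analysis workflow of a typical morphometry study: normality
screening (Kolmogorov-Smirnov/Lilliefors, D'Agostino-Pearson,
Shapiro-Wilk), Welch's unequal-variance t-test for two groups with an
automatic Mann-Whitney fallback for non-Gaussian endpoints, one-way
ANOVA with post hoc t-tests against control for multi-group designs,
chi-square for lesion frequencies, and a univariate adaptation of the
robust-regression-plus-outlier-removal (ROUT) procedure.  Significance
defaults to alpha = 0.01; summaries are mean +/- SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.01

#: a sample is treated as non-Gaussian when any normality test rejects
#: at this level, switching the two-group comparison to Mann-Whitney
NORMALITY_REJECT_P = 1e-3


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM summary of one endpoint in one group."""

    n: int
    mean: float
    sem: float
    values: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def summarize(values) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need n >= 2 for a mean +/- SEM summary")
    return GroupSummary(n=n, mean=float(arr.mean()),
                        sem=float(arr.std(ddof=1) / np.sqrt(n)), values=arr)


def test_normality(values) -> dict:
    """P-values of the three distribution tests.

    Below n = 8 the D'Agostino-Pearson test is undefined and is omitted
    (flagged); a constant sample is flagged degenerate with NaN p-values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need n >= 3 for normality testing")
    out: dict = {"degenerate": False, "omitted": []}
    if np.ptp(arr) == 0:
        out["degenerate"] = True
        out.update(kolmogorov_smirnov=np.nan, dagostino_pearson=np.nan,
                   shapiro_wilk=np.nan)
        return out
    out["kolmogorov_smirnov"] = float(lilliefors(arr, dist="norm")[1])
    if arr.size >= 8:
        out["dagostino_pearson"] = float(sps.normaltest(arr).pvalue)
    else:
        out["omitted"].append("dagostino_pearson")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large-n p-value accuracy warning
        out["shapiro_wilk"] = float(sps.shapiro(arr).pvalue)
    return out


def _rejects_normality(arr: np.ndarray) -> bool:
    if arr.size < 8:
        return False
    res = test_normality(arr)
    ps = [res[k] for k in ("kolmogorov_smirnov", "dagostino_pearson", "shapiro_wilk")
          if k in res]
    return bool(ps) and min(ps) < NORMALITY_REJECT_P


def compare_two(a, b, force: str | None = None,
                alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Two-group comparison: Welch's t by default, Mann-Whitney when
    either sample rejects normality (or when forced).

    Welch degrees of freedom follow Welch-Satterthwaite; the Mann-Whitney
    p-value is exact for small untied samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if force is None:
        test = "mann_whitney" if (_rejects_normality(a) or _rejects_normality(b)) \
            else "welch_t"
        selected_automatically = True
    else:
        if force not in ("welch_t", "mann_whitney"):
            raise ValueError(f"unknown test {force!r}")
        test = force
        selected_automatically = False
    if test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        details = {"df": float(res.df), "auto": selected_automatically}
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            # fully degenerate: no evidence of a difference
            stat, p, details = 0.0, 1.0, {"auto": selected_automatically}
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            details = {"auto": selected_automatically}
    return ComparisonResult(test_name=test, statistic=stat, p_value=p,
                            significant=bool(p < alpha), alpha=alpha,
                            details=details)


def compare_many(groups, alpha: float = DEFAULT_ALPHA,
                 control_index: int = 0) -> ComparisonResult:
    """One-way ANOVA across >= 3 groups with post hoc t-tests vs control.

    With exactly two groups the comparison falls through to
    :func:`compare_two`.  Post hoc pairs are reported in
    ``details["posthoc"]`` as (index, statistic, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if len(groups) == 2:
        return compare_two(groups[0], groups[1], alpha=alpha)
    f_stat, p = sps.f_oneway(*groups)
    control = groups[control_index]
    posthoc = []
    for i, g in enumerate(groups):
        if i == control_index:
            continue
        res = sps.ttest_ind(control, g, equal_var=False)
        posthoc.append({"group": i, "statistic": float(res.statistic),
                        "p_value": float(res.pvalue),
                        "significant": bool(res.pvalue < alpha)})
    return ComparisonResult(test_name="anova_posthoc", statistic=float(f_stat),
                            p_value=float(p), significant=bool(p < alpha),
                            alpha=alpha, details={"posthoc": posthoc})


def compare_frequencies(events_a: int, n_a: int, events_b: int, n_b: int,
                        alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """2x2 chi-square on lesion counts, Fisher's exact p when cells are thin.

    The chi-square statistic (no continuity correction) is always
    reported; when any expected cell is below 5 the p-value comes from
    Fisher's exact test and the fallback is flagged.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("denominators must be positive")
    if not 0 <= events_a <= n_a or not 0 <= events_b <= n_b:
        raise ValueError("event counts cannot exceed denominators")
    table = np.array([[events_a, n_a - events_a], [events_b, n_b - events_b]])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return ComparisonResult(test_name="chi_square", statistic=0.0,
                                p_value=1.0, significant=False, alpha=alpha,
                                details={"exact": False, "degenerate": True})
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    exact = bool((expected < 5).any())
    if exact:
        p = float(sps.fisher_exact(table).pvalue)
    return ComparisonResult(test_name="chi_square", statistic=float(chi2),
                            p_value=float(p), significant=bool(p < alpha),
                            alpha=alpha, details={"exact": exact})


def remove_outliers_rout(values, q_pct: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Univariate ROUT-style outlier removal at FDR level Q (percent).

    Robust location/scale fit (median, MAD x 1.4826), two-sided normal
    p-values on the standardized residuals, Benjamini-Hochberg selection
    at Q.  Returns (kept, outliers); removed points are reported, never
    silently dropped.  Below n = 10 the data are returned untouched with
    a warning.
    """
    arr = np.asarray(values, dtype=float)
    if not 0 < q_pct < 100:
        raise ValueError("Q must lie in (0, 100) percent")
    if arr.size < 10:
        warnings.warn("n < 10: ROUT skipped, no outliers removed", stacklevel=2)
        return arr.copy(), np.empty(0)
    center = float(np.median(arr))
    mad = float(np.median(np.abs(arr - center)))
    scale = 1.4826 * mad
    if scale == 0.0:
        # a majority of identical values; anything else is infinitely far
        mask = arr != center
        return arr[~mask], arr[mask]
    z = np.abs(arr - center) / scale
    pvals = 2.0 * sps.norm.sf(z)
    reject, *_ = multipletests(pvals, alpha=q_pct / 100.0, method="fdr_bh")
    return arr[~reject], arr[reject]


def percent_change(treated, control) -> float:
    """Signed percent change of the treated mean vs the control mean."""
    t_mean = treated.mean if isinstance(treated, GroupSummary) \
        else float(np.asarray(treated, dtype=float).mean())
    c_mean = control.mean if isinstance(control, GroupSummary) \
        else float(np.asarray(control, dtype=float).mean())
    if c_mean == 0:
        raise ValueError("control mean is zero; percent change undefined")
    return 100.0 * (t_mean - c_mean) / c_mean
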