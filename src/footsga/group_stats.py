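"""Statistical battery for cohort comparisons.

Covers the analysis chain used for two-group gait comparisons:

* Lilliefors normality test (Kolmogorov-Smirnov statistic against a
  normal with estimated mean/SD, p-value from a seeded Monte-Carlo null);
* two-group location test that branches on normality: Student's t when
  both samples look normal, Mann-Whitney rank-sum otherwise (a paired
  Wilcoxon signed-rank variant is available for paired designs);
* balanced two-way ANOVA (Group x Side) with Tukey-HSD post-hoc;
* Hedges' g standardized mean difference with the small-sample
  correction J = 1 - 3/(4(n1+n2) - 9);
* control-referenced subgroup selection: threshold = mean + 1 SD of the
  control values (sample SD, n-1);
* Pearson correlation with a seeded bootstrap 95% CI (BCa by default,
  percentile optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatTestResult",
    "EffectSize",
    "AnovaResult",
    "SubgroupResult",
    "CorrelationResult",
    "lilliefors",
    "compare_two_groups",
    "two_way_anova",
    "hedges_g",
    "select_subgroup",
    "pearson_bootstrap",
]

ALPHA = 0.05


@dataclass
class StatTestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...] | int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class EffectSize:
    """Hedges' g with sample sizes and whether J-correction was applied."""

    g: float
    n1: int
    n2: int
    correction_applied: bool


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Tukey-adjusted pairwise comparisons."""

    table: pd.DataFrame
    tukey: pd.DataFrame
    f_group: float
    p_group: float
    f_side: float
    p_side: float
    f_interaction: float
    p_interaction: float
    degenerate: bool = False


@dataclass
class SubgroupResult:
    mask: np.ndarray
    threshold: float
    n_selected: int


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int
    ci_type: str = "bca"


# ---------------------------------------------------------------------------
# Lilliefors


def _lilliefors_statistic(x: np.ndarray) -> np.ndarray:
    """KS distance to N(mean, sd) with both estimated; vectorized on rows."""
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[-1]
    z = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, ddof=1, keepdims=True)
    z.sort(axis=-1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_null(n: int, n_sims: int, seed: int) -> np.ndarray:
    key = (n, n_sims, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_sims, n))
        _NULL_CACHE[key] = np.sort(_lilliefors_statistic(sims))
    return _NULL_CACHE[key]


def lilliefors(
    sample, n_sims: int = 10_000, seed: int = 0
) -> StatTestResult:
    """Lilliefors test of composite normality.

    The p-value is Monte-Carlo: the observed KS statistic is ranked
    against ``n_sims`` statistics simulated under the null (standard
    normal samples of the same size), p = (1 + #{D_null >= D}) /
    (n_sims + 1).  The null table is cached per (n, n_sims, seed).
    """
    x = np.asarray(sample, float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("lilliefors requires a 1-D sample with n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    d = float(_lilliefors_statistic(x)[0])
    null = _lilliefors_null(len(x), n_sims, seed)
    n_ge = len(null) - np.searchsorted(null, d - 1e-12, side="left")
    p = (1 + n_ge) / (n_sims + 1)
    return StatTestResult(method="lilliefors", statistic=d, p_value=float(p), n=len(x))


# ---------------------------------------------------------------------------
# two-group comparison


def compare_two_groups(
    x,
    y,
    alpha: float = ALPHA,
    paired: bool = False,
    n_sims: int = 10_000,
    seed: int = 0,
) -> StatTestResult:
    """Two-tailed location comparison with a normality-dependent branch.

    If both samples pass Lilliefors at ``alpha``: Student's t-test
    (paired t if ``paired``).  Otherwise a rank test: Mann-Whitney
    rank-sum for independent samples, Wilcoxon signed-rank if ``paired``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4 or len(y) < 4:
        raise ValueError("need n >= 4 in each group")
    normal = True
    for s in (x, y):
        if np.ptp(s) == 0:
            normal = False
            break
        if lilliefors(s, n_sims=n_sims, seed=seed).p_value < alpha:
            normal = False
            break
    if np.array_equal(x, y):
        # degenerate identical inputs: no evidence of any difference
        method = "t" if normal else "rank"
        return StatTestResult(method=method, statistic=0.0, p_value=1.0,
                              n=(len(x), len(y)))
    if normal:
        if paired:
            res = stats.ttest_rel(x, y)
            method = "paired-t"
        else:
            res = stats.ttest_ind(x, y)
            method = "t"
    else:
        if paired:
            res = stats.wilcoxon(x, y)
            method = "wilcoxon-signed-rank"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            method = "mann-whitney"
    return StatTestResult(
        method=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
    )


# ---------------------------------------------------------------------------
# two-way ANOVA with Tukey post-hoc


def two_way_anova(values, group, side) -> AnovaResult:
    """Two-way ANOVA of ``values`` on Group x Side with Tukey HSD.

    Expects one observation per subject-side in a (near-)balanced 2x2
    layout.  With identical values everywhere the model is degenerate
    and a no-effect result (F=0, p=1) is returned.
    """
    values = np.asarray(values, float)
    df = pd.DataFrame(
        {"value": values, "group": list(group), "side": list(side)}
    )
    counts = df.groupby(["group", "side"]).size()
    n_groups = df["group"].nunique()
    n_sides = df["side"].nunique()
    if len(counts) < n_groups * n_sides or (counts < 1).any():
        raise ValueError("empty cell in the Group x Side layout")
    if np.ptp(values) == 0:
        tab = pd.DataFrame(
            {"F": [0.0] * 3, "PR(>F)": [1.0] * 3},
            index=["C(group)", "C(side)", "C(group):C(side)"],
        )
        return AnovaResult(
            table=tab, tukey=pd.DataFrame(),
            f_group=0.0, p_group=1.0, f_side=0.0, p_side=1.0,
            f_interaction=0.0, p_interaction=1.0, degenerate=True,
        )

    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    model = ols("value ~ C(group) * C(side)", data=df).fit()
    tab = anova_lm(model, typ=2)
    cell = (df["group"] + "/" + df["side"]).to_numpy()
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), cell)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return AnovaResult(
        table=tab,
        tukey=tukey,
        f_group=float(tab.loc["C(group)", "F"]),
        p_group=float(tab.loc["C(group)", "PR(>F)"]),
        f_side=float(tab.loc["C(side)", "F"]),
        p_side=float(tab.loc["C(side)", "PR(>F)"]),
        f_interaction=float(tab.loc["C(group):C(side)", "F"]),
        p_interaction=float(tab.loc["C(group):C(side)", "PR(>F)"]),
    )


# ---------------------------------------------------------------------------
# Hedges' g


def hedges_g(x, y, correct: bool = True) -> EffectSize:
    """Standardized mean difference (M1 - M2) / pooled SD.

    With ``correct=True`` the small-sample bias correction
    J = 1 - 3/(4(n1+n2) - 9) is applied; ``correct=False`` reproduces
    the uncorrected quotient.  Sign convention: first argument minus
    second.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each sample")
    sd_pooled = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if sd_pooled == 0:
        raise ValueError("pooled SD is zero: effect size undefined")
    g = (x.mean() - y.mean()) / sd_pooled
    if correct:
        g *= 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return EffectSize(g=float(g), n1=n1, n2=n2, correction_applied=correct)


# ---------------------------------------------------------------------------
# subgroup selection


def select_subgroup(atyp_pd, atyp_control) -> SubgroupResult:
    """Patients whose Atyp exceeds the control mean + 1 sample SD.

    ``atyp_control`` holds per-control-subject Atyp values (each already
    averaged over the dominant and non-dominant sides); the selection is
    strict (values equal to the threshold are excluded).
    """
    atyp_pd = np.asarray(atyp_pd, float)
    atyp_control = np.asarray(atyp_control, float)
    if len(atyp_control) < 2:
        raise ValueError("need at least 2 control subjects for the threshold")
    threshold = float(atyp_control.mean() + atyp_control.std(ddof=1))
    mask = atyp_pd > threshold
    return SubgroupResult(mask=mask, threshold=threshold, n_selected=int(mask.sum()))


# ---------------------------------------------------------------------------
# bootstrap correlation


def _pearson_vec(x, y, axis=-1):
    xm = x - np.mean(x, axis=axis, keepdims=True)
    ym = y - np.mean(y, axis=axis, keepdims=True)
    num = np.sum(xm * ym, axis=axis)
    den = np.sqrt(np.sum(xm * xm, axis=axis) * np.sum(ym * ym, axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def pearson_bootstrap(
    x, y, n_boot: int = 1000, seed: int = 0, ci_type: str = "bca"
) -> CorrelationResult:
    """Pearson r with two-sided t-test p and a seeded bootstrap 95% CI.

    Pairs are resampled with replacement ``n_boot`` times; the CI is
    bias-corrected and accelerated (BCa) by default, plain percentile on
    request.  Exactly collinear data short-circuit to a degenerate CI at
    r itself.  Bit-reproducible for a fixed seed.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if ci_type not in ("bca", "percentile"):
        raise ValueError("ci_type must be 'bca' or 'percentile'")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-12:
        lo = hi = float(np.sign(r))
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.bootstrap(
                (x, y),
                _pearson_vec,
                paired=True,
                vectorized=True,
                n_resamples=n_boot,
                confidence_level=0.95,
                method="BCa" if ci_type == "bca" else "percentile",
                rng=np.random.default_rng(seed),
            )
        lo, hi = res.confidence_interval
        if not (np.isfinite(lo) and np.isfinite(hi)):
            # degenerate resamples (possible at very small n): fall back to
            # the percentile interval over the non-degenerate resamples
            dist = res.bootstrap_distribution
            dist = dist[np.isfinite(dist)]
            lo, hi = np.percentile(dist, [2.5, 97.5]) if len(dist) else (r, r)
        lo = float(np.clip(lo, -1.0, 1.0))
        hi = float(np.clip(hi, -1.0, 1.0))
    return CorrelationResult(
        r=float(r), p_value=float(p), ci_low=lo, ci_high=hi,
        n=len(x), n_boot=n_boot, seed=seed, ci_type=ci_type,
    )
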