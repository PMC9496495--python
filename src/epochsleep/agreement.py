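"""Two-device agreement statistics for sleep indices and epochs.

Implements the comparison battery used in wearable validation studies:

* paired TOST equivalence tests (two one-sided paired t tests, or two
  one-sided Wilcoxon signed-rank tests with exact sign-flip enumeration
  at small n) against a-priori margins;
* Bland-Altman limits of agreement for repeated measures, with the
  within-subject correlation absorbed through one-way ANOVA variance
  components, and proportional bias quantified by a working-independence
  estimating-equation slope with cluster-robust (sandwich) confidence
  intervals;
* Shrout-Fleiss single-rater intraclass correlations, ICC(2,1) for
  absolute agreement and ICC(3,1) for consistency, from two-way ANOVA
  mean squares;
* epoch-level sensitivity, specificity, accuracy and likelihood ratios
  of a test device against a designated reference device, pooled and
  per subject, restricted to nighttime minutes.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timeutil import clock_to_slot

__all__ = [
    "TostResult",
    "BAResult",
    "IccResult",
    "ConfusionMetrics",
    "tost_paired_t",
    "tost_wilcoxon",
    "bland_altman_rm",
    "icc_shrout_fleiss",
    "epoch_confusion",
    "equivalence_table",
    "DEFAULT_MARGINS",
]

#: a-priori equivalence margins per weekly variable (minutes except where noted)
DEFAULT_MARGINS = {
    "bedtime": 30.0,
    "sleep_onset": 30.0,
    "sleep_offset": 30.0,
    "waketime": 30.0,
    "midpoint": 30.0,
    "tib": 30.0,
    "tst": 30.0,
    "regularity": 10.0,
    "sol": 10.0,
    "waso": 10.0,
    "sf": 5.0,    # events
    "se": 3.0,    # percentage points
}


@dataclasses.dataclass(frozen=True)
class TostResult:
    variable: str
    margin: float
    mean_diff: float
    p_lower: float
    p_upper: float
    p_tost: float
    equivalent: bool
    method: str
    n: int


@dataclasses.dataclass(frozen=True)
class BAResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_total: float
    var_between: float
    var_within: float
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    n_subjects: int
    n_pairs: int


@dataclasses.dataclass(frozen=True)
class IccResult:
    icc_2_1: float
    icc_3_1: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    n_subjects: int
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    mean_sensitivity: float
    sensitivity_ci: tuple[float, float]
    mean_specificity: float
    specificity_ci: tuple[float, float]
    n_epochs: int
    n_subjects: int


# ---------------------------------------------------------------------------
# TOST equivalence


def _degenerate_tost(variable, margin, center, method, n, alpha) -> TostResult:
    # zero-variance differences: equivalence is certain iff |center| < margin
    p = 0.0 if abs(center) < margin else 1.0
    return TostResult(variable, margin, center, p, p, p, p < alpha, method, n)


def tost_paired_t(
    diffs: Sequence[float],
    margin: float,
    alpha: float = 0.05,
    variable: str = "",
) -> TostResult:
    """Two one-sided paired t tests of |mean difference| < margin.

    The lower test rejects H0: mean <= -margin; the upper test rejects
    H0: mean >= +margin.  ``p_tost`` is the larger of the two one-sided
    p values, and equivalence is declared when it is below ``alpha``.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("paired TOST needs at least two differences")
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    n = d.size
    if sd == 0.0:
        return _degenerate_tost(variable, margin, mean, "paired-t", n, alpha)
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + margin) / se
    t_upper = (mean - margin) / se
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p_tost = max(p_lower, p_upper)
    return TostResult(variable, margin, mean, p_lower, p_upper, p_tost,
                      p_tost < alpha, "paired-t", n)


def _signed_rank_exact(x: np.ndarray, alternative: str) -> float:
    """Exact one-sided signed-rank p by enumerating all sign assignments.

    Zeros are dropped (Wilcoxon's rule); ties take midranks, so the
    enumeration is the exact permutation distribution of the observed
    absolute values.
    """
    x = x[x != 0]
    n = x.size
    if n == 0:
        # no information either way
        return 1.0
    ranks = stats.rankdata(np.abs(x))
    w_obs = float(ranks[x > 0].sum())
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_all = signs @ ranks
    if alternative == "greater":
        return float(np.mean(w_all >= w_obs - 1e-12))
    return float(np.mean(w_all <= w_obs + 1e-12))


def tost_wilcoxon(
    diffs: Sequence[float],
    margin: float,
    alpha: float = 0.05,
    variable: str = "",
    exact_max_n: int = 10,
) -> TostResult:
    """Two one-sided Wilcoxon signed-rank tests of equivalence.

    Shifts the differences by +/- the margin and tests each shifted set
    for location above (below) zero.  Up to ``exact_max_n`` non-zero
    differences the null distribution is enumerated exactly over all
    sign assignments; beyond that the normal approximation with
    continuity correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("signed-rank TOST needs at least two differences")
    if margin <= 0:
        raise ValueError("equivalence margin must be positive")
    center = float(np.median(d))
    if np.all(d == d[0]):
        return _degenerate_tost(variable, margin, float(d[0]), "wilcoxon", d.size, alpha)
    lower = d + margin   # should be > 0 when d > -margin
    upper = d - margin   # should be < 0 when d < +margin
    p_lower = _one_sided_signed_rank(lower, "greater", exact_max_n)
    p_upper = _one_sided_signed_rank(upper, "less", exact_max_n)
    p_tost = max(p_lower, p_upper)
    return TostResult(variable, margin, center, p_lower, p_upper, p_tost,
                      p_tost < alpha, "wilcoxon", d.size)


def _one_sided_signed_rank(x: np.ndarray, alternative: str, exact_max_n: int) -> float:
    nz = np.count_nonzero(x)
    if nz == 0:
        return 1.0
    if nz <= exact_max_n:
        return _signed_rank_exact(x, alternative)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(x, alternative=alternative, zero_method="wilcox",
                             correction=True, method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Repeated-measures Bland-Altman


def bland_altman_rm(pairs: pd.DataFrame, subject: str = "subject_id",
                    a: str = "a", b: str = "b") -> BAResult:
    """Bland-Altman agreement for repeated measures per subject.

    Differences are ``d = a - b`` per person-day.  The SD entering the
    limits of agreement combines the between-subject and within-subject
    variance components from a one-way ANOVA of ``d`` on subject
    (method of moments), so the limits describe a *single* future
    difference rather than a subject mean.  Proportional bias is the
    slope of ``d`` on the pair mean, fitted by working-independence
    estimating equations with a cluster-by-subject sandwich variance.
    """
    df = pairs[[subject, a, b]].dropna()
    d = df[a].to_numpy(float) - df[b].to_numpy(float)
    m = (df[a].to_numpy(float) + df[b].to_numpy(float)) / 2.0
    groups = df[subject].to_numpy()
    subject_ids = pd.unique(groups)
    k = len(subject_ids)
    if k < 2:
        raise ValueError(
            "repeated-measures Bland-Altman needs >= 2 subjects; "
            "use a single-level analysis for one subject"
        )
    n = d.size

    grand = float(np.mean(d))
    group_means = np.array([d[groups == g].mean() for g in subject_ids])
    group_sizes = np.array([(groups == g).sum() for g in subject_ids])
    ssb = float(np.sum(group_sizes * (group_means - grand) ** 2))
    ssw = float(sum(((d[groups == g] - d[groups == g].mean()) ** 2).sum() for g in subject_ids))
    msb = ssb / (k - 1)
    msw = ssw / (n - k) if n > k else 0.0
    # average cluster size for unbalanced method-of-moments
    n0 = (n - float(np.sum(group_sizes**2)) / n) / (k - 1)
    var_between = max(0.0, (msb - msw) / n0)
    var_within = msw
    sd_total = float(np.sqrt(var_between + var_within))

    slope, slope_ci, slope_p = _gee_slope(d, m, groups)
    return BAResult(
        bias=grand,
        loa_low=grand - 1.96 * sd_total,
        loa_high=grand + 1.96 * sd_total,
        sd_total=sd_total,
        var_between=var_between,
        var_within=var_within,
        slope=slope,
        slope_ci=slope_ci,
        slope_p=slope_p,
        n_subjects=k,
        n_pairs=n,
    )


def _gee_slope(d: np.ndarray, m: np.ndarray, groups: np.ndarray) -> tuple[float, tuple[float, float], float]:
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        return 0.0, (0.0, 0.0), 1.0
    import statsmodels.api as sm

    exog = sm.add_constant(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(d, exog, groups=groups, family=sm.families.Gaussian(),
                       cov_struct=sm.cov_struct.Independence())
        # Mancl-DeRouen bias-reduced sandwich plus a t critical value on
        # G-1 df: the standard small-sample treatment of cluster-robust
        # intervals when the number of clusters is modest
        res = model.fit(cov_type="bias_reduced")
    n_clusters = len(np.unique(groups))
    slope = float(res.params[1])
    se = float(res.bse[1])
    tcrit = stats.t.ppf(0.975, max(n_clusters - 1, 1))
    return slope, (slope - tcrit * se, slope + tcrit * se), float(res.pvalues[1])


# ---------------------------------------------------------------------------
# Intraclass correlations


def icc_shrout_fleiss(matrix: np.ndarray | pd.DataFrame) -> IccResult:
    """Single-rater Shrout-Fleiss ICCs from an n-subjects x k-raters table.

    ICC(2,1) treats raters as random (absolute agreement); ICC(3,1)
    treats them as fixed (consistency).  Complete cases only.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ICC needs an n x k matrix with k >= 2 raters")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least three complete subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom31 = msr + (k - 1) * mse
    denom21 = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom31 <= 0 or msr == 0:
        return IccResult(0.0, 0.0, msr, msc, mse, n, degenerate=True)
    icc31 = (msr - mse) / denom31
    icc21 = (msr - mse) / denom21 if denom21 > 0 else 0.0
    return IccResult(float(icc21), float(icc31), msr, msc, mse, n)


# ---------------------------------------------------------------------------
# Epoch-level confusion metrics


def epoch_confusion(
    paired: pd.DataFrame,
    reference: str = "a",
    night_start: str = "19:00",
    night_end: str = "11:59",
    alpha: float = 0.05,
) -> ConfusionMetrics:
    """Sensitivity/specificity of the test device against the reference.

    Sensitivity is the proportion of reference *sleep* minutes the test
    device also scores as sleep; specificity the proportion of reference
    *wake* minutes scored as wake.  Restricted to nighttime minutes
    (default 19:00-11:59).  Pooled values feed the likelihood ratios
    (LR+ = sens/(1-spec), LR- = (1-sens)/spec); per-subject means carry
    a t-based 95% CI.  Subjects without reference wake (sleep) minutes
    are excluded from the per-subject specificity (sensitivity) mean.
    """
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    test = "b" if reference == "a" else "a"
    ns = clock_to_slot(night_start)
    ne = clock_to_slot(night_end)
    slot = (
        paired["timestamp"].dt.hour * 60 + paired["timestamp"].dt.minute - 720
    ) % 1440
    night = paired[(slot >= ns) & (slot <= ne)]
    if night.empty:
        raise ValueError("no nighttime epochs in the paired table")
    ref = night[f"sleeping_{reference}"].to_numpy() == 1
    tst = night[f"sleeping_{test}"].to_numpy() == 1

    tp = int(np.sum(ref & tst))
    fn = int(np.sum(ref & ~tst))
    tn = int(np.sum(~ref & ~tst))
    fp = int(np.sum(~ref & tst))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn)
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")

    per_sens, per_spec = [], []
    for sid, grp in night.groupby("subject_id"):
        r = grp[f"sleeping_{reference}"].to_numpy() == 1
        t = grp[f"sleeping_{test}"].to_numpy() == 1
        if r.any():
            per_sens.append(np.sum(r & t) / np.sum(r))
        else:
            warnings.warn(f"subject {sid}: no reference sleep minutes; skipped in mean sensitivity")
        if (~r).any():
            per_spec.append(np.sum(~r & ~t) / np.sum(~r))
        else:
            warnings.warn(f"subject {sid}: no reference wake minutes; skipped in mean specificity")

    def _mean_ci(vals: list[float]) -> tuple[float, tuple[float, float]]:
        v = np.asarray(vals, float)
        mu = float(np.mean(v))
        if v.size < 2:
            return mu, (float("nan"), float("nan"))
        half = stats.t.ppf(1 - alpha / 2, v.size - 1) * np.std(v, ddof=1) / np.sqrt(v.size)
        return mu, (mu - half, mu + half)

    mean_sens, sens_ci = _mean_ci(per_sens)
    mean_spec, spec_ci = _mean_ci(per_spec)
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        mean_sensitivity=mean_sens,
        sensitivity_ci=sens_ci,
        mean_specificity=mean_spec,
        specificity_ci=spec_ci,
        n_epochs=len(night),
        n_subjects=night["subject_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# Variable-by-variable equivalence report


def equivalence_table(
    weekly_a: pd.DataFrame,
    weekly_b: pd.DataFrame,
    margins: Optional[dict[str, float]] = None,
    alpha: float = 0.05,
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Paired TOST report across weekly summary variables.

    Pairs subjects present in both weekly tables and, per variable,
    reports device means +/- SD, both TOST p values (paired-t and
    Wilcoxon) and a default method chosen by a Shapiro-Wilk normality
    check on the differences (Wilcoxon when normality is rejected at
    0.05).  Differences are A - B of per-subject weekly means.
    """
    margins = {**DEFAULT_MARGINS, **(margins or {})}
    if variables is None:
        variables = [v for v in margins if f"{v}_mean" in weekly_a.columns or v in weekly_a.columns]
    merged = weekly_a.merge(weekly_b, on="subject_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping subjects between the weekly tables")
    rows = []
    for var in variables:
        cols = _variable_columns(var, weekly_a)
        ca, cb = f"{cols}_a", f"{cols}_b"
        va = merged[ca].to_numpy(float)
        vb = merged[cb].to_numpy(float)
        d = va - vb
        t_res = tost_paired_t(d, margins[var], alpha=alpha, variable=var)
        w_res = tost_wilcoxon(d, margins[var], alpha=alpha, variable=var)
        if np.ptp(d) == 0:
            normal = True
        else:
            normal = stats.shapiro(d).pvalue >= 0.05
        chosen = t_res if normal else w_res
        rows.append({
            "variable": var,
            "n": len(d),
            "mean_a": float(np.mean(va)),
            "sd_a": float(np.std(va, ddof=1)),
            "mean_b": float(np.mean(vb)),
            "sd_b": float(np.std(vb, ddof=1)),
            "mean_diff": float(np.mean(d)),
            "margin": margins[var],
            "p_tost_t": t_res.p_tost,
            "p_tost_wilcoxon": w_res.p_tost,
            "method": chosen.method,
            "p_tost": chosen.p_tost,
            "equivalent": chosen.equivalent,
        })
    return pd.DataFrame(rows)


def _variable_columns(var: str, frame: pd.DataFrame) -> str:
    if f"{var}_mean" in frame.columns:
        return f"{var}_mean"
    if var in frame.columns:
        return var
    raise KeyError(f"variable {var!r} not found in weekly table")
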