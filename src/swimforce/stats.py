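"""Agreement statistics for comparing two force-estimation pathways.

Covers the full suite used to validate one measurement method against
another on paired per-stroke summaries and time-normalized waveforms:

* paired t-test and Cohen's d with the conventional magnitude labels
  (negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large);
* ICC(2,1) — single-measures, absolute-agreement intraclass correlation from
  a two-way random-effects ANOVA, with the F-based 95% confidence interval
  (McGraw & Wong) and agreement labels (< 0.75 low, 0.75–0.90 medium,
  > 0.90 good);
* Bland–Altman analysis: bias (mean difference), SD of the differences,
  95% limits of agreement (bias ± 1.96·SD), confidence bounds for the limits,
  a one-sample t-test of the differences against zero (fixed bias) and the
  Pearson correlation between pair means and differences (proportional bias);
* the coefficient of multiple correlation (CMC) for waveform similarity,
  with the usual bands (0–0.64 poor, 0.65–0.74 moderate, 0.75–0.84 good,
  0.85–0.94 very good, 0.95–1 excellent).

The limits-of-agreement confidence bounds follow the published form

    upper = (D̄ + 1.96·SD) − t·√(3·SD²/n)
    lower = (D̄ − 1.96·SD) + t·√(3·SD²/n)

with t the two-sided 5% point on n−1 degrees of freedom — note the bounds
point *inward*; :meth:`BlandAltmanResult.loa_confidence_intervals` offers the
conventional symmetric ± intervals as well.  SD of the differences is the
n−1 (mean-square-corrected) sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "paired_t_test",
    "cohens_d",
    "effect_size_label",
    "icc_2_1",
    "ICCResult",
    "fixed_bias_test",
    "bland_altman",
    "BlandAltmanResult",
    "cmc",
    "CMCResult",
    "time_normalize",
    "agreement_report",
    "AgreementReport",
]


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in paired sample")
    return x, y


def paired_t_test(x, y):
    """Classical paired t-test; returns (t, two-sided p) with n−1 df.

    Identical vectors (all differences zero) return ``(0.0, 1.0)`` by
    convention; a nonzero constant difference (zero variance but nonzero
    mean) has an undefined statistic and is rejected.
    """
    x, y = _paired(x, y)
    diff = x - y
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        raise ValueError("zero variance of differences with nonzero mean: t undefined")
    res = _st.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def effect_size_label(d: float) -> str:
    """Cohen's magnitude bands for |d|."""
    d = abs(d)
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def cohens_d(x, y, variant: str = "pooled"):
    """Cohen's d effect size between two samples; returns (d, label).

    ``pooled``: |mean₁ − mean₂| / pooled SD (Welch-free, classical form).
    ``paired``: |mean of differences| / SD of differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if variant == "pooled":
        if x.size < 2 or y.size < 2:
            raise ValueError("need at least two observations per group")
        n1, n2 = x.size, y.size
        s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
        if s2 == 0:
            if np.mean(x) == np.mean(y):
                return 0.0, "negligible"
            raise ValueError("zero pooled variance with unequal means: d undefined")
        d = abs(np.mean(x) - np.mean(y)) / np.sqrt(s2)
    elif variant == "paired":
        x, y = _paired(x, y)
        diff = x - y
        sd = np.std(diff, ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                return 0.0, "negligible"
            raise ValueError("zero SD of differences with nonzero mean: d undefined")
        d = abs(np.mean(diff)) / sd
    else:
        raise ValueError("variant must be 'pooled' or 'paired'")
    d = float(d)
    return d, effect_size_label(d)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float
    label: str
    msr: float
    msc: float
    mse: float
    n: int
    k: int


def _icc_label(icc: float) -> str:
    if icc < 0.75:
        return "low"
    if icc <= 0.90:
        return "medium"
    return "good"


def icc_2_1(x, y, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): single measures, absolute agreement, two-way random effects.

    Subjects are rows (the paired observations), the two methods are columns.
    The point estimate comes from the two-way ANOVA mean squares,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

    which penalizes systematic offsets between methods (absolute agreement,
    unlike the consistency form).  The confidence interval is the standard
    F-based interval of McGraw & Wong; p is for H₀: ICC = 0 via
    F = MSR/MSE on (n−1, (n−1)(k−1)) df.
    """
    x, y = _paired(x, y)
    data = np.column_stack([x, y])
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("zero between-subject variance: ICC undefined")

    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (mse > 0 or msc > 0):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = _st.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = _st.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        ci_low = ci_high = 1.0

    if mse > 0:
        f0 = msr / mse
        p = float(_st.f.sf(f0, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    icc = float(icc)
    return ICCResult(icc, float(ci_low), float(ci_high), p, _icc_label(icc), float(msr), float(msc), float(mse), n, k)


def fixed_bias_test(diff):
    """One-sample t-test of the paired differences against zero; (t, p)."""
    diff = np.asarray(diff, dtype=float)
    if diff.size < 2:
        raise ValueError("need at least two differences")
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero variance of differences: test undefined")
    res = _st.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BlandAltmanResult:
    n: int
    bias: float  # mean difference x − y
    sd_diff: float  # n−1 sample SD of the differences
    loa_low: float
    loa_high: float
    ci_upper_limit: float  # published-form bound for the upper LOA
    ci_lower_limit: float  # published-form bound for the lower LOA
    fixed_bias_t: float
    fixed_bias_p: float
    effect_size: float
    effect_size_label: str
    proportional_r: float
    proportional_p: float
    degenerate: bool = False

    @property
    def has_fixed_bias(self) -> bool:
        return self.fixed_bias_p < 0.05

    @property
    def has_proportional_bias(self) -> bool:
        return self.proportional_p < 0.05

    def loa_confidence_intervals(self, symmetric: bool = False, alpha: float = 0.05):
        """CI bounds for the limits of agreement.

        With ``symmetric=False`` (default) returns the published inner-bound
        pair ``(lower_limits, upper_limits)``; with ``symmetric=True`` returns
        the conventional two-sided intervals ``((lo−, lo+), (hi−, hi+))``.
        """
        t_crit = _st.t.ppf(1 - alpha / 2, self.n - 1)
        half = t_crit * np.sqrt(3.0 * self.sd_diff**2 / self.n)
        if symmetric:
            return (
                (self.loa_low - half, self.loa_low + half),
                (self.loa_high - half, self.loa_high + half),
            )
        return (self.loa_low + half, self.loa_high - half)


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of two paired measurement methods."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("Bland–Altman analysis needs at least 3 pairs")
    diff = x - y
    means = 0.5 * (x + y)
    n = diff.size
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        return BlandAltmanResult(
            n, bias, 0.0, bias, bias, np.nan, np.nan, np.nan, np.nan, np.nan, "undefined", np.nan, np.nan, degenerate=True
        )

    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    t_crit = float(_st.t.ppf(1 - alpha / 2, n - 1))
    half = t_crit * np.sqrt(3.0 * sd**2 / n)
    ci_upper_limit = loa_high - half  # published form: inner interval
    ci_lower_limit = loa_low + half

    t_stat, p_fixed = fixed_bias_test(diff)
    d = abs(bias) / sd
    r, p_prop = _st.pearsonr(means, diff)

    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_upper_limit=float(ci_upper_limit),
        ci_lower_limit=float(ci_lower_limit),
        fixed_bias_t=t_stat,
        fixed_bias_p=p_fixed,
        effect_size=float(d),
        effect_size_label=effect_size_label(d),
        proportional_r=float(r),
        proportional_p=float(p_prop),
    )


@dataclass
class CMCResult:
    value: float
    label: str
    clipped: bool  # True when the radicand was negative and reported as 0


def _cmc_label(c: float) -> str:
    if c < 0.65:
        return "poor"
    if c < 0.75:
        return "moderate"
    if c < 0.85:
        return "good"
    if c < 0.95:
        return "very good"
    return "excellent"


def cmc(waveforms) -> CMCResult:
    """Coefficient of multiple correlation across M time-normalized waveforms.

        CMC = √(1 − [Σₜ Σₘ (Yₘₜ − Ȳₜ)² / (T(M−1))] / [Σₜ Σₘ (Yₘₜ − Ȳ)² / (MT−1)])

    with Ȳₜ the across-waveform mean at each time point and Ȳ the grand
    mean.  Values near 1 mean the waveforms share shape, amplitude and
    timing.  Flat (zero-variance) waveform sets are rejected; a negative
    radicand (between-waveform scatter exceeding total scatter) is reported
    as 0 with ``clipped=True``.
    """
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2:
        raise ValueError("waveforms must be a 2-D array (M, T)")
    m, t = w.shape
    if m < 2 or t < 2:
        raise ValueError("need at least 2 waveforms of at least 2 time points")
    if not np.isfinite(w).all():
        raise ValueError("non-finite waveform values")

    mean_t = w.mean(axis=0)
    grand = w.mean()
    denom = np.sum((w - grand) ** 2) / (m * t - 1)
    if denom == 0:
        raise ValueError("flat waveforms: zero total variance")
    num = np.sum((w - mean_t[None, :]) ** 2) / (t * (m - 1))
    radicand = 1.0 - num / denom
    if radicand < 0:
        return CMCResult(0.0, _cmc_label(0.0), True)
    value = float(np.sqrt(radicand))
    return CMCResult(value, _cmc_label(value), False)


def time_normalize(waveform, n_points: int = 101, t=None) -> np.ndarray:
    """Resample a waveform onto ``n_points`` evenly spaced points over 0–100%.

    Linear interpolation; ``t`` optionally supplies (possibly non-uniform)
    sample times, otherwise samples are assumed evenly spaced.
    """
    v = np.asarray(waveform, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("waveform must be a 1-D series of at least 2 samples")
    if n_points < 2:
        raise ValueError("need at least 2 output points")
    if t is None:
        x = np.linspace(0.0, 1.0, v.size)
    else:
        t = np.asarray(t, dtype=float)
        if t.shape != v.shape:
            raise ValueError("t must match the waveform length")
        x = (t - t[0]) / (t[-1] - t[0])
    return np.interp(np.linspace(0.0, 1.0, n_points), x, v)


@dataclass
class AgreementReport:
    """Aggregate agreement between two pathways over a set of strokes."""

    n_strokes: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    icc: ICCResult
    bland_altman: BlandAltmanResult
    cmc_per_stroke: list
    cmc_mean: float
    cmc_label: str
    n_points: int


def agreement_report(means_x, means_y, waveform_pairs, n_points: int = 101) -> AgreementReport:
    """Full agreement suite on per-stroke means plus per-stroke waveform pairs.

    ``waveform_pairs`` is a sequence of ``(wx, wy)`` force waveforms, one pair
    per stroke, of arbitrary (per-stroke) lengths; each pair is
    time-normalized to ``n_points`` and scored with the 2-waveform CMC, then
    summarized by the mean CMC across strokes.
    """
    means_x = np.asarray(means_x, dtype=float)
    means_y = np.asarray(means_y, dtype=float)
    if means_x.size == 0:
        raise ValueError("no strokes to compare")
    icc = icc_2_1(means_x, means_y)
    ba = bland_altman(means_x, means_y)
    cmcs = []
    for wx, wy in waveform_pairs:
        pair = np.vstack([time_normalize(wx, n_points), time_normalize(wy, n_points)])
        cmcs.append(cmc(pair).value)
    cmc_mean = float(np.mean(cmcs)) if cmcs else np.nan
    return AgreementReport(
        n_strokes=int(means_x.size),
        mean_x=float(np.mean(means_x)),
        mean_y=float(np.mean(means_y)),
        sd_x=float(np.std(means_x, ddof=1)) if means_x.size > 1 else 0.0,
        sd_y=float(np.std(means_y, ddof=1)) if means_y.size > 1 else 0.0,
        icc=icc,
        bland_altman=ba,
        cmc_per_stroke=cmcs,
        cmc_mean=cmc_mean,
        cmc_label=_cmc_label(cmc_mean) if cmcs else "undefined",
        n_points=n_points,
    )
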