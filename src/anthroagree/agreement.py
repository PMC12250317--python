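"""Method-agreement statistics for comparing two measurement methods.

The battery a method-comparison validation study runs for each prediction
equation against a reference method (here: DXA): Shapiro-Wilk normality
gating, paired t / Wilcoxon with Bonferroni families, bias with its
standard error and 95% CI, Bland-Altman limits of agreement, reduced
major axis (RMA) regression, Pearson/Spearman correlation with verbal
bands, two-way single-measurement ICC (absolute agreement and
consistency) with F-based CIs, the technical error of measurement (TEM)
for duplicate readings, and the paired-design sample-size formula.

Sign convention: the bias is ``mean(reference - estimate)``, so a
*positive* bias means the equation *under*-estimates the reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "BiasStats",
    "BlandAltman",
    "PairedTestResult",
    "CorrelationResult",
    "ICCResult",
    "AgreementReport",
    "normality_gate",
    "paired_test",
    "bonferroni_threshold",
    "bias_stats",
    "bland_altman",
    "rma_regression",
    "correlation",
    "icc",
    "icc_band",
    "tem",
    "fisher_z_icc_ci",
    "paired_sample_size",
    "agreement_report",
]

Gate = Literal["normal", "non_normal"]

#: Bonferroni family sizes used by the validation study (number of
#: equations compared per output variable).
FAMILY_SIZES = {"FP": 34, "FM": 6, "LP": 3, "LM": 13}

#: Verbal bands for correlation coefficients (on |r|).
CORRELATION_BANDS = (
    (0.7, "very_strong"),
    (0.4, "strong"),
    (0.3, "moderate"),
    (0.2, "weak"),
    (0.0, "none"),
)

#: Verbal bands for ICC values.
ICC_BANDS = (
    (0.8, "almost_perfect"),
    (0.6, "substantial"),
    (0.4, "moderate"),
    (0.2, "fair"),
    (0.0, "slight"),
)


@dataclass
class PairedSample:
    """Per-subject estimates ``x`` aligned with reference values ``y``."""

    x: np.ndarray
    y: np.ndarray
    family: str = "FP"
    equation_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be aligned 1-d arrays of equal length")
        if self.n < 3:
            raise ValueError(f"paired sample needs n >= 3, got {self.n}")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("paired sample must not contain missing values")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def differences(self) -> np.ndarray:
        """reference - estimate (positive = equation underestimates)."""
        return self.y - self.x


@dataclass
class BiasStats:
    mean_diff: float
    sd_diff: float
    sed: float
    ci95: tuple[float, float]


@dataclass
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass
class PairedTestResult:
    p_value: float
    test_used: Literal["t", "wilcoxon"]
    statistic: float = float("nan")
    note: str = ""


@dataclass
class CorrelationResult:
    coefficient: float
    type: Literal["pearson", "spearman"]
    band: str


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    mode: Literal["absolute", "consistency"]


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> Gate:
    """Shapiro-Wilk gate: ``"normal"`` iff p >= alpha.

    A constant vector cannot be tested and is routed to the
    non-parametric branch with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(arr) == 0.0:
        warnings.warn("constant vector: Shapiro-Wilk undefined, treating as non-normal", stacklevel=2)
        return "non_normal"
    p = stats.shapiro(arr).pvalue
    return "normal" if p >= alpha else "non_normal"


def paired_test(sample: PairedSample, gate: Optional[Gate] = None) -> PairedTestResult:
    """Two-sided paired comparison of estimate vs reference.

    Uses the paired t-test when ``gate`` is ``"normal"`` (equivalently, a
    one-sample t on the differences), else the Wilcoxon signed-rank test
    (exact for n <= 25 without ties, asymptotic with continuity
    correction otherwise).  If ``gate`` is None it is derived from the
    normality of both vectors.
    """
    if gate is None:
        gx, gy = normality_gate(sample.x), normality_gate(sample.y)
        gate = "normal" if (gx == "normal" and gy == "normal") else "non_normal"
    d = sample.differences
    if np.all(d == 0.0):
        return PairedTestResult(1.0, "t", 0.0, "all differences zero; methods identical")
    if gate == "normal":
        res = stats.ttest_rel(sample.y, sample.x)
        return PairedTestResult(float(res.pvalue), "t", float(res.statistic))
    has_ties = np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)
    if sample.n <= 25 and not has_ties and np.all(d != 0):
        res = stats.wilcoxon(d, method="exact")
    else:
        res = stats.wilcoxon(d, method="approx", correction=True)
    return PairedTestResult(float(res.pvalue), "wilcoxon", float(res.statistic))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def bias_stats(sample: PairedSample, conf: float = 0.95) -> BiasStats:
    """Mean bias, SD of the differences, SED = SD/sqrt(n) and the t-based CI."""
    d = sample.differences
    n = sample.n
    if n < 2:
        raise ValueError("bias statistics need n >= 2")
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    sed = sd_diff / math.sqrt(n)
    tq = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    return BiasStats(mean_diff, sd_diff, sed, (mean_diff - tq * sed, mean_diff + tq * sed))


def bland_altman(sample: PairedSample) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    d = sample.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    means = (sample.x + sample.y) / 2.0
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, means, d)


def rma_regression(y: Sequence[float], x: Sequence[float]) -> tuple[float, float]:
    """Reduced major axis (geometric-mean) regression of y on x.

    slope = sign(r) * SD(y)/SD(x); intercept = mean(y) - slope * mean(x).
    ``y`` is the reference method (the study regresses DXA on the
    equation estimate).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    sx = np.std(xa, ddof=1)
    sy = np.std(ya, ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("RMA regression needs non-zero variance in both variables")
    r = float(np.corrcoef(xa, ya)[0, 1])
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(np.mean(ya)) - slope * float(np.mean(xa))
    return float(slope), intercept


def _band(value: float, bands: tuple[tuple[float, str], ...]) -> str:
    for cutoff, label in bands:
        if value >= cutoff:
            return label
    return bands[-1][1]


def correlation(sample: PairedSample, gate: Optional[Gate] = None) -> CorrelationResult:
    """Pearson (normal gate) or Spearman correlation with its verbal band."""
    if gate is None:
        gx, gy = normality_gate(sample.x), normality_gate(sample.y)
        gate = "normal" if (gx == "normal" and gy == "normal") else "non_normal"
    if gate == "normal":
        r = float(stats.pearsonr(sample.x, sample.y).statistic)
        kind: Literal["pearson", "spearman"] = "pearson"
    else:
        if np.ptp(sample.x) == 0.0 or np.ptp(sample.y) == 0.0:
            raise ValueError("Spearman correlation undefined for an all-ties vector")
        r = float(stats.spearmanr(sample.x, sample.y).statistic)
        kind = "spearman"
    return CorrelationResult(r, kind, _band(abs(r), CORRELATION_BANDS))


def _anova_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (subjects x methods) ANOVA mean squares for n x 2 data."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between methods
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc(
    sample: PairedSample,
    mode: Literal["absolute", "consistency"],
    conf: float = 0.95,
    truncate_method_variance: bool = True,
) -> ICCResult:
    """Two-way single-measurement intraclass correlation.

    ``consistency`` is ICC(C,1): the between-method variance is excluded
    from the denominator, so a constant shift between methods does not
    hurt.  ``absolute`` is ICC(A,1): the method variance counts as error.
    CIs use the standard F-distribution construction (Satterthwaite
    degrees of freedom for the absolute case).  Negative estimates are
    returned as computed.

    By default a *negative* between-method variance-component estimate
    (MSC < MSE, possible in samples although the population component is
    non-negative) is truncated at zero, which guarantees
    ICC(A,1) <= ICC(C,1) whenever subjects are more variable than the
    residual.  ``truncate_method_variance=False`` gives the raw
    McGraw-Wong formula as reported by pingouin/irr.
    """
    if mode not in ("absolute", "consistency"):
        raise ValueError(f"mode must be 'absolute' or 'consistency', got {mode!r}")
    if sample.n < 5:
        raise ValueError("ICC confidence intervals need n >= 5")
    msr, msc, mse, n, k = _anova_mean_squares(sample.x, sample.y)
    if msr == 0.0 and msc == 0.0 and mse == 0.0:
        raise ValueError("ICC undefined: zero total variance")
    alpha = 1.0 - conf
    if mode == "consistency":
        if mse == 0.0:
            return ICCResult(1.0, (1.0, 1.0), mode)
        value = (msr - mse) / (msr + (k - 1) * mse)
        fobs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return ICCResult(float(value), (float(lo), float(hi)), mode)
    method_component = msc - mse
    if truncate_method_variance:
        method_component = max(method_component, 0.0)
    denom = msr + (k - 1) * mse + k * method_component / n
    if denom == 0.0:
        raise ValueError("ICC(absolute) undefined: zero denominator")
    value = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        return ICCResult(1.0, (1.0, 1.0), mode)
    # McGraw & Wong (1996) CI with Satterthwaite df
    r = value
    a = k * r / (n * (1 - r)) if r != 1.0 else float("inf")
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r != 1.0 else float("inf")
    if math.isinf(a) or math.isinf(b):
        return ICCResult(float(value), (float("nan"), float("nan")), mode)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(float(value), (float(lo), float(hi)), mode)


def icc_band(value: float) -> str:
    """Verbal agreement band for an ICC (values <= 0 are 'poor')."""
    if value <= 0.0:
        return "poor"
    return _band(value, ICC_BANDS)


def tem(duplicate_pairs: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Technical error of measurement from duplicate readings.

    ``tem_abs = sqrt(sum(d_i^2) / (2n))`` over the n duplicate pairs;
    the relative TEM expresses it as a percentage of the grand mean.
    Returns ``(tem_abs, tem_relative_percent)``.
    """
    pairs = np.asarray(duplicate_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 duplicate pairs, shaped (n, 2)")
    d = pairs[:, 0] - pairs[:, 1]
    tem_abs = math.sqrt(float(np.sum(d**2)) / (2 * pairs.shape[0]))
    grand = float(pairs.mean())
    if grand == 0.0:
        raise ValueError("relative TEM undefined: zero grand mean")
    return tem_abs, tem_abs / grand * 100.0


def fisher_z_icc_ci(icc_value: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform CI for a correlation-type coefficient.

    ``atanh(icc) +/- z_{1-alpha/2} / sqrt(n - 3)``, back-transformed.
    """
    if n < 4:
        raise ValueError("Fisher z CI needs n >= 4")
    if abs(icc_value) >= 1.0:
        if abs(icc_value) == 1.0:
            warnings.warn("|icc| = 1: degenerate CI", stacklevel=2)
            return (icc_value, icc_value)
        raise ValueError(f"icc must lie in (-1, 1), got {icc_value}")
    z = math.atanh(icc_value)
    half = stats.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def paired_sample_size(delta: float, sd_diff: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Minimum n for a paired design, two-sided normal approximation.

    ``n = ceil(((z_{1-alpha/2} + z_power) * sd_diff / delta)^2)``,
    clamped to a minimum of 2.
    """
    if delta <= 0 or sd_diff <= 0:
        raise ValueError("delta and sd_diff must be strictly positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = math.ceil(((za + zb) * sd_diff / delta) ** 2)
    return max(n, 2)


@dataclass
class AgreementReport:
    """One equation's full row of agreement statistics vs the reference."""

    equation_id: str
    family: str
    n: int
    mean_diff: float
    sd_diff: float
    sed: float
    ci95: tuple[float, float]
    p_value: float
    test_used: str
    significant_after_bonferroni: bool
    icc_absolute: float
    icc_absolute_ci: tuple[float, float]
    icc_consistency: float
    icc_consistency_ci: tuple[float, float]
    corr: float
    corr_type: str
    corr_band: str
    rma_slope: float
    rma_intercept: float
    loa: tuple[float, float]
    gate: str = "normal"
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def icc_absolute_band(self) -> str:
        return icc_band(self.icc_absolute)

    @property
    def icc_consistency_band(self) -> str:
        return icc_band(self.icc_consistency)


def agreement_report(
    sample: PairedSample,
    alpha: float = 0.05,
    family_size: Optional[int] = None,
    gate: Optional[Gate] = None,
) -> AgreementReport:
    """Run the full battery on one paired sample.

    The normality gate (unless supplied) checks both the estimate and the
    reference vectors; the Bonferroni family size defaults to the study's
    per-family comparison counts.
    """
    if gate is None:
        gx, gy = normality_gate(sample.x), normality_gate(sample.y)
        gate = "normal" if (gx == "normal" and gy == "normal") else "non_normal"
    m = family_size if family_size is not None else FAMILY_SIZES.get(sample.family, 1)
    test = paired_test(sample, gate)
    bias = bias_stats(sample)
    ba = bland_altman(sample)
    slope, intercept = rma_regression(sample.y, sample.x)
    corr = correlation(sample, gate)
    icc_a = icc(sample, "absolute")
    icc_c = icc(sample, "consistency")
    return AgreementReport(
        equation_id=sample.equation_id,
        family=sample.family,
        n=sample.n,
        mean_diff=bias.mean_diff,
        sd_diff=bias.sd_diff,
        sed=bias.sed,
        ci95=bias.ci95,
        p_value=test.p_value,
        test_used=test.test_used,
        significant_after_bonferroni=test.p_value < bonferroni_threshold(alpha, m),
        icc_absolute=icc_a.icc,
        icc_absolute_ci=icc_a.ci95,
        icc_consistency=icc_c.icc,
        icc_consistency_ci=icc_c.ci95,
        corr=corr.coefficient,
        corr_type=corr.type,
        corr_band=corr.band,
        rma_slope=slope,
        rma_intercept=intercept,
        loa=(ba.loa_lower, ba.loa_upper),
        gate=gate,
    )
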