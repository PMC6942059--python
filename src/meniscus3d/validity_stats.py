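"""Statistical toolkit for the method-agreement study.

Normality (Shapiro–Wilk), two-sample comparison with Cohen's d,
consistency regression between modalities (OLS with adjusted R²),
intra-rater intraclass correlation, and a-priori power / sample size from
the noncentral t distribution — the toolchain used to validate a new
measurement against a reference modality on a small cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

_ICC_TYPE = {
    "oneway": "ICC(1,1)",
    "twoway_consistency": "ICC(C,1)",
    "twoway_agreement": "ICC(A,1)",
}


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    cohens_d: float
    df: float


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """Simple OLS y ~ x with the fields such studies tabulate."""

    b: float  # unstandardized slope
    se_b: float
    beta: float  # standardized slope
    t_stat: float
    p_value: float
    r2_adj: float
    f_stat: float
    df: tuple
    intercept: float


@dataclasses.dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95_low: float
    ci95_high: float
    model: str


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Inputs of an a-priori sample-size calculation."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.95
    test: str = "one_sample"
    tails: str = "two"

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size must be > 0")
        if self.test not in ("one_sample", "two_sample"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.tails not in ("one", "two"):
            raise ValueError(f"tails must be 'one' or 'two'")


def shapiro_wilk(x) -> tuple:
    """Shapiro–Wilk W and p for 3 <= n <= 5000 finite values."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def cohens_d(mean_difference: float, sd: float) -> float:
    """Standardized mean difference from summary statistics."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return mean_difference / sd


def two_sample_t(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test with Cohen's d.

    This mirrors how paired CT/MRI measurements are compared in
    method-agreement studies (a paired test would be statistically tighter;
    see :func:`paired_t`).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    var_p = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if var_p == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(var_p)
    return TTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=float(d),
        df=float(na + nb - 2),
    )


def paired_t(a, b) -> TTestResult:
    """Paired t-test with d computed on the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired test needs equal-length samples, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(a, b)
    return TTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=float(diff.mean() / sd),
        df=float(len(a) - 1),
    )


def consistency_regression(y_ct, x_mri) -> RegressionResult:
    """OLS of the reference-modality value on the test-modality value.

    Adjusted R² = 1 - (1 - R²)(n - 1)/(n - 2); F has (1, n - 2) df.
    """
    y = np.asarray(y_ct, dtype=float)
    x = np.asarray(x_mri, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("regression needs equal-length samples, n >= 3")
    if x.var(ddof=1) == 0:
        raise ValueError("zero variance in the independent variable")
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    sy = y.std(ddof=1)
    beta = b * x.std(ddof=1) / sy if sy > 0 else np.nan
    return RegressionResult(
        b=b,
        se_b=float(fit.bse[1]),
        beta=float(beta),
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        r2_adj=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        df=(1, int(fit.df_resid)),
        intercept=float(fit.params[0]),
    )


def icc_intra_rater(measurements, model: str = "twoway_agreement") -> ICCResult:
    """Intraclass correlation for repeated measurements (single measures).

    ``measurements`` is (n_subjects, k_repeats), k >= 2; the default model
    is two-way absolute agreement (ICC(2,1)); one-way and two-way
    consistency variants are exposed via ``model``.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("measurements must be (n_subjects, k>=2)")
    if m.shape[0] < 5:
        raise ValueError("ICC needs at least 5 subjects")
    if not np.isfinite(m).all():
        raise ValueError("missing repeat in the measurement matrix")
    if model not in _ICC_TYPE:
        raise ValueError(f"unknown ICC model {model!r}")
    n, k = m.shape
    if float(m.var(axis=1, ddof=1).sum()) == 0.0:
        # repeats agree exactly: the variance-ratio limit is 1
        return ICCResult(icc=1.0, ci95_low=1.0, ci95_high=1.0, model=model)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # pingouin emits divide-by-zero warnings when repeats agree exactly
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    row = table.loc[_ICC_TYPE[model]]
    lo, hi = row["CI95"]
    return ICCResult(
        icc=float(row["ICC"]), ci95_low=float(lo), ci95_high=float(hi), model=model
    )


def achieved_power(
    d: float,
    n: int,
    alpha: float = 0.05,
    test: str = "one_sample",
    tails: str = "two",
) -> float:
    """Power of a t-test at effect size ``d`` and per-group size ``n``,
    from the noncentral t distribution."""
    if n < 2:
        return 0.0
    if test == "one_sample":
        df = n - 1
        nc = d * np.sqrt(n)
    else:
        df = 2 * n - 2
        nc = d * np.sqrt(n / 2.0)
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(
            1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        )
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc))


def required_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n with power >= the requested power; deterministic scan."""
    for n in range(2, n_max + 1):
        if achieved_power(spec.effect_size_d, n, spec.alpha, spec.test, spec.tails) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} unreachable for d={spec.effect_size_d} within n<={n_max}")
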