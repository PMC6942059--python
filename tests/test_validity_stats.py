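"""Statistical toolkit: dual-implementation oracles and identities."""

import shutil
import subprocess

import numpy as np
import pytest

from meniscus3d import (
    PowerSpec,
    achieved_power,
    cohens_d,
    consistency_regression,
    icc_intra_rater,
    required_sample_size,
    shapiro_wilk,
    two_sample_t,
)
from meniscus3d.validity_stats import paired_t


class TestShapiroWilk:
    def test_normal_quantiles_high_w(self):
        from scipy import stats

        x = stats.norm.ppf((np.arange(1, 11) - 0.5) / 10)
        w, p = shapiro_wilk(x)
        assert w > 0.99

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_r_implementation(self):
        x = [2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0]
        w, p = shapiro_wilk(x)
        script = (
            "r <- shapiro.test(c(2,4,4,4,5,5,7,9));"
            "cat(sprintf('%.6f %.6f', r$statistic, r$p.value))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        assert w == pytest.approx(float(out[0]), abs=1e-4)
        assert p == pytest.approx(float(out[1]), abs=1e-4)


class TestTwoSampleT:
    def test_identical_samples(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p_value == 1.0
        assert r.cohens_d == 0.0

    def test_closed_form_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        r = two_sample_t(a, b)
        sp2 = ((a.var(ddof=1)) * 2 + (b.var(ddof=1)) * 2) / 4
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert r.t == pytest.approx(t_expected, abs=1e-10)
        assert r.cohens_d == pytest.approx((a.mean() - b.mean()) / np.sqrt(sp2), abs=1e-10)

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        fwd = two_sample_t(a, b)
        rev = two_sample_t(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])

    def test_effect_size_from_summary(self):
        # surface-difference summary 0.82 +/- 0.62 mm gives d = 1.32
        assert cohens_d(0.82, 0.62) == pytest.approx(1.32, abs=0.005)

    def test_paired_variant(self, rng):
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.3, 0.1, 10)
        r = paired_t(a, b)
        assert r.df == 9
        assert r.p_value < 0.01


class TestConsistencyRegression:
    def test_identity_line(self):
        x = np.arange(10, dtype=float)
        r = consistency_regression(x, x)
        assert r.b == pytest.approx(1.0, abs=1e-12)
        assert r.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert r.beta == pytest.approx(1.0, abs=1e-12)

    def test_exact_affine_recovery(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 7.0])
        y = 3.5 + 2.0 * x
        r = consistency_regression(y, x)
        assert r.b == pytest.approx(2.0, abs=1e-10)
        assert r.intercept == pytest.approx(3.5, abs=1e-10)
        assert r.r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_oracle(self, rng):
        # hand-computed least squares via covariance formulas
        x = rng.normal(10, 2, 15)
        y = 2.0 + 0.97 * x + rng.normal(0, 0.3, 15)
        r = consistency_regression(y, x)
        b_hat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert r.b == pytest.approx(b_hat, abs=1e-10)
        n = len(x)
        resid = y - (r.intercept + r.b * x)
        r2 = 1 - resid.var(ddof=0) / y.var(ddof=0)
        assert r.r2_adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 2), abs=1e-10)
        assert r.df == (1, n - 2)

    def test_simulated_modality_consistency(self, rng):
        truth = rng.uniform(500, 1500, 10)
        ct = truth + rng.normal(0, 5, 10)
        mri = truth + rng.normal(0, 5, 10)
        r = consistency_regression(ct, mri)
        assert r.r2_adj >= 0.99
        assert abs(r.b - 1.0) < 3 * r.se_b

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            consistency_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestICC:
    def test_identical_repeats(self):
        m = np.column_stack([np.arange(8.0), np.arange(8.0)])
        assert icc_intra_rater(m).icc == 1.0

    def test_model_distinction_on_shifted_repeats(self):
        base = np.arange(8.0)
        m = np.column_stack([base, base + 0.5])
        assert icc_intra_rater(m, "twoway_consistency").icc == pytest.approx(1.0, abs=1e-9)
        assert icc_intra_rater(m, "twoway_agreement").icc < 1.0

    def test_small_rater_noise_regime(self, rng):
        subj = rng.normal(0, 1.0, 8)
        m = np.column_stack(
            [subj + rng.normal(0, 0.05, 8), subj + rng.normal(0, 0.05, 8)]
        )
        r = icc_intra_rater(m)
        assert r.icc >= 0.99
        assert r.ci95_low <= r.icc <= r.ci95_high

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_null_regime_wide_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = np.column_stack([rng.normal(0, 1, 8), rng.normal(0, 1, 8)])
        r = icc_intra_rater(m)
        assert r.ci95_high - r.ci95_low > 0.5  # tiny n: the CI must be wide
        assert r.ci95_low < 0.3

    def test_missing_repeat_rejected(self):
        m = np.column_stack([np.arange(8.0), np.arange(8.0)])
        m[3, 1] = np.nan
        with pytest.raises(ValueError):
            icc_intra_rater(m)


class TestPower:
    def test_published_sample_size(self):
        spec = PowerSpec(effect_size_d=1.32, alpha=0.05, power=0.95)
        assert required_sample_size(spec) == 10

    def test_monotone_in_power(self):
        n95 = required_sample_size(PowerSpec(1.32, power=0.95))
        n99 = required_sample_size(PowerSpec(1.32, power=0.99))
        assert n99 >= n95

    def test_against_statsmodels_oracle(self):
        import statsmodels.stats.power as smp

        spec = PowerSpec(effect_size_d=0.5, alpha=0.05, power=0.80)
        n = required_sample_size(spec)
        oracle = smp.TTestPower()
        # brute scan over the independent implementation
        n_oracle = next(
            m
            for m in range(2, 1000)
            if oracle.power(0.5, m, 0.05, alternative="two-sided") >= 0.80
        )
        assert n == n_oracle

    def test_unreachable_power(self):
        with pytest.raises(ValueError):
            required_sample_size(PowerSpec(0.001, power=0.99), n_max=100)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(effect_size_d=-1.0)
        with pytest.raises(ValueError):
            PowerSpec(effect_size_d=1.0, alpha=1.5)
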