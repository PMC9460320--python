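"""Agreement statistics against brute-force oracles and reference software."""

import math

import numpy as np
import pytest

from swimforce import stats as st


def exact_moments_sample(mean, sd, n, seed=0):
    """Sample with exactly the requested mean and (ddof=1) sd."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPairedTTest:
    def test_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 2.3, 2.8])
        t, p = st.paired_t_test(x, y)
        # brute-force evaluation of the defining formula
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), len(d) - 1)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_vectors_convention(self):
        t, p = st.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            st.paired_t_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])


class TestCohensD:
    def test_identical_groups(self):
        d, label = st.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and label == "negligible"

    def test_unit_separation_pooled(self):
        x = exact_moments_sample(0.0, 1.0, 50, seed=1)
        y = exact_moments_sample(1.0, 1.0, 50, seed=2)
        d, label = st.cohens_d(x, y, "pooled")
        assert d == pytest.approx(1.0, abs=1e-12)
        assert label == "large"

    def test_flume_pressure_summary_consistency(self):
        """Pooled d from the summary pressures −1.48 ± 0.07 vs −0.92 ± 0.06 kPa
        (n = 10 runs each) evaluates to ≈ 8.59."""
        x = exact_moments_sample(-1.48, 0.07, 10, seed=3)
        y = exact_moments_sample(-0.92, 0.06, 10, seed=4)
        d, label = st.cohens_d(x, y, "pooled")
        assert d == pytest.approx(0.56 / math.sqrt((0.07**2 + 0.06**2) / 2), abs=1e-9)
        assert d == pytest.approx(8.59, abs=0.01)
        assert label == "large"

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 30)
        d1, _ = st.cohens_d(x, y, "pooled")
        d2, _ = st.cohens_d(7.3 * x, 7.3 * y, "pooled")
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_paired_variant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.2, 2.1, 3.4, 4.1])
        d, _ = st.cohens_d(x, y, "paired")
        diff = x - y
        assert d == pytest.approx(abs(diff.mean()) / diff.std(ddof=1), abs=1e-12)


def brute_force_icc_2_1(data):
    """Independent two-way ANOVA decomposition via explicit loops."""
    n, k = data.shape
    grand = data.sum() / (n * k)
    ssr = ssc = sse = 0.0
    row_means = [sum(data[i]) / k for i in range(n)]
    col_means = [sum(data[:, j]) / n for j in range(k)]
    for i in range(n):
        ssr += k * (row_means[i] - grand) ** 2
    for j in range(k):
        ssc += n * (col_means[j] - grand) ** 2
    for i in range(n):
        for j in range(k):
            sse += (data[i, j] - row_means[i] - col_means[j] + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    DATA = np.array(
        [[9.0, 10.0], [11.0, 13.0], [4.0, 6.0], [7.0, 6.0], [10.0, 12.0]]
    )

    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = st.icc_2_1(x, x.copy())
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_anova(self):
        res = st.icc_2_1(self.DATA[:, 0], self.DATA[:, 1])
        assert res.icc == pytest.approx(brute_force_icc_2_1(self.DATA), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = len(self.DATA)
        df = pd.DataFrame(
            {
                "targets": list(range(n)) * 2,
                "raters": ["a"] * n + ["b"] * n,
                "scores": np.concatenate([self.DATA[:, 0], self.DATA[:, 1]]),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        res = st.icc_2_1(self.DATA[:, 0], self.DATA[:, 1])
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin reports the CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(row["CI95"][0], abs=5.1e-3)
        assert res.ci_high == pytest.approx(row["CI95"][1], abs=5.1e-3)
        assert res.p == pytest.approx(row["pval"], rel=1e-6)

    def test_offset_penalized_absolute_agreement(self):
        """A constant offset between methods must lower ICC(2,1) far below 1
        even though a consistency-type ICC would remain 1."""
        x = np.linspace(0.0, 1.0, 20)
        res = st.icc_2_1(x, x + 5.0)
        assert res.icc < 0.1

    def test_relabeling_invariance(self):
        a = st.icc_2_1(self.DATA[:, 0], self.DATA[:, 1])
        b = st.icc_2_1(self.DATA[:, 1], self.DATA[:, 0])
        assert a.icc == pytest.approx(b.icc, abs=1e-12)

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ValueError):
            st.icc_2_1([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestBlandAltman:
    def test_textbook_peak_flow_example(self):
        """Reproduces a classic peak-flow agreement example from its printed
        summary: bias −2.1 l/min, SD 38.8, n = 17."""
        n, bias, sd = 17, -2.1, 38.8
        diff = exact_moments_sample(bias, sd, n, seed=6)
        x = exact_moments_sample(450.0, 100.0, n, seed=7)
        res = st.bland_altman(x, x - diff)
        assert res.bias == pytest.approx(bias, abs=1e-9)
        assert res.sd_diff == pytest.approx(sd, abs=1e-9)
        assert res.loa_low == pytest.approx(bias - 1.96 * sd, abs=1e-9)
        assert res.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-9)
        # published-form CI bounds computed by hand
        from scipy.stats import t as tdist

        half = tdist.ppf(0.975, n - 1) * math.sqrt(3.0 * sd**2 / n)
        assert res.ci_upper_limit == pytest.approx(bias + 1.96 * sd - half, abs=1e-9)
        assert res.ci_lower_limit == pytest.approx(bias - 1.96 * sd + half, abs=1e-9)
        # conventional symmetric intervals bracket each limit
        (lo_lo, lo_hi), (hi_lo, hi_hi) = res.loa_confidence_intervals(symmetric=True)
        assert lo_lo < res.loa_low < lo_hi
        assert hi_lo < res.loa_high < hi_hi

    def test_identical_methods_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = st.bland_altman(x, x.copy())
        assert res.degenerate
        assert res.bias == 0.0 and res.sd_diff == 0.0

    def test_fixed_bias_detected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10.0, 2.0, 50)
        y = x + 1.0 + rng.normal(0.0, 0.3, 50)
        res = st.bland_altman(x, y)
        assert res.has_fixed_bias
        assert not res.has_proportional_bias

    def test_proportional_bias_detected(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(5.0, 25.0, 60)
        y = 1.5 * x + rng.normal(0.0, 0.5, 60)
        res = st.bland_altman(x, y)
        assert res.has_proportional_bias


def brute_force_cmc(w):
    """Direct evaluation of the CMC formula with explicit loops."""
    m, t = w.shape
    ybar_t = [sum(w[:, j]) / m for j in range(t)]
    ybar = sum(sum(row) for row in w) / (m * t)
    num = sum((w[i, j] - ybar_t[j]) ** 2 for i in range(m) for j in range(t)) / (t * (m - 1))
    den = sum((w[i, j] - ybar) ** 2 for i in range(m) for j in range(t)) / (m * t - 1)
    return math.sqrt(max(0.0, 1.0 - num / den))


class TestCMC:
    def test_identical_waveforms(self):
        w = np.tile(np.sin(np.linspace(0, np.pi, 101)), (2, 1))
        res = st.cmc(w)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.label == "excellent"

    def test_independent_noise_is_poor(self):
        rng = np.random.default_rng(10)
        w = rng.normal(size=(2, 101))
        res = st.cmc(w)
        assert res.value < 0.64

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(11)
        base = np.sin(np.linspace(0, np.pi, 101))
        w = np.vstack([base, base + 0.1 * rng.normal(size=101)])
        res = st.cmc(w)
        assert res.value == pytest.approx(brute_force_cmc(w), abs=1e-10)
        assert 0.64 < res.value < 1.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(12)
        w = rng.normal(size=(2, 50)) + np.sin(np.linspace(0, 2 * np.pi, 50))
        assert st.cmc(w).value == pytest.approx(st.cmc(w[::-1]).value, abs=1e-12)

    def test_flat_waveforms_rejected(self):
        with pytest.raises(ValueError):
            st.cmc(np.ones((2, 10)))

    def test_negative_radicand_clipped_and_flagged(self):
        # anti-phase waveforms: within-time scatter exceeds total scatter
        base = np.sin(np.linspace(0, 2 * np.pi, 50))
        res = st.cmc(np.vstack([base, -base]))
        assert res.value == 0.0
        assert res.clipped


class TestTimeNormalize:
    def test_identity_when_already_target_length(self):
        v = np.sin(np.linspace(0, 1, 101))
        np.testing.assert_allclose(st.time_normalize(v, 101), v, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        v = np.linspace(0.0, 5.0, 37)
        out = st.time_normalize(v, 144)
        np.testing.assert_allclose(out, np.linspace(0.0, 5.0, 144), atol=1e-12)

    def test_half_sine_peak_preserved(self):
        v = np.sin(np.pi * np.linspace(0.0, 1.0, 87))
        out = st.time_normalize(v, 101)
        assert out[50] == pytest.approx(1.0, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.time_normalize(np.array([1.0, 2.0]), 1)
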