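"""Summary stats, contingency/chi-square, correlation-t, dispersion, and ESD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cpglandscape.datasets import CGI_GENE_CONTINGENCY
from cpglandscape.distribution_stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    correlation_t_test,
    density_histogram,
    dispersion_diagnostic,
    esd_outlier_test,
    expected_cpg_fraction,
    histogram_correlation,
    presence_contingency,
    summarize_counts,
)
from cpglandscape.genome_model import InputError


class TestSummaries:
    def test_hand_computed_summary(self):
        s = summarize_counts(np.array([2, 2, 4, 8, 0]))
        assert s.avg == pytest.approx(3.2)
        assert s.std_dev == pytest.approx(math.sqrt(36.8 / 4), abs=1e-12)
        assert (s.min, s.max, s.median) == (0, 8, 2.0)
        assert s.df == 4  # bins holding at least one element

    def test_constant_and_simple_cases(self):
        assert summarize_counts(np.array([0, 1, 2, 3])).avg == 1.5
        assert summarize_counts(np.full(5, 7)).std_dev == 0.0
        with pytest.raises(InputError):
            summarize_counts(np.array([]))


class TestContingency:
    def test_presence_cells_partition_the_bins(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(1.0, 500)
        b = rng.poisson(1.0, 500)
        t = presence_contingency(a, b)
        assert t.n == 500
        same = presence_contingency(a, a)
        assert same.b == same.c == 0  # identity => no discordant cells

    def test_all_zero_tracks_fully_concordant(self):
        t = presence_contingency(np.zeros(50), np.zeros(50))
        assert t.a == 50 and t.concordance == 1.0

    def test_published_human_table_concordance(self):
        assert round(CGI_GENE_CONTINGENCY["human"].concordance, 2) == 0.76

    def test_chi_square_expected_counts_oracle(self):
        stat, p, dof = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        # direct sum((O-E)^2/E): E = 15 everywhere, sum = 4 * 25/15
        assert stat == pytest.approx(20 / 3)
        assert dof == 1
        assert chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))[0] == 0.0

    def test_chi_square_matches_scipy(self):
        t = ContingencyTable2x2(123, 45, 67, 89)
        for continuity, correction in (("none", False), ("yates", True)):
            stat, p, _ = chi_square_2x2(t, continuity)
            ref = sps.chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=correction
            )
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_chi_square_transpose_and_swap_invariance(self, cells):
        t = ContingencyTable2x2(*cells)
        stat, _, _ = chi_square_2x2(t)
        assert chi_square_2x2(t.transpose())[0] == pytest.approx(stat, rel=1e-12)
        swapped = ContingencyTable2x2(t.a, t.c, t.b, t.d)
        assert chi_square_2x2(swapped)[0] == pytest.approx(stat, rel=1e-12)

    def test_zero_margin_names_the_margin(self):
        with pytest.raises(InputError, match="margin"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestCorrelation:
    def test_t_formula_identity_and_scipy_p(self):
        rng = np.random.default_rng(1)
        for n in (5, 30, 200):
            x = rng.normal(size=n)
            y = x * 0.5 + rng.normal(size=n)
            res = correlation_t_test(x, y)
            assert res.t == pytest.approx(
                res.r * math.sqrt(n - 2) / math.sqrt(1 - res.r**2), rel=1e-13
            )
            ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_perfect_and_null_correlation_limits(self):
        x = np.arange(10.0)
        res = correlation_t_test(x, x)
        assert res.r == 1.0 and math.isinf(res.t) and res.p == 0.0
        # exactly balanced pairing -> r = 0 -> t = 0
        res0 = correlation_t_test([1, 2, 3, 4], [1, 2, 2, 1])
        assert res0.t == pytest.approx(0.0, abs=1e-12)

    def test_df_convention_flag(self):
        x = [1.0, 2, 3, 4, 5]
        y = [1.1, 1.9, 3.2, 3.8, 5.1]
        assert correlation_t_test(x, y).df == 3
        assert correlation_t_test(x, y, df_convention="n-1").df == 4

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            correlation_t_test([1, 1, 1], [1, 2, 3])


class TestHistograms:
    def test_density_histogram_and_cap(self):
        h = density_histogram(np.array([0, 0, 1, 2, 2]))
        assert h.to_dict() == {0: 2, 1: 1, 2: 2}
        capped = density_histogram(np.array([0, 0, 1, 2, 2]), cap=1)
        assert capped.to_dict() == {0: 2, 1: 3}
        with pytest.raises(InputError):
            density_histogram(np.array([]))

    def test_histogram_correlation_equals_direct_pearson(self):
        ha = density_histogram(np.repeat([0, 1, 2, 3, 4], [3, 5, 9, 4, 1]))
        hb = density_histogram(np.repeat([0, 1, 2, 3, 4], [2, 6, 8, 5, 1]))
        res = histogram_correlation(ha, hb)
        ref = sps.pearsonr([3, 5, 9, 4, 1], [2, 6, 8, 5, 1])
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert histogram_correlation(ha, ha).r == 1.0

    def test_drop_zero_class_removes_only_density_zero(self):
        ha = density_histogram(np.repeat([0, 1, 2, 3], [10, 5, 3, 2]))
        hb = density_histogram(np.repeat([0, 1, 2, 3], [1, 5, 3, 2]))
        with_zero = histogram_correlation(ha, hb)
        without = histogram_correlation(ha, hb, drop_zero_class=True)
        assert without.n == with_zero.n - 1
        assert without.r == pytest.approx(1.0)


def test_expected_cpg_frequency_under_independence():
    assert expected_cpg_fraction(0.42) == pytest.approx(0.0441)


class TestDispersion:
    def test_simulated_family_verdicts(self):
        rng = np.random.default_rng(42)
        geo = rng.geometric(0.1, 5000) - 1  # support {0,1,...}
        assert dispersion_diagnostic(geo).verdict == "heavy-tailed/clustered"
        pois = rng.poisson(40, 5000)
        d = dispersion_diagnostic(pois)
        assert d.verdict == "binomial-like"
        assert d.loglik_poisson > d.loglik_geometric

    def test_constant_counts_binomial_like(self):
        d = dispersion_diagnostic(np.full(50, 3))
        assert d.variance_mean_ratio == 0.0
        assert d.verdict == "binomial-like"

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            dispersion_diagnostic(np.zeros(20))


def _iterated_grubbs(x, k, alpha):
    """Independent oracle: Rosner's procedure as a plain loop of Grubbs steps."""
    x = list(map(float, x))
    idx = list(range(len(x)))
    out = []
    for i in range(k):
        n = len(x)
        mean = sum(x) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
        dev = [abs(v - mean) for v in x]
        j = dev.index(max(dev))
        r = dev[j] / sd
        t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        lam = (n - 1) * t / math.sqrt((n - 2 + t * t) * n)
        out.append((idx[j], r, lam))
        x.pop(j)
        idx.pop(j)
    n_out = max([i + 1 for i, (_, r, lam) in enumerate(out) if r > lam], default=0)
    return out, n_out


class TestEsd:
    def test_single_gross_outlier_flagged(self):
        steps = esd_outlier_test([2, 3, 2, 4, 3, 100], max_outliers=2, alpha=0.05)
        flagged = [s.index for s in steps if s.is_outlier]
        assert flagged == [5]

    def test_matches_iterated_grubbs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(10, 2, 25)
            x[rng.integers(25)] += rng.choice([-1, 1]) * rng.uniform(5, 15)
            steps = esd_outlier_test(x, max_outliers=4, alpha=0.05)
            ref, n_out = _iterated_grubbs(x, 4, 0.05)
            for s, (ri, rr, rlam) in zip(steps, ref):
                assert s.index == ri
                assert s.statistic == pytest.approx(rr, rel=1e-10)
                assert s.critical_value == pytest.approx(rlam, rel=1e-10)
            assert sum(s.is_outlier for s in steps) == n_out

    def test_reduces_to_grubbs_at_one_outlier(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=15)
            [step] = esd_outlier_test(x, max_outliers=1, alpha=0.05)
            ref, n_out = _iterated_grubbs(x, 1, 0.05)
            assert step.statistic == pytest.approx(ref[0][1], rel=1e-12)
            assert step.is_outlier == (n_out == 1)

    def test_planted_chromosome_scale_outlier(self):
        # 24 chromosome-level densities, one planted 2.5x extreme
        rng = np.random.default_rng(5)
        dens = rng.normal(40, 6, 24)
        dens[18] = 100.0
        steps = esd_outlier_test(dens, max_outliers=3, alpha=0.05)
        assert any(s.index == 18 and s.is_outlier for s in steps)

    def test_degenerate_inputs(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert esd_outlier_test([5, 5, 5, 5, 5], max_outliers=2) == []
        with pytest.raises(InputError):
            esd_outlier_test([1, 2, 3, 4], max_outliers=2)
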