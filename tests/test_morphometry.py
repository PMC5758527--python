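"""Shell indices, population aggregation and inter-population statistics."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pearlclim import morphometry as m
from pearlclim.errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidMeasurementError,
    UndefinedCorrelationError,
)

from conftest import make_population


def shell(L, H, W, sid="s1", pid="p1", **kw):
    return m.ShellRecord(sid, pid, L, H, W, kw.pop("year", 2000), **kw)


class TestIndices:
    @pytest.mark.parametrize(
        "L, W, expected",
        [(100.0, 30.0, 30.0), (104.5, 31.2, 29.8565)],
    )
    def test_sci_ratio(self, L, W, expected):
        assert m.compute_sci(shell(L, 0.5 * L, W)) == pytest.approx(expected, abs=1e-4)

    def test_sci_integrated_value(self):
        # 30 / sqrt(pi * 100 * 50) * 100
        got = m.compute_sci_integrated(shell(100.0, 50.0, 30.0))
        assert got == pytest.approx(30.0 / math.sqrt(math.pi * 5000) * 100, rel=1e-12)
        assert got == pytest.approx(23.937, abs=1e-3)

    def test_sci_integrated_symmetric_case(self):
        # cube-like shell (bypasses the record invariant W < L on purpose)
        fake = SimpleNamespace(shell_id="x", length_mm=10.0, height_mm=10.0,
                               width_mm=10.0)
        assert m.compute_sci_integrated(fake) == pytest.approx(
            100.0 / math.sqrt(math.pi), rel=1e-12
        )

    @given(
        L=st.floats(51, 200),
        h_ratio=st.floats(0.3, 0.9),
        w_ratio=st.floats(0.1, 0.6),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance_and_identity(self, L, h_ratio, w_ratio, c):
        """SCI and SCI_I are ratios: invariant to uniform rescaling, and
        SCI_I / SCI == sqrt(L / (pi * H)) exactly."""
        s1 = shell(L, h_ratio * L, w_ratio * L)
        s2 = shell(c * L, c * h_ratio * L, c * w_ratio * L)
        assert m.compute_sci(s1) == pytest.approx(m.compute_sci(s2), rel=1e-9)
        assert m.compute_sci_integrated(s1) == pytest.approx(
            m.compute_sci_integrated(s2), rel=1e-9
        )
        ratio = m.compute_sci_integrated(s1) / m.compute_sci(s1)
        assert ratio == pytest.approx(
            math.sqrt(s1.length_mm / (math.pi * s1.height_mm)), rel=1e-9
        )

    @pytest.mark.parametrize(
        "L, H, W",
        [(0.0, 1.0, 0.5), (100.0, 0.0, 30.0), (100.0, 50.0, 0.0),
         (100.0, 50.0, 120.0), (40.0, 50.0, 20.0)],
    )
    def test_invalid_measurements_rejected(self, L, H, W):
        with pytest.raises(InvalidMeasurementError):
            shell(L, H, W)


class TestFilterAndAggregate:
    def test_filter_boundary_inclusive(self):
        shells = [shell(L, 0.5 * L, 0.3 * L, sid=str(L)) for L in (45.0, 50.0, 120.0)]
        kept = m.filter_shells(shells)
        assert [s.length_mm for s in kept] == [50.0, 120.0]
        assert m.filter_shells(kept) == kept  # identity when all pass

    def test_filter_all_below_gives_empty(self, caplog):
        shells = [shell(45.0, 20.0, 12.0)]
        with caplog.at_level("WARNING"):
            assert m.filter_shells(shells) == []
        assert "empty" in caplog.text

    def test_aggregate_mean_and_sem(self):
        shells = [shell(100, 50, 28, sid="a"), shell(100, 50, 30, sid="b")]
        pop = m.aggregate_population(shells, status="viable")
        assert pop.mean_sci == pytest.approx(29.0)
        assert pop.sem_sci == pytest.approx(1.0)
        assert pop.n_shells == 2

    def test_aggregate_single_shell_sem_missing(self):
        pop = m.aggregate_population([shell(100, 50, 28)])
        assert pop.mean_sci == pytest.approx(28.0)
        assert math.isnan(pop.sem_sci)

    def test_aggregate_constant_scis(self):
        shells = [shell(100, 50, 27, sid=f"s{i}") for i in range(25)]
        pop = m.aggregate_population(shells)
        assert pop.mean_sci == pytest.approx(27.0)
        assert pop.sem_sci == pytest.approx(0.0)

    def test_aggregate_uses_mean_of_indices_not_index_of_means(self):
        # two non-proportional shells: mean of per-shell SCI differs from the
        # SCI of the mean shell; the former is the defined population value
        shells = [shell(100, 50, 20, sid="a"), shell(200, 100, 80, sid="b")]
        pop = m.aggregate_population(shells)
        mean_of_indices = (20.0 + 40.0) / 2
        index_of_means = 100 * pop.mean_width_mm / pop.mean_length_mm
        assert pop.mean_sci == pytest.approx(mean_of_indices)
        assert pop.mean_sci != pytest.approx(index_of_means)

    def test_low_n_flagged(self):
        pop = m.aggregate_population(
            [shell(100, 50, 28, sid=f"s{i}") for i in range(6)], status="viable"
        )
        assert pop.period == "recent" and not pop.sufficient_n

    def test_altitude_split_excludes_middle_band(self):
        pops = [make_population(i, 28, altitude=a)
                for i, a in enumerate([100, 199, 250, 301, 400])]
        lowland, mountain = m.split_by_altitude(pops)
        assert len(lowland) == 2 and len(mountain) == 2


class TestGroupComparison:
    def test_pooled_df(self):
        a = [make_population(i, 28 + 0.1 * i) for i in range(21)]
        b = [make_population(100 + i, 29 + 0.1 * i, status="declining")
             for i in range(24)]
        res = m.compare_group_means(a, b)
        assert res.df == 43

    @given(na=st.integers(2, 30), nb=st.integers(2, 30))
    @settings(max_examples=50, derandomize=True)
    def test_pooled_df_any_sizes(self, na, nb):
        rng = np.random.default_rng(na * 100 + nb)
        a = [make_population(i, 28 + rng.normal()) for i in range(na)]
        b = [make_population(100 + i, 28 + rng.normal()) for i in range(nb)]
        assert m.compare_group_means(a, b).df == na + nb - 2

    def test_identical_groups(self):
        pops = [make_population(i, s) for i, s in enumerate([27.0, 28.0, 29.0])]
        res = m.compare_group_means(pops, pops)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_insufficient_groups(self):
        with pytest.raises(InsufficientDataError):
            m.compare_group_means([make_population(0, 28)], [make_population(1, 29)])

    def test_power_on_separated_groups(self):
        """Groups 1.5 SCI units apart (sd 0.5, n=20) are detected at p<0.001
        essentially always."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = [make_population(i, v) for i, v in
                 enumerate(rng.normal(28.0, 0.5, 20))]
            b = [make_population(50 + i, v) for i, v in
                 enumerate(rng.normal(29.5, 0.5, 20))]
            hits += m.compare_group_means(a, b).p < 0.001
        assert hits / n_rep >= 0.99


class TestNormality:
    def test_normal_samples_pass(self):
        rng = np.random.default_rng(11)
        passes = sum(
            m.normality_check(rng.standard_normal(500)).p > 0.05
            for _ in range(100)
        )
        assert passes >= 90

    def test_exponential_samples_fail(self):
        rng = np.random.default_rng(12)
        rejects = sum(
            m.normality_check(rng.exponential(1.0, 500)).p < 0.05
            for _ in range(100)
        )
        assert rejects >= 95

    def test_matches_statsmodels_lilliefors_statistic(self):
        """Independent cross-check of the statistic (not the Monte-Carlo p)."""
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(13)
        x = rng.standard_normal(80)
        d_sm, _ = lilliefors(x, dist="norm", pvalmethod="approx")
        d_ours, _, _ = m.normality_check(x)
        assert d_ours == pytest.approx(d_sm, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            m.normality_check([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDistributionError):
            m.normality_check([2.0] * 10)


def _glm_pops(rng, slope_viable, slope_declining, noise, n_per=10):
    pops = []
    for i in range(2 * n_per):
        status = "viable" if i < n_per else "declining"
        L = rng.uniform(60, 120)
        slope = slope_viable if status == "viable" else slope_declining
        W = slope * L + rng.normal(0, noise)
        pops.append(make_population(i, 100 * W / L, status=status,
                                    mean_length=L, mean_width=W))
    return pops


class TestWidthGlm:
    def test_no_group_effect_retains_length_only(self, rng):
        res = m.fit_width_glm(_glm_pops(rng, 0.28, 0.28, 0.1))
        assert res.retained_terms == ["length"]
        assert res.r_squared > 0.95

    def test_group_effect_detected(self, rng):
        res = m.fit_width_glm(_glm_pops(rng, 0.28, 0.30, 0.02))
        retained = set(res.retained_terms)
        assert retained & {"population_group", "length:population_group"}
        p_by_term = {t.name: t.p for t in res.terms}
        assert min(
            p_by_term.get("population_group", 1.0),
            p_by_term.get("length:population_group", 1.0),
        ) < 0.001

    def test_too_few_per_level(self, rng):
        pops = _glm_pops(rng, 0.28, 0.28, 0.1, n_per=2)
        with pytest.raises(InsufficientDataError):
            m.fit_width_glm(pops)

    def test_null_false_positive_rate(self):
        """With no group effect, backward elimination keeps only length in
        >= 90% of replicates at alpha = 0.05."""
        rng = np.random.default_rng(42)
        keeps = sum(
            m.fit_width_glm(_glm_pops(rng, 0.28, 0.28, 0.1)).retained_terms
            == ["length"]
            for _ in range(200)
        )
        assert keeps / 200 >= 0.90


def _latitude_pops(rng, slope_recent, slope_historical, noise, n_recent=25,
                   n_hist=12):
    pops = []
    for i in range(n_recent + n_hist):
        recent = i < n_recent
        lat = rng.uniform(50, 70)
        slope = slope_recent if recent else slope_historical
        sci = 28.0 + slope * (lat - 60.0) + rng.normal(0, noise)
        pops.append(make_population(i, sci, lat=lat,
                                    period="recent" if recent else "historical"))
    return pops


class TestSeparateSlopes:
    def test_numerator_df_is_two(self, rng):
        res = m.separate_slopes_test(_latitude_pops(rng, -0.35, 0.0, 0.8))
        assert res.df_num == 2

    def test_null_p_uniform(self):
        """Both periods on the same line: p-values are Uniform(0,1)."""
        rng = np.random.default_rng(99)
        pvals = [
            m.separate_slopes_test(_latitude_pops(rng, 0.0, 0.0, 0.8)).p
            for _ in range(500)
        ]
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_power_on_diverging_slopes(self):
        rng = np.random.default_rng(100)
        hits = sum(
            m.separate_slopes_test(_latitude_pops(rng, -0.35, 0.0, 0.8)).p < 0.01
            for _ in range(200)
        )
        assert hits / 200 >= 0.95

    def test_missing_latitude_rejected(self, rng):
        pops = _latitude_pops(rng, 0.0, 0.0, 0.8)
        pops[0].latitude_deg = float("nan")
        with pytest.raises(Exception):
            m.separate_slopes_test(pops)


class TestCorrelations:
    def test_perfect_negative_monotone(self, rng):
        x = np.sort(rng.uniform(0, 10, 20))
        res = m.rank_correlation(x, -(x**3))
        assert res.statistic == pytest.approx(-1.0)

    def test_null_rho_small(self):
        rng = np.random.default_rng(7)
        hits = sum(
            abs(m.rank_correlation(rng.normal(size=100),
                                   rng.normal(size=100)).statistic) < 0.3
            for _ in range(500)
        )
        assert hits / 500 >= 0.99

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            m.rank_correlation([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])

    def test_sample_size_bias_absent_in_generator(self, world):
        """Population mean SCI should not correlate with how many shells were
        measured (the generator draws them independently)."""
        pops = world["populations"]
        res = m.rank_correlation([p.n_shells for p in pops],
                                 [p.mean_sci for p in pops])
        assert abs(res.statistic) < 0.3
        assert res.p > 0.05
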