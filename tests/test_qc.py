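import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colonyflow import (
    CultureCount,
    Verdict,
    classify,
    doubling_time,
    population_doublings,
    scatter_report,
    spearman_correlation,
)


def _spearman_rank_formula(x, y):
    """Brute-force oracle: 1 - 6 Σd² / (n(n²-1)) on tie-free data."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1.0 - 6.0 * float((d**2).sum()) / (n * (n**2 - 1))


class TestPopulationDoublings:
    def test_one_doubling(self):
        assert population_doublings(CultureCount(1e5, 2e5, 2)) == pytest.approx(1.0)

    def test_no_growth(self):
        assert population_doublings(CultureCount(1e5, 1e5, 2)) == 0.0

    def test_fourfold_expansion(self):
        # 1.25e5 plated, 5e5 harvested: log2(4) = 2 doublings
        assert population_doublings(
            CultureCount(1.25e5, 5e5, 4)
        ) == pytest.approx(2.0)

    def test_cell_loss_negative(self):
        assert population_doublings(CultureCount(2e5, 1e5, 2)) < 0

    @pytest.mark.parametrize("n0,n", [(0, 1e5), (1e5, 0), (-1, 1e5)])
    def test_invalid_counts(self, n0, n):
        with pytest.raises(ValueError):
            CultureCount(n0, n, 2)

    def test_additivity_over_serial_intervals(self):
        # PD(n0 → k·n0) + PD(k·n0 → k²·n0) = PD(n0 → k²·n0)
        n0, k = 1.3e5, 3.7
        pd1 = population_doublings(CultureCount(n0, k * n0, 1))
        pd2 = population_doublings(CultureCount(k * n0, k**2 * n0, 1))
        total = population_doublings(CultureCount(n0, k**2 * n0, 2))
        assert pd1 + pd2 == pytest.approx(total)


class TestDoublingTime:
    @pytest.mark.parametrize(
        "pd_value,days,expected",
        [(2.0, 2.0, 1.0), (1.0, 3.0, 3.0), (np.log2(4), 4.0, 2.0)],
    )
    def test_closed_forms(self, pd_value, days, expected):
        assert doubling_time(pd_value, days) == pytest.approx(expected)

    def test_undefined_for_non_growing_culture(self):
        with pytest.raises(ValueError, match="did not grow"):
            doubling_time(0.0, 2.0)
        with pytest.raises(ValueError):
            doubling_time(-1.0, 2.0)


class TestClassify:
    def test_just_below_threshold_substandard(self):
        assert classify(39.9).verdict is Verdict.SUBSTANDARD

    def test_at_threshold_acceptable(self):
        # the rule is strictly "lower than": equality passes
        assert classify(40.0).verdict is Verdict.ACCEPTABLE

    def test_custom_threshold(self):
        assert classify(55.0, threshold=60.0).verdict is Verdict.SUBSTANDARD

    def test_verdict_flips_exactly_at_threshold(self):
        thr = 40.0
        grid = np.arange(0.0, 80.0, 0.1)
        for v in grid:
            expected = Verdict.SUBSTANDARD if v < thr else Verdict.ACCEPTABLE
            assert classify(float(v), thr).verdict is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(-1.0)
        with pytest.raises(ValueError):
            classify(10.0, threshold=-5.0)


class TestSpearman:
    def test_perfect_decreasing(self):
        res = spearman_correlation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks x = 1..5, ranks y = (2,1,4,3,5): d = (−1,1,−1,1,0), Σd² = 4
        # rho = 1 − 6·4 / (5·24) = 0.8
        res = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(
            _spearman_rank_formula([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        )
        assert res.rho == pytest.approx(0.8)

    def test_exhaustive_small_n_matches_rank_formula(self):
        # all 720 orderings of y against a fixed x at n = 6
        x = [1, 2, 3, 4, 5, 6]
        for perm in itertools.permutations(range(6)):
            y = [10 + p for p in perm]
            res = spearman_correlation(x, y)
            assert res.rho == pytest.approx(
                _spearman_rank_formula(x, y), abs=1e-12
            )

    def test_null_distribution_centred_on_zero(self):
        # Monte-Carlo oracle: independent x, y at n = 32
        rng = np.random.default_rng(0)
        rhos = [
            spearman_correlation(rng.random(32), rng.random(32)).rho
            for _ in range(1000)
        ]
        assert abs(np.mean(rhos)) < 0.02

    def test_fisher_interval_matches_published_style(self):
        # build an n = 32 data set whose rho lands near the strong negative
        # association regime and check the Fisher-z interval against the
        # closed form computed independently
        rng = np.random.default_rng(7)
        x = rng.random(32)
        y = -x + 0.8 * rng.random(32)
        res = spearman_correlation(x, y)
        from scipy.stats import norm

        z = np.arctanh(res.rho)
        se = 1.03 / np.sqrt(32 - 3)
        zcrit = norm.ppf(0.975)
        lo, hi = np.tanh([z - zcrit * se, z + zcrit * se])
        assert res.ci_low == pytest.approx(lo, abs=1e-9)
        assert res.ci_high == pytest.approx(hi, abs=1e-9)
        assert res.ci_low < res.rho < res.ci_high

    def test_interval_covers_null_at_nominal_rate(self):
        rng = np.random.default_rng(3)
        cover = 0
        trials = 400
        for _ in range(trials):
            res = spearman_correlation(rng.random(32), rng.random(32))
            cover += res.ci_low <= 0.0 <= res.ci_high
        assert cover / trials > 0.90

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-500, 500), min_size=5, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        ys = rng.permutation(len(xs)).astype(float)
        base = spearman_correlation(np.asarray(xs, float), ys).rho
        transformed = spearman_correlation(np.exp(np.asarray(xs) / 100.0), ys).rho
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2, 3])  # too short
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3, 4], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, np.nan, 4], [1, 2, 3, 4])


class TestScatterReport:
    def test_cohort_table_shape(self):
        rng = np.random.default_rng(0)
        standard = [(rng.uniform(40, 80), rng.uniform(1, 3), "standard")
                    for _ in range(32)]
        challenged = [(rng.uniform(5, 39), rng.uniform(1.5, 4), "challenge")
                      for _ in range(16)]
        report = scatter_report(standard + challenged)
        assert len(report) == 48
        assert set(report["protocol"]) == {"standard", "challenge"}
        assert (report["threshold_um_per_h"] == 40.0).all()

    def test_all_below_threshold_all_substandard(self):
        report = scatter_report([(10.0, 2.0, "a"), (20.0, 2.5, "a")])
        assert (report["verdict"] == "SUBSTANDARD").all()

    def test_empty_label_grouped_as_unlabelled(self):
        report = scatter_report([(50.0, 2.0, "")])
        assert report.loc[0, "protocol"] == "unlabelled"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            scatter_report([])

    def test_plot_scatter_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        report = scatter_report([(50.0, 2.0, "standard"), (30.0, 3.0, "5xPBS"),
                                 (45.0, 2.2, "standard"), (20.0, 3.5, "7dNoF")])
        from colonyflow import plot_scatter

        ax = plot_scatter(report)
        assert ax.get_xlabel().startswith("MMS")
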