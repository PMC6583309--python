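"""Per-term OLS trend fitting, BH correction, screening and cloud weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titletrends.ngrams import FrequencyTable, TermSeries
from titletrends.synth import sample_term_counts
from titletrends.trends import (
    ScreenReport,
    TrendResult,
    TrendScreenModel,
    bh_adjust,
    cloud_weights,
    fit_term_trend,
    screen,
)


def series(years, freq, term="t"):
    return TermSeries(term=term, years=np.asarray(years), freq=np.asarray(freq, dtype=float))


def textbook_bh(p):
    """Independent step-up oracle: q_i = min_{j>=i} min(1, p_(j) * m / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestFitTermTrend:
    def test_worked_example_against_closed_form(self):
        # years 2000..2003, f=[1,2,2,3]: S_xy=3, S_xx=5, SSE=0.2, df=2
        r = fit_term_trend(series([2000, 2001, 2002, 2003], [1, 2, 2, 3]))
        assert r.slope == pytest.approx(0.6, abs=1e-12)
        assert r.se == pytest.approx(np.sqrt(0.2 / 2 / 5), abs=1e-12)  # 0.14142...
        assert r.t == pytest.approx(0.6 / np.sqrt(0.02), abs=1e-9)     # 4.2426...
        assert r.n_years == 4

    def test_perfect_linear_fit_has_zero_p(self):
        y = np.arange(1976, 2016)
        r = fit_term_trend(series(y, 2.0 + 0.5 * (y - 1976)))
        assert r.slope == pytest.approx(0.5, abs=1e-9)
        assert r.p == 0.0

    def test_all_zero_series_is_null(self):
        r = fit_term_trend(series([2000, 2001, 2002], [0, 0, 0]))
        assert r.slope == 0.0 and r.p == 1.0

    def test_constant_nonzero_series_is_null(self):
        r = fit_term_trend(series([2000, 2001, 2002, 2003], [7.3] * 4))
        assert r.slope == 0.0 and r.p == 1.0

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError, match="3 years"):
            fit_term_trend(series([2000, 2001], [1, 2]))

    def test_constant_year_vector_rejected(self):
        with pytest.raises(ValueError, match="constant year"):
            fit_term_trend(series([2000, 2000, 2000], [1, 2, 3]))

    def test_matches_independent_least_squares_on_random_series(self, rng):
        """Slope/intercept agree with matrix least squares to 1e-8; se/t/p with scipy."""
        from scipy import stats as sps

        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = np.sort(rng.choice(np.arange(1950, 2020), size=n, replace=False)).astype(float)
            y = rng.normal(10, 5, size=n) + rng.normal(0, 1) * (x - x.mean())
            r = fit_term_trend(series(x, y))
            beta_hat, alpha_hat = np.linalg.lstsq(
                np.column_stack([x, np.ones_like(x)]), y, rcond=None
            )[0]
            assert r.slope == pytest.approx(beta_hat, abs=1e-8)
            assert r.intercept == pytest.approx(alpha_hat, abs=1e-8)
            lr = sps.linregress(x, y)
            assert r.se == pytest.approx(lr.stderr, rel=1e-9)
            assert r.p == pytest.approx(lr.pvalue, rel=1e-9, abs=1e-300)

    def test_ci_covers_slope_estimate(self):
        r = fit_term_trend(series([2000, 2001, 2002, 2003], [1, 2, 2, 3]))
        assert r.ci_low <= r.slope <= r.ci_high
        assert r.total_change == pytest.approx(r.slope * 3)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_textbook_definition_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50)))
            np.testing.assert_allclose(bh_adjust(p), textbook_bh(list(p)), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjustment_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p)) and np.all(q <= 1.0)
        # permutation equivariance
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def synthetic_table(rng, n_null=30, injected=(("riser", 50.0, 8.0),), years=(1976, 2015),
                    tokens_per_year=50000):
    ys = list(range(years[0], years[1] + 1))
    counts = {}
    for i in range(n_null):
        counts[f"null{i:03d}"] = sample_term_counts(50.0, 0.0, ys, tokens_per_year, rng)
    for term, b, s in injected:
        counts[term] = sample_term_counts(b, s, ys, tokens_per_year, rng)
    return FrequencyTable(order=1, years=ys, counts=counts,
                          denominators=np.full(len(ys), tokens_per_year))


class TestScreen:
    def test_injected_increasing_term_tops_list(self, rng):
        table = synthetic_table(rng)
        report = screen(table, fdr_threshold=0.01, k=5)
        assert report.top_increased and report.top_increased[0].term == "riser"

    def test_zero_threshold_empties_top_lists(self, rng):
        report = screen(synthetic_table(rng), fdr_threshold=0.0, k=5)
        assert report.top_increased == [] and report.top_decreased == []

    def test_k_truncates_to_significant_set(self, rng):
        table = synthetic_table(rng, injected=(("riser", 50.0, 8.0), ("faller", 400.0, -8.0)))
        report = screen(table, fdr_threshold=0.01, k=100)
        assert len(report.top_increased) <= report.n_significant
        assert {r.term for r in report.top_increased} | {r.term for r in report.top_decreased} <= {
            r.term for r in report.results if r.q < 0.01
        }

    def test_slope_ties_break_lexicographically(self):
        ys = list(range(2000, 2010))
        trend = np.arange(10) * 10 + 5
        table = FrequencyTable(
            order=1, years=ys,
            counts={"beta": trend.copy(), "alpha": trend.copy(),
                    "null": np.full(10, 5)},
            denominators=np.full(10, 1000),
        )
        report = screen(table, fdr_threshold=0.05, k=2, low_freq_threshold=1e-6)
        assert [r.term for r in report.top_increased] == ["alpha", "beta"]

    def test_no_retained_terms_is_an_error(self):
        table = FrequencyTable(order=1, years=[2000, 2001, 2002],
                               counts={"w": np.array([1, 0, 0])},
                               denominators=np.array([10**6] * 3))
        with pytest.raises(ValueError, match="retained"):
            screen(table, low_freq_threshold=0.5)

    def test_q_values_bound_p_values(self, rng):
        report = screen(synthetic_table(rng), k=5)
        for r in report.results:
            assert r.q >= r.p and r.q <= 1.0


class TestCloudWeights:
    def _report(self, slope, q):
        r = TrendResult(term="older adults", slope=slope, intercept=0.0, se=1.0,
                        ci_low=slope - 2, ci_high=slope + 2, t=1.0, p=q, q=q,
                        n_years=40, total_change=slope * 39)
        return ScreenReport(results=[r], fdr_threshold=0.01)

    def test_weight_is_total_absolute_change(self):
        w = cloud_weights(self._report(2.38, 1e-6), year_span=39)
        assert w == {"older adults": pytest.approx(92.82)}

    def test_sign_invariant(self):
        up = cloud_weights(self._report(2.38, 1e-6), 39)
        down = cloud_weights(self._report(-2.38, 1e-6), 39)
        assert up == down

    def test_non_significant_terms_absent(self):
        assert cloud_weights(self._report(2.38, 0.5), 39) == {}

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            cloud_weights(self._report(1.0, 1e-6), 0)


class TestModelResults:
    def test_model_fit_summary_and_weights(self, rng):
        table = synthetic_table(rng)
        res = TrendScreenModel(table).fit(k=5)
        text = res.summary()
        assert "riser" in text and "FDR threshold: 0.01" in text
        weights = res.cloud_weights()
        assert weights["riser"] == pytest.approx(
            abs(res.top_increased[0].slope) * 39
        )

    def test_from_records_constructor(self):
        from conftest import make_record

        recs = [make_record(pmid=str(i), year=2000 + i, title="risk of bias rising")
                for i in range(5)]
        model = TrendScreenModel.from_records(recs, order=2)
        assert model.table.order == 2
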