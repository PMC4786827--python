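"""Selection proxies, cooperative epochs, and the Price decomposition."""

import numpy as np
import pytest

from mlsel_pgg.engine import payoffs
from mlsel_pgg.stats import (
    RunRecord,
    aggregate_runs,
    cooperative_epochs,
    fit_trend,
    price_decomposition,
    price_oracle,
    summarize_run,
    variance_proxies_arrays,
    viability_condition,
)


class TestVarianceProxies:
    def test_uniform_population_has_no_variation(self):
        vb, vw = variance_proxies_arrays(np.full((3, 5), 0.7))
        assert vb == pytest.approx(0.0, abs=1e-15)
        assert vw == pytest.approx(0.0, abs=1e-15)

    def test_worked_two_group_example(self):
        # group means 0.5 and 1.0; within variances 0.25 and 0
        vb, vw = variance_proxies_arrays(np.array([[0.0, 1.0], [1.0, 1.0]]))
        assert vb == pytest.approx(0.0625)
        assert vw == pytest.approx(0.125)

    def test_single_group_has_zero_between_variance(self):
        vb, _ = variance_proxies_arrays(np.array([[0.1, 0.9, 0.4]]))
        assert vb == 0.0

    def test_law_of_total_variance(self, rng):
        # population variance of all members = between + within, for equal
        # group sizes and population (divide-by-N) variances
        for _ in range(25):
            c = rng.random((int(rng.integers(2, 8)), int(rng.integers(2, 9))))
            vb, vw = variance_proxies_arrays(c)
            assert vb + vw == pytest.approx(float(np.var(c)), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            variance_proxies_arrays(np.empty((0, 0)))


class TestCooperativeEpochs:
    def test_worked_example(self):
        ep = cooperative_epochs([0.7, 0.7, 0.5, 0.8], threshold=0.6)
        assert ep.epochs == [(0, 2), (3, 1)]
        assert ep.mean_length == pytest.approx(1.5)
        assert ep.count == 2 and ep.defined

    def test_no_epochs_when_always_below(self):
        ep = cooperative_epochs([0.1, 0.5, 0.6], threshold=0.6)
        assert ep.count == 0 and not ep.defined and ep.mean_length == 0.0

    def test_single_epoch_spanning_whole_series(self):
        ep = cooperative_epochs([0.9] * 12, threshold=0.6)
        assert ep.epochs == [(0, 12)]
        assert ep.mean_length == 12.0

    def test_threshold_boundary_is_exclusive(self):
        # a generation at exactly the threshold ends an epoch
        ep = cooperative_epochs([0.7, 0.6, 0.7], threshold=0.6)
        assert ep.epochs == [(0, 1), (2, 1)]


def _pgg_groups(traits, r, w0):
    """Binary contribute/defect groups with public-goods payoffs."""
    out = []
    for t in traits:
        t = np.asarray(t, dtype=float)
        out.append((t, payoffs(t, w0=w0, r=r, n=len(t))))
    return out


class TestPriceDecomposition:
    def test_pure_groups_show_only_between_selection(self):
        groups = _pgg_groups([[1, 1, 1, 1], [0, 0, 0, 0]], r=2.0, w0=0.0)
        d = price_decomposition(groups)
        assert d.between_term == pytest.approx(0.25)
        assert d.within_term == pytest.approx(0.0)
        assert d.mean_payoff == pytest.approx(1.5)
        assert d.predicted_delta_p == pytest.approx(1 / 6)

    def test_mixed_single_group_shows_only_within_selection(self):
        groups = _pgg_groups([[1, 1, 0, 0]], r=2.0, w0=0.0)
        d = price_decomposition(groups)
        assert d.between_term == pytest.approx(0.0)
        assert d.within_term == pytest.approx(-0.25)
        assert d.predicted_delta_p == pytest.approx(-1 / 6)

    def test_two_level_tug_of_war(self):
        groups = _pgg_groups([[1, 1, 1, 1], [1, 1, 0, 0]], r=2.0, w0=0.0)
        d = price_decomposition(groups)
        assert d.between_term == pytest.approx(0.0625)
        assert d.within_term == pytest.approx(-0.125)
        assert d.mean_payoff == pytest.approx(1.75)
        assert d.predicted_delta_p == pytest.approx(-1 / 28)

    def test_identity_holds_by_construction(self, rng):
        for _ in range(50):
            g = int(rng.integers(1, 6))
            groups = [
                (rng.integers(0, 2, size=5).astype(float), rng.random(5) + 0.5)
                for _ in range(g)
            ]
            d = price_decomposition(groups)
            assert d.predicted_delta_p * d.mean_payoff == pytest.approx(
                d.between_term + d.within_term, abs=1e-14
            )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            g = int(rng.integers(1, 6))
            n = int(rng.integers(2, 7))
            r = 1.0 + rng.random() * (n - 1.0) * 0.95 + 1e-6
            traits = rng.integers(0, 2, size=(g, n)).astype(float)
            groups = _pgg_groups(traits, r=r, w0=float(rng.random() * 3))
            d = price_decomposition(groups)
            assert d.predicted_delta_p == pytest.approx(
                price_oracle(groups), abs=1e-12
            )

    def test_closed_forms_for_public_goods_payoff(self, rng):
        # between = (r-1) Var_q(p_j), within = -E_q[Var_j(p_ij)]
        for _ in range(50):
            g, n = int(rng.integers(1, 6)), int(rng.integers(2, 7))
            r = 2.5 if n > 2 else 1.5
            traits = rng.integers(0, 2, size=(g, n)).astype(float)
            groups = _pgg_groups(traits, r=r, w0=0.0)
            d = price_decomposition(groups)
            p_j = traits.mean(axis=1)
            assert d.between_term == pytest.approx((r - 1) * np.var(p_j), abs=1e-12)
            assert d.within_term == pytest.approx(
                -np.mean(np.var(traits, axis=1)), abs=1e-12
            )

    def test_homogeneous_trait_population_is_static(self):
        groups = _pgg_groups([[1, 1, 1], [1, 1, 1]], r=2.0, w0=0.0)
        assert price_oracle(groups) == pytest.approx(0.0, abs=1e-15)
        assert price_decomposition(groups).predicted_delta_p == pytest.approx(0.0)

    def test_weak_selection_limit_washes_out_change(self):
        groups_strong = _pgg_groups([[1, 1, 0, 0], [1, 0, 0, 0]], r=2.0, w0=0.0)
        groups_weak = _pgg_groups([[1, 1, 0, 0], [1, 0, 0, 0]], r=2.0, w0=1000.0)
        assert abs(price_oracle(groups_weak)) < abs(price_oracle(groups_strong)) / 100

    def test_nonpositive_mean_payoff_rejected(self):
        with pytest.raises(ValueError):
            price_decomposition([(np.array([1.0, 0.0]), np.array([0.0, 0.0]))])


class TestViabilityCondition:
    def test_pure_between_variance_favors_altruists(self):
        assert viability_condition(0.25, 0.0, r=2.0, n=4)

    def test_strong_within_variance_blocks_altruists(self):
        assert not viability_condition(0.0625, 0.125, r=2.0, n=4)

    def test_zero_between_variance_never_viable(self):
        assert not viability_condition(0.0, 0.01, r=2.0, n=4)

    def test_matches_sign_of_price_delta(self, rng):
        for _ in range(100):
            g, n = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            r = 1.0 + rng.random() * (n - 1.05) + 0.01
            traits = rng.integers(0, 2, size=(g, n)).astype(float)
            groups = _pgg_groups(traits, r=r, w0=0.0)
            delta = price_oracle(groups)
            p_j = traits.mean(axis=1)
            viable = viability_condition(
                float(np.var(p_j)), float(np.mean(np.var(traits, axis=1))), r, n
            )
            if abs(delta) > 1e-12:
                assert viable == (delta > 0)


def _record(mean_series):
    T = len(mean_series)
    freqs = np.zeros((T, 27))
    freqs[:, 2] = 1.0
    return RunRecord(
        generation=np.arange(T),
        mean_contribution=np.asarray(mean_series, dtype=float),
        var_between=np.zeros(T),
        mean_var_within=np.zeros(T),
        freqs=freqs,
    )


class TestAggregation:
    def test_identical_runs_have_zero_ci_width(self):
        runs = [_record([0.5, 0.7, 0.9])] * 3
        ag = aggregate_runs(runs)
        lo, hi = ag.ci95_overall
        assert hi - lo == pytest.approx(0.0)
        assert ag.ci_defined

    def test_mean_of_run_means(self):
        ag = aggregate_runs([_record([0.6] * 10), _record([0.8] * 10)])
        assert ag.mean_contribution_overall == pytest.approx(0.7)

    def test_single_run_ci_flagged_undefined(self):
        ag = aggregate_runs([_record([0.6, 0.6])])
        assert not ag.ci_defined
        assert ag.ci95_overall == (pytest.approx(0.6), pytest.approx(0.6))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([_record([0.5]), _record([0.5, 0.6])])

    def test_summary_windows(self):
        rec = _record([0.0] * 80 + [1.0] * 20)
        s = summarize_run(rec)
        assert s.mean_contribution_overall == pytest.approx(0.2)
        assert s.mean_contribution_stabilized == pytest.approx(1.0)
        assert s.mean_epoch_length == pytest.approx(20.0)

    def test_trend_fit_recovers_slope(self):
        fit = fit_trend([0.0, 1.0, 2.0, 3.0], [0.1, 0.3, 0.5, 0.7])
        assert fit.slope == pytest.approx(0.2)

    def test_dataframe_round_trip(self):
        rec = _record([0.1, 0.9, 0.4])
        back = RunRecord.from_dataframe(rec.to_dataframe())
        assert np.allclose(back.mean_contribution, rec.mean_contribution)
        assert np.allclose(back.freqs, rec.freqs)
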