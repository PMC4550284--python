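"""Stochastic simulator: reproducibility, limits, and agreement with theory."""

import numpy as np
import pytest
from scipy import stats

from replidyn import (
    ModelParams,
    estimate_metrics,
    mean_investigations_published,
    metric_table,
    simulate,
    steady_state_analytic,
    steady_state_renewal,
)


class TestReproducibility:
    def test_same_seed_bit_identical(self, basic_params):
        r1 = simulate(basic_params.replace(a=200.0), n_steps=200, seed=11)
        r2 = simulate(basic_params.replace(a=200.0), n_steps=200, seed=11)
        assert np.array_equal(r1.tally, r2.tally)
        assert np.array_equal(r1.is_true, r2.is_true)
        assert np.array_equal(r1.reps, r2.reps)
        assert r1.acts_novel == r2.acts_novel

    def test_different_seeds_differ(self, basic_params):
        r1 = simulate(basic_params.replace(a=200.0), n_steps=200, seed=11)
        r2 = simulate(basic_params.replace(a=200.0), n_steps=200, seed=12)
        assert not np.array_equal(r1.tally, r2.tally)


class TestLimits:
    def test_certain_base_rate_all_true(self):
        p = ModelParams(b=1.0, r=0.3, power_new=0.8, alpha_new=0.05)
        res = simulate(p.replace(a=500.0), n_steps=100, seed=1)
        assert res.is_true.all()
        table = metric_table(res.distribution())
        occupied = (table.p_true + table.p_false) > 0
        assert np.all(table.precision[occupied] == 1.0)

    def test_null_model_no_true_hypotheses(self):
        p = ModelParams(b=0.0, r=0.3, power_new=0.8, alpha_new=0.05)
        results = [simulate(p.replace(a=500.0), n_steps=100, seed=s) for s in range(8)]
        table = estimate_metrics(results)
        occupied = table.p_false > 0
        assert np.all(table.precision[occupied] == 0.0)
        lo, hi = table.precision_ci
        assert np.nanmax(hi[occupied] - lo[occupied]) == 0.0

    def test_no_replication_mean_investigations_zero(self, basic_params):
        res = simulate(basic_params.replace(r=0.0, a=500.0), n_steps=50, seed=2)
        assert mean_investigations_published(res) == 0.0


class TestAgreementWithTheory:
    def test_tally_masses_match_series_within_mc_error(self, basic_params):
        # full communication: cumulative proportions approach the series values
        p = basic_params.replace(a=2000.0)
        res = simulate(p, n_steps=1500, seed=5)
        d = res.distribution()
        exact = steady_state_analytic(p)
        n = d.total_mass
        for s in range(-4, 6):
            for true in (True, False):
                obs = d.mass_at(s, true) / n if d.s_min <= s <= d.s_max else 0.0
                exp = exact.mass_at(s, true) if exact.s_min <= s <= exact.s_max else 0.0
                if exp < 1e-4:
                    continue
                se = np.sqrt(exp * (1 - exp) / n)
                assert abs(obs - exp) < 3 * se + 2e-4, f"tally {s} true={true}"

    def test_mean_replications_per_published(self, basic_params):
        # geometric finding count: mean replications = r/(1-r) under full communication
        res = simulate(basic_params.replace(a=2000.0), n_steps=1500, seed=6)
        assert mean_investigations_published(res) == pytest.approx(0.25, abs=0.01)

    def test_replication_load_with_partial_communication(self, suppressed_novel_negatives):
        sol = steady_state_renewal(suppressed_novel_negatives)
        res = simulate(suppressed_novel_negatives.replace(a=2000.0), n_steps=1500, seed=7)
        assert mean_investigations_published(res) == pytest.approx(sol.lam, rel=0.05)

    def test_investigation_count_geometric(self, suppressed_novel_negatives):
        # published investigation counts follow a geometric law with the
        # renewal continuation probability
        sol = steady_state_renewal(suppressed_novel_negatives)
        res = simulate(suppressed_novel_negatives.replace(a=2000.0), n_steps=2500, seed=8)
        hist = res.investigation_histogram().astype(float)
        kmax = np.searchsorted(np.cumsum(hist) / hist.sum(), 0.995)
        obs = np.append(hist[:kmax], hist[kmax:].sum())
        k = np.arange(kmax)
        probs = (1 - sol.rho) * sol.rho**k
        probs = np.append(probs, 1 - probs.sum())
        chi2 = stats.chisquare(obs, hist.sum() * probs)
        assert chi2.pvalue > 0.001

    def test_ratio_estimates_invariant_to_activity_scale(self, suppressed_novel_negatives):
        slow = simulate(suppressed_novel_negatives.replace(a=500.0), n_steps=4000, seed=9)
        fast = simulate(suppressed_novel_negatives.replace(a=4000.0), n_steps=500, seed=10)
        t_slow = metric_table(slow.distribution())
        t_fast = metric_table(fast.distribution())
        for s in (-2, -1, 0, 1, 2, 3):
            n_s = (
                slow.distribution().mass_at(s) + slow.distribution().mass_at(s, False)
                if t_slow.s_min <= s <= t_slow.s_max
                else 0
            )
            if n_s < 200:
                continue
            a, b = t_slow.precision_at(s), t_fast.precision_at(s)
            se = np.sqrt(a * (1 - a) / n_s) if 0 < a < 1 else 0.02
            assert abs(a - b) < 4 * se + 0.02


class TestEstimateMetrics:
    def test_single_run_point_estimates_only(self, basic_params):
        res = simulate(basic_params.replace(a=500.0), n_steps=100, seed=3)
        table = estimate_metrics([res])
        assert table.precision_ci is None

    def test_ci_attached_with_eight_seeds(self, basic_params):
        results = [simulate(basic_params.replace(a=500.0), n_steps=100, seed=s) for s in range(8)]
        table = estimate_metrics(results)
        assert table.precision_ci is not None
        lo, hi = table.precision_ci
        occupied = (table.p_true + table.p_false) > 50
        assert np.all(lo[occupied] <= hi[occupied])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_metrics([])
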