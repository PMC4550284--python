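"""Transition kernel, novel inflow, renewal and time-stepping engines."""

import numpy as np
import pytest

from replidyn import (
    ModelParams,
    metric_table,
    novel_inflow,
    steady_state,
    steady_state_analytic,
    steady_state_renewal,
    steady_state_timestep,
    transition_kernel,
)


def max_tally_diff(d1, d2):
    """Max per-tally absolute difference of two distributions, aligned and folded."""
    lo = max(d1.s_min, d2.s_min)
    hi = min(d1.s_max, d2.s_max)
    a, b = d1.aggregated(lo, hi), d2.aggregated(lo, hi)
    return float(
        np.max(np.abs(a.mass_true - b.mass_true) + np.abs(a.mass_false - b.mass_false))
    )


class TestKernel:
    def test_full_communication(self):
        p = ModelParams(b=0.1, r=0.2, power_new=0.8, alpha_new=0.05)
        k = transition_kernel(p)
        assert (k.up_true, k.down_true, k.stay_true) == (0.8, pytest.approx(0.2), 0.0)
        assert (k.up_false, k.down_false) == (0.05, pytest.approx(0.95))

    def test_suppressed_positive_replications(self):
        p = ModelParams(b=0.1, r=0.2, power_new=0.8, alpha_new=0.05, c_rep_pos=0.2)
        k = transition_kernel(p)
        assert k.up_true == pytest.approx(0.16)
        assert k.down_true == pytest.approx(0.2)
        assert k.stay_true == pytest.approx(0.64)

    def test_immobile_false_hypotheses(self):
        p = ModelParams(b=0.1, r=0.2, power_new=0.8, alpha_new=0.0, alpha_rep=0.0, c_rep_neg=0.0)
        k = transition_kernel(p)
        assert (k.up_false, k.down_false, k.stay_false) == (0.0, 0.0, 1.0)

    def test_rows_sum_to_one(self):
        p = ModelParams(b=0.1, r=0.3, power_new=0.7, alpha_new=0.1, c_rep_pos=0.3, c_rep_neg=0.6)
        k = transition_kernel(p)
        assert k.up_true + k.down_true + k.stay_true == pytest.approx(1.0)
        assert k.up_false + k.down_false + k.stay_false == pytest.approx(1.0)


class TestNovelInflow:
    def test_arithmetic(self):
        p = ModelParams(b=0.001, r=0.2, power_new=0.8, alpha_new=0.05, c_new_neg=0.0)
        f = novel_inflow(p)  # A(1-r) = 0.8
        assert f.true_pos == pytest.approx(6.4e-4)
        assert f.true_neg == 0.0
        assert f.true_unpublished == pytest.approx(1.6e-4)

    def test_full_communication_leaves_nothing_unpublished(self):
        p = ModelParams(b=0.3, r=0.2, power_new=0.8, alpha_new=0.05)
        f = novel_inflow(p)
        assert f.true_unpublished == f.false_unpublished == 0.0

    def test_null_model_inflow_all_false(self):
        p = ModelParams(b=0.0, r=0.2, power_new=0.8, alpha_new=0.05)
        f = novel_inflow(p)
        assert f.true_pos == f.true_neg == f.true_unpublished == 0.0
        assert f.false_pos > 0


class TestRenewal:
    def test_full_communication_reduces_to_series(self):
        for b, r, power, alpha in [(0.1, 0.2, 0.8, 0.05), (1e-3, 0.5, 0.6, 0.1)]:
            p = ModelParams(b=b, r=r, power_new=power, alpha_new=alpha)
            sol = steady_state_renewal(p)
            assert sol.pi_pub == 1.0
            assert sol.rho == pytest.approx(r, abs=1e-15)
            assert max_tally_diff(sol.dist, steady_state_analytic(p)) < 1e-8

    def test_publication_probability_and_replication_load(self, suppressed_novel_negatives):
        sol = steady_state_renewal(suppressed_novel_negatives)
        assert sol.pi_pub == pytest.approx(0.05075, abs=1e-10)
        assert sol.lam == pytest.approx(4.9261, abs=5e-4)

    def test_high_tallies_become_reliable(self, suppressed_novel_negatives):
        table = metric_table(steady_state_renewal(suppressed_novel_negatives).dist)
        assert table.precision_at(3) > 0.80

    def test_rejects_targeting(self):
        p = ModelParams(
            b=0.1, r=0.2, power_new=0.8, alpha_new=0.05, r_T=0.5, target_set=frozenset({1})
        )
        with pytest.raises(ValueError, match="timestep"):
            steady_state_renewal(p)

    def test_rejects_pure_replication(self):
        p = ModelParams(b=0.1, r=1.0, power_new=0.8, alpha_new=0.05)
        with pytest.raises(ValueError, match="steady state"):
            steady_state_renewal(p)

    def test_mass_accounting_with_partial_communication(self):
        p = ModelParams(b=0.01, r=0.3, power_new=0.7, alpha_new=0.1, c_new_neg=0.3, c_rep_neg=0.5)
        sol = steady_state_renewal(p)
        d = sol.dist
        assert d.published_mass == pytest.approx(sol.pi_pub, abs=1e-9)
        assert d.total_mass == pytest.approx(1.0, abs=1e-9)


class TestTimestep:
    def test_matches_series_under_full_communication(self, basic_params):
        res = steady_state_timestep(basic_params, tol=1e-11, n_steps=200_000)
        diff = max_tally_diff(res.dist, steady_state_analytic(basic_params))
        assert diff < 1e-6

    def test_matches_renewal_with_partial_communication(self, suppressed_novel_negatives):
        res = steady_state_timestep(suppressed_novel_negatives, tol=1e-9, n_steps=100_000)
        diff = max_tally_diff(res.dist, steady_state_renewal(suppressed_novel_negatives).dist)
        assert diff < 1e-6

    def test_invariant_to_activity_scale(self, suppressed_novel_negatives):
        slow = steady_state_timestep(suppressed_novel_negatives, tol=1e-9, n_steps=100_000)
        fast = steady_state_timestep(
            suppressed_novel_negatives.replace(a=7.0, n=3), tol=1e-9, n_steps=100_000
        )
        assert max_tally_diff(slow.dist, fast.dist) < 1e-5

    def test_unique_steady_state_from_any_start(self, suppressed_novel_negatives):
        # the seeded starting population is diluted away as 1/t, so after a
        # long run the ratios agree with the empty-start run
        from replidyn import make_lattice

        p = suppressed_novel_negatives.replace(a=50.0)
        seeded = make_lattice(-5, 5)
        seeded.mass_true[:] = 0.2  # arbitrary composition, far from steady
        seeded.mass_false[:] = 0.02
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # fixed-length runs
            empty = steady_state_timestep(p, tol=0.0, n_steps=100_000).dist
            warm = steady_state_timestep(p, tol=0.0, n_steps=100_000, init=seeded).dist
        te, tw = metric_table(empty), metric_table(warm)
        pub = empty.published_mass
        for s in range(max(te.s_min, tw.s_min), min(te.s_max, tw.s_max) + 1):
            if (empty.mass_at(s) + empty.mass_at(s, False)) / pub < 1e-3:
                continue
            assert te.precision[te.index(s)] == pytest.approx(
                tw.precision[tw.index(s)], abs=1e-3
            )

    def test_targeting_improves_high_tally_sensitivity(self):
        p = ModelParams(
            b=0.001,
            r=0.1,
            power_new=0.8,
            alpha_new=0.05,
            c_new_neg=0.0,
            r_T=0.5,
            target_set=frozenset({1, 2, 3}),
        )
        targeted = metric_table(steady_state_timestep(p, n_steps=60_000).dist)
        untargeted = metric_table(steady_state_timestep(p.replace(r_T=0.0), n_steps=60_000).dist)
        # effort aimed at tallies 1..3 pushes true hypotheses beyond the target range
        assert targeted.sensitivity_ge(4) > untargeted.sensitivity_ge(4) + 0.1
        # while precision is nearly unchanged
        for s in range(1, 8):
            assert abs(targeted.precision_at(s) - untargeted.precision_at(s)) < 0.08

    def test_nonconvergence_is_reported(self, basic_params):
        with pytest.warns(UserWarning, match="did not converge"):
            res = steady_state_timestep(basic_params, tol=0.0, n_steps=500)
        assert not res.converged

    def test_masses_stay_nonnegative(self, suppressed_novel_negatives):
        res = steady_state_timestep(suppressed_novel_negatives, n_steps=5_000, tol=0.0)
        assert (res.dist.mass_true >= 0).all() and (res.dist.mass_false >= 0).all()


class TestEngineSelection:
    def test_auto_routes_by_regime(self, basic_params):
        d1 = steady_state(basic_params)  # simple regime -> analytic
        d2 = steady_state(basic_params, engine="renewal")
        assert max_tally_diff(d1, d2) < 1e-8

    def test_unknown_engine_rejected(self, basic_params):
        with pytest.raises(ValueError, match="unknown engine"):
            steady_state(basic_params, engine="magic")
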