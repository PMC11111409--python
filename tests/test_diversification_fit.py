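import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import gammaln

import divconflict as dc
from divconflict import (
    EQUAL,
    VAR_EXT,
    VAR_SPEC,
    build_windows,
    episodic_bd_loglik,
    fit_episodic_model,
    tree_from_branching_ages,
    windows_from_boundaries,
)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def constant_rate_loglik(tree, lam, mu, rho=1.0):
    """Closed-form constant-rate birth–death log-likelihood (crown
    conditioning, ranked-tree convention), written independently of the
    piecewise machinery."""
    r = lam - mu
    denom_coef = lam * (1.0 - rho) - mu

    if abs(r) < 1e-12:
        # critical case lambda = mu: 1 - E(t) = rho / (1 + rho lam t)
        def e_of(t):
            return 1.0 - rho / (1.0 + rho * lam * t)

        def phi_of(t):
            return rho / (1.0 + rho * lam * t) ** 2
    else:
        def e_of(t):
            return 1.0 - rho * r / (rho * lam + denom_coef * math.exp(-r * t))

        def phi_of(t):
            d = rho * lam + denom_coef * math.exp(-r * t)
            return rho * r * r * math.exp(-r * t) / (d * d)

    ages = sorted(tree.internal_ages(exclude_root=True))
    n = len(ages) + 2
    total = gammaln(n)
    for x in ages:
        total += math.log(lam) + math.log(phi_of(x))
    big_t = tree.root_age
    total += 2.0 * math.log(phi_of(big_t))
    total -= 2.0 * math.log(1.0 - e_of(big_t))
    return total


def yule_ranked_loglik(tree, lam):
    """Product of exponential waiting densities of the pure-birth process,
    assembled directly from the ranked branching ages."""
    ages = sorted(tree.internal_ages(exclude_root=True), reverse=True)
    ages = [tree.root_age] + ages + [0.0]  # ages[k-2] = moment of k lineages
    n = len(ages)  # number of tips (n-2 interior ages + crown + present)
    # with k lineages on the age interval (ages[k-1], ages[k-2]): a branching
    # occurs at rate k*lam until k = n, then n lineages reach the present
    total = 0.0
    for k in range(2, n):
        total += math.log(k * lam) - k * lam * (ages[k - 2] - ages[k - 1])
    total += -n * lam * (ages[n - 2] - ages[n - 1])
    return total


def ode_loglik(tree, windows, lam_vec, mu_vec, rho=1.0):
    """Numerical-integration oracle: solve the backward equations for E and
    ln(Phi) with a stiff-safe solver, window by window."""
    edges = np.asarray(windows.bounds[::-1])
    k = windows.n_windows
    lam_asc = np.asarray(lam_vec)[::-1]
    mu_asc = np.asarray(mu_vec)[::-1]

    def solve_to(t_target):
        state = np.array([1.0 - rho, math.log(rho)])
        t0 = 0.0
        for j in range(k):
            t1 = min(edges[j + 1], t_target)
            if t1 <= t0 + 1e-15:
                if t_target <= edges[j + 1]:
                    break
                continue
            lam, mu = lam_asc[j], mu_asc[j]

            def rhs(t, y):
                e, _ = y
                return [mu - (lam + mu) * e + lam * e * e,
                        -(lam + mu - 2.0 * lam * e)]

            sol = solve_ivp(rhs, (t0, t1), state, method="Radau",
                            rtol=1e-11, atol=1e-13)
            state = sol.y[:, -1]
            t0 = t1
            if t_target <= edges[j + 1] + 1e-15:
                break
        return state

    ages = sorted(tree.internal_ages(exclude_root=True))
    n = len(ages) + 2
    total = gammaln(n)
    for x in ages:
        j = min(int(np.searchsorted(edges, x, side="right")) - 1, k - 1)
        e, logphi = solve_to(x)
        total += math.log(lam_asc[j]) + logphi
    e_root, logphi_root = solve_to(tree.root_age)
    total += 2.0 * logphi_root - 2.0 * math.log(1.0 - e_root)
    return total


# --------------------------------------------------------------------------
# Window construction
# --------------------------------------------------------------------------

class TestBuildWindows:
    def test_uniform_events_make_three_equal_windows(self):
        # 300 branching ages spread uniformly over (0, 15)
        ages = np.linspace(14.95, 0.05, 300)
        tree = tree_from_branching_ages([15.0] + list(ages))
        windows = build_windows(tree, min_width=5.0, min_events=50)
        assert windows.bounds == (15.0, 10.0, 5.0, 0.0)
        assert all(count >= 50 for count in windows.events)

    def test_sparse_tree_collapses_to_single_window(self):
        tree = dc.simulate_yule_tree(30, 0.5, seed=1)
        windows = build_windows(tree, min_width=5.0, min_events=50)
        assert windows.n_windows == 1
        assert windows.bounds == (tree.root_age, 0.0)
        assert windows.events == (28,)

    def test_event_counts_sum_to_n_minus_two(self):
        tree = dc.simulate_yule_tree(150, 0.4, seed=2)
        windows = build_windows(tree, min_width=5.0, min_events=50)
        assert sum(windows.events) == 148

    def test_widths_are_multiples_except_root_most(self):
        tree = dc.simulate_yule_tree(200, 0.25, seed=3)
        windows = build_windows(tree, min_width=5.0, min_events=50)
        for width in windows.widths[1:]:
            assert width % 5.0 == pytest.approx(0.0, abs=1e-9)

    def test_every_window_meets_event_minimum(self):
        for seed in range(5):
            tree = dc.simulate_yule_tree(160, 0.3, seed=100 + seed)
            windows = build_windows(tree, min_width=5.0, min_events=50)
            if windows.n_windows > 1:
                assert min(windows.events) >= 50

    def test_boundary_event_goes_to_older_window(self):
        # events at exactly 5.0 must count toward the window above 5
        tree = tree_from_branching_ages([12.0, 5.0, 1.0])
        windows = windows_from_boundaries(tree, [5.0])
        assert windows.events == (1, 1)

    def test_explicit_boundaries_tile_root_to_present(self):
        tree = dc.simulate_yule_tree(60, 0.75, seed=4)
        windows = windows_from_boundaries(tree, [6.0, 2.0])
        assert windows.bounds[0] == pytest.approx(tree.root_age)
        assert windows.bounds[-1] == 0.0
        assert sum(windows.events) == 58


# --------------------------------------------------------------------------
# Likelihood correctness
# --------------------------------------------------------------------------

class TestEpisodicLoglik:
    def fixture_tree(self, n=40, seed=10):
        return dc.simulate_yule_tree(n, 0.5, seed=seed)

    def test_single_regime_equals_constant_rate_closed_form(self):
        tree = self.fixture_tree()
        windows = windows_from_boundaries(tree, [4.0, 2.0, 1.0])
        for lam, mu, rho in [(0.6, 0.0, 1.0), (0.8, 0.3, 1.0),
                             (0.5, 0.2, 0.6), (0.4, 0.4, 0.9)]:
            k = windows.n_windows
            piecewise = episodic_bd_loglik(tree, windows, [lam] * k,
                                           [mu] * k, rho)
            closed = constant_rate_loglik(tree, lam, mu, rho)
            assert abs(piecewise - closed) < 1e-8

    def test_pure_birth_matches_ranked_waiting_densities(self):
        tree = self.fixture_tree()
        windows = windows_from_boundaries(tree, [3.0])
        lam = 0.47
        piecewise = episodic_bd_loglik(tree, windows, [lam, lam], [0.0, 0.0],
                                       rho=1.0)
        assert abs(piecewise - yule_ranked_loglik(tree, lam)) < 1e-6

    def test_piecewise_rates_match_ode_integration(self):
        tree = self.fixture_tree(n=25, seed=12)
        windows = windows_from_boundaries(tree, [4.0, 1.5])
        rng = np.random.default_rng(0)
        for _ in range(3):
            lam = rng.uniform(0.1, 1.5, size=3)
            mu = rng.uniform(0.0, 1.2, size=3)
            got = episodic_bd_loglik(tree, windows, lam, mu, rho=0.8)
            want = ode_loglik(tree, windows, lam, mu, rho=0.8)
            assert abs(got - want) < 1e-6

    def test_refining_a_window_leaves_likelihood_unchanged(self):
        tree = self.fixture_tree()
        coarse = windows_from_boundaries(tree, [3.0])
        fine = windows_from_boundaries(tree, [4.5, 3.0, 1.0])
        a = episodic_bd_loglik(tree, coarse, [0.7, 0.4], [0.2, 0.1], 1.0)
        b = episodic_bd_loglik(tree, fine, [0.7, 0.7, 0.4, 0.4],
                               [0.2, 0.2, 0.1, 0.1], 1.0)
        assert abs(a - b) < 1e-8

    def test_continuous_across_equal_rates_boundary(self):
        tree = self.fixture_tree()
        windows = windows_from_boundaries(tree, [])
        base = episodic_bd_loglik(tree, windows, [0.5], [0.5], 1.0)
        for eps in (1e-7, -1e-7):
            nearby = episodic_bd_loglik(tree, windows, [0.5 + eps], [0.5], 1.0)
            assert abs(nearby - base) < 1e-3

    def test_invalid_inputs_rejected(self):
        tree = self.fixture_tree()
        windows = windows_from_boundaries(tree, [])
        with pytest.raises(ValueError):
            episodic_bd_loglik(tree, windows, [0.5], [0.1], rho=0.0)
        with pytest.raises(ValueError):
            episodic_bd_loglik(tree, windows, [0.5, 0.5], [0.1], rho=1.0)
        with pytest.raises(ValueError):
            episodic_bd_loglik(tree, windows, [-0.5], [0.1], rho=1.0)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

class TestFitting:
    def test_equal_fit_dominates_analytic_yule_mle(self):
        """On a pure-birth tree the optimizer must reach at least the
        likelihood of the closed-form Yule MLE, and the fitted net rate must
        track it (mu itself is a noisy ridge direction on a single tree)."""
        tree = dc.simulate_yule_tree(200, 0.75, seed=42)
        windows = windows_from_boundaries(tree, [])
        fit = fit_episodic_model(tree, windows, variant=EQUAL, rho=1.0)
        ages = tree.internal_ages(exclude_root=True)
        analytic = len(ages) / (2 * tree.root_age + sum(ages))
        at_mle = episodic_bd_loglik(tree, windows, [analytic], [1e-9], 1.0)
        assert fit.loglik >= at_mle - 1e-6
        assert fit.net_rates[0] == pytest.approx(analytic, rel=0.1)

    def test_variable_model_nests_equal_model(self):
        tree = dc.simulate_yule_tree(80, 0.6, seed=8)
        windows = windows_from_boundaries(tree, [2.0])
        equal = fit_episodic_model(tree, windows, variant=EQUAL)
        for variant in (VAR_SPEC, VAR_EXT):
            bigger = fit_episodic_model(tree, windows, variant=variant)
            assert bigger.loglik >= equal.loglik - 1e-6
            assert bigger.n_params == windows.n_windows + 1

    def test_aic_prefers_complexity_matching_the_data(self):
        sched, _ = dc.experiment_preset("experiment1")
        shifted_votes = 0
        constant_votes = 0
        for i in range(4):
            shifted = dc.prune_extinct(
                dc.simulate_bd_tree(sched, 80, seed=300 + i))
            windows = windows_from_boundaries(shifted, [6.0, 2.0])
            var = fit_episodic_model(shifted, windows, variant=VAR_SPEC)
            eq = fit_episodic_model(shifted, windows, variant=EQUAL)
            shifted_votes += var.aic < eq.aic
            steady = dc.simulate_yule_tree(80, 0.4, seed=400 + i)
            windows = windows_from_boundaries(steady, [steady.root_age / 2])
            var = fit_episodic_model(steady, windows, variant=VAR_SPEC)
            eq = fit_episodic_model(steady, windows, variant=EQUAL)
            constant_votes += eq.aic <= var.aic
        assert shifted_votes >= 3
        assert constant_votes >= 3

    def test_fit_report_table_shape(self):
        tree = dc.simulate_yule_tree(60, 0.5, seed=15)
        windows = windows_from_boundaries(tree, [1.0])
        fit = fit_episodic_model(tree, windows, variant=VAR_SPEC)
        frame = fit.to_frame()
        assert list(frame.columns) == ["older_bound", "younger_bound",
                                       "n_events", "lambda", "mu", "net_rate"]
        assert len(frame) == windows.n_windows
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
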