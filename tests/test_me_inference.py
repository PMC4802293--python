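"""Episodic birth-death likelihood and mass-extinction time estimation."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from extsig import treesim as ts
from extsig.me_inference import (
    EpisodicBDModel,
    _episodic_loglik,
    _Profile,
    fit_bd,
    fit_me_time,
    loglik_bd,
    loglik_episodic,
)
from extsig.timetree import drop_extinct, write_newick
from extsig.treestats import branching_times


def ode_loglik(ages, intervals, events, rho0):
    """Independent oracle: propagate x(t) and log q(t) by numerical ODE
    integration instead of the closed forms, then assemble identically."""
    evs = sorted(events)

    def rates(t):
        lam = mu = None
        for a, l, m in intervals:
            if t >= a - 1e-12:
                lam, mu = l, m
        return lam, mu

    def rhs(t, y):
        x = y[0]
        lam, mu = rates(t)
        r = lam - mu
        return [r * x - lam * x * x, r - 2 * lam * x]

    def x_lnq(t):
        x, lnq = rho0, math.log(rho0)
        prev = 0.0
        for a, rho in evs:
            if a >= t:
                break
            sol = solve_ivp(rhs, (prev, a), [x, lnq], rtol=1e-11, atol=1e-13)
            x, lnq = sol.y[0, -1], sol.y[1, -1]
            x, lnq = rho * x, lnq + math.log(rho)
            prev = a
        if t > prev:
            sol = solve_ivp(rhs, (prev, t), [x, lnq], rtol=1e-11, atol=1e-13)
            x, lnq = sol.y[0, -1], sol.y[1, -1]
        return x, lnq

    x1, lnq1 = x_lnq(ages[0])
    ll = 2 * lnq1 - 2 * math.log(x1)
    for t in ages[1:]:
        _, lnq = x_lnq(t)
        ll += math.log(rates(t)[0]) + lnq
    return ll


def yule_forward_loglik(ages, lam):
    """Forward pure-birth density of the oriented history (up to a
    lambda-independent constant): with k lineages the waiting time is
    Exp(k lambda), and each of the n-2 non-root splits contributes a rate
    factor."""
    x = np.concatenate([ages, [0.0]])
    g = -np.diff(x)
    k = np.arange(2, len(x) + 1)
    return float(np.sum(np.log(k[:-1] * lam)) - lam * np.sum(k * g))


class TestConstantRateLikelihood:
    def test_yule_limit_matches_forward_density(self, bd_reconstructed_pool):
        """With mu=0 and full sampling the likelihood must equal the
        closed-form pure-birth density of the same branching times, up to
        one additive constant shared across lambda."""
        tree = bd_reconstructed_pool[0]
        ages = branching_times(tree)
        offsets = [
            loglik_bd(tree, lam, 0.0) - yule_forward_loglik(ages, lam)
            for lam in (0.25, 1.0, 2.0, 5.0)
        ]
        assert np.ptp(offsets) < 1e-8

    def test_matches_ode_oracle(self, bd_reconstructed_pool):
        tree = bd_reconstructed_pool[1]
        ages = branching_times(tree)
        impl = loglik_bd(tree, 1.7, 0.8, 0.6)
        orc = ode_loglik(ages, [(0.0, 1.7, 0.8)], [], 0.6)
        assert impl == pytest.approx(orc, abs=1e-7)

    def test_supercritical_mu_allowed(self, bd_reconstructed_pool):
        val = loglik_bd(bd_reconstructed_pool[0], 1.0, 1.4)
        assert np.isfinite(val)

    def test_matches_ape_birthdeath_mle(self, rng):
        """ML estimates of (b-d, d/b) on one large tree must agree with
        ape::birthdeath, which maximizes the same conditioned likelihood
        independently."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cross-check cannot run")
        sim = ts.ConditionedSimulator(
            ts.BDRegime(2.0, 1.0), ts.SimConfig(n_extant=200)
        )
        tree = drop_extinct(sim.sample(rng))
        lam, mu, _ = fit_bd(tree)
        script = (
            'library(ape); tr <- read.tree(text=readLines("stdin")); '
            'fit <- birthdeath(tr); cat(fit$para[1], fit$para[2], "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], input=write_newick(tree) + "\n",
            capture_output=True, text=True, check=True,
        )
        a_ape, r_ape = (float(x) for x in out.stdout.split())
        assert lam - mu == pytest.approx(r_ape, abs=2e-3)
        assert mu / lam == pytest.approx(a_ape, abs=2e-3)

    def test_net_rate_recovery(self):
        """ML estimates of r = lambda - mu are close to truth on average
        over replicate 100-tip trees."""
        rng = np.random.default_rng(77)
        sim = ts.ConditionedSimulator(
            ts.BDRegime(2.0, 1.0), ts.SimConfig(n_extant=100)
        )
        rs = []
        for _ in range(15):
            lam, mu, _ = fit_bd(drop_extinct(sim.sample(rng)))
            rs.append(lam - mu)
        assert np.median(rs) == pytest.approx(1.0, abs=0.25)


class TestEpisodicLikelihood:
    def test_rho_one_equal_rates_is_noop(self, bd_reconstructed_pool):
        tree = bd_reconstructed_pool[2]
        crown = branching_times(tree)[0]
        m = EpisodicBDModel(2.0, 1.0, 2.0, 1.0, t_me=crown / 2, rho_me=1.0)
        assert loglik_episodic(tree, m) == pytest.approx(
            loglik_bd(tree, 2.0, 1.0), abs=1e-8
        )

    def test_matches_ode_oracle_with_event(self, bd_reconstructed_pool):
        tree = bd_reconstructed_pool[3]
        ages = branching_times(tree)
        t_me = ages[0] * 0.37
        m = EpisodicBDModel(1.4, 0.5, 2.2, 1.1, t_me=t_me, rho_me=0.15, rho_0=0.8)
        impl = loglik_episodic(tree, m)
        orc = ode_loglik(
            ages, [(0.0, 2.2, 1.1), (t_me, 1.4, 0.5)], [(t_me, 0.15)], 0.8
        )
        assert impl == pytest.approx(orc, abs=1e-7)

    def test_continuous_in_event_age_between_nodes(self, bd_reconstructed_pool):
        tree = bd_reconstructed_pool[4]
        ages = branching_times(tree)
        mids = (ages[2] + ages[1]) / 2
        eps = (ages[1] - ages[2]) / 1e6
        f = lambda t: loglik_episodic(
            tree, EpisodicBDModel(2.0, 0.5, 2.0, 0.5, t_me=t, rho_me=0.4)
        )
        assert f(mids + eps) == pytest.approx(f(mids - eps), abs=1e-3)

    def test_event_outside_tree_raises(self, bd_reconstructed_pool):
        tree = bd_reconstructed_pool[0]
        crown = branching_times(tree)[0]
        with pytest.raises(ValueError):
            loglik_episodic(
                tree, EpisodicBDModel(2, 1, 2, 1, t_me=crown + 1, rho_me=0.5)
            )

    def test_nested_model_dominates_constant_rate(self, me_reconstructed_pool):
        """The maximized episodic likelihood is at least the constant-rate
        maximum (the latter is the rho_me = 1 submodel)."""
        tree = me_reconstructed_pool[0]
        _, _, ll_const = fit_bd(tree)
        fit = fit_me_time(tree, n_grid=40, refine=False)
        assert fit.loglik >= ll_const - 1e-6


class TestFitMETime:
    def test_recovers_event_age_on_large_tree(self, rng):
        sim = ts.ConditionedSimulator(ts.me_regime(), ts.SimConfig(n_extant=150))
        ests = []
        for _ in range(3):
            tree = drop_extinct(sim.sample(rng))
            ests.append(fit_me_time(tree, n_grid=50).t_me)
        assert np.median(ests) == pytest.approx(1.0, abs=0.25)

    def test_small_tree_estimates_bracket_truth(self, me_reconstructed_pool):
        ests = [
            fit_me_time(t, n_grid=40, refine=False).t_me
            for t in me_reconstructed_pool[:8]
        ]
        assert 0.5 < np.median(ests) < 1.5

    def test_pure_bd_tree_prefers_weak_event(self, bd_reconstructed_pool):
        """On a tree without a mass extinction the fitted event is weak:
        either survival near 1 or a nearly flat profile."""
        fit = fit_me_time(bd_reconstructed_pool[6], n_grid=40, refine=False)
        assert fit.rho_me > 0.5 or fit.flat_profile

    def test_determinism(self, me_reconstructed_pool):
        a = fit_me_time(me_reconstructed_pool[1], n_grid=25, refine=False)
        b = fit_me_time(me_reconstructed_pool[1], n_grid=25, refine=False)
        assert a.t_me == b.t_me and a.loglik == b.loglik

    def test_requires_ten_tips(self, rng):
        small = drop_extinct(
            ts.simulate_bd_conditional(
                ts.BDRegime(2.0, 0.5), ts.SimConfig(n_extant=5), rng
            )
        )
        with pytest.raises(Exception):
            fit_me_time(small)
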