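"""DEC model: rate matrix, transition probabilities, pruning likelihood
against exhaustive enumeration, fitting, range-dependent simulation, and
the event-cost arithmetic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extsig import dec_biogeo as dec
from extsig.dec_biogeo import (
    A,
    AB,
    B,
    NULL,
    DECModel,
    EventCostTable,
    RangeDDParams,
    build_q,
    dec_fit,
    dec_loglik,
    event_cost,
    simulate_dec_states,
    simulate_range_dd,
    transition_probs,
)
from extsig.timetree import drop_extinct, read_newick
from extsig.treesim import simulate_trees, BDRegime, SimConfig


def enumeration_loglik(tree, tip_states, model):
    """Exhaustive sum over all internal-node states and ordered
    cladogenetic outcomes (independent of the pruning recursion)."""
    q = build_q(model)
    nodes = tree.internal_nodes()
    P = {id(n): transition_probs(q, n.edge_length) for n in tree.preorder()}
    opts = []
    for n in nodes:
        node_opts = []
        for s in (A, B, AB):
            for (uv, w) in dec._cladogenesis_outcomes(s):
                node_opts.append((s, uv, w))
        opts.append(node_opts)
    total = 0.0
    for combo in itertools.product(*opts):
        assign = {id(n): c for n, c in zip(nodes, combo)}
        pr = 1.0 / 3.0  # flat root prior over the observable states
        for n in nodes:
            s, (u, v), w = assign[id(n)]
            pr *= w
            if n.parent is not None:
                ps, (pu, pv), _ = assign[id(n.parent)]
                side = pu if n is n.parent.children[0] else pv
                pr *= P[id(n)][side, s]
            for child, cs in zip(n.children, (u, v)):
                if child.is_tip:
                    st = dec.STATE_INDEX[tip_states[child.label]]
                    pr *= P[id(child)][cs, st]
        total += pr
    return math.log(total)


class TestQMatrix:
    def test_zero_rates_zero_matrix(self):
        assert np.allclose(build_q(DECModel(0, 0, 0, 0)), 0.0)

    def test_sparsity_pattern(self):
        q = build_q(DECModel(0.3, 0.4, 0.1, 0.2))
        assert q[A, B] == 0 and q[B, A] == 0  # no direct single-area moves
        assert q[AB, NULL] == 0               # one event removes one area
        assert q[NULL].sum() == 0             # null is absorbing
        assert q[A, AB] == 0.3 and q[B, AB] == 0.4
        assert q[AB, B] == 0.1 and q[AB, A] == 0.2  # lose X at e_X
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_label_swap_symmetry(self):
        q = build_q(DECModel(0.3, 0.3, 0.2, 0.2))
        perm = [NULL, B, A, AB]
        assert np.allclose(q, q[np.ix_(perm, perm)])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            DECModel(-0.1, 0, 0, 0)


class TestTransitionProbs:
    @pytest.fixture()
    def q(self):
        return build_q(DECModel(0.7, 0.2, 0.4, 0.9))

    def test_identity_at_zero(self, q):
        assert np.allclose(transition_probs(q, 0.0), np.eye(4))

    def test_series_for_small_t(self, q):
        t = 1e-5
        p = transition_probs(q, t)
        assert np.allclose(p, np.eye(4) + q * t, atol=5 * t * t * np.abs(q).max() ** 2)

    def test_matches_scaled_taylor_sum(self, q):
        """Independent oracle: squared Taylor-series summation."""
        for t in (0.3, 2.0, 17.0):
            m, k = q * t, 0
            while np.abs(m).max() > 1e-3:
                m, k = m / 2.0, k + 1
            term = np.eye(4)
            total = np.eye(4)
            for j in range(1, 30):
                term = term @ m / j
                total = total + term
            for _ in range(k):
                total = total @ total
            assert np.allclose(transition_probs(q, t), total, atol=1e-10)

    @pytest.mark.parametrize("t", [0.0, 0.5, 5.0, 100.0])
    def test_rows_sum_to_one(self, q, t):
        assert np.allclose(transition_probs(q, t).sum(axis=1), 1.0, atol=1e-9)


SMALL_TREES = [
    ("(a:1,b:1);", {"a": "A", "b": "A"}),
    ("(a:1,b:1);", {"a": "A", "b": "B"}),
    ("((a:1,b:1):1,c:2);", {"a": "A", "b": "AB", "c": "B"}),
    ("(((a:1,b:1):1,c:2):0.5,d:2.5);", {"a": "A", "b": "B", "c": "AB", "d": "A"}),
    (
        "(((a:1,b:1):1,c:2):0.5,(d:2,e:2):0.5);",
        {"a": "B", "b": "B", "c": "A", "d": "AB", "e": "A"},
    ),
]


class TestPruningLikelihood:
    @pytest.mark.parametrize("newick,tips", SMALL_TREES)
    def test_matches_enumeration(self, newick, tips):
        tree = read_newick(newick)
        model = DECModel(0.31, 0.47, 0.23, 0.11)
        assert dec_loglik(tree, tips, model) == pytest.approx(
            enumeration_loglik(tree, tips, model), abs=1e-8
        )

    def test_two_tip_hand_enumeration(self):
        """2-tip tree, both tips in A: explicit sum over root states with
        the exponentiated Q."""
        tree = read_newick("(a:2,b:2);")
        model = DECModel(0.4, 0.4, 0.15, 0.15)
        p = transition_probs(build_q(model), 2.0)
        total = 0.0
        for s in (A, B, AB):
            for (u, v), w in dec._cladogenesis_outcomes(s):
                total += (1 / 3) * w * p[u, A] * p[v, A]
        assert dec_loglik(tree, {"a": "A", "b": "A"}, model) == pytest.approx(
            math.log(total), abs=1e-12
        )

    def test_no_movement_limit(self):
        """With all rates zero and every tip in A, the likelihood is the
        root prior mass on A."""
        tree = read_newick("((a:1,b:1):1,c:2);")
        ll = dec_loglik(tree, {t: "A" for t in "abc"}, DECModel(0, 0, 0, 0))
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_relabel_symmetry(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        model = DECModel(0.5, 0.5, 0.3, 0.3)
        tips = {"a": "A", "b": "AB", "c": "B"}
        swapped = {"a": "B", "b": "AB", "c": "A"}
        assert dec_loglik(tree, tips, model) == pytest.approx(
            dec_loglik(tree, swapped, model), abs=1e-12
        )

    def test_unknown_tip_state_raises(self):
        tree = read_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            dec_loglik(tree, {"a": "A", "b": "C"}, DECModel(0.1, 0.1, 0.1, 0.1))


class TestDECFit:
    def test_no_extirpation_signal(self, rng):
        """Data simulated with e = 0 pull the extirpation MLE to zero."""
        trees = simulate_trees(BDRegime(1.0, 0.0), 3, rng, SimConfig(n_extant=25))
        model = DECModel(0.4, 0.4, 0.0, 0.0)
        es = []
        for tree in trees:
            states = simulate_dec_states(tree, model, rng)
            fit = dec_fit(tree, states)
            es.append(fit.e)
        assert np.median(es) < 0.02

    def test_determinism(self, rng):
        tree = simulate_trees(BDRegime(1.0, 0.0), 1, rng, SimConfig(n_extant=15))[0]
        states = simulate_dec_states(tree, DECModel(0.3, 0.3, 0.05, 0.05), rng)
        a, b = dec_fit(tree, states), dec_fit(tree, states)
        assert (a.d, a.e, a.root_call) == (b.d, b.e, b.root_call)

    def test_parameter_recovery_within_2se(self):
        """Pooled ML on model-correct anagenetic simulations recovers the
        generating (d, e) within two standard errors (observed-information
        SEs from the pooled likelihood)."""
        rng = np.random.default_rng(55)
        d_true, e_true = 0.25, 0.08
        model = DECModel(d_true, d_true, e_true, e_true)
        trees = simulate_trees(BDRegime(1.0, 0.0), 20, rng, SimConfig(n_extant=30))
        data = [(t, simulate_dec_states(t, model, rng)) for t in trees]

        def pooled_nll(theta):
            d, e = np.exp(theta)
            m = DECModel(d, d, e, e)
            return -sum(dec_loglik(t, s, m) for t, s in data)

        from scipy.optimize import minimize

        res = minimize(
            pooled_nll, [math.log(0.2), math.log(0.1)], method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9},
        )
        d_hat, e_hat = np.exp(res.x)
        # numerical observed information on the log scale; the step must be
        # large enough to beat cancellation in the pooled NLL differences
        h = 0.05
        hess = np.zeros((2, 2))
        f0 = pooled_nll(res.x)
        for i in range(2):
            for j in range(2):
                xpp = res.x.copy(); xpp[i] += h; xpp[j] += h
                xpm = res.x.copy(); xpm[i] += h; xpm[j] -= h
                xmp = res.x.copy(); xmp[i] -= h; xmp[j] += h
                xmm = res.x.copy(); xmm[i] -= h; xmm[j] -= h
                hess[i, j] = (
                    pooled_nll(xpp) - pooled_nll(xpm) - pooled_nll(xmp) + pooled_nll(xmm)
                ) / (4 * h * h)
        se_log = np.sqrt(np.diag(np.linalg.inv(hess)))
        assert abs(math.log(d_hat) - math.log(d_true)) < 2 * se_log[0]
        assert abs(math.log(e_hat) - math.log(e_true)) < 2.5 * se_log[1]


class TestRangeDependentSimulation:
    def test_no_extinction_tip_states(self, rng):
        params = RangeDDParams(x_a=0.0, x_b=0.0, d_ab=0.0, d_ba=0.0, s_ab=0.0)
        tree, states = simulate_range_dd(params, 10, rng, pilot_runs=20)
        assert tree.n_extant == 10
        assert len(tree.extinct_tips()) == 0
        assert set(states.values()) <= {"A", "B", "AB"}

    def test_symmetric_scenario_balance(self, rng):
        """With symmetric rates, tips containing A and tips containing B
        are exchangeable over replicates."""
        params = RangeDDParams()  # symmetric defaults
        from extsig.dec_biogeo import RangeDDSimulator

        sim = RangeDDSimulator(params, n_extant=15, pilot_runs=40)
        count_a = count_b = 0
        for _ in range(20):
            _, states = sim.sample(rng)
            vals = list(states.values())
            count_a += sum("A" in v for v in vals)
            count_b += sum("B" in v for v in vals)
        total = count_a + count_b
        assert abs(count_a - count_b) / total < 0.2

    def test_asymmetric_extinction_depletes_b(self, rng):
        from extsig.dec_biogeo import RangeDDSimulator

        sym = RangeDDSimulator(RangeDDParams(x_a=0.9, x_b=0.9), n_extant=15,
                               pilot_runs=30)
        asym = RangeDDSimulator(RangeDDParams(x_a=0.4, x_b=1.9), n_extant=15,
                                pilot_runs=30)

        def b_fraction(sim, reps=12):
            tot = with_b = 0
            for _ in range(reps):
                _, states = sim.sample(rng)
                vals = list(states.values())
                tot += len(vals)
                with_b += sum("B" in v for v in vals)
            return with_b / tot

        assert b_fraction(asym) < b_fraction(sym)


class TestEventCosts:
    def test_default_costs(self):
        assert EventCostTable() == EventCostTable(0.01, 0.01, 1.0, 2.0)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"U": 2, "E": 2, "V": 1}, 2.03),  # high extinction asymmetry
            ({"U": 2, "D": 1}, 2.02),          # single dispersal event
            ({"D": 3}, 6.0),                   # nested ancestral area
            ({}, 0.0),
            ({"V": 0, "U": 0, "E": 0, "D": 0}, 0.0),
        ],
    )
    def test_scenario_costs(self, counts, expected):
        assert event_cost(counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            event_cost({"D": -1})

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            event_cost({"X": 1})

    def test_custom_costs(self):
        costs = EventCostTable(vicariance=1, duplication=1, extinction=1, dispersal=1)
        assert event_cost({"V": 1, "U": 2, "E": 3, "D": 4}, costs) == 10

    @given(
        counts=st.fixed_dictionaries(
            {k: st.integers(min_value=0, max_value=50) for k in "VUED"}
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cost_is_linear_in_counts(self, counts):
        """The total cost equals the sum of per-event-type costs and
        doubles when every count doubles."""
        total = event_cost(counts)
        parts = sum(event_cost({k: v}) for k, v in counts.items())
        assert total == pytest.approx(parts, abs=1e-12)
        doubled = event_cost({k: 2 * v for k, v in counts.items()})
        assert doubled == pytest.approx(2 * total, abs=1e-12)
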