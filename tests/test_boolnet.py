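"""Boolean-network parsing, synchronous dynamics and the exact stationary
oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmesim.boolnet import (RuleSyntaxError, attractor_cycle,
                            exact_stationary_distribution, parse_rule,
                            parse_rules, perturbation_branch_probability,
                            rule_inputs, rule_to_str, update_states)
from tmesim.demo import make_toy_network, pcc_network, psc_network


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_rule_inputs_and_structure():
    net = parse_rules("targets, factors\nA, B & !C\nB, 1\nC, 0\n")
    assert net.nodes == ["A", "B", "C"]
    assert rule_inputs(net.rules["A"]) == {"B", "C"}
    assert rule_inputs(net.rules["B"]) == set()


def test_undeclared_node_is_named_in_error():
    with pytest.raises(RuleSyntaxError, match="Z"):
        parse_rules("targets, factors\nA, B\nB, Z\n")


def test_duplicate_target_rejected():
    with pytest.raises(RuleSyntaxError, match="duplicate"):
        parse_rules("targets, factors\nA, B\nA, !B\nB, A\n")


def test_receptor_must_not_carry_rule():
    with pytest.raises(RuleSyntaxError, match="receptor"):
        parse_rules("targets, factors\nR, A\nA, R\n", receptors=["R"])


@pytest.mark.parametrize("expr,env,expected", [
    ("!B | C & D", {"B": 1, "C": 1, "D": 1}, True),    # NOT > AND > OR
    ("!B | C & D", {"B": 1, "C": 1, "D": 0}, False),
    ("!(B | C) & D", {"B": 0, "C": 0, "D": 1}, True),
    ("B & !C", {"B": 1, "C": 0}, True),
    ("B & !C", {"B": 1, "C": 1}, False),
    ("1", {}, True),
    ("0 | A", {"A": 1}, True),
])
def test_operator_precedence(expr, env, expected):
    names = sorted(set(env) | {"A"})
    rules = "targets, factors\nX, " + expr + "\n"
    rules += "".join(f"{u}, {u}\n" for u in names)
    net = parse_rules(rules)
    X = np.zeros((1, net.n), dtype=bool)
    for name, val in env.items():
        X[0, net.index[name]] = val
    out = net.apply_rules(X)
    assert out[0, net.index["X"]] == expected


@pytest.mark.parametrize("make_net", [pcc_network, psc_network,
                                      lambda: make_toy_network(6, 3, seed=5)])
def test_parse_serialize_parse_identity(make_net):
    net = make_net()
    again = parse_rules(net.to_text(), name=net.name, receptors=net.receptors,
                        phenotype_nodes=net.phenotype_nodes,
                        secretion_nodes=net.secretion_nodes)
    assert again.nodes == net.nodes
    assert again.rules == net.rules


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10 ** 6))
def test_random_network_roundtrip_and_eval_equivalence(n, seed):
    """Serialization preserves the truth table of every rule."""
    net = make_toy_network(n, k=min(3, n), seed=seed)
    again = parse_rules(net.to_text(), name=net.name)
    states = np.array(np.meshgrid(*[[0, 1]] * n)).T.reshape(-1, n).astype(bool)
    assert np.array_equal(net.apply_rules(states), again.apply_rules(states))


def test_rule_to_str_minimal_parens():
    ast = parse_rule("(A | B) & !C")
    assert rule_to_str(ast) == "(A | B) & !C"
    assert rule_to_str(parse_rule("A | B & C")) == "A | B & C"


# ---------------------------------------------------------------------------
# Synchronous dynamics
# ---------------------------------------------------------------------------

def test_deterministic_update_q0():
    net = parse_rules("targets, factors\nA, B & C\nB, B\nC, C\n")
    for b, c in [(1, 1), (1, 0), (0, 1)]:
        X = np.array([[0, b, c]], dtype=bool)
        out = update_states(net, X, q=0.0)
        assert out[0, 0] == (b and c)


def test_update_is_synchronous_from_frozen_snapshot():
    # A and B swap values every step only under true synchrony
    net = parse_rules("targets, factors\nA, B\nB, A\n")
    X = np.array([[1, 0]], dtype=bool)
    out = update_states(net, X, q=0.0)
    assert out.tolist() == [[False, True]]


def test_perturbation_branch_frequency(rng):
    """With identity rules, a state change happens iff the gamma branch
    fires: empirical rate matches 1 - (1-q)^n."""
    n, q, trials = 10, 0.01, 100_000
    rules = "targets, factors\n" + "".join(f"g{i}, g{i}\n" for i in range(n))
    net = parse_rules(rules)
    X = rng.random((trials, n)) < 0.5
    out = update_states(net, X, q=q, rng=rng)
    changed = (out != X).any(axis=1).mean()
    expected = perturbation_branch_probability(q, n)
    assert expected == pytest.approx(1 - 0.99 ** 10)
    se = np.sqrt(expected * (1 - expected) / trials)
    assert abs(changed - expected) < 4 * se


def test_clamped_node_survives_perturbation(rng):
    net = parse_rules("targets, factors\nKRAS, !KRAS\nB, B\n")
    X = np.zeros((64, 2), dtype=bool)
    for _ in range(50):
        X = update_states(net, X, q=0.5, rng=rng, clamps=[("KRAS", 1)])
        assert X[:, 0].all()


def test_clamp_mask_restricts_cells(rng):
    net = parse_rules("targets, factors\nA, A\n")
    X = np.zeros((10, 1), dtype=bool)
    mask = np.zeros(10, dtype=bool)
    mask[:4] = True
    out = update_states(net, X, q=0.0, rng=rng, clamps=[("A", 1, mask)])
    assert out[:4, 0].all() and not out[4:, 0].any()


def test_receptor_overwrite_order(rng):
    # receptor written after perturbation, clamps after receptors
    net = parse_rules("targets, factors\nA, R\n", receptors=["R"])
    X = np.zeros((8, 2), dtype=bool)
    out = update_states(net, X, receptor_values={"R": True}, q=0.9, rng=rng)
    assert out[:, net.index["R"]].all()


# ---------------------------------------------------------------------------
# Exact stationary oracle
# ---------------------------------------------------------------------------

def test_stationary_identity_rule_symmetric():
    net = parse_rules("targets, factors\nA, A\n")
    pi = exact_stationary_distribution(net, q=0.2)
    assert pi == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize("q", [0.01, 0.1, 0.3])
def test_stationary_constant_rule_closed_form(q):
    """F(x) = 1 gives pi(0) = q/(1+q), pi(1) = 1/(1+q) (balance equations)."""
    net = parse_rules("targets, factors\nA, 1\n")
    pi = exact_stationary_distribution(net, q=q)
    assert pi[0] == pytest.approx(q / (1 + q), rel=1e-12)
    assert pi[1] == pytest.approx(1 / (1 + q), rel=1e-12)


def test_stationary_strictly_positive(abc_net):
    pi = exact_stationary_distribution(abc_net, q=0.05)
    assert pi.min() > 0
    assert pi.sum() == pytest.approx(1.0)


def test_stationary_matches_empirical_visits(abc_net):
    """Long-run visit frequencies of the simulated chain agree with the
    exact stationary vector."""
    q = 0.1
    pi = exact_stationary_distribution(abc_net, q=q)
    rng = np.random.default_rng(7)
    n_chains, n_steps, burn = 200, 600, 100
    X = rng.random((n_chains, 3)) < 0.5
    counts = np.zeros(8)
    for t in range(n_steps):
        X = update_states(abc_net, X, q=q, rng=rng)
        if t >= burn:
            codes = X @ (1 << np.arange(3))
            counts += np.bincount(codes, minlength=8)
    freq = counts / counts.sum()
    n_eff = n_chains * (n_steps - burn) / 10  # autocorrelation discount
    se = np.sqrt(pi * (1 - pi) / n_eff)
    assert (np.abs(freq - pi) < 3 * se + 1e-3).all()


def test_stationary_with_clamp_puts_no_mass_on_clamped_off_states():
    net = parse_rules("targets, factors\nA, B\nB, A\n")
    pi = exact_stationary_distribution(net, q=0.1, clamps=[("A", 1)])
    # states with bit A = 0 are unreachable
    assert pi[0] == 0 and pi[2] == 0
    assert pi.sum() == pytest.approx(1.0)


def test_stationary_refuses_large_networks():
    net = make_toy_network(12, 2, seed=0)
    with pytest.raises(ValueError, match="12"):
        exact_stationary_distribution(net, q=0.1, max_nodes=11)


def test_q0_attractors_match_enumeration(abc_net):
    """Deterministic attractor from every start state agrees with brute-force
    iteration of the rule map."""
    n = abc_net.n
    states = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    image = abc_net.apply_rules(states)
    codes = image @ (1 << np.arange(n))
    for start in range(2 ** n):
        cyc = attractor_cycle(abc_net, states[start])
        # brute force: iterate the map until repetition
        seen, s = [], start
        while s not in seen:
            seen.append(s)
            s = int(codes[s])
        brute = seen[seen.index(s):]
        got = [int(c @ (1 << np.arange(n))) for c in cyc]
        # same cycle up to rotation
        assert len(got) == len(brute)
        assert set(got) == set(brute)
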