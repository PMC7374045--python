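"""Stochastic synchronous Boolean networks.

Each cell type is described by a Boolean network whose nodes are either
*receptor* nodes (set by the extracellular environment each step) or
*regulatory* nodes updated by logic rules.  Dynamics follow the random
Boolean network convention: with probability ``1 - (1-q)^n`` the state is
perturbed by a random bit-flip vector, otherwise all regulatory rules are
applied synchronously.  Any positive flip probability ``q`` makes the chain
ergodic with a unique stationary distribution, which for small networks can
be computed exactly and serves as a test oracle.

Rule files follow the BoolNet plain-text convention::

    targets, factors
    A, B & !C
    Proliferation, A | (B & !A)

with operators ``!`` (NOT), ``&`` (AND), ``|`` (OR), parentheses and the
constants ``0``/``1``; precedence is NOT > AND > OR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BooleanNetwork",
    "RuleSyntaxError",
    "parse_rule",
    "parse_rules",
    "parse_rule_file",
    "rule_to_str",
    "update_states",
    "perturbation_branch_probability",
    "exact_stationary_distribution",
    "attractor_cycle",
]


class RuleSyntaxError(ValueError):
    """Malformed or inconsistent Boolean rule text."""


# ---------------------------------------------------------------------------
# Rule expressions: tokenizer + recursive-descent parser -> tuple AST
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.-]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str, line: str = "") -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"unexpected character {text[pos]!r} in rule {line or text!r}")
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    return tokens


def parse_rule(text: str):
    """Parse one Boolean expression into a tuple AST.

    AST nodes: ``('var', name)``, ``('const', bool)``, ``('not', a)``,
    ``('and', a, b)``, ``('or', a, b)``.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() == "|":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_not()
        while peek() == "&":
            take()
            node = ("and", node, parse_not())
        return node

    def parse_not():
        if peek() == "!":
            take()
            return ("not", parse_not())
        return parse_atom()

    def parse_atom():
        tok = peek()
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise RuleSyntaxError(f"unbalanced parentheses in rule {text!r}")
            take()
            return node
        if tok in ("0", "1"):
            take()
            return ("const", tok == "1")
        if tok is None or tok in ("&", "|", ")"):
            raise RuleSyntaxError(f"unexpected end or operator in rule {text!r}")
        return ("var", take())

    node = parse_or()
    if pos != len(tokens):
        raise RuleSyntaxError(f"trailing tokens in rule {text!r}")
    return node


def rule_inputs(ast) -> set[str]:
    kind = ast[0]
    if kind == "var":
        return {ast[1]}
    if kind == "const":
        return set()
    out: set[str] = set()
    for child in ast[1:]:
        out |= rule_inputs(child)
    return out


def rule_to_str(ast, _parent: int = 0) -> str:
    """Serialize an AST back to rule text (minimal parentheses)."""
    prec = {"or": 1, "and": 2, "not": 3, "var": 4, "const": 4}
    kind = ast[0]
    if kind == "var":
        s = ast[1]
    elif kind == "const":
        s = "1" if ast[1] else "0"
    elif kind == "not":
        s = "!" + rule_to_str(ast[1], prec["not"])
    elif kind == "and":
        s = " & ".join(rule_to_str(c, prec["and"]) for c in ast[1:])
    else:  # or
        s = " | ".join(rule_to_str(c, prec["or"]) for c in ast[1:])
    if prec[kind] < _parent:
        s = "(" + s + ")"
    return s


def _compile_rule(ast, index: dict[str, int]):
    """Compile an AST into a vectorized evaluator over a (cells, nodes) bool array."""

    def build(node) -> str:
        kind = node[0]
        if kind == "var":
            return f"X[:, {index[node[1]]}]"
        if kind == "const":
            return "_ONES" if node[1] else "_ZEROS"
        if kind == "not":
            return f"~({build(node[1])})"
        op = " & " if kind == "and" else " | "
        return "(" + op.join(build(c) for c in node[1:]) + ")"

    src = build(ast)
    code = compile(src, "<rule>", "eval")

    def evaluate(X: np.ndarray, _ones=None, _zeros=None) -> np.ndarray:
        env = {"X": X,
               "_ONES": np.ones(X.shape[0], dtype=bool) if _ones is None else _ones,
               "_ZEROS": np.zeros(X.shape[0], dtype=bool) if _zeros is None else _zeros}
        return eval(code, {"__builtins__": {}}, env)  # noqa: S307 - sanitized AST

    return evaluate


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """A cell-type Boolean network.

    Parameters
    ----------
    name : str
        Cell-type label (e.g. ``"PCC"``).
    nodes : list of str
        All node names, receptors first then regulatory nodes in rule order.
    receptors : list of str
        Nodes set by the environment; they carry no logic rule.
    rules : dict
        Maps each regulatory node to its rule AST.
    phenotype_nodes : list of str
        Regulatory nodes read out as cellular phenotypes
        (Proliferation, Apoptosis, ...).
    secretion_nodes : dict
        Maps cytokine name -> regulatory node whose state switches secretion
        between the basal rate 1 (OFF) and the active rate R (ON).
    """

    name: str
    nodes: list[str]
    receptors: list[str]
    rules: dict[str, tuple]
    phenotype_nodes: list[str] = field(default_factory=list)
    secretion_nodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise RuleSyntaxError(f"duplicate node names in network {self.name!r}")
        declared = set(self.nodes)
        rec = set(self.receptors)
        if not rec <= declared:
            raise RuleSyntaxError(f"receptor nodes {sorted(rec - declared)} not declared")
        for target, ast in self.rules.items():
            if target in rec:
                raise RuleSyntaxError(f"receptor node {target!r} must not carry a rule")
            missing = rule_inputs(ast) - declared
            if missing:
                raise RuleSyntaxError(
                    f"rule for {target!r} references undeclared node(s) {sorted(missing)}")
        for target in declared - rec:
            if target not in self.rules:
                raise RuleSyntaxError(f"regulatory node {target!r} has no rule")
        for label, group in (("phenotype", self.phenotype_nodes),
                             ("secretion", list(self.secretion_nodes.values()))):
            for node in group:
                if node not in self.rules:
                    raise RuleSyntaxError(
                        f"{label} annotation {node!r} must name a regulatory node")
        self.index = {name: i for i, name in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.receptor_idx = np.array([self.index[r] for r in self.receptors], dtype=int)
        self._regulatory = [u for u in self.nodes if u not in rec]
        self._evaluators = [(self.index[u], _compile_rule(self.rules[u], self.index))
                            for u in self._regulatory]

    @property
    def regulatory_nodes(self) -> list[str]:
        return list(self._regulatory)

    def apply_rules(self, X: np.ndarray) -> np.ndarray:
        """Apply all regulatory rules synchronously to a frozen snapshot.

        ``X`` has shape (cells, n); receptor columns are copied unchanged.
        """
        out = X.copy()
        ones = np.ones(X.shape[0], dtype=bool)
        zeros = np.zeros(X.shape[0], dtype=bool)
        for j, fn in self._evaluators:
            out[:, j] = fn(X, ones, zeros)
        return out

    def to_text(self) -> str:
        lines = ["targets, factors"]
        for u in self._regulatory:
            lines.append(f"{u}, {rule_to_str(self.rules[u])}")
        return "\n".join(lines) + "\n"


def parse_rules(text: str, name: str = "net", receptors=(), phenotype_nodes=(),
                secretion_nodes=None) -> BooleanNetwork:
    """Parse BoolNet-style rule text plus node-kind annotations."""
    rules: dict[str, tuple] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise RuleSyntaxError(f"line {lineno}: expected 'target, factors', got {raw!r}")
        target, expr = line.split(",", 1)
        target = target.strip()
        if not target or not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.-]*", target):
            raise RuleSyntaxError(f"line {lineno}: bad target name {target!r}")
        if target in rules:
            raise RuleSyntaxError(f"line {lineno}: duplicate target {target!r}")
        try:
            rules[target] = parse_rule(expr)
        except RuleSyntaxError as exc:
            raise RuleSyntaxError(f"line {lineno}: {exc}") from None
        order.append(target)

    for target in order:
        if target in receptors:
            raise RuleSyntaxError(f"receptor node {target!r} must not carry a rule")
    declared = set(order) | set(receptors)
    for lineno, target in enumerate(order, start=1):
        missing = rule_inputs(rules[target]) - declared
        if missing:
            raise RuleSyntaxError(
                f"rule for {target!r} references undeclared node(s) {sorted(missing)}")

    nodes = list(receptors) + order
    return BooleanNetwork(name=name, nodes=nodes, receptors=list(receptors),
                          rules=rules, phenotype_nodes=list(phenotype_nodes),
                          secretion_nodes=dict(secretion_nodes or {}))


def parse_rule_file(path, name=None, receptors=(), phenotype_nodes=(),
                    secretion_nodes=None) -> BooleanNetwork:
    with open(path) as fh:
        text = fh.read()
    return parse_rules(text, name=name or str(path), receptors=receptors,
                       phenotype_nodes=phenotype_nodes, secretion_nodes=secretion_nodes)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def perturbation_branch_probability(q: float, n_flippable: int) -> float:
    """Probability that at least one of ``n_flippable`` nodes is flipped."""
    return 1.0 - (1.0 - q) ** n_flippable


def update_states(net: BooleanNetwork, X: np.ndarray, receptor_values=None,
                  q: float = 0.0, rng: np.random.Generator | None = None,
                  clamps=None, perturb_receptors: bool = False) -> np.ndarray:
    """One synchronous update of a population of cells sharing one network.

    Per cell: draw i.i.d. Bernoulli(q) flip indicators over the flippable
    nodes (receptors excluded by default, since the environment overwrites
    them anyway); if any indicator fires the next state is the XOR of the
    current state with the flip vector, otherwise all rules are applied
    synchronously.  Receptor values are then written and clamps re-applied,
    in that order, so clamped nodes are permanent for every realization.

    Parameters
    ----------
    X : (cells, n) bool array
        Current states; not modified.
    receptor_values : dict, optional
        node name -> bool scalar or (cells,) array.
    clamps : sequence of (node, value) or (node, value, mask), optional
        ``mask`` restricts the clamp to a subset of cells.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    X = np.asarray(X, dtype=bool)
    nxt = net.apply_rules(X)
    if q > 0.0:
        if rng is None:
            raise ValueError("q > 0 requires an rng")
        gamma = rng.random(X.shape) < q
        if not perturb_receptors and net.receptor_idx.size:
            gamma[:, net.receptor_idx] = False
        perturbed = gamma.any(axis=1)
        if perturbed.any():
            nxt[perturbed] = X[perturbed] ^ gamma[perturbed]
    if receptor_values:
        for node, val in receptor_values.items():
            nxt[:, net.index[node]] = val
    if clamps:
        for clamp in clamps:
            if len(clamp) == 2:
                node, val = clamp
                nxt[:, net.index[node]] = val
            else:
                node, val, mask = clamp
                nxt[mask, net.index[node]] = val
    return nxt


# ---------------------------------------------------------------------------
# Exact small-network oracle
# ---------------------------------------------------------------------------

def _states_matrix(free_nodes: int) -> np.ndarray:
    """All 2^k binary states as a (2^k, k) bool array; bit j of the integer
    encoding corresponds to column j."""
    ints = np.arange(2 ** free_nodes, dtype=np.uint32)
    return (ints[:, None] >> np.arange(free_nodes)) & 1


def exact_stationary_distribution(net: BooleanNetwork, q: float,
                                  receptor_values=None, clamps=None,
                                  max_nodes: int = 12) -> np.ndarray:
    """Exact stationary distribution of the perturbed synchronous chain.

    Builds the full 2^k x 2^k transition matrix over the regulatory nodes
    (receptors, if any, are frozen at ``receptor_values``) and solves the
    balance equations.  Entry ``pi[s]`` is the stationary probability of the
    state whose regulatory bit ``j`` is bit ``j`` of the integer ``s``.

    Only feasible for small networks; refuses beyond ``max_nodes`` regulatory
    nodes.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("the chain is ergodic only for 0 < q < 1")
    reg = net.regulatory_nodes
    k = len(reg)
    if k > max_nodes:
        raise ValueError(
            f"network has {k} regulatory nodes; the exact oracle is limited to "
            f"{max_nodes} (2^n transition matrix)")
    if net.receptors and receptor_values is None:
        raise ValueError("receptor_values required for networks with receptor nodes")

    n_states = 2 ** k
    reg_cols = np.array([net.index[u] for u in reg])
    states = np.zeros((n_states, net.n), dtype=bool)
    states[:, reg_cols] = _states_matrix(k).astype(bool)
    if receptor_values:
        for node, val in receptor_values.items():
            states[:, net.index[node]] = bool(val)

    clamp_pairs = [(net.index[c[0]], bool(c[1])) for c in (clamps or [])]
    reg_pos = {col: j for j, col in enumerate(reg_cols)}

    def encode(mat: np.ndarray) -> np.ndarray:
        for col, val in clamp_pairs:
            mat[:, col] = val
        bits = mat[:, reg_cols].astype(np.uint32)
        return (bits << np.arange(k, dtype=np.uint32)).sum(axis=1)

    # deterministic synchronous image of every state (receptors frozen)
    nxt = net.apply_rules(states)
    if receptor_values:
        for node, val in receptor_values.items():
            nxt[:, net.index[node]] = bool(val)
    f_img = encode(nxt)

    clamp_bits = [(reg_pos[col], val) for col, val in clamp_pairs if col in reg_pos]

    def project(codes: np.ndarray) -> np.ndarray:
        out = codes.copy()
        for j, val in clamp_bits:
            if val:
                out |= np.uint32(1 << j)
            else:
                out &= np.uint32(~(1 << j) & (2 ** k - 1))
        return out

    P = np.zeros((n_states, n_states))
    codes = np.arange(n_states, dtype=np.uint32)
    no_flip = (1.0 - q) ** k
    for g in range(1, n_states):
        w = q ** bin(g).count("1") * (1.0 - q) ** (k - bin(g).count("1"))
        np.add.at(P, (codes, project(codes ^ np.uint32(g))), w)
    np.add.at(P, (codes, project(f_img)), no_flip)

    # solve pi P = pi, sum(pi) = 1
    A = P.T - np.eye(n_states)
    A[-1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def attractor_cycle(net: BooleanNetwork, start: np.ndarray,
                    receptor_values=None, clamps=None, max_steps: int = 4096):
    """Deterministic (q=0) attractor reached from ``start``: list of states."""
    X = np.asarray(start, dtype=bool).reshape(1, -1).copy()
    seen: dict[bytes, int] = {}
    trajectory = []
    for step in range(max_steps + 1):
        key = X.tobytes()
        if key in seen:
            return trajectory[seen[key]:]
        seen[key] = step
        trajectory.append(X[0].copy())
        X = update_states(net, X, receptor_values=receptor_values, q=0.0, clamps=clamps)
    raise RuntimeError("no cycle found within max_steps")
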