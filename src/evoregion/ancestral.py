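"""Ancestral evoregion reconstruction under the Mk model.

Tip states are evoregion assignments (letters) plus the widespread class,
treated as an ordinary extra state.  The default model is equal-rates Mk
with ``k`` states: every off-diagonal transition has rate ``q = rate/(k-1)``
so ``rate`` is the total departure rate from any state, and the transition
probability has the closed form
``P_ij(t) = 1/k + (delta_ij - 1/k) * exp(-k q t)``.

Ancestral states are summarized two ways: exact marginal posteriors from an
up-down pruning pass, and stochastic character maps — full histories sampled
conditional on the tips by drawing node states from their joint conditional
distribution and filling each branch by rejection sampling (with a
uniformization fallback for branches where rejection is inefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DiscreteCharacter",
    "AncestralSummary",
    "mk_transition_matrix",
    "mk_loglik",
    "fit_mk_rate",
    "mk_marginal_posteriors",
    "simmap",
]


@dataclass
class DiscreteCharacter:
    """A single discrete character: one state per tip, ordered state list."""

    tip_states: dict[str, str]
    states: list[str]

    @classmethod
    def from_assignments(cls, assignments: pd.Series | dict) -> "DiscreteCharacter":
        tip_states = dict(assignments)
        states = sorted(set(tip_states.values()))
        return cls(tip_states=tip_states, states=states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, state: str) -> int:
        return self.states.index(state)


@dataclass
class AncestralSummary:
    """Node posteriors and sampled histories from stochastic mapping.

    ``node_posteriors``: internal node id -> probability vector (DataFrame,
    columns = states).  ``maps``: per sampled map, a dict edge (child node
    id) -> list of (state, duration) segments running parent -> child.
    ``change_counts``: number of state changes in each map.
    """

    states: list[str]
    node_posteriors: pd.DataFrame
    maps: list[dict[int, list[tuple[str, float]]]]
    rate: float
    change_counts: np.ndarray = field(default_factory=lambda: np.array([]))


def mk_transition_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """Closed-form ER transition matrix for elapsed time ``t``."""
    q = rate / (k - 1)
    e = np.exp(-k * q * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, (1.0 + (k - 1) * e) / k)
    return p


def _indexed_tree(tree: dendropy.Tree):
    """Assign stable integer ids (postorder) and collect node structure."""
    nodes = list(tree.postorder_node_iter())
    for i, nd in enumerate(nodes):
        nd._mk_id = i
    return nodes


def _tip_likelihoods(nodes, char: DiscreteCharacter) -> dict[int, np.ndarray]:
    k = char.n_states
    out = {}
    for nd in nodes:
        if nd.is_leaf():
            v = np.zeros(k)
            label = nd.taxon.label
            if label not in char.tip_states:
                raise ValueError(f"tip {label!r} has no state")
            v[char.index_of(char.tip_states[label])] = 1.0
            out[nd._mk_id] = v
    return out


def _downpass(tree, char, rate):
    """Conditional likelihoods L[v][s] = P(data below v | state(v)=s), with
    per-node log scaling factors to avoid underflow."""
    nodes = _indexed_tree(tree)
    k = char.n_states
    tipL = _tip_likelihoods(nodes, char)
    L: dict[int, np.ndarray] = {}
    logscale = 0.0
    for nd in nodes:
        if nd.is_leaf():
            L[nd._mk_id] = tipL[nd._mk_id]
            continue
        v = np.ones(k)
        for ch in nd.child_nodes():
            t = ch.edge.length
            if t is None:
                raise ValueError("all branch lengths must be present")
            p = mk_transition_matrix(k, rate, t)
            v = v * (p @ L[ch._mk_id])
        s = v.sum()
        if s <= 0:
            raise ValueError("zero likelihood; inconsistent tip states")
        L[nd._mk_id] = v / s
        logscale += np.log(s)
    return nodes, L, logscale


def mk_loglik(tree: dendropy.Tree, char: DiscreteCharacter, rate: float) -> float:
    """Log-likelihood of the tip states by Felsenstein pruning.

    Equal-rates Mk with a uniform root prior over the character's states.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    nodes, L, logscale = _downpass(tree, char, rate)
    root = nodes[-1]
    k = char.n_states
    return float(logscale + np.log(np.sum(L[root._mk_id] / k)))


def fit_mk_rate(tree: dendropy.Tree, char: DiscreteCharacter,
                bounds: tuple[float, float] = (1e-6, 1e3)) -> float:
    """Maximum-likelihood ER rate by bounded 1-D search on the log scale."""
    if len(set(char.tip_states.values())) < 2:
        warnings.warn("all tips share one state; rate pinned to lower bound")
        return bounds[0]
    res = minimize_scalar(
        lambda lr: -mk_loglik(tree, char, np.exp(lr)),
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def mk_marginal_posteriors(tree: dendropy.Tree, char: DiscreteCharacter,
                           rate: float) -> pd.DataFrame:
    """Exact marginal ancestral-state posteriors at every internal node.

    Standard up-down algorithm: combine each node's downpass conditional
    likelihood with the likelihood of the rest of the tree.
    """
    nodes, L, _ = _downpass(tree, char, rate)
    k = char.n_states
    root = nodes[-1]
    out: dict[int, np.ndarray] = {root._mk_id: np.full(k, 1.0 / k)}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        par = nd.parent_node
        # parent's partial excluding this child's subtree
        excl = out[par._mk_id].copy()
        for sib in par.child_nodes():
            if sib is nd:
                continue
            p = mk_transition_matrix(k, rate, sib.edge.length)
            excl = excl * (p @ L[sib._mk_id])
        p = mk_transition_matrix(k, rate, nd.edge.length)
        o = p.T @ excl
        out[nd._mk_id] = o / o.sum()
    rows = {}
    for nd in nodes:
        if not nd.is_leaf():
            post = out[nd._mk_id] * L[nd._mk_id]
            rows[nd._mk_id] = post / post.sum()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=char.states)
    df.index.name = "node_id"
    return df.sort_index()


def _sample_node_states(tree, char, rate, L, rng) -> dict[int, int]:
    """Joint sample of all node states from their conditional distribution."""
    k = char.n_states
    root = tree.seed_node
    states: dict[int, int] = {}
    pr = L[root._mk_id] / k
    pr = pr / pr.sum()
    states[root._mk_id] = int(rng.choice(k, p=pr))
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        p = mk_transition_matrix(k, rate, nd.edge.length)
        par_state = states[nd.parent_node._mk_id]
        w = p[par_state] * L[nd._mk_id]
        w = w / w.sum()
        states[nd._mk_id] = int(rng.choice(k, p=w))
    return states


def _simulate_bridge_rejection(k, rate, t, a, b, rng, max_tries=1000):
    """Forward-simulate the ER chain from ``a`` over ``t``; accept if it ends
    in ``b``.  Returns the jump times and states, or None after max_tries."""
    for _ in range(max_tries):
        times, jumps = [], []
        state, clock = a, 0.0
        while True:
            clock += rng.exponential(1.0 / rate)
            if clock >= t:
                break
            others = [s for s in range(k) if s != state]
            state = int(others[rng.integers(k - 1)])
            times.append(clock)
            jumps.append(state)
        if state == b:
            return times, jumps
    return None


def _simulate_bridge_uniformization(k, rate, t, a, b, rng, tol=1e-12):
    """Sample a CTMC bridge by uniformization with rate ``rate`` (the ER
    departure rate), for which the virtual chain has no self-jumps."""
    q = rate / (k - 1)
    p_ab = mk_transition_matrix(k, rate, t)[a, b]
    # R = I + Q/rate has zero diagonal and 1/(k-1) off-diagonal
    r = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(r, 0.0)
    # sample the number of jumps N | endpoints
    probs, rn = [], np.eye(k)
    log_pois = -rate * t
    n, cum = 0, 0.0
    terms = []
    while cum < 1.0 - tol and n < 10000:
        pois = np.exp(log_pois)
        term = pois * rn[a, b] / p_ab
        terms.append(term)
        cum += term
        n += 1
        rn = rn @ r
        log_pois += np.log(rate * t) - np.log(n)
    terms = np.array(terms)
    terms = np.clip(terms, 0, None)
    terms /= terms.sum()
    n_jumps = int(rng.choice(len(terms), p=terms))
    # sample the jump chain states backward-conditioned on the endpoint
    rpow = [np.eye(k)]
    for _ in range(n_jumps):
        rpow.append(rpow[-1] @ r)
    chain = [a]
    for m in range(1, n_jumps):
        prev = chain[-1]
        w = r[prev] * rpow[n_jumps - m][:, b]
        w = w / w.sum()
        chain.append(int(rng.choice(k, p=w)))
    if n_jumps >= 1:
        chain.append(b)
    times = np.sort(rng.uniform(0.0, t, size=n_jumps)).tolist()
    return times, chain[1:]


def _edge_segments(k, rate, t, a, b, rng, max_tries=1000):
    res = _simulate_bridge_rejection(k, rate, t, a, b, rng, max_tries)
    if res is None:
        res = _simulate_bridge_uniformization(k, rate, t, a, b, rng)
    times, jumps = res
    segs = []
    prev_t, prev_s = 0.0, a
    for tm, st in zip(times, jumps):
        segs.append((prev_s, tm - prev_t))
        prev_t, prev_s = tm, st
    segs.append((prev_s, t - prev_t))
    return segs


def simmap(
    tree: dendropy.Tree,
    char: DiscreteCharacter,
    rate: float | None = None,
    n_maps: int = 100,
    seed: int = 0,
) -> AncestralSummary:
    """Stochastic character maps of evoregion history on the phylogeny.

    For each map, internal-node states are drawn from their joint posterior
    (root from its marginal, then each child given its parent), and every
    branch is filled with a state history conditioned on its endpoint states.
    Node posteriors are the per-node state frequencies across maps.

    ``rate=None`` fits the ER rate by maximum likelihood first.
    """
    if rate is None:
        rate = fit_mk_rate(tree, char)
    rng = np.random.default_rng(seed)
    nodes, L, _ = _downpass(tree, char, rate)
    k = char.n_states
    internal_ids = [nd._mk_id for nd in nodes if not nd.is_leaf()]
    freq = {i: np.zeros(k) for i in internal_ids}
    maps, change_counts = [], []
    for _ in range(n_maps):
        states = _sample_node_states(tree, char, rate, L, rng)
        history: dict[int, list[tuple[str, float]]] = {}
        n_changes = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            a = states[nd.parent_node._mk_id]
            b = states[nd._mk_id]
            segs = _edge_segments(k, rate, nd.edge.length, a, b, rng)
            history[nd._mk_id] = [(char.states[s], dt) for s, dt in segs]
            n_changes += len(segs) - 1
        for i in internal_ids:
            freq[i][states[i]] += 1
        maps.append(history)
        change_counts.append(n_changes)
    post = pd.DataFrame.from_dict(
        {i: freq[i] / n_maps for i in internal_ids},
        orient="index", columns=char.states,
    )
    post.index.name = "node_id"
    return AncestralSummary(
        states=char.states,
        node_posteriors=post.sort_index(),
        maps=maps,
        rate=float(rate),
        change_counts=np.array(change_counts),
    )
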