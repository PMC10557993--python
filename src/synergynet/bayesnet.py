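"""Binary Bayesian networks with explicit conditional probability tables.

A network is a directed acyclic graph over binary ("on"/"off") nodes.  Each
node carries a CPT giving the probability of being *on* for every
configuration of its parents; a root node's CPT is a single prior row.  Two
inference paths are provided: exact enumeration of the joint distribution
(small networks) and ancestral sampling.  Sampling records, per node, the
single uniform exogenous-noise draw that decided its state, so every sampled
realization supports exact counterfactual replay (see
:mod:`synergynet.interventions`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ResourceError, StructureError

__all__ = [
    "Cpt",
    "BayesNet",
    "JointTable",
    "Realization",
    "validate_network",
    "topological_order",
    "joint_distribution",
    "marginals",
    "sample",
    "sample_dataframe",
    "replay_states",
    "MAX_EXACT_NODES",
]

#: Largest node count for which exact enumeration is attempted (2^20 states).
MAX_EXACT_NODES = 20


@dataclass(frozen=True)
class Cpt:
    """Conditional probability table for one binary node.

    Parameters
    ----------
    parents:
        Ordered parent labels.  May be empty (root node).
    rows:
        Mapping from each parent-state combination -- a tuple of 0/1 in
        parent order -- to the probability that the node is on.  A root has
        the single key ``()``.
    """

    parents: tuple[str, ...]
    rows: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(
            self, "rows", {tuple(int(b) for b in k): float(v) for k, v in self.rows.items()}
        )

    @classmethod
    def root(cls, prior: float) -> "Cpt":
        """CPT of a parentless node with ``P(on) = prior``."""
        return cls(parents=(), rows={(): float(prior)})

    @classmethod
    def from_sequence(cls, parents: tuple[str, ...] | list[str], probs) -> "Cpt":
        """Build from probabilities listed in binary-counting order of parents."""
        parents = tuple(parents)
        combos = list(itertools.product((0, 1), repeat=len(parents)))
        probs = list(probs)
        if len(probs) != len(combos):
            raise ValueError(f"expected {len(combos)} probabilities, got {len(probs)}")
        return cls(parents=parents, rows=dict(zip(combos, probs)))

    def prob(self, parent_states: tuple[int, ...]) -> float:
        return self.rows[tuple(int(b) for b in parent_states)]

    def table(self) -> np.ndarray:
        """Probabilities as an array of shape ``(2,) * len(parents)``."""
        t = np.empty((2,) * len(self.parents), dtype=float)
        for combo, p in self.rows.items():
            t[combo] = p
        return t


@dataclass(frozen=True)
class BayesNet:
    """A binary Bayesian network: node labels plus one CPT per node."""

    nodes: tuple[str, ...]
    cpts: dict[str, Cpt]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))

    def parents(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].parents

    def graph(self) -> nx.DiGraph:
        """The parent→child graph as a :class:`networkx.DiGraph`."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, cpt in self.cpts.items():
            g.add_edges_from((p, child) for p in cpt.parents)
        return g

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self.graph(), node)

    def is_root(self, node: str) -> bool:
        return len(self.cpts[node].parents) == 0

    def with_cpt(self, node: str, cpt: Cpt) -> "BayesNet":
        """Copy of the network with one node's CPT replaced."""
        new = dict(self.cpts)
        new[node] = cpt
        return BayesNet(nodes=self.nodes, cpts=new)


@dataclass(frozen=True)
class JointTable:
    """Exact joint distribution over all network states.

    ``probs`` has shape ``(2,) * K`` with axis *i* indexing the state of
    ``variables[i]``.
    """

    variables: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2,) * len(self.variables):
            raise ValueError("probability array shape does not match variable count")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_mapping(cls, variables, mapping) -> "JointTable":
        variables = tuple(variables)
        probs = np.zeros((2,) * len(variables))
        for state, p in mapping.items():
            probs[tuple(int(b) for b in state)] = p
        return cls(variables=variables, probs=probs)

    def prob(self, state) -> float:
        """Probability of one full state (tuple in variable order)."""
        return float(self.probs[tuple(int(b) for b in state)])

    def total(self) -> float:
        return float(self.probs.sum())

    def marginalize(self, keep) -> "JointTable":
        """Marginal joint table over ``keep`` (original relative order kept)."""
        keep = list(keep)
        missing = [v for v in keep if v not in self.variables]
        if missing:
            raise ValueError(f"unknown variable label(s): {missing}")
        kept = [v for v in self.variables if v in keep]
        drop_axes = tuple(i for i, v in enumerate(self.variables) if v not in keep)
        return JointTable(variables=tuple(kept), probs=self.probs.sum(axis=drop_axes))

    def as_mapping(self) -> dict[tuple[int, ...], float]:
        return {
            combo: float(self.probs[combo])
            for combo in itertools.product((0, 1), repeat=len(self.variables))
        }


@dataclass(frozen=True)
class Realization:
    """One sampled state of the network plus its exogenous noise record.

    The reconstruction rule ties the two together: a node is on exactly when
    its noise draw is strictly below the CPT probability of its parents'
    realized states.  Keeping the noises makes individual-level (hard)
    interventions well-defined counterfactuals.
    """

    states: dict[str, int]
    noises: dict[str, float]


def validate_network(net: BayesNet) -> list[str]:
    """Return human-readable violations; an empty list means the net is valid.

    Checks label uniqueness, CPT completeness (one row per parent-state
    combination, binary domains only), probability ranges, and acyclicity.
    Violations are returned rather than raised so callers can report all
    problems at once.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for node in net.nodes:
        if not node:
            violations.append("empty node label")
        if node in seen:
            violations.append(f"duplicate node label {node!r}")
        seen.add(node)
    for node in net.nodes:
        cpt = net.cpts.get(node)
        if cpt is None:
            violations.append(f"node {node!r} has no CPT")
            continue
        for p in cpt.parents:
            if p not in seen:
                violations.append(f"node {node!r} lists unknown parent {p!r}")
        expected = set(itertools.product((0, 1), repeat=len(cpt.parents)))
        got = set(cpt.rows)
        for combo in sorted(expected - got):
            violations.append(f"node {node!r} missing CPT row for parent states {combo}")
        for combo in sorted(got - expected):
            violations.append(
                f"node {node!r} has CPT row {combo} not matching its {len(cpt.parents)} parent(s)"
            )
        for combo, p in sorted(cpt.rows.items()):
            if not (0.0 <= p <= 1.0):
                violations.append(
                    f"node {node!r} CPT probability {p} for parent states {combo} outside [0, 1]"
                )
    extra = set(net.cpts) - seen
    for node in sorted(extra):
        violations.append(f"CPT given for unknown node {node!r}")
    g = net.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle_nodes = sorted({u for u, _ in nx.find_cycle(g)})
        violations.append(f"cycle detected involving nodes {cycle_nodes}")
    return violations


def _require_valid(net: BayesNet) -> None:
    violations = validate_network(net)
    if violations:
        raise StructureError("invalid network: " + "; ".join(violations))


def topological_order(net: BayesNet) -> tuple[str, ...]:
    """Parents-before-children order, ties broken lexicographically by label."""
    g = net.graph()
    try:
        return tuple(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle_nodes = sorted({u for u, _ in nx.find_cycle(g)})
        raise StructureError(f"cycle detected involving nodes {cycle_nodes}") from None


def joint_distribution(net: BayesNet) -> JointTable:
    """Exact joint distribution by full enumeration.

    The probability of a full state is the product over nodes of the CPT
    probability of that node's state given its parents' states.  Refuses
    networks above :data:`MAX_EXACT_NODES` nodes; sample instead.
    """
    _require_valid(net)
    order = topological_order(net)
    k = len(order)
    if k > MAX_EXACT_NODES:
        raise ResourceError(
            f"exact enumeration over {k} nodes needs 2^{k} states; "
            f"limit is {MAX_EXACT_NODES} -- use sampling instead"
        )
    index = {v: i for i, v in enumerate(order)}
    probs = np.ones((2,) * k)
    for node in order:
        cpt = net.cpts[node]
        i = index[node]
        pidx = [index[p] for p in cpt.parents]
        t = cpt.table()
        # Broadcast P(node=1 | parents) over the full state space: put the
        # CPT axes at the parent positions (ascending), size-1 elsewhere.
        axis_order = np.argsort(pidx) if pidx else []
        t = np.transpose(t, axis_order) if pidx else t
        shape = [1] * k
        for j in sorted(pidx):
            shape[j] = 2
        p_on = t.reshape(shape)
        state_i = np.arange(2).reshape([2 if j == i else 1 for j in range(k)])
        probs = probs * np.where(state_i == 1, p_on, 1.0 - p_on)
    return JointTable(variables=order, probs=probs)


def marginals(joint: JointTable) -> dict[str, float]:
    """Per-variable probability of being on (the population prevalence)."""
    out: dict[str, float] = {}
    for i, v in enumerate(joint.variables):
        axes = tuple(j for j in range(len(joint.variables)) if j != i)
        out[v] = float(joint.probs.sum(axis=axes)[1])
    return out


def _sample_arrays(
    net: BayesNet, n: int, seed: int
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Vectorized ancestral sampling.

    Returns ``(order, states, noises)`` with arrays of shape ``(n, K)``;
    columns follow the topological order.  One uniform noise per node per
    realization; a node is on iff its noise is strictly below its CPT
    probability given the already-sampled parent states.
    """
    _require_valid(net)
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError(f"n must be an integer, got {type(n).__name__}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise ValueError(f"seed must be an integer, got {type(seed).__name__}")
    order = topological_order(net)
    index = {v: i for i, v in enumerate(order)}
    rng = np.random.default_rng(seed)
    states = np.zeros((n, len(order)), dtype=np.int8)
    noises = np.empty((n, len(order)), dtype=float)
    for node in order:
        i = index[node]
        cpt = net.cpts[node]
        u = rng.random(n)
        noises[:, i] = u
        t = cpt.table()
        if cpt.parents:
            cols = tuple(states[:, index[p]] for p in cpt.parents)
            p_on = t[cols]
        else:
            p_on = np.full(n, float(t))
        states[:, i] = u < p_on
    return order, states, noises


def sample(net: BayesNet, n: int, seed: int) -> list[Realization]:
    """Draw ``n`` realizations (with recorded exogenous noises).

    Deterministic: identical ``(net, n, seed)`` yields identical output.
    """
    order, states, noises = _sample_arrays(net, n, seed)
    return [
        Realization(
            states={v: int(states[r, i]) for i, v in enumerate(order)},
            noises={v: float(noises[r, i]) for i, v in enumerate(order)},
        )
        for r in range(n)
    ]


def sample_dataframe(net: BayesNet, n: int, seed: int):
    """Sampled states as a pandas DataFrame (columns in topological order).

    The efficient bulk path used by the synthetic-data generators; noise
    records are dropped.
    """
    import pandas as pd

    order, states, _ = _sample_arrays(net, n, seed)
    return pd.DataFrame(states, columns=list(order))


def replay_states(
    net: BayesNet, noises: dict[str, float], clamps: dict[str, int] | None = None
) -> dict[str, int]:
    """Recompute all states from recorded noises via the reconstruction rule.

    ``clamps`` forces the given nodes to fixed states regardless of their
    noise (the do-operator's mechanics); descendants then update
    deterministically because their noises are reused.
    """
    clamps = clamps or {}
    order = topological_order(net)
    states: dict[str, int] = {}
    for node in order:
        if node in clamps:
            states[node] = int(clamps[node])
            continue
        cpt = net.cpts[node]
        p_on = cpt.prob(tuple(states[p] for p in cpt.parents))
        states[node] = int(noises[node] < p_on)
    return states
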