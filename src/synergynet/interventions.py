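"""Population-level (soft) and individual-level (hard) interventions.

A *nudge* shifts probability mass in a root node's prior while leaving every
conditional mechanism untouched -- the model of a population-wide public
health measure.  Its effect is reported per node as the change in log-odds
of the exact post- versus pre-intervention marginals.  Nudges are restricted
to root nodes: a non-root's marginal is determined by its parents and CPT,
so "changing it while keeping all conditionals fixed" is not a free
operation.

A *do* intervention clamps nodes of one sampled realization to fixed states
and replays the recorded exogenous noises through the network, yielding the
counterfactual for that individual.  Because the noises are reused, the
update is deterministic and idempotent even for stochastic CPTs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .bayesnet import (
    BayesNet,
    Cpt,
    Realization,
    joint_distribution,
    marginals,
    replay_states,
)
from .errors import InterventionError

__all__ = [
    "NudgeSpec",
    "DoSpec",
    "NodeEffect",
    "EffectReport",
    "nudge",
    "population_effect",
    "do_intervention",
]


@dataclass(frozen=True)
class NudgeSpec:
    """Move ``delta`` probability mass toward state 1 of root node ``node``."""

    node: str
    delta: float


@dataclass(frozen=True)
class DoSpec:
    """Clamp each node in ``clamps`` to the given 0/1 state."""

    clamps: dict[str, int]

    def __post_init__(self) -> None:
        if not self.clamps:
            raise ValueError("DoSpec needs at least one clamped node")
        for node, state in self.clamps.items():
            if state not in (0, 1):
                raise ValueError(f"clamp state for {node!r} must be 0 or 1, got {state}")


@dataclass(frozen=True)
class NodeEffect:
    """Before/after marginals of one node and their log-odds change (natural log)."""

    node: str
    baseline: float
    post: float
    delta_log_odds: float
    infinite: bool  # a marginal hit exactly 0 or 1, so the change is +/-inf


@dataclass(frozen=True)
class EffectReport:
    """Per-node intervention effects, in network node order."""

    effects: tuple[NodeEffect, ...]

    def __getitem__(self, node: str) -> NodeEffect:
        for e in self.effects:
            if e.node == node:
                return e
        raise KeyError(node)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node": e.node,
                    "baseline": e.baseline,
                    "post": e.post,
                    "delta_log_odds": e.delta_log_odds,
                }
                for e in self.effects
            ]
        ).set_index("node")


def _validate_nudge(net: BayesNet, spec: NudgeSpec) -> float:
    if spec.node not in net.nodes:
        raise ValueError(f"unknown node {spec.node!r}")
    if not net.is_root(spec.node):
        raise InterventionError(
            f"cannot nudge non-root node {spec.node!r}: its marginal is fixed by "
            "its parents and CPT, so only root priors are free parameters of a "
            "soft intervention"
        )
    prior = net.cpts[spec.node].prob(())
    post = prior + spec.delta
    if not (0.0 <= post <= 1.0):
        raise InterventionError(
            f"nudge of {spec.delta:+g} moves prior {prior:g} of {spec.node!r} "
            f"to {post:g}, outside [0, 1]"
        )
    return post


def nudge(net: BayesNet, spec: NudgeSpec) -> BayesNet:
    """The network with the root prior shifted by ``delta``; all CPTs untouched."""
    post = _validate_nudge(net, spec)
    return net.with_cpt(spec.node, Cpt.root(post))


def _log_odds(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1.0 - p))


def population_effect(net: BayesNet, spec: NudgeSpec) -> EffectReport:
    """Exact per-node marginal change of a nudge, as log-odds deltas.

    Marginals are computed by exact enumeration before and after the nudge.
    Non-descendants of the nudged node are unaffected (to numerical
    precision): a soft intervention only propagates causally downstream.
    """
    nudged = nudge(net, spec)
    before = marginals(joint_distribution(net))
    after = marginals(joint_distribution(nudged))
    effects = []
    for node in net.nodes:
        b, a = before[node], after[node]
        lb, la = _log_odds(b), _log_odds(a)
        infinite = math.isinf(lb) or math.isinf(la)
        if infinite:
            delta = 0.0 if la == lb else (math.inf if la > lb else -math.inf)
        else:
            delta = la - lb
        effects.append(
            NodeEffect(node=node, baseline=b, post=a, delta_log_odds=delta, infinite=infinite)
        )
    return EffectReport(effects=tuple(effects))


def do_intervention(net: BayesNet, realization: Realization, spec: DoSpec) -> Realization:
    """Counterfactual of one realization under hard clamps.

    Clamped nodes take their forced states regardless of noise; every other
    node is recomputed in topological order from the *original* recorded
    noises.  Non-descendants of the clamped set are therefore bit-identical
    to the input, and repeating the same clamps is idempotent.
    """
    unknown = sorted(set(spec.clamps) - set(net.nodes))
    if unknown:
        raise ValueError(f"clamp on unknown node(s): {unknown}")
    states = replay_states(net, realization.noises, clamps=spec.clamps)
    return Realization(states=states, noises=dict(realization.noises))
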