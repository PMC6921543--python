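"""Core-network reduction of Boolean networks.

A large regulatory network usually carries many nodes that do not shape its
long-run behavior: *output* nodes (childless — they read the state but feed
nothing back), clamped *input* nodes, and *transduction* nodes that merely
relay a single signal forward.  Removing them leaves the feedback-bearing
core whose states determine everything else.

Three reductions are provided:

``strip_outputs``
    iteratively deletes childless nodes.  This is dynamics-exact: the
    projection of the full trajectory onto the survivors equals the reduced
    network's trajectory, and the removed nodes are reconstructable
    step-for-step from it.

``remove_inputs``
    substitutes a constant clamp value into every child of a parentless
    node and simplifies.

``collapse_chains``
    removes every node with exactly one parent and one child (parent ≠
    child), composing its relay function — with negation parity — into the
    child.  Collapsing shortens the relay path by one synchronous step, so
    the collapsed core's transient timing is *advanced* by the recorded
    delay relative to the full network; fixed points are unaffected.  Nodes
    on 2-cycles are never collapsed, which preserves feedback loops such as
    the published MCP-5/SCF mutual-inhibition pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .network import BooleanNetwork, BoolRule

__all__ = [
    "RemovedNode",
    "CoreNetwork",
    "strip_outputs",
    "remove_inputs",
    "collapse_chains",
    "reduce_network",
    "reconstruct",
]


@dataclass(frozen=True)
class RemovedNode:
    """Bookkeeping for one removed node.

    ``rule`` is the update the node obeyed at removal time (parents are
    surviving or later-removed nodes); ``clamp`` is set for removed inputs
    instead.  ``delay`` is the number of original synchronous steps the
    stored rule spans: ``node(k) = rule(parents(k - delay))``.  Plain
    outputs span 1 step; a collapsed relay accumulates the spans of relays
    already composed into its rule; clamped inputs are constant (0).
    """

    name: str
    kind: str  # "output" | "input" | "collapsed"
    rule: BoolRule | None = None
    clamp: int | None = None
    delay: int = 0


@dataclass
class CoreNetwork:
    """A reduced network plus everything needed to restore removed nodes."""

    network: BooleanNetwork
    removed: list[RemovedNode] = field(default_factory=list)

    @property
    def removed_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.removed)

    def reconstruction_order(self) -> list[RemovedNode]:
        """Removed nodes ordered so each depends only on core nodes or
        nodes earlier in the order.  Raises on a cyclic dependency (which a
        correct reduction cannot produce)."""
        core_set = set(self.network.nodes)
        recs = {r.name: r for r in self.removed}
        g = nx.DiGraph()
        g.add_nodes_from(recs)
        for r in self.removed:
            if r.rule is None:
                continue
            for p in r.rule.parents:
                if p in recs:
                    g.add_edge(p, r.name)
                elif p not in core_set:
                    raise ValueError(
                        f"removed node {r.name!r} depends on unknown node {p!r}"
                    )
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:  # pragma: no cover - defensive
            raise ValueError("cyclic dependency among removed nodes") from exc
        return [recs[n] for n in order]


def strip_outputs(net: BooleanNetwork) -> CoreNetwork:
    """Iteratively delete childless nodes until none remain childless."""
    current = net
    removed: list[RemovedNode] = []
    while True:
        g = current.to_digraph()
        childless = [nd for nd in current.nodes if g.out_degree(nd) == 0]
        if not childless:
            break
        for nd in childless:
            removed.append(
                RemovedNode(nd, "output", rule=current.rules[nd], delay=1)
            )
        keep = [nd for nd in current.nodes if nd not in set(childless)]
        current = current.subnetwork(keep)
    return CoreNetwork(network=current, removed=removed)


def remove_inputs(
    net: BooleanNetwork, clamps: Mapping[str, int]
) -> CoreNetwork:
    """Clamp parentless nodes to constants and simplify their children."""
    for nd, val in clamps.items():
        if nd not in net.nodes:
            raise ValueError(f"unknown node {nd!r}")
        if nd not in net.structural_inputs():
            raise ValueError(f"cannot clamp {nd!r}: it has parents")
        if val not in (0, 1):
            raise ValueError("clamp values must be 0/1")
    keep = [nd for nd in net.nodes if nd not in clamps]
    rules = {}
    for nd in keep:
        rule = net.rules[nd].restrict(clamps)
        rules[nd] = rule
    reduced = BooleanNetwork(
        rules, nodes=keep, inputs=set(net.inputs) - set(clamps)
    )
    removed = [
        RemovedNode(nd, "input", clamp=int(v)) for nd, v in clamps.items()
    ]
    return CoreNetwork(network=reduced, removed=removed)


def _compose(child_rule: BoolRule, via: str, relay: BoolRule) -> BoolRule:
    """Substitute ``via = relay(relay.parents)`` into ``child_rule``."""
    new_parents = [p for p in child_rule.parents if p != via]
    for p in relay.parents:
        if p not in new_parents:
            new_parents.append(p)
    m = len(new_parents)
    pos = {p: i for i, p in enumerate(new_parents)}
    table = []
    for row in range(2**m):
        bits = {p: (row >> (m - 1 - pos[p])) & 1 for p in new_parents}
        via_val = relay([bits[p] for p in relay.parents])
        table.append(
            child_rule(
                [via_val if p == via else bits[p] for p in child_rule.parents]
            )
        )
    return BoolRule(tuple(new_parents), tuple(table))


def collapse_chains(net: BooleanNetwork) -> CoreNetwork:
    """Remove in-degree-1 / out-degree-1 relay nodes, composing negation
    parity into the child and recording the one-step delay each collapse
    introduces."""
    current = net
    removed: list[RemovedNode] = []
    # extra original-steps already embedded in a node's composed rule
    embed: dict[str, int] = {}
    while True:
        g = current.to_digraph()
        target = None
        for nd in current.nodes:
            if nd in current.inputs:
                continue
            parents = current.rules[nd].parents
            children = [c for c in current.nodes if nd in current.rules[c].parents]
            if len(parents) != 1 or len(children) != 1:
                continue
            (q,), (c,) = parents, children
            if q == c or nd in (q, c):
                continue  # protect 2-cycles and self-loops
            target = (nd, q, c)
            break
        if target is None:
            break
        nd, q, c = target
        relay = current.rules[nd]
        span = 1 + embed.get(nd, 0)
        removed.append(
            RemovedNode(nd, "collapsed", rule=relay, delay=span)
        )
        embed[c] = embed.get(c, 0) + span
        rules = {}
        for other in current.nodes:
            if other == nd:
                continue
            rule = current.rules[other]
            rules[other] = _compose(rule, nd, relay) if nd in rule.parents else rule
        keep = [x for x in current.nodes if x != nd]
        current = BooleanNetwork(rules, nodes=keep, inputs=current.inputs)
    return CoreNetwork(network=current, removed=removed)


def reduce_network(
    net: BooleanNetwork,
    clamps: Mapping[str, int] | None = None,
    collapse: bool = True,
) -> CoreNetwork:
    """Full reduction: clamp inputs, strip outputs, optionally collapse
    transduction chains.  Removal records from all stages are concatenated
    (later stages first in reconstruction order handling)."""
    removed: list[RemovedNode] = []
    current = net
    if clamps:
        stage = remove_inputs(current, clamps)
        removed += stage.removed
        current = stage.network
    stage = strip_outputs(current)
    removed += stage.removed
    current = stage.network
    if collapse:
        stage = collapse_chains(current)
        removed += stage.removed
        current = stage.network
    return CoreNetwork(network=current, removed=removed)


def reconstruct(
    core_trajectory: Sequence[Mapping[str, int] | Sequence[int]],
    core: CoreNetwork,
    initial_full_state: Mapping[str, int],
) -> list[dict[str, int]]:
    """Rebuild the full-network trajectory from a core trajectory.

    Each removed node's recorded one-step rule is evaluated along the
    trajectory in dependency order: ``x(k+1) = rule(predecessors at k)``,
    with ``x(0)`` taken from ``initial_full_state`` and clamped inputs held
    constant.  When the core stage is dynamics-exact (outputs stripped,
    inputs clamped, no chain collapse) the result equals simulating the full
    network.
    """
    order = core.reconstruction_order()
    nodes = core.network.nodes
    states: list[dict[str, int]] = []
    for st in core_trajectory:
        if isinstance(st, Mapping):
            states.append({n: int(st[n]) for n in nodes})
        else:
            if len(st) != len(nodes):
                raise ValueError("core state length mismatch")
            states.append({n: int(b) for n, b in zip(nodes, st)})
    for rec in order:
        if rec.kind == "input":
            for st in states:
                st[rec.name] = rec.clamp
            continue
        rule = rec.rule
        d = max(rec.delay, 1)
        init = int(initial_full_state[rec.name])
        for k in range(len(states)):
            if k < d:
                # before the rule's span is available, hold the start value
                states[k][rec.name] = init
            else:
                states[k][rec.name] = rule(
                    [states[k - d][p] for p in rule.parents]
                )
    return states
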