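"""Semi-tensor-product (STP) state dynamics of Boolean networks.

A joint state of an ``n``-node network is a vertex of the Boolean n-cube, or
equivalently a canonical unit vector ("delta state") of dimension ``2**n``.
With every node's rule folded into one logical matrix ``M`` (each column a
unit vector), the synchronous dynamics become the linear-looking recursion

    X(k+1) = M ⋉ X(k)

where ``⋉`` is the semi-tensor product.  The delta index convention used
throughout (and verified against the published macrophage state tables) is

    index = 1 + integer value of the complemented bit string,

with the first node in the order the most significant bit; equivalently
``index = 2**n - value(bits)``.  All-ones is index 1, all-zeros is ``2**n``.

The transition structure is held as a successor array (total function on
``1..2**n``); the dense logical matrix is materialized on demand.  The
algebraic STP construction (per-node structure matrices lifted with
Kronecker projectors and combined with a Khatri-Rao / power-reducing step)
is provided alongside the direct column-by-column evaluation so the two can
be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import BooleanNetwork

__all__ = [
    "DeltaState",
    "TransitionSystem",
    "state_to_index",
    "index_to_state",
    "stp",
    "step",
    "transition_matrix",
    "stp_transition_matrix",
    "find_attractors",
    "trajectory",
    "export_evolution_map",
]

#: hard size cap: state space 2**MAX_NODES
MAX_NODES = 11


@dataclass(frozen=True)
class DeltaState:
    """A joint Boolean state identified by its delta index."""

    n: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 2**self.n:
            raise ValueError(f"index {self.index} outside [1, {2**self.n}]")

    @property
    def bits(self) -> tuple[int, ...]:
        return index_to_state(self.index, self.n)


def state_to_index(bits: Sequence[int], n: int | None = None) -> int:
    """Delta index of a bit vector (first bit most significant)."""
    bits = tuple(int(b) for b in bits)
    if n is not None and len(bits) != n:
        raise ValueError(f"expected {n} bits, got {len(bits)}")
    if any(b not in (0, 1) for b in bits):
        raise ValueError("bits must be 0/1")
    value = 0
    for b in bits:
        value = (value << 1) | b
    return 2 ** len(bits) - value


def index_to_state(index: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`state_to_index`."""
    if not 1 <= index <= 2**n:
        raise ValueError(f"index {index} outside [1, {2**n}]")
    value = 2**n - index
    return tuple((value >> (n - 1 - i)) & 1 for i in range(n))


# ---------------------------------------------------------------------------
# semi-tensor product machinery
# ---------------------------------------------------------------------------

def stp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Semi-tensor product of two matrices.

    For ``a`` (m×n) and ``b`` (p×q), with ``t = lcm(n, p)``::

        a ⋉ b = (a ⊗ I_{t/n}) (b ⊗ I_{t/p})

    Reduces to the ordinary matrix product when ``n == p``.
    """
    a = np.atleast_2d(np.asarray(a))
    b = np.atleast_2d(np.asarray(b))
    n, p = a.shape[1], b.shape[0]
    t = np.lcm(n, p)
    return np.kron(a, np.eye(t // n, dtype=a.dtype)) @ np.kron(
        b, np.eye(t // p, dtype=b.dtype)
    )


def _projector(i: int, n: int) -> np.ndarray:
    """2 × 2**n logical matrix extracting variable ``i`` from the joint
    delta state: column s is the delta vector of node i's bit in state s.

    Built purely from Kronecker products: ``1_{2^i}ᵀ ⊗ I_2 ⊗ 1_{2^{n-1-i}}ᵀ``.
    """
    left = np.ones((1, 2**i))
    right = np.ones((1, 2 ** (n - 1 - i)))
    return np.kron(np.kron(left, np.eye(2)), right)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product — the power-reducing step that fuses
    the per-node next-state delta vectors into the joint delta vector."""
    out = mats[0]
    for m in mats[1:]:
        cols = [np.kron(out[:, j], m[:, j]) for j in range(out.shape[1])]
        out = np.stack(cols, axis=1)
    return out


def _local_structure_matrix(table: Sequence[int]) -> np.ndarray:
    """2 × 2**p structure matrix of a node rule.

    Column ordering follows the delta convention: column r corresponds to the
    parent pattern with delta index r+1 (all-ones first).
    """
    p2 = len(table)
    m = np.zeros((2, p2))
    for r in range(p2):
        # delta column r holds parent integer value p2-1-r
        out = table[p2 - 1 - r]
        m[0 if out == 1 else 1, r] = 1.0
    return m


def stp_transition_matrix(bn: BooleanNetwork) -> np.ndarray:
    """Joint transition matrix via the algebraic STP construction.

    Each node's local structure matrix is lifted to the full state space by
    composing it (ordinary STP of logical matrices) with the Khatri-Rao
    product of its parents' Kronecker projectors; the lifted per-node
    matrices are then fused with one more Khatri-Rao step.  No joint state is
    ever stepped explicitly.
    """
    n = bn.n
    if n > MAX_NODES:
        raise ValueError(f"network has {n} > {MAX_NODES} nodes")
    pos = {nd: i for i, nd in enumerate(bn.nodes)}
    lifted = []
    for nd in bn.nodes:
        rule = bn.rules[nd]
        if rule.parents:
            proj = _khatri_rao([_projector(pos[p], n) for p in rule.parents])
            lifted.append(stp(_local_structure_matrix(rule.table), proj))
        else:
            col = np.zeros((2, 1))
            col[0 if rule.table[0] == 1 else 1, 0] = 1.0
            lifted.append(col @ np.ones((1, 2**n)))
    return _khatri_rao(lifted)


# ---------------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------------

def step(bn: BooleanNetwork, state: DeltaState) -> DeltaState:
    """One synchronous update, in delta-state terms."""
    if state.n != bn.n:
        raise ValueError("state size does not match network")
    nxt = bn.step(index_to_state(state.index, bn.n))
    return DeltaState(bn.n, state_to_index(nxt))


@dataclass
class TransitionSystem:
    """Total successor map on the delta-state space plus its attractor
    decomposition (fixed points and cycles) and basin partition."""

    n: int
    successor: np.ndarray  # shape (2**n,), successor[i-1] = delta index
    attractors: list[tuple[int, ...]] = field(default_factory=list)
    basin: dict[int, int] = field(default_factory=dict)  # state -> attractor id

    @property
    def n_states(self) -> int:
        return 2**self.n

    def matrix(self) -> np.ndarray:
        """Dense logical transition matrix M (column j-1 = e_{succ(j)})."""
        m = np.zeros((self.n_states, self.n_states))
        for j in range(self.n_states):
            m[self.successor[j] - 1, j] = 1.0
        return m

    def fixed_points(self) -> list[int]:
        return [a[0] for a in self.attractors if len(a) == 1]

    def cycles(self) -> list[tuple[int, ...]]:
        return [a for a in self.attractors if len(a) > 1]


def transition_matrix(bn: BooleanNetwork) -> TransitionSystem:
    """Build the full transition structure by direct evaluation of every
    state, then decompose into attractors and basins."""
    n = bn.n
    if n > MAX_NODES:
        raise ValueError(f"network has {n} > {MAX_NODES} nodes")
    size = 2**n
    succ = np.empty(size, dtype=np.int64)
    for idx in range(1, size + 1):
        succ[idx - 1] = state_to_index(bn.step(index_to_state(idx, n)))
    ts = TransitionSystem(n=n, successor=succ)
    find_attractors(ts)
    return ts


def find_attractors(ts: TransitionSystem) -> list[tuple[int, ...]]:
    """Enumerate attractors (fixed points and cycles) and assign every state
    to its basin.  Iterative coloring, no recursion; O(2**n)."""
    size = ts.n_states
    succ = ts.successor
    attractor_of = np.full(size, -1, dtype=np.int64)  # -1 unknown
    attractors: list[tuple[int, ...]] = []
    for start in range(1, size + 1):
        if attractor_of[start - 1] >= 0:
            continue
        path: list[int] = []
        seen_at: dict[int, int] = {}
        s = start
        while attractor_of[s - 1] < 0 and s not in seen_at:
            seen_at[s] = len(path)
            path.append(s)
            s = int(succ[s - 1])
        if attractor_of[s - 1] >= 0:
            aid = int(attractor_of[s - 1])
        else:
            # new cycle: states from the first visit of s onward
            cyc = tuple(path[seen_at[s]:])
            # canonical rotation: start at smallest index
            k = cyc.index(min(cyc))
            cyc = cyc[k:] + cyc[:k]
            aid = len(attractors)
            attractors.append(cyc)
        for st in path:
            attractor_of[st - 1] = aid
    ts.attractors = attractors
    ts.basin = {s: int(attractor_of[s - 1]) for s in range(1, size + 1)}
    return attractors


def trajectory(
    bn: BooleanNetwork, initial: DeltaState, max_steps: int
) -> list[DeltaState]:
    """Iterate from ``initial`` until a state repeats or ``max_steps`` taken.

    The returned sequence includes the first repeated state, so a fixed
    point appears twice at the end.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    out = [initial]
    seen = {initial.index}
    for _ in range(max_steps):
        nxt = step(bn, out[-1])
        out.append(nxt)
        if nxt.index in seen:
            break
        seen.add(nxt.index)
    return out


def export_evolution_map(
    ts: TransitionSystem,
    highlight: Sequence[DeltaState] | Sequence[int] = (),
    fmt: str = "dot",
    labeler=None,
) -> str:
    """Render the full state-transition graph as DOT or GraphML text.

    One node per delta state, one edge per transition; ``highlight`` states
    (the experimentally observed path) are marked.  Node order is the delta
    index, so output is deterministic.
    """
    hi = {h.index if isinstance(h, DeltaState) else int(h) for h in highlight}
    if labeler is None:
        labeler = lambda i: f"e{i}"
    if fmt == "dot":
        lines = ["digraph evolution {", "  rankdir=LR;"]
        for i in range(1, ts.n_states + 1):
            attrs = f'label="{labeler(i)}"'
            if i in hi:
                attrs += ', style=filled, color=red, fillcolor="#ffcccc"'
            lines.append(f"  s{i} [{attrs}];")
        for i in range(1, ts.n_states + 1):
            lines.append(f"  s{i} -> s{int(ts.successor[i - 1])};")
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        import io

        import networkx as nx

        g = nx.DiGraph()
        for i in range(1, ts.n_states + 1):
            g.add_node(i, label=labeler(i), highlighted=i in hi)
        for i in range(1, ts.n_states + 1):
            g.add_edge(i, int(ts.successor[i - 1]))
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown format {fmt!r}")
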