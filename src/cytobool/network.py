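"""Boolean network containers.

A :class:`BooleanNetwork` is a synchronous Boolean dynamical system: every
node holds a bit and all nodes update simultaneously, each through its own
update rule evaluated on the *current* joint state.  Rules are stored as
explicit truth tables over an ordered parent list, which makes evaluation,
restriction (clamping) and composition exact set operations rather than
symbolic manipulation.

Rules can also be expressed as sum-of-products (SOP) term lists — the form
regulatory functions are usually written in (e.g. ``IL-10 & !MIP-1beta``) —
and the module converts losslessly between the two representations (SOP →
table here; minimal table → SOP lives in :mod:`cytobool.logic`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "BoolRule",
    "BooleanNetwork",
    "sop_to_table",
    "format_sop",
    "parse_expression",
    "parse_boolnet",
]

#: literal: (parent name, negated?)
Literal = tuple[str, bool]
#: product term: conjunction of literals
Term = tuple[Literal, ...]


def _row_index(bits: Sequence[int]) -> int:
    """Truth-table row index of a parent bit pattern, first parent = MSB."""
    idx = 0
    for b in bits:
        idx = (idx << 1) | (1 if b else 0)
    return idx


def sop_to_table(parents: Sequence[str], terms: Iterable[Term]) -> tuple[int, ...]:
    """Evaluate a sum-of-products over ``parents`` into a truth table.

    An empty term list is the constant-0 function; a term with no literals is
    the constant-1 product (so ``[()]`` is constant 1).
    """
    parents = list(parents)
    pos = {p: i for i, p in enumerate(parents)}
    terms = [tuple(t) for t in terms]
    for t in terms:
        for name, _ in t:
            if name not in pos:
                raise ValueError(f"literal {name!r} is not among parents {parents}")
    n = len(parents)
    out = []
    for row in range(2**n):
        bits = [(row >> (n - 1 - i)) & 1 for i in range(n)]
        val = 0
        for t in terms:
            if all((bits[pos[name]] == (0 if neg else 1)) for name, neg in t):
                val = 1
                break
        out.append(val)
    return tuple(out)


def format_sop(terms: Sequence[Term]) -> str:
    """Human-readable SOP string: ``A & !B | C``; constants ``0`` / ``1``."""
    if not terms:
        return "0"
    parts = []
    for t in terms:
        if not t:
            parts.append("1")
        else:
            parts.append(" & ".join(("!" + n) if neg else n for n, neg in t))
    return " | ".join(parts)


@dataclass(frozen=True)
class BoolRule:
    """Update rule of one node: ordered parents plus an explicit truth table.

    ``table`` has ``2**len(parents)`` entries; row ``r`` is the output for the
    parent bit pattern whose integer value (first parent most significant)
    is ``r``.
    """

    parents: tuple[str, ...]
    table: tuple[int, ...]
    sop: tuple[Term, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.table) != 2 ** len(self.parents):
            raise ValueError(
                f"table length {len(self.table)} != 2**{len(self.parents)}"
            )
        if any(v not in (0, 1) for v in self.table):
            raise ValueError("truth table entries must be 0/1")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent names")

    @classmethod
    def from_sop(cls, parents: Sequence[str], terms: Iterable[Term]) -> "BoolRule":
        terms = tuple(tuple(t) for t in terms)
        return cls(tuple(parents), sop_to_table(parents, terms), terms)

    @classmethod
    def constant(cls, value: int) -> "BoolRule":
        return cls((), (1 if value else 0,), ((),) if value else ())

    @classmethod
    def identity(cls, parent: str) -> "BoolRule":
        return cls((parent,), (0, 1), (((parent, False),),))

    def __call__(self, bits: Sequence[int]) -> int:
        if len(bits) != len(self.parents):
            raise ValueError("wrong number of parent bits")
        return self.table[_row_index(bits)]

    def is_constant(self) -> bool:
        return len(set(self.table)) <= 1

    def essential_parents(self) -> tuple[str, ...]:
        """Parents the table actually depends on."""
        keep = []
        n = len(self.parents)
        for i, p in enumerate(self.parents):
            shift = n - 1 - i
            dep = any(
                self.table[r] != self.table[r ^ (1 << shift)]
                for r in range(2**n)
                if not (r >> shift) & 1
            )
            if dep:
                keep.append(p)
        return tuple(keep)

    def restrict(self, assignment: Mapping[str, int]) -> "BoolRule":
        """Partially evaluate: fix some parents to constants."""
        fixed = {p: assignment[p] for p in self.parents if p in assignment}
        if not fixed:
            return self
        rest = [p for p in self.parents if p not in fixed]
        n, m = len(self.parents), len(rest)
        new = []
        for row in range(2**m):
            bits = []
            j = 0
            for p in self.parents:
                if p in fixed:
                    bits.append(fixed[p])
                else:
                    bits.append((row >> (m - 1 - j)) & 1)
                    j += 1
            new.append(self.table[_row_index(bits)])
        return BoolRule(tuple(rest), tuple(new))

    def expression(self) -> str:
        if self.sop is not None:
            return format_sop(self.sop)
        # canonical (unminimized) SOP from the 1-rows
        n = len(self.parents)
        terms: list[Term] = []
        for row in range(2**n):
            if self.table[row]:
                terms.append(
                    tuple(
                        (p, not ((row >> (n - 1 - i)) & 1))
                        for i, p in enumerate(self.parents)
                    )
                )
        return format_sop(terms)


class BooleanNetwork:
    """Synchronous Boolean network over a fixed, ordered node list.

    Parameters
    ----------
    rules:
        Mapping node name → :class:`BoolRule`.  Every parent referenced by a
        rule must itself be a node.
    nodes:
        Optional explicit node order (defaults to rule-insertion order).  The
        order is significant: it fixes state tuples and the delta-state
        indexing used by :mod:`cytobool.stp`.
    inputs:
        Nodes with no regulatory rule.  They hold their value (self-copy),
        which is how clamped experimental inputs behave over a run.
    """

    def __init__(
        self,
        rules: Mapping[str, BoolRule],
        nodes: Sequence[str] | None = None,
        inputs: Iterable[str] = (),
    ) -> None:
        self.inputs = frozenset(inputs)
        order = list(nodes) if nodes is not None else list(rules)
        known = set(order)
        full: dict[str, BoolRule] = {}
        for name in order:
            if name in self.inputs and name not in rules:
                full[name] = BoolRule.identity(name)
            elif name in rules:
                full[name] = rules[name]
            else:
                raise ValueError(f"node {name!r} has no rule and is not an input")
        extra = set(rules) - known
        if extra:
            raise ValueError(f"rules for unknown nodes: {sorted(extra)}")
        for child, rule in full.items():
            for p in rule.parents:
                if p not in known:
                    raise ValueError(
                        f"rule for {child!r} references unknown node {p!r}"
                    )
        self.nodes: tuple[str, ...] = tuple(order)
        self.rules: dict[str, BoolRule] = full
        self._pos = {n: i for i, n in enumerate(self.nodes)}

    # -- basic properties --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    def parents_of(self, node: str) -> tuple[str, ...]:
        return self.rules[node].parents

    def children_of(self, node: str) -> tuple[str, ...]:
        return tuple(
            c
            for c in self.nodes
            if node in self.rules[c].parents and not (c in self.inputs and c == node)
        )

    def structural_inputs(self) -> tuple[str, ...]:
        """Nodes with no parents (declared inputs count)."""
        return tuple(
            nd
            for nd in self.nodes
            if nd in self.inputs or not self.rules[nd].parents
        )

    # -- dynamics ----------------------------------------------------------
    def step(self, state: Sequence[int]) -> tuple[int, ...]:
        """One synchronous update of every node."""
        if len(state) != self.n:
            raise ValueError(f"state length {len(state)} != {self.n} nodes")
        return tuple(
            self.rules[nd]([state[self._pos[p]] for p in self.rules[nd].parents])
            for nd in self.nodes
        )

    def trajectory(self, state: Sequence[int], steps: int) -> list[tuple[int, ...]]:
        out = [tuple(int(b) for b in state)]
        for _ in range(steps):
            out.append(self.step(out[-1]))
        return out

    # -- structure ---------------------------------------------------------
    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child in self.nodes:
            if child in self.inputs:
                continue
            for p in self.rules[child].parents:
                g.add_edge(p, child)
        return g

    def subnetwork(self, keep: Sequence[str]) -> "BooleanNetwork":
        """Restrict to ``keep``; every kept node's parents must be kept too."""
        keep_set = set(keep)
        rules = {}
        for nd in keep:
            rule = self.rules[nd]
            missing = [p for p in rule.parents if p not in keep_set]
            if missing:
                raise ValueError(f"{nd!r} depends on removed nodes {missing}")
            rules[nd] = rule
        return BooleanNetwork(
            rules, nodes=list(keep), inputs=self.inputs & keep_set
        )

    def __repr__(self) -> str:
        return f"BooleanNetwork(n={self.n}, inputs={sorted(self.inputs)})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.inputs == other.inputs
            and all(
                self.rules[nd].parents == other.rules[nd].parents
                and self.rules[nd].table == other.rules[nd].table
                for nd in self.nodes
            )
        )

    # -- BoolNet-style text ------------------------------------------------
    def to_boolnet(self) -> str:
        """Serialize in the BoolNet ``targets, factors`` text format.

        Node names are sanitized (non ``[A-Za-z0-9_]`` characters become
        ``_``) because the BoolNet grammar does not admit hyphens.
        """
        def clean(name: str) -> str:
            return re.sub(r"[^A-Za-z0-9_]", "_", name)

        lines = ["targets, factors"]
        for nd in self.nodes:
            if nd in self.inputs:
                lines.append(f"{clean(nd)}, {clean(nd)}")
                continue
            rule = self.rules[nd]
            sop = rule.sop
            if sop is None:
                expr = rule.expression()
            else:
                expr = format_sop(sop)
            for p in sorted(rule.parents, key=len, reverse=True):
                expr = re.sub(rf"(?<![\w-]){re.escape(p)}(?![\w-])", clean(p), expr)
            lines.append(f"{clean(nd)}, {expr}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# expression / BoolNet parsing
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\()|(\))|(!)|(&)|(\|)|([A-Za-z0-9_][A-Za-z0-9_\-]*))")


def _tokenize(text: str) -> list[str]:
    out, i = [], 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if not m or m.end() == i:
            if text[i:].strip():
                raise ValueError(f"cannot tokenize {text[i:]!r}")
            break
        out.append(m.group(m.lastindex))
        i = m.end()
    return out


def parse_expression(text: str) -> tuple[tuple[str, ...], "BoolRule"]:
    """Parse ``A & !B | C`` into a :class:`BoolRule`.

    Grammar (standard precedence ``!`` > ``&`` > ``|``)::

        or   := and ('|' and)*
        and  := unary ('&' unary)*
        unary:= '!' unary | '(' or ')' | NAME | '0' | '1'

    Returns the parents in first-appearance order plus the rule.
    """
    tokens = _tokenize(text)
    names: list[str] = []
    for t in tokens:
        if t not in "()!&|" and t not in ("0", "1") and t not in names:
            names.append(t)
    pos = {nm: i for i, nm in enumerate(names)}
    k = 0

    def peek() -> str | None:
        return tokens[k] if k < len(tokens) else None

    def eat(tok: str | None = None) -> str:
        nonlocal k
        if k >= len(tokens):
            raise ValueError("unexpected end of expression")
        t = tokens[k]
        if tok is not None and t != tok:
            raise ValueError(f"expected {tok!r}, got {t!r}")
        k += 1
        return t

    # evaluate to a set of satisfying rows over the full name list
    nbits = len(names)

    def eval_or() -> set[int]:
        rows = eval_and()
        while peek() == "|":
            eat("|")
            rows = rows | eval_and()
        return rows

    def eval_and() -> set[int]:
        rows = eval_unary()
        while peek() == "&":
            eat("&")
            rows = rows & eval_unary()
        return rows

    def eval_unary() -> set[int]:
        t = peek()
        if t == "!":
            eat("!")
            return set(range(2**nbits)) - eval_unary()
        if t == "(":
            eat("(")
            rows = eval_or()
            eat(")")
            return rows
        t = eat()
        if t == "0":
            return set()
        if t == "1":
            return set(range(2**nbits))
        i = pos[t]
        shift = nbits - 1 - i
        return {r for r in range(2**nbits) if (r >> shift) & 1}

    rows = eval_or()
    if k != len(tokens):
        raise ValueError(f"trailing tokens: {tokens[k:]}")
    table = tuple(1 if r in rows else 0 for r in range(2**nbits))
    return tuple(names), BoolRule(tuple(names), table)


def parse_boolnet(text: str) -> BooleanNetwork:
    """Read a BoolNet-style ``targets, factors`` document."""
    rules: dict[str, BoolRule] = {}
    inputs: list[str] = []
    order: list[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if "," not in line:
            raise ValueError(f"malformed line: {raw!r}")
        target, expr = (s.strip() for s in line.split(",", 1))
        order.append(target)
        if expr == target:
            inputs.append(target)
            continue
        _, rule = parse_expression(expr)
        rules[target] = rule
    return BooleanNetwork(rules, nodes=order, inputs=inputs)
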