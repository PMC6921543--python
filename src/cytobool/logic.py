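"""Boolean update-rule determination from binarized time courses.

For each child, the observed synchronous transitions — parent bits at grid
step k against the child's bit at k+1 (49 transitions from 50 samples, or
196 when the four replicates are pooled) — populate a truth table.  Rows
never observed stay *don't-care*; rows observed with contradictory outcomes
are resolved by majority vote with the conflict count retained.  The table
is then reduced to a minimal two-level sum-of-products with don't-cares
used freely — Quine–McCluskey minimization, the automated equivalent of
reading a Karnaugh map.

Two consistency checks follow: predictive agreement of the minimized
function on the observed transitions, and whether each parent's positive /
negated appearance (unateness) matches the promotion / inhibition sign of
its LP weight.  When either fails, inference escalates from averaged
profiles to the pooled per-replicate transitions, which can fill rows the
averaged data never visited; for children stuck at logic high, plain
self-maintenance (x' = x) is admitted as a candidate and chosen when it
agrees best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sympy import And, Not, Or, Symbol, false, true
from sympy.logic import SOPform

from .network import BoolRule, Term, format_sop

__all__ = [
    "TruthTable",
    "BooleanFunction",
    "build_truth_table",
    "minimize_sop",
    "check_consistency",
    "refit_per_replicate",
    "ConsistencyReport",
]

MAX_PARENTS = 5  # 2**5 = 32 < 50 samples: the motif size the grid supports


@dataclass
class TruthTable:
    """Observed-transition table over ≤ 5 parents.

    ``outputs[r]`` is 0/1 or None (don't-care, never observed); ``support``
    counts observations per row; ``conflicts`` counts overruled (minority)
    observations per row.
    """

    parents: tuple[str, ...]
    outputs: list[int | None]
    support: list[int]
    conflicts: list[int]
    child: str = "child"

    @property
    def n_rows(self) -> int:
        return 2 ** len(self.parents)

    def minterms(self) -> list[int]:
        return [r for r, v in enumerate(self.outputs) if v == 1]

    def dont_cares(self) -> list[int]:
        return [r for r, v in enumerate(self.outputs) if v is None]


def build_truth_table(
    parents: Sequence[str],
    parent_bits: np.ndarray,
    child_next_bits: Sequence[int],
    child: str = "child",
) -> TruthTable:
    """Tally transitions into a truth table.

    ``parent_bits`` is (T × P): parent states at steps k = 1..T;
    ``child_next_bits`` the child's state at k+1 for the same rows.  With a
    50-point grid, T = 49 — the last sample has no successor.
    """
    parents = tuple(parents)
    if len(parents) > MAX_PARENTS:
        raise ValueError(f"at most {MAX_PARENTS} parents supported")
    B = np.asarray(parent_bits, dtype=int)
    y = np.asarray(child_next_bits, dtype=int)
    if B.ndim != 2 or B.shape != (len(y), len(parents)):
        raise ValueError("parent_bits must be (T, P) matching child bits")
    if np.any((B != 0) & (B != 1)) or np.any((y != 0) & (y != 1)):
        raise ValueError("bits must be 0/1")
    n_rows = 2 ** len(parents)
    ones = np.zeros(n_rows, dtype=int)
    zeros = np.zeros(n_rows, dtype=int)
    weights = 1 << np.arange(len(parents) - 1, -1, -1)
    rows = B @ weights
    for r, out in zip(rows, y):
        if out:
            ones[r] += 1
        else:
            zeros[r] += 1
    outputs: list[int | None] = []
    support: list[int] = []
    conflicts: list[int] = []
    for r in range(n_rows):
        tot = ones[r] + zeros[r]
        support.append(int(tot))
        if tot == 0:
            outputs.append(None)
            conflicts.append(0)
        else:
            # majority vote; ties resolve to 0 (inactive), mirroring the
            # constant-0 tie rule for fully unobserved tables
            val = 1 if ones[r] > zeros[r] else 0
            outputs.append(val)
            conflicts.append(int(min(ones[r], zeros[r])))
    return TruthTable(parents, outputs, support, conflicts, child=child)


@dataclass(frozen=True)
class BooleanFunction:
    """A minimized update rule: SOP terms plus the completed truth table
    (don't-cares filled in by the minimal cover)."""

    parents: tuple[str, ...]
    terms: tuple[Term, ...]
    rule: BoolRule
    child: str = "child"

    @property
    def expression(self) -> str:
        return format_sop(self.terms)

    def __call__(self, bits: Sequence[int]) -> int:
        return self.rule(bits)

    def predict(self, parent_bits: np.ndarray) -> np.ndarray:
        B = np.asarray(parent_bits, dtype=int)
        return np.array([self.rule(row) for row in B])


def _sympy_to_terms(expr, parents: Sequence[str]) -> tuple[Term, ...]:
    if expr is true or expr == True:  # noqa: E712 - sympy singleton
        return ((),)
    if expr is false or expr == False:  # noqa: E712
        return ()
    def term_of(e) -> Term:
        lits = e.args if isinstance(e, And) else (e,)
        out = []
        for lit in lits:
            if isinstance(lit, Not):
                out.append((str(lit.args[0]), True))
            else:
                out.append((str(lit), False))
        # literal order follows the parent order for determinism
        order = {p: i for i, p in enumerate(parents)}
        return tuple(sorted(out, key=lambda l: order[l[0]]))

    terms = expr.args if isinstance(expr, Or) else (expr,)
    out = [term_of(t) for t in terms]
    return tuple(sorted(out))  # deterministic lexicographic term order


def minimize_sop(table: TruthTable) -> BooleanFunction:
    """Minimal sum-of-products covering the table's 1-rows, excluding its
    0-rows, with don't-cares used freely (Quine–McCluskey).

    A table with no defined rows yields the constant-0 function.
    """
    parents = table.parents
    minterms = table.minterms()
    dontcares = table.dont_cares()
    if not minterms:
        rule = BoolRule(parents, tuple([0] * table.n_rows), ())
        return BooleanFunction(parents, (), rule, child=table.child)
    # row index r has parent bits = binary expansion of r, first parent MSB;
    # SOPform expects minterms as bit value integers with symbols[0] the MSB
    syms = [Symbol(p) for p in parents]
    expr = SOPform(syms, minterms, dontcares)
    terms = _sympy_to_terms(expr, parents)
    rule = BoolRule.from_sop(parents, terms)
    return BooleanFunction(parents, terms, rule, child=table.child)


@dataclass(frozen=True)
class ConsistencyReport:
    agreement: float
    sign_status: dict[str, str]  # parent -> "match" | "mismatch" | "mixed" | "none"
    escalate: bool


def _unateness(rule: BoolRule, parent: str) -> str:
    """Direction of influence of one variable: "positive", "negative",
    "none" (non-essential) or "mixed"."""
    i = rule.parents.index(parent)
    n = len(rule.parents)
    shift = n - 1 - i
    up = down = False
    for r in range(2**n):
        if (r >> shift) & 1:
            continue
        lo, hi = rule.table[r], rule.table[r | (1 << shift)]
        if hi > lo:
            up = True
        elif hi < lo:
            down = True
    if up and down:
        return "mixed"
    if up:
        return "positive"
    if down:
        return "negative"
    return "none"


def check_consistency(
    fn: BooleanFunction,
    lp_signs: Mapping[str, str],
    parent_bits: np.ndarray,
    child_next_bits: Sequence[int],
    min_agreement: float = 0.85,
) -> ConsistencyReport:
    """Score a function against observed transitions and LP link signs.

    Agreement is the fraction of transitions predicted correctly.  A parent
    whose LP sign is promotion must enter the function positively
    (positive unate), inhibition negatively; a mixed (non-unate) dependence
    always escalates.
    """
    y = np.asarray(child_next_bits, dtype=int)
    pred = fn.predict(parent_bits)
    agreement = float(np.mean(pred == y)) if len(y) else 1.0
    sign_status: dict[str, str] = {}
    mismatch = False
    for parent in fn.parents:
        u = _unateness(fn.rule, parent)
        want = lp_signs.get(parent)
        if u == "mixed":
            sign_status[parent] = "mixed"
            mismatch = True
        elif u == "none" or want is None:
            sign_status[parent] = "none"
        elif (u == "positive") == (want == "promotion"):
            sign_status[parent] = "match"
        else:
            sign_status[parent] = "mismatch"
            mismatch = True
    return ConsistencyReport(
        agreement=agreement,
        sign_status=sign_status,
        escalate=bool(mismatch or agreement < min_agreement),
    )


def refit_per_replicate(
    parents: Sequence[str],
    replicate_parent_bits: Sequence[np.ndarray],
    replicate_child_next_bits: Sequence[Sequence[int]],
    child: str = "child",
    consider_self_regulation: bool = True,
) -> BooleanFunction:
    """Re-determine a rule from pooled per-replicate transitions.

    All replicates' transitions enter one table (supports summed), filling
    rows the averaged profiles may have missed.  For a child observed at
    logic high throughout, the self-maintenance rule x' = x is admitted as
    a candidate and returned when it matches the pooled transitions at
    least as well as the minimized table.
    """
    B = np.vstack([np.asarray(b, dtype=int) for b in replicate_parent_bits])
    y = np.concatenate(
        [np.asarray(v, dtype=int) for v in replicate_child_next_bits]
    )
    table = build_truth_table(parents, B, y, child=child)
    fn = minimize_sop(table)
    if consider_self_regulation and np.all(y == 1):
        self_fn = BooleanFunction(
            (child,),
            (((child, False),),),
            BoolRule.identity(child),
            child=child,
        )
        # the child held high: x' = x predicts 1 everywhere it was high
        agree_table = float(np.mean(fn.predict(B) == y))
        if 1.0 >= agree_table:
            return self_fn
    return fn
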