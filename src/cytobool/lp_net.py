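"""Sparse regulatory-structure inference by linear programming.

Each protein (child) is explained as a sparse linear combination of the
other proteins' expression levels,

    x_i = w_i0 + Σ_{j≠i} w_{j,i} x_j ,

with positive weights read as promotion and negative as inhibition.  Per
child, the LP minimizes

    Σ_j |w_{j,i}| x̄_j  +  (1/Υ) w_i0  +  (1/λ) Σ_l ζ_l

subject to: for every sample m with the child active (x_{i,m} ≥ δ_i) the
predictor must reach the threshold, w_i0 + Σ w_{j,i} x_{j,m} ≥ δ_i; for
every inactive sample it must stay below a non-negative slack ζ_l.  (As
printed, the inactive-sample constraint duplicates the active one, which
would leave the slacks meaningless; the implemented direction — predictor
≤ ζ_l when the child is inactive — is the one that matches the stated
purpose of selecting down-regulating parents.)  Absolute weights are
linearized the standard way, w = w⁺ − w⁻ with both parts non-negative;
x̄_j is the sample mean of the parent's level, the same quantity used by
the contribution-based pruning rule.

λ is selected per child by k-fold cross-validation of the linear model's
prediction error over a log-spaced grid capped at L·σ², and links whose
contribution |w_{j,i}|·x̄_j falls below a fraction (default 70%) of the
strongest contribution into the same child are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "LPProblem",
    "LPSolution",
    "WeightedNetwork",
    "NetworkMetrics",
    "solve_child_lp",
    "select_lambda",
    "prune",
    "metrics",
    "network_from_fixture",
]

DEFAULT_UPSILON = 100.0


@dataclass
class LPProblem:
    """One child's structure-inference instance.

    ``parent_samples`` is (n_samples × n_parents); ``child_samples``
    (n_samples,) holds the child's level at the predicted sample (lag the
    rows upstream if predicting the next grid step).
    """

    child: str
    parents: tuple[str, ...]
    parent_samples: np.ndarray
    child_samples: np.ndarray
    delta: float
    upsilon: float = DEFAULT_UPSILON
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.parent_samples = np.asarray(self.parent_samples, dtype=float)
        self.child_samples = np.asarray(self.child_samples, dtype=float)
        if self.parent_samples.ndim != 2:
            raise ValueError("parent_samples must be 2-D")
        if self.parent_samples.shape != (
            len(self.child_samples),
            len(self.parents),
        ):
            raise ValueError("sample matrix shape mismatch")
        if len(self.parents) == 0:
            raise ValueError("candidate parent set is empty")
        if self.lam <= 0 or self.upsilon <= 0:
            raise ValueError("lam and upsilon must be > 0")

    @property
    def active_mask(self) -> np.ndarray:
        return self.child_samples >= self.delta


@dataclass
class LPSolution:
    weights: dict[str, float]
    bias: float
    slacks: np.ndarray
    objective: float
    status: str

    def predictor(self, parent_samples: np.ndarray, parents: Sequence[str]):
        w = np.array([self.weights[p] for p in parents])
        return self.bias + parent_samples @ w


class LPInfeasibleError(RuntimeError):
    pass


def solve_child_lp(problem: LPProblem, tol: float = 1e-9) -> LPSolution:
    """Solve one child's LP exactly (HiGHS).

    Variable layout: [w⁺ (P), w⁻ (P), w0, ζ (L)] with everything ≥ 0.
    """
    X = problem.parent_samples
    n_samples, P = X.shape
    active = problem.active_mask
    inactive_idx = np.flatnonzero(~active)
    L = len(inactive_idx)

    xbar = X.mean(axis=0)
    c = np.concatenate(
        [xbar, xbar, [1.0 / problem.upsilon], np.full(L, 1.0 / problem.lam)]
    )
    n_var = 2 * P + 1 + L

    rows, rhs = [], []
    # active samples:  -(w0 + Σ w x) <= -δ
    for m in np.flatnonzero(active):
        row = np.zeros(n_var)
        row[:P] = -X[m]
        row[P : 2 * P] = X[m]
        row[2 * P] = -1.0
        rows.append(row)
        rhs.append(-problem.delta)
    # inactive samples:  w0 + Σ w x - ζ_l <= 0
    for li, m in enumerate(inactive_idx):
        row = np.zeros(n_var)
        row[:P] = X[m]
        row[P : 2 * P] = -X[m]
        row[2 * P] = 1.0
        row[2 * P + 1 + li] = -1.0
        rows.append(row)
        rhs.append(0.0)

    res = linprog(
        c,
        A_ub=np.array(rows) if rows else None,
        b_ub=np.array(rhs) if rhs else None,
        bounds=[(0, None)] * n_var,
        method="highs",
    )
    if not res.success:
        raise LPInfeasibleError(
            f"LP for child {problem.child!r} failed: {res.message}"
        )
    z = res.x
    w = z[:P] - z[P : 2 * P]
    w[np.abs(w) < tol] = 0.0
    return LPSolution(
        weights={p: float(v) for p, v in zip(problem.parents, w)},
        bias=float(z[2 * P]),
        slacks=z[2 * P + 1 :].copy(),
        objective=float(res.fun),
        status="optimal",
    )


def select_lambda(
    parent_samples: np.ndarray,
    child_samples: np.ndarray,
    parents: Sequence[str],
    delta: float,
    folds: int = 5,
    grid: Sequence[float] | None = None,
    upsilon: float = DEFAULT_UPSILON,
    child: str = "child",
    seed: int = 0,
) -> float:
    """Pick λ by k-fold cross-validated prediction error.

    The grid defaults to 8 log-spaced values capped at L·σ² (L the count of
    inactive samples, σ² the variance of the pooled parent samples); with
    degenerate zero-variance data the cap is undefined and a fixed default
    of 1.0 is returned.
    """
    X = np.asarray(parent_samples, dtype=float)
    y = np.asarray(child_samples, dtype=float)
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n_samples]")
    if grid is None:
        sigma2 = float(np.var(X))
        L = int(np.sum(y < delta))
        cap = L * sigma2
        if cap <= 0:
            return 1.0
        grid = np.geomspace(cap * 1e-4, cap, 8)
    grid = list(grid)
    if len(grid) == 1:
        return float(grid[0])

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for i, idx in enumerate(order):
        fold_of[idx] = i % folds

    best = (np.inf, float(grid[0]))
    for lam in grid:
        errs = []
        for f in range(folds):
            train, test = fold_of != f, fold_of == f
            if not np.any(train) or not np.any(test):
                continue
            try:
                sol = solve_child_lp(
                    LPProblem(
                        child=child,
                        parents=tuple(parents),
                        parent_samples=X[train],
                        child_samples=y[train],
                        delta=delta,
                        upsilon=upsilon,
                        lam=float(lam),
                    )
                )
            except LPInfeasibleError:
                continue
            pred = sol.predictor(X[test], parents)
            errs.append(float(np.mean((pred - y[test]) ** 2)))
        mse = float(np.mean(errs)) if errs else np.inf
        if mse < best[0] - 1e-15:
            best = (mse, float(lam))
    return best[1]


@dataclass
class WeightedNetwork:
    """Directed weighted regulatory network: LP weights on links, biases on
    nodes."""

    nodes: tuple[str, ...]
    links: list[tuple[str, str, float]]  # (parent, child, weight)
    biases: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for p, ch, w in self.links:
            if p not in known or ch not in known:
                raise ValueError(f"link {p}->{ch} references unknown node")
            if w == 0:
                raise ValueError(f"retained link {p}->{ch} has zero weight")

    def parents_of(self, child: str) -> list[tuple[str, float]]:
        return [(p, w) for p, ch, w in self.links if ch == child]

    def children_of(self, parent: str) -> list[str]:
        return [ch for p, ch, _ in self.links if p == parent]


@dataclass(frozen=True)
class NetworkMetrics:
    """Countable properties of a weighted network (summary-table style)."""

    n_nodes: int
    n_links: int
    density: float
    n_promotion: int
    n_inhibition: int
    input_nodes: int
    output_nodes: int
    nodes_with_ge4_parents: int
    n_attractors: int | None = None


def metrics(
    network: WeightedNetwork, n_attractors: int | None = None
) -> NetworkMetrics:
    """Node/link/sign counts; density is links per node (0 for an empty
    network by convention)."""
    n_nodes = len(network.nodes)
    n_links = len(network.links)
    promo = sum(1 for *_, w in network.links if w > 0)
    inhib = sum(1 for *_, w in network.links if w < 0)
    with_parents = {ch for _, ch, _ in network.links}
    with_children = {p for p, _, _ in network.links}
    parent_count = {nd: 0 for nd in network.nodes}
    for _, ch, _ in network.links:
        parent_count[ch] += 1
    return NetworkMetrics(
        n_nodes=n_nodes,
        n_links=n_links,
        density=(n_links / n_nodes) if n_nodes else 0.0,
        n_promotion=promo,
        n_inhibition=inhib,
        input_nodes=sum(1 for nd in network.nodes if nd not in with_parents),
        output_nodes=sum(1 for nd in network.nodes if nd not in with_children),
        nodes_with_ge4_parents=sum(1 for v in parent_count.values() if v >= 4),
        n_attractors=n_attractors,
    )


def prune(
    network: WeightedNetwork,
    mean_expression: Mapping[str, float],
    fraction: float = 0.7,
    drop_nodes: Sequence[str] = (),
) -> WeightedNetwork:
    """Contribution-based link pruning.

    Per child, a parent's contribution is |w_{j,i}|·x̄_j (x̄ the mean level
    over grid points and replicates); links below ``fraction`` of the
    strongest contribution into that child are removed.  ``drop_nodes``
    (e.g. proteins failing the control screen) are removed with all their
    links; orphan nodes disappear.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    dropped = set(drop_nodes)
    kept_links: list[tuple[str, str, float]] = []
    children = {ch for _, ch, _ in network.links}
    for child in children:
        if child in dropped:
            continue
        cand = [
            (p, w)
            for p, w in network.parents_of(child)
            if p not in dropped
        ]
        if not cand:
            continue
        contrib = {p: abs(w) * float(mean_expression[p]) for p, w in cand}
        cmax = max(contrib.values())
        for p, w in cand:
            if cmax == 0 or contrib[p] >= fraction * cmax:
                kept_links.append((p, child, w))
    touched = {p for p, _, _ in kept_links} | {ch for _, ch, _ in kept_links}
    nodes = tuple(nd for nd in network.nodes if nd in touched)
    return WeightedNetwork(
        nodes=nodes,
        links=kept_links,
        biases={nd: b for nd, b in network.biases.items() if nd in touched},
        provenance={**network.provenance, "prune_fraction": fraction},
    )


def network_from_fixture(fx) -> WeightedNetwork:
    """Weighted view of a published fixture (printed LP weights)."""
    links = [
        (parent, child, float(w))
        for child, ws in fx.weights.items()
        for parent, w in ws.items()
    ]
    return WeightedNetwork(
        nodes=tuple(fx.network.nodes),
        links=links,
        provenance={"fixture": fx.name},
    )
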