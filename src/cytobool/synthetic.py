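"""Synthetic cytokine panels with known Boolean ground truth.

The raw panel behind the published macrophage networks is not deposited, so
every downstream stage is validated on generated data instead: a random (or
hand-picked) synchronous Boolean network is simulated on the resampling
grid, and each node's 0/1 state is rendered into a continuous expression
level through one of three archetypal temporal shape kernels —

* promotion:   ``c · t / (1 + t)``      (saturating rise from 0)
* inhibition:  ``c / (1 + t) + bias``   (decay to an offset)
* bell:        ``c · exp(-(t-center)² / (2·width²))``

with the kernel clock restarting at every Boolean switch, multiplicative
log-normal replicate noise, and a detection floor.  The design mirrors the
study layout: 27 proteins × 7 time points (0, 0.5, 1, 3, 6, 12, 24 h) × 4
replicates × control + stimulus groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import BooleanNetwork, BoolRule

__all__ = [
    "ShapeKernel",
    "SyntheticDesign",
    "TimeSeriesPanel",
    "shape_value",
    "generate_ground_truth_bn",
    "default_kernels",
    "render_panel",
    "DESIGN_TIMES",
]

#: measurement times of the study design (hours)
DESIGN_TIMES = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0)


@dataclass(frozen=True)
class ShapeKernel:
    """One temporal shape archetype.  ``c`` is the amplitude in expression
    units; ``bias`` applies to inhibition only; ``center``/``width`` (hours)
    to the bell only."""

    kind: str
    c: float
    bias: float = 0.0
    center: float = 6.0
    width: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("promotion", "inhibition", "bell"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.c < 0:
            raise ValueError("amplitude c must be >= 0")
        if self.kind == "inhibition" and self.bias < 0:
            raise ValueError("bias must be >= 0")
        if self.kind == "bell" and self.width <= 0:
            raise ValueError("width must be > 0")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return shape_value(self, t)

    def range_over(self, horizon: float = 24.0) -> tuple[float, float]:
        """Min/max of the kernel over ``[0, horizon]`` (used to detect
        overlapping high/low rendering ranges)."""
        tt = np.linspace(0.0, horizon, 513)
        vv = shape_value(self, tt)
        return float(np.min(vv)), float(np.max(vv))


def shape_value(kernel: ShapeKernel, t: float | np.ndarray):
    """Evaluate a shape kernel at time ``t`` (hours, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if kernel.kind == "promotion":
        out = kernel.c * t / (1.0 + t)
    elif kernel.kind == "inhibition":
        out = kernel.c / (1.0 + t) + kernel.bias
    else:
        out = kernel.c * np.exp(-((t - kernel.center) ** 2) / (2 * kernel.width**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticDesign:
    """Experimental layout of a rendered panel.

    ``noise_sigma`` is the log-normal multiplicative scatter between
    replicates; ``floor`` the assay detection floor (values are clipped up
    to it).  ``seed`` fully determines the rendered panel.
    """

    proteins: tuple[str, ...]
    times: tuple[float, ...] = DESIGN_TIMES
    replicates: int = 4
    groups: tuple[str, ...] = ("LPS",)
    control_group: str = "control"
    noise_sigma: float = 0.15
    floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0 or self.floor < 0:
            raise ValueError("noise_sigma and floor must be >= 0")


@dataclass
class TimeSeriesPanel:
    """Tidy measurement table plus its design and (for synthetic panels)
    the Boolean ground truth it was rendered from."""

    data: pd.DataFrame  # columns protein, group, replicate, time_h, value
    design: SyntheticDesign
    truth: dict | None = None  # group -> node -> bits on the step grid
    step_times: tuple[float, ...] | None = None
    warnings: list[str] = field(default_factory=list)

    def values(
        self, protein: str, group: str, replicate: int | None = None
    ) -> pd.DataFrame:
        d = self.data
        sel = (d["protein"] == protein) & (d["group"] == group)
        if replicate is not None:
            sel &= d["replicate"] == replicate
        return d.loc[sel].sort_values("time_h")

    def check_complete(self) -> list[tuple]:
        """Return missing (protein, group, replicate, time) combinations."""
        d = self.design
        groups = (d.control_group, *d.groups)
        idx = pd.MultiIndex.from_product(
            [d.proteins, groups, range(1, d.replicates + 1), d.times],
            names=["protein", "group", "replicate", "time_h"],
        )
        have = pd.MultiIndex.from_frame(
            self.data[["protein", "group", "replicate", "time_h"]]
        )
        return list(idx.difference(have))


def generate_ground_truth_bn(
    n_nodes: int, max_parents: int = 3, seed: int = 0
) -> BooleanNetwork:
    """Random synchronous Boolean network for recovery experiments.

    Every node gets a non-constant rule depending essentially on at most
    ``max_parents`` nodes (self-loops allowed).  A single-node network is
    forced to the self-copy rule.  Fully reproducible from ``seed``.
    """
    if not 1 <= n_nodes <= 11:
        raise ValueError("n_nodes must be in [1, 11]")
    if max_parents < 1 or max_parents > 3:
        raise ValueError("max_parents must be in [1, 3]")
    names = [f"N{i+1}" for i in range(n_nodes)]
    if n_nodes == 1:
        return BooleanNetwork({names[0]: BoolRule.identity(names[0])})
    rng = np.random.default_rng(seed)
    rules = {}
    for nd in names:
        while True:
            k = int(rng.integers(1, max_parents + 1))
            k = min(k, n_nodes)
            parents = tuple(rng.choice(names, size=k, replace=False))
            table = tuple(int(b) for b in rng.integers(0, 2, size=2**k))
            rule = BoolRule(parents, table)
            if rule.is_constant():
                continue
            if rule.essential_parents() != parents:
                continue
            rules[nd] = rule
            break
    return BooleanNetwork(rules, nodes=names)


def default_kernels(
    nodes: Sequence[str],
    low: ShapeKernel | None = None,
    high: ShapeKernel | None = None,
) -> dict[str, tuple[ShapeKernel, ShapeKernel]]:
    """Well-separated (low, high) kernel pair for every node.

    Defaults emulate a cytokine panel in pg/mL: a low state decaying toward
    a small basal offset and a clearly separated high plateau.
    """
    low = low or ShapeKernel("inhibition", c=20.0, bias=5.0)
    high = high or ShapeKernel("inhibition", c=200.0, bias=300.0)
    return {nd: (low, high) for nd in nodes}


def _boolean_course(
    bn: BooleanNetwork, initial: Sequence[int], step_times: np.ndarray
) -> np.ndarray:
    """Synchronous Boolean states at every step-grid time; shape (K, n)."""
    states = [tuple(int(b) for b in initial)]
    for _ in range(len(step_times) - 1):
        states.append(bn.step(states[-1]))
    return np.asarray(states, dtype=int)


def render_panel(
    bn: BooleanNetwork,
    kernels: Mapping[str, tuple[ShapeKernel, ShapeKernel]],
    design: SyntheticDesign,
    initial_states: Mapping[str, Sequence[int]] | None = None,
    step_times: Sequence[float] | None = None,
) -> TimeSeriesPanel:
    """Render Boolean dynamics into a noisy continuous panel.

    The network is stepped on ``step_times`` (default: the 50-point
    resampling grid).  A protein's continuous level at measurement time t is
    its current-state kernel evaluated at the time elapsed since its last
    Boolean switch (kernel clock reset), times log-normal replicate noise,
    clipped up to the detection floor.  The control group is rendered from
    the all-low state; each stimulus group starts from ``initial_states``
    (default: all-high).
    """
    if step_times is None:
        from .fitting import ResampleGrid

        step_times = ResampleGrid.standard().times
    step_times = np.asarray(step_times, dtype=float)
    if set(bn.nodes) != set(design.proteins):
        raise ValueError("design proteins must match network nodes")

    warnings: list[str] = []
    for nd in bn.nodes:
        lo, hi = kernels[nd]
        lo_min, lo_max = lo.range_over(design.times[-1])
        hi_min, hi_max = hi.range_over(design.times[-1])
        if hi_min <= lo_max:
            warnings.append(
                f"{nd}: high/low kernel ranges overlap "
                f"([{lo_min:.3g},{lo_max:.3g}] vs [{hi_min:.3g},{hi_max:.3g}]); "
                "binarization may be unidentifiable"
            )
        if not hi_max > lo_max:
            raise ValueError(f"{nd}: high-state kernel must exceed the low state")

    initial_states = dict(initial_states or {})
    rng = np.random.default_rng(design.seed)
    rows = []
    truth: dict[str, dict[str, tuple[int, ...]]] = {}
    groups = (design.control_group, *design.groups)
    for group in groups:
        if group == design.control_group:
            # unstimulated reference: held at the low state, noise only
            course = np.zeros((len(step_times), bn.n), dtype=int)
        else:
            init = list(initial_states.get(group, [1] * bn.n))
            course = _boolean_course(bn, init, step_times)
        truth[group] = {
            nd: tuple(course[:, i]) for i, nd in enumerate(bn.nodes)
        }
        # per-node switch times on the step grid
        for i, nd in enumerate(bn.nodes):
            bits = course[:, i]
            switch_time = np.empty(len(step_times))
            last = step_times[0]
            for k in range(len(step_times)):
                if k > 0 and bits[k] != bits[k - 1]:
                    last = step_times[k]
                switch_time[k] = last
            lo, hi = kernels[nd]
            for t in design.times:
                k = int(np.searchsorted(step_times, t, side="right") - 1)
                kern = hi if bits[k] else lo
                clean = shape_value(kern, max(t - switch_time[k], 0.0))
                for rep in range(1, design.replicates + 1):
                    noise = (
                        np.exp(rng.normal(0.0, design.noise_sigma))
                        if design.noise_sigma > 0
                        else 1.0
                    )
                    rows.append(
                        (nd, group, rep, t, max(clean * noise, design.floor))
                    )
    df = pd.DataFrame(
        rows, columns=["protein", "group", "replicate", "time_h", "value"]
    )
    return TimeSeriesPanel(
        data=df,
        design=design,
        truth=truth,
        step_times=tuple(float(t) for t in step_times),
        warnings=warnings,
    )
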