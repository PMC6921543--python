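"""Registry of the published macrophage activation networks.

Three fully printed Boolean networks — M1 (LPS), M2a (IL-4) and M2c
(IL-10) — are bundled as JSON data: update rules, linear-programming link
weights, node attributions, the published core-network membership, and the
experimentally observed state paths in delta-index form.  They serve as
exact regression fixtures for the dynamics, reduction and metrics code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .network import BooleanNetwork, BoolRule

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("M1", "M2a", "M2c")


@dataclass(frozen=True)
class Fixture:
    """One published activation network plus its core and observed path."""

    name: str
    stimulus: str
    network: BooleanNetwork
    weights: Mapping[str, Mapping[str, float]]  # child -> parent -> LP weight
    attribution: Mapping[str, str]  # child -> Input/IS/Output/State
    core_nodes: tuple[str, ...]
    core: BooleanNetwork | None  # collapsed core rules, where published
    collapsed: Mapping[str, dict] | None
    trajectory_indices: tuple[int, ...]
    trajectory_states: tuple[tuple[int, ...], ...]
    trajectory_order: tuple[str, ...]
    stable_states: Mapping[int, tuple[int, ...]]
    table2: Mapping[str, Mapping[str, float]]

    @property
    def n_links(self) -> int:
        return sum(len(w) for w in self.weights.values())


def _terms(raw) -> tuple:
    return tuple(tuple((name, bool(neg)) for name, neg in term) for term in raw)


def load_fixture(name: str) -> Fixture:
    """Load one of the published networks: ``M1``, ``M2a`` or ``M2c``."""
    key = name.strip()
    lookup = {n.lower(): n for n in FIXTURE_NAMES}
    if key.lower() not in lookup:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    fname = key.lower() + ".json"
    data = json.loads(
        resources.files("cytobool.data").joinpath(fname).read_text()
    )

    def parent_order(spec) -> list[str]:
        # printed link (weight) order first, then literals the weight list
        # does not cover (e.g. a self-loop with no printed weight)
        parents = list(spec["weights"])
        for term in spec["terms"]:
            for nm, _ in term:
                if nm not in parents:
                    parents.append(nm)
        return parents

    rules = {
        child: BoolRule.from_sop(parent_order(spec), _terms(spec["terms"]))
        for child, spec in data["rules"].items()
    }
    network = BooleanNetwork(rules, nodes=data["nodes"], inputs=data["inputs"])

    core_info = data["core"]
    core = None
    if core_info.get("rules"):
        core_rules = {
            child: BoolRule.from_sop(
                sorted({nm for term in raw for nm, _ in term})
                or [],
                _terms(raw),
            )
            for child, raw in core_info["rules"].items()
        }
        core = BooleanNetwork(core_rules, nodes=core_info["nodes"])

    traj = data["trajectory"]
    return Fixture(
        name=data["name"],
        stimulus=data["stimulus"],
        network=network,
        weights={c: dict(s["weights"]) for c, s in data["rules"].items()},
        attribution={c: s["attribution"] for c, s in data["rules"].items()},
        core_nodes=tuple(core_info["nodes"]),
        core=core,
        collapsed=core_info.get("collapsed"),
        trajectory_indices=tuple(traj["indices"]),
        trajectory_states=tuple(tuple(s) for s in traj["states"]),
        trajectory_order=tuple(traj["node_order"]),
        stable_states={int(k): tuple(v) for k, v in data["stable_states"].items()},
        table2=data["table2"],
    )
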