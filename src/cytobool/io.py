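"""File formats: tidy panel CSV, SIF/GraphML networks, BoolNet text, DOT.

The panel dialect is one row per measurement with columns
``protein, group, replicate, time_h, value``.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .lp_net import WeightedNetwork
from .network import BooleanNetwork, parse_boolnet
from .synthetic import SyntheticDesign, TimeSeriesPanel

PANEL_COLUMNS = ["protein", "group", "replicate", "time_h", "value"]


def write_panel_csv(panel: TimeSeriesPanel, path: str | Path) -> None:
    panel.data[PANEL_COLUMNS].to_csv(path, index=False)


def read_panel_csv(
    path: str | Path, design: SyntheticDesign | None = None
) -> TimeSeriesPanel:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns {missing}")
    if (df["value"] < 0).any():
        raise ValueError("panel contains negative values")
    if design is None:
        groups = sorted(df["group"].unique())
        control = "control" if "control" in groups else groups[0]
        design = SyntheticDesign(
            proteins=tuple(sorted(df["protein"].unique())),
            times=tuple(sorted(df["time_h"].unique())),
            replicates=int(df["replicate"].max()),
            groups=tuple(g for g in groups if g != control),
            control_group=control,
        )
    return TimeSeriesPanel(data=df[PANEL_COLUMNS].copy(), design=design)


def write_sif(network: WeightedNetwork, path: str | Path) -> None:
    """SIF: ``parent <sign> child`` per line, sign ``+``/``-`` by weight."""
    lines = [
        f"{p}\t{'+' if w > 0 else '-'}\t{c}" for p, c, w in network.links
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def weighted_to_graphml(network: WeightedNetwork) -> str:
    g = nx.DiGraph()
    for nd in network.nodes:
        g.add_node(nd, bias=float(network.biases.get(nd, 0.0)))
    for p, c, w in network.links:
        g.add_edge(p, c, weight=float(w), sign="+" if w > 0 else "-")
    buf = _io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode()


def write_graphml(network: WeightedNetwork, path: str | Path) -> None:
    Path(path).write_text(weighted_to_graphml(network))


def write_boolnet(bn: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(bn.to_boolnet())


def read_boolnet(path: str | Path) -> BooleanNetwork:
    return parse_boolnet(Path(path).read_text())


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
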