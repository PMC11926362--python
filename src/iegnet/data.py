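"""Core data types and file I/O for the IEG network pipeline.

The pipeline consumes a long-format nucleus-counts table (one row per
animal x brain region) produced by catFISH quantification: every DAPI
nucleus in a sampled field is classified as negative, H1a-positive only,
Arc-positive only, or double-labeled.  All downstream objects — activation
tables, interregional correlation matrices, thresholded functional
networks — are defined here together with readers/writers for the standard
exchange formats (CSV, YAML, GraphML, weighted edge lists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

GROUPS = ("home_cage", "vehicle", "iso")
MARKERS = ("H1a", "Arc", "double")

#: The 14 quantified brain areas, in canonical order.
DEFAULT_REGIONS = (
    "upDG", "lowDG", "pCA3", "dCA3", "pCA1", "dCA1",
    "gRSC", "dRSC",
    "Cg1", "PL", "IL",
    "PV", "LDDM", "LDVL",
)

DEFAULT_ANATOMICAL_GROUPS: Mapping[str, str] = {
    "upDG": "hippocampus", "lowDG": "hippocampus",
    "pCA3": "hippocampus", "dCA3": "hippocampus",
    "pCA1": "hippocampus", "dCA1": "hippocampus",
    "gRSC": "RSC", "dRSC": "RSC",
    "Cg1": "PFC", "PL": "PFC", "IL": "PFC",
    "PV": "thalamus", "LDDM": "thalamus", "LDVL": "thalamus",
}

COUNT_COLUMNS = (
    "animal_id", "group", "region",
    "n_total", "n_h1a_only", "n_arc_only", "n_double",
)


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


@dataclass(frozen=True)
class RegionPanel:
    """The ordered set of quantified brain regions and their anatomy.

    Parameters
    ----------
    region_ids
        Ordered region labels; matched case-sensitively against input
        tables.
    anatomical_group
        Map from region to one of ``hippocampus``, ``RSC``, ``PFC``,
        ``thalamus`` (or any custom grouping).
    """

    region_ids: tuple[str, ...] = DEFAULT_REGIONS
    anatomical_group: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANATOMICAL_GROUPS)
    )

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region ids must be unique")
        missing = [r for r in self.region_ids if r not in self.anatomical_group]
        if missing:
            raise ValidationError(f"regions without anatomical group: {missing}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def regions_in(self, anatomical: str) -> tuple[str, ...]:
        return tuple(
            r for r in self.region_ids if self.anatomical_group[r] == anatomical
        )

    @property
    def anatomical_groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.region_ids:
            seen.setdefault(self.anatomical_group[r], None)
        return tuple(seen)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "region_ids": list(self.region_ids),
            "anatomical_group": {r: self.anatomical_group[r] for r in self.region_ids},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionPanel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            region_ids=tuple(payload["region_ids"]),
            anatomical_group=dict(payload["anatomical_group"]),
        )


def default_panel() -> RegionPanel:
    """The 14-region panel used throughout: 6 hippocampal subfields,
    2 retrosplenial, 3 prefrontal and 3 thalamic areas."""
    return RegionPanel()


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-sample or multi-group contrast.

    ``direction`` is the sign of the effect in the second sample relative
    to the first (``increase`` / ``decrease`` / ``none``); ``arrow_code``
    encodes significance with one, two or three arrows for p < 0.05,
    < 0.01 and < 0.001, and ``=`` for p >= 0.05.
    """

    label: str
    statistic: float
    p_value: float
    direction: str
    arrow_code: str
    stat_name: str = "U"

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "none"):
            raise ValidationError(f"bad direction {self.direction!r}")


@dataclass
class CorrelationMatrix:
    """14x14 symmetric Pearson-r matrix for one group x marker.

    ``matrix`` is a region-labelled DataFrame; undefined entries (a region
    with zero across-animal variance) are NaN and are excluded from pooled
    r statistics downstream.
    """

    group: str
    marker: str
    matrix: pd.DataFrame
    n_animals: int

    def __post_init__(self) -> None:
        m = self.matrix
        if list(m.index) != list(m.columns):
            raise ValidationError("matrix rows and columns must agree")
        vals = m.to_numpy(float)
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValidationError("correlation matrix must be symmetric")
        off = vals[~np.eye(len(m), dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValidationError("off-diagonal r outside [-1, 1]")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    def upper_triangle(self, dropna: bool = True) -> pd.Series:
        """The 91 unordered-pair r values, indexed by (region_a, region_b)."""
        regions = self.regions
        idx, vals = [], []
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                idx.append((a, b))
                vals.append(self.matrix.at[a, b])
        s = pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))
        return s.dropna() if dropna else s

    def to_csv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, index_label="region")

    @classmethod
    def from_csv(
        cls, path: str | Path, group: str = "", marker: str = "", n_animals: int = 0
    ) -> "CorrelationMatrix":
        m = pd.read_csv(path, index_col=0)
        m.index.name = None
        return cls(group=group, marker=marker, matrix=m, n_animals=n_animals)


@dataclass
class FunctionalNetwork:
    """Thresholded weighted undirected functional network.

    Nodes are the 14 panel regions (kept even when isolated); an edge
    joins two regions whose across-animal correlation strictly exceeds
    ``threshold``, weighted by that r value.
    """

    group: str
    marker: str
    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        for a, b, w in self.graph.edges(data="weight"):
            if a == b:
                raise ValidationError("self-loops are not allowed")
            if w is None or not w > self.threshold:
                raise ValidationError(
                    f"edge ({a}, {b}) weight {w} does not exceed threshold"
                )

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        return sorted((min(a, b), max(a, b), w) for a, b, w in
                      self.graph.edges(data="weight"))


# ---------------------------------------------------------------------------
# Counts table I/O


def validate_counts(df: pd.DataFrame, panel: RegionPanel) -> pd.DataFrame:
    """Validate a long-format counts table against the data model.

    Raises :class:`ValidationError` naming the first offending row for:
    missing columns, unknown group or region, negative counts, duplicate
    (animal, region) cells, or label-class counts exceeding the total.
    """
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.loc[:, list(COUNT_COLUMNS)].copy()
    for col in ("n_total", "n_h1a_only", "n_arc_only", "n_double"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: column {col!r} must be a non-negative integer "
                f"(got {df[col].iloc[row]!r})"
            )
        df[col] = vals.astype(int)
    unknown_group = ~df["group"].isin(GROUPS)
    if unknown_group.any():
        row = int(np.flatnonzero(unknown_group.to_numpy())[0])
        raise ValidationError(f"row {row}: unknown group {df['group'].iloc[row]!r}")
    unknown_region = ~df["region"].isin(panel.region_ids)
    if unknown_region.any():
        row = int(np.flatnonzero(unknown_region.to_numpy())[0])
        raise ValidationError(f"row {row}: unknown region {df['region'].iloc[row]!r}")
    labeled = df["n_h1a_only"] + df["n_arc_only"] + df["n_double"]
    over = labeled > df["n_total"]
    if over.any():
        row = int(np.flatnonzero(over.to_numpy())[0])
        raise ValidationError(
            f"row {row}: label-class counts sum to {labeled.iloc[row]} "
            f"> n_total {df['n_total'].iloc[row]}"
        )
    dup = df.duplicated(subset=["animal_id", "region"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"row {row}: duplicate (animal, region) cell "
            f"({df['animal_id'].iloc[row]!r}, {df['region'].iloc[row]!r})"
        )
    return df.reset_index(drop=True)


def read_counts(path: str | Path, panel: RegionPanel | None = None) -> pd.DataFrame:
    """Read and validate a counts CSV/TSV (delimiter sniffed from header)."""
    panel = panel or default_panel()
    sep = "\t" if "\t" in Path(path).read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    return validate_counts(df, panel)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(COUNT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Network I/O


def write_network(net: FunctionalNetwork, path: str | Path) -> None:
    """Write a network as GraphML (``.graphml``) or a weighted edge list.

    The edge-list dialect is TSV with a commented metadata header; both
    formats round-trip node ids, edge weights and the threshold exactly
    (weights via repr, i.e. full float precision).
    """
    path = Path(path)
    if path.suffix == ".graphml":
        g = net.graph.copy()
        g.graph.update(
            group=net.group, marker=net.marker, threshold=float(net.threshold)
        )
        nx.write_graphml(g, path)
        return
    lines = [
        f"# group\t{net.group}",
        f"# marker\t{net.marker}",
        f"# threshold\t{float(net.threshold)!r}",
        "# nodes\t" + "\t".join(net.nodes),
    ]
    for a, b, w in net.edge_list():
        lines.append(f"{a}\t{b}\t{float(w)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> FunctionalNetwork:
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        meta = g.graph
        net = nx.Graph()
        net.add_nodes_from(g.nodes)
        for a, b, d in g.edges(data=True):
            net.add_edge(a, b, weight=float(d["weight"]))
        return FunctionalNetwork(
            group=meta.get("group", ""), marker=meta.get("marker", ""),
            graph=net, threshold=float(meta.get("threshold", float("-inf"))),
        )
    meta: dict[str, str] = {}
    nodes: list[str] = []
    g = nx.Graph()
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, rest = line[1:].strip().partition("\t")
            if key == "nodes":
                nodes = rest.split("\t")
            else:
                meta[key] = rest
            continue
        a, b, w = line.split("\t")
        g.add_edge(a, b, weight=float(w))
    g.add_nodes_from(nodes)
    ordered = nx.Graph()
    ordered.add_nodes_from(nodes or g.nodes)
    ordered.add_edges_from(g.edges(data=True))
    return FunctionalNetwork(
        group=meta.get("group", ""), marker=meta.get("marker", ""),
        graph=ordered, threshold=float(meta.get("threshold", "-inf")),
    )


def comparison_to_dict(res: ComparisonResult) -> dict:
    return {
        "label": res.label,
        "stat_name": res.stat_name,
        "statistic": None if np.isnan(res.statistic) else float(res.statistic),
        "p_value": None if np.isnan(res.p_value) else float(res.p_value),
        "direction": res.direction,
        "arrow_code": res.arrow_code,
    }


def write_comparisons(results: Iterable[ComparisonResult], path: str | Path) -> None:
    rows = [comparison_to_dict(r) for r in results]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2, ensure_ascii=False))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
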