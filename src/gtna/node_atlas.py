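"""Network node tables: ROI identities, hemispheres, and MNI sphere geometry.

The two packaged atlases describe the task-driven bimanual-coordination
networks: ``N1`` (21 ROIs active in both age groups) and ``N2`` (12 ROIs
over-activated in older adults).  Node tables define the vertex set and
vertex order of every graph built downstream; hemisphere labels come from
the table's Side column, never from the sign of the x coordinate, so
midline nodes (e.g. cerebellar vermis at x = +/-2) keep their printed
assignment.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "Node",
    "NodeTable",
    "load_node_table",
    "packaged_node_table",
    "sphere_voxel_indices",
    "interhemispheric_pairs",
    "NODE_TABLE_COLUMNS",
    "EXPECTED_NODE_COUNTS",
]

#: required columns of a node-table TSV, in emission order
NODE_TABLE_COLUMNS = [
    "network_id",
    "figure_index",
    "label",
    "brodmann",
    "hemisphere",
    "x",
    "y",
    "z",
]

#: node counts of the packaged atlases; enforced when loading these ids
EXPECTED_NODE_COUNTS = {"N1": 21, "N2": 12}

VALID_HEMISPHERES = {"L", "R"}


class NodeTableError(ValueError):
    """Raised when a node table fails validation."""


@dataclass(frozen=True)
class Node:
    """One ROI: a graph vertex with anatomical identity and MNI position."""

    label: str
    anatomical_name: str
    brodmann: str
    hemisphere: str
    mni_xyz: tuple[int, int, int]
    figure_index: int


@dataclass(frozen=True)
class NodeTable:
    """Ordered ROI set of one network; row order is graph vertex order."""

    network_id: str
    nodes: tuple[Node, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [node.label for node in self.nodes]

    @property
    def hemispheres(self) -> list[str]:
        return [node.hemisphere for node in self.nodes]

    def coordinates(self) -> list[tuple[int, int, int]]:
        return [node.mni_xyz for node in self.nodes]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "network_id": self.network_id,
                "figure_index": node.figure_index,
                "label": node.label,
                "brodmann": node.brodmann,
                "hemisphere": node.hemisphere,
                "x": node.mni_xyz[0],
                "y": node.mni_xyz[1],
                "z": node.mni_xyz[2],
            }
            for node in self.nodes
        ]
        return pd.DataFrame(rows, columns=NODE_TABLE_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        """Re-emit the table; round-trips bitwise with the packaged fixtures."""
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _anatomical_name(label: str) -> str:
    """Anatomical name is the label with any parenthetical qualifier removed."""
    head = label.split("(", 1)[0].strip()
    return head if head else label


def load_node_table(path: str | Path, network_id: str) -> NodeTable:
    """Load and validate a node-table TSV.

    Parameters
    ----------
    path
        Tab-separated file with header columns ``network_id, figure_index,
        label, brodmann, hemisphere, x, y, z``.
    network_id
        Identifier the file must declare on every row.  For the packaged
        atlas ids ``N1``/``N2`` the node count is additionally enforced
        (21 and 12 nodes respectively).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise NodeTableError(f"{path}: missing columns {missing}")

    nodes: list[Node] = []
    seen_indices: set[int] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        for col in NODE_TABLE_COLUMNS:
            if getattr(row, col) == "":
                raise NodeTableError(
                    f"{path} row {row_number}: missing value for '{col}'"
                )
        if row.network_id != network_id:
            raise NodeTableError(
                f"{path} row {row_number}: network_id '{row.network_id}' "
                f"does not match requested '{network_id}'"
            )
        if row.hemisphere not in VALID_HEMISPHERES:
            raise NodeTableError(
                f"{path} row {row_number}: hemisphere '{row.hemisphere}' "
                "not in {'L', 'R'}"
            )
        try:
            figure_index = int(row.figure_index)
            xyz = (int(row.x), int(row.y), int(row.z))
        except ValueError as exc:
            raise NodeTableError(f"{path} row {row_number}: {exc}") from exc
        if figure_index in seen_indices:
            raise NodeTableError(
                f"{path} row {row_number}: duplicate figure_index {figure_index}"
            )
        seen_indices.add(figure_index)
        nodes.append(
            Node(
                label=row.label,
                anatomical_name=_anatomical_name(row.label),
                brodmann=row.brodmann,
                hemisphere=row.hemisphere,
                mni_xyz=xyz,
                figure_index=figure_index,
            )
        )

    expected = EXPECTED_NODE_COUNTS.get(network_id)
    if expected is not None and len(nodes) != expected:
        raise NodeTableError(
            f"{path}: network {network_id} must have {expected} nodes, "
            f"found {len(nodes)}"
        )
    return NodeTable(network_id=network_id, nodes=tuple(nodes))


def packaged_node_table(network_id: str) -> NodeTable:
    """Load one of the packaged atlases (``N1`` or ``N2``)."""
    if network_id not in EXPECTED_NODE_COUNTS:
        raise NodeTableError(
            f"no packaged table for '{network_id}'; choose from "
            f"{sorted(EXPECTED_NODE_COUNTS)}"
        )
    resource = importlib.resources.files("gtna.data").joinpath(
        f"{network_id.lower()}_nodes.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return load_node_table(path, network_id)


def sphere_voxel_indices(
    center_mni: tuple[float, float, float],
    radius: float,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> set[tuple[int, int, int]]:
    """Voxel indices of an ROI sphere on a regular grid.

    A voxel with 0-based index ``(i, j, k)`` has its center at
    ``origin + index * voxel_size`` (mm).  The voxel belongs to the sphere
    iff its center lies within Euclidean distance ``radius`` of the sphere
    center (strict ``<=`` test on center-to-center distance).  The ROI
    spheres of the packaged atlases use radius 6 mm; the rasterisation grid
    is a free parameter because the analysis never fixed one.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if any(v <= 0 for v in voxel_size):
        raise ValueError(f"voxel sizes must be positive, got {voxel_size}")

    ranges = []
    for c, v, o in zip(center_mni, voxel_size, origin):
        lo = math.ceil((c - radius - o) / v)
        hi = math.floor((c + radius - o) / v)
        ranges.append(range(lo, hi + 1))

    r2 = radius * radius
    result: set[tuple[int, int, int]] = set()
    for idx in itertools.product(*ranges):
        d2 = sum(
            (o + i * v - c) ** 2
            for i, v, o, c in zip(idx, voxel_size, origin, center_mni)
        )
        if d2 <= r2 + 1e-12:
            result.add(idx)
    return result


def interhemispheric_pairs(table: NodeTable) -> set[tuple[int, int]]:
    """Unordered vertex-index pairs whose endpoints lie in opposite hemispheres.

    Returns every pair ``(i, j)`` with ``i < j`` (0-based positions in the
    table's vertex order) such that the two nodes carry different hemisphere
    labels.  The size of the set is always ``n_L * n_R``.
    """
    hemis = table.hemispheres
    return {
        (i, j)
        for i, j in itertools.combinations(range(len(hemis)), 2)
        if hemis[i] != hemis[j]
    }
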