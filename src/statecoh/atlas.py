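"""Node atlas: labelled brain locations defining the analysis node set.

An atlas is a table of nodes with an integer id, an anatomical name, a
hemisphere and Talairach-Tournoux coordinates in mm.  Node order defines the
node axis of all tensors and the lexicographic node-pair enumeration.

The packaged 80-node fixture carries the eight published cerebellar nodes
(ids 73-80: dentate nuclei, posterior lobes, Crus I/II, both hemispheres)
with their printed Talairach-Tournoux coordinates; the 72 cortical nodes are
*synthetic placeholders* (grid-layout coordinates, generic names) standing in
for coordinates published elsewhere — replace them with a real atlas file for
any anatomical interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["NodeAtlas", "load_atlas", "default_atlas"]

_COLUMNS = ["node_id", "name", "hemisphere", "x_mm", "y_mm", "z_mm"]


@dataclass
class NodeAtlas:
    """Ordered node table; row position i is tensor node index i."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas missing columns: {missing}")
        if self.table["node_id"].duplicated().any():
            dups = self.table.loc[self.table["node_id"].duplicated(), "node_id"]
            raise ValueError(f"duplicate node ids: {sorted(set(dups))}")
        for c in ("x_mm", "y_mm", "z_mm"):
            if not pd.api.types.is_numeric_dtype(self.table[c]):
                raise ValueError(f"non-numeric coordinates in column {c}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def by_index(self, i: int) -> pd.Series:
        """Node at tensor position ``i`` (0-based row order)."""
        return self.table.iloc[i]

    def by_id(self, node_id: int) -> pd.Series:
        sel = self.table[self.table["node_id"] == node_id]
        if sel.empty:
            raise KeyError(f"no node with id {node_id}")
        return sel.iloc[0]

    def head(self, n: int) -> "NodeAtlas":
        """Atlas restricted to the first ``n`` nodes (for reduced node counts)."""
        if n > len(self.table):
            raise ValueError(f"atlas has only {len(self.table)} nodes, need {n}")
        return NodeAtlas(self.table.iloc[:n].copy())

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_atlas(path: str | Path) -> NodeAtlas:
    """Read a tab-separated atlas (node_id, name, hemisphere, x_mm, y_mm, z_mm)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty atlas file: {path}") from exc
    if table.empty:
        raise ValueError(f"atlas file has no rows: {path}")
    try:
        return NodeAtlas(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def default_atlas() -> NodeAtlas:
    """The packaged 80-node fixture (synthetic cortical placeholders)."""
    ref = resources.files("statecoh.data").joinpath("atlas_80node_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_atlas(path)
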