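"""Readers and writers for the formats the pipeline consumes.

No science lives here: alignments (FASTA), rooted trees (Newick),
occurrence tables (CSV) and gridded environmental layers (ESRI ASCII)
are parsed into plain in-memory containers used by every other module.

Conventions
-----------
* Alignment metadata travels in the FASTA id as pipe-separated fields
  ``id|region|population``; a sidecar CSV (columns id,region,population)
  overrides it.
* Alignment columns are 0-based; gap ranges are half-open ``[start, end)``.
* Grid coordinates are abstract planar map units; no CRS handling.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "PhyloTree",
    "GridStack",
    "OccurrenceTable",
    "load_alignment",
    "save_alignment",
    "load_tree",
    "save_tree",
    "load_grid",
    "save_grid",
    "load_grid_stack",
    "load_occurrences",
    "save_occurrences",
]

IUPAC = set("ACGTRYSWKMBDHVN-")

#: bases matched by each (possibly ambiguous) nucleotide symbol
AMBIGUITY = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass
class Alignment:
    """A multiple sequence alignment with per-sequence geographic metadata.

    ``meta[id]`` maps to a dict with keys ``region`` and optionally
    ``population``; unknown metadata is stored as empty strings.
    """

    ids: list[str]
    seqs: list[str]
    meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not self.seqs or not self.seqs[0]:
            raise ValueError("empty alignment")
        length = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise ValueError(
                    f"ragged alignment: sequence {sid!r} has length {len(s)}, "
                    f"expected {length}"
                )
        for sid in self.ids:
            self.meta.setdefault(sid, {"region": "", "population": ""})

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def regions(self) -> set[str]:
        return {m.get("region", "") for m in self.meta.values()} - {""}


def _parse_meta_from_id(raw_id: str) -> tuple[str, dict[str, str]]:
    parts = raw_id.split("|")
    sid = parts[0]
    meta = {"region": "", "population": ""}
    if len(parts) > 1:
        meta["region"] = parts[1]
    if len(parts) > 2:
        meta["population"] = parts[2]
    return sid, meta


def load_alignment(path: str | Path, meta_csv: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and gap characters (``-``, ``.``, ``~``)
    normalized to ``-``.  Metadata is parsed from pipe-separated id
    suffixes (``id|region|population``); *meta_csv*, if given, overrides
    it per id.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unparseable FASTA file: {path}")
    ids, seqs, meta = [], [], {}
    for rec in records:
        sid, m = _parse_meta_from_id(rec.id)
        seq = str(rec.seq).upper().replace(".", "-").replace("~", "-")
        ids.append(sid)
        seqs.append(seq)
        meta[sid] = m
    if meta_csv is not None:
        table = pd.read_csv(meta_csv, dtype=str).fillna("")
        for _, row in table.iterrows():
            if row["id"] in meta:
                meta[row["id"]]["region"] = row.get("region", "")
                if "population" in row:
                    meta[row["id"]]["population"] = row["population"]
    return Alignment(ids=ids, seqs=seqs, meta=meta)


def save_alignment(aln: Alignment, path: str | Path) -> None:
    """Write FASTA with metadata embedded as ``id|region|population``."""
    records = []
    for sid, seq in zip(aln.ids, aln.seqs):
        m = aln.meta.get(sid, {})
        label = sid
        if m.get("region") or m.get("population"):
            label = f"{sid}|{m.get('region', '')}|{m.get('population', '')}"
        records.append(SeqRecord(Seq(seq), id=label, description=""))
    SeqIO.write(records, str(path), "fasta-2line")


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, thinly wrapping dendropy.

    Internal node labels that parse as floats are exposed as support
    values in [0, 1].  Polytomies are preserved.
    """

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def support(self, node: dendropy.Node) -> float | None:
        if node.label is not None:
            try:
                return float(node.label)
            except ValueError:
                return None
        return None

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def load_tree(path_or_string: str | Path) -> PhyloTree:
    """Read a single rooted Newick tree (path or literal string)."""
    text = str(path_or_string)
    if not text.lstrip().startswith("("):
        text = Path(path_or_string).read_text()
    n_trees = text.count(";")
    if n_trees > 1:
        raise ValueError(f"expected a single Newick tree, found {n_trees}")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc
    if not any(True for _ in tree.leaf_node_iter()):
        raise ValueError("tree has no tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return PhyloTree(tree=tree)


def save_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


class GridStack:
    """A stack of co-registered 2-D environmental layers.

    All layers share shape, nodata mask, cell size and origin (the x, y of
    the lower-left cell corner).  The mask is the union of per-layer
    nodata masks; values under the mask are undefined.
    """

    def __init__(
        self,
        layers: Mapping[str, np.ndarray],
        mask: np.ndarray | None = None,
        cell_size: float = 1.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> None:
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        if not names:
            raise ValueError("empty grid stack")
        shapes = {name: np.asarray(arr).shape for name, arr in layers.items()}
        if len(set(shapes.values())) != 1:
            bad = ", ".join(f"{k}:{v}" for k, v in sorted(shapes.items()))
            raise ValueError(f"layer shape mismatch: {bad}")
        self.names: list[str] = names
        self.arrays: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=float).copy() for k, v in layers.items()
        }
        shape = next(iter(self.arrays.values())).shape
        union = np.zeros(shape, dtype=bool)
        for arr in self.arrays.values():
            union |= ~np.isfinite(arr)
        if mask is not None:
            union |= np.asarray(mask, dtype=bool)
        self.mask: np.ndarray = union
        self.cell_size = float(cell_size)
        self.origin = (float(origin[0]), float(origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.arrays.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def __contains__(self, name: str) -> bool:
        return name in self.arrays

    def subset(self, names: Sequence[str]) -> "GridStack":
        missing = [n for n in names if n not in self.arrays]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return GridStack(
            {n: self.arrays[n] for n in names},
            mask=self.mask, cell_size=self.cell_size, origin=self.origin,
        )

    def valid_values(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_unmasked, n_layers) array of values at unmasked cells."""
        names = list(names) if names is not None else self.names
        cols = [self.arrays[n][~self.mask] for n in names]
        return np.column_stack(cols)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y).

        Row 0 is the top row, matching array layout; y grows upward from
        the origin at the lower-left corner.
        """
        nrow, _ = self.shape
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size))
        row = nrow - 1 - row_from_bottom
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def extract(self, name: str, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        arr = self.arrays[name]
        vals = np.empty(len(xs))
        for i, (x, y) in enumerate(zip(xs, ys)):
            r, c = self.cell_of(x, y)
            vals[i] = arr[r, c]
        return vals


NODATA = -9999.0


def save_grid(name_or_grid, path: str | Path, *, stack: GridStack | None = None) -> None:
    """Write one layer as an ESRI ASCII grid (bit-exact round trip).

    Accepts either ``save_grid(stack, path)`` for a single-layer stack or
    ``save_grid(name, path, stack=stack)``.
    """
    if isinstance(name_or_grid, GridStack):
        stack = name_or_grid
        if len(stack.names) != 1:
            raise ValueError("save_grid on a multi-layer stack needs a layer name")
        name = stack.names[0]
    else:
        name = name_or_grid
        if stack is None:
            raise ValueError("stack required when saving by layer name")
    arr = stack.arrays[name].copy()
    arr[stack.mask] = NODATA
    nrow, ncol = arr.shape
    buf = _io.StringIO()
    buf.write(f"ncols {ncol}\n")
    buf.write(f"nrows {nrow}\n")
    buf.write(f"xllcorner {stack.origin[0]!r}\n")
    buf.write(f"yllcorner {stack.origin[1]!r}\n")
    buf.write(f"cellsize {stack.cell_size!r}\n")
    buf.write(f"NODATA_value {NODATA!r}\n")
    for row in arr:
        buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def load_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Read one ESRI ASCII grid -> (values, nodata mask, cellsize, origin)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.array(
        [[float(v) for v in line.split()] for line in lines[i:] if line.strip()]
    )
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid body shape {values.shape} disagrees with header")
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return values, mask, header.get("cellsize", 1.0), origin


def load_grid_stack(paths: Iterable[str | Path] | str | Path) -> GridStack:
    """Read several ``.asc`` layers (or a directory of them) into a stack.

    Layer names come from file stems.  The stack mask is the union of
    per-layer nodata masks.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.asc"))
    paths = [Path(p) for p in paths]  # type: ignore[union-attr]
    if not paths:
        raise ValueError("no grid layers found")
    layers: dict[str, np.ndarray] = {}
    masks = []
    cell, origin = 1.0, (0.0, 0.0)
    shapes = {}
    for p in paths:
        vals, mask, cell, origin = load_grid(p)
        layers[p.stem] = vals
        masks.append(mask)
        shapes[p.stem] = vals.shape
    if len(set(shapes.values())) != 1:
        bad = ", ".join(f"{k}:{v}" for k, v in sorted(shapes.items()))
        raise ValueError(f"layer shape mismatch: {bad}")
    union = np.zeros(next(iter(shapes.values())), dtype=bool)
    for m in masks:
        union |= m
    return GridStack(layers, mask=union, cell_size=cell, origin=origin)


@dataclass
class OccurrenceTable:
    """Point records (id, x, y) flagged as presence or background."""

    table: pd.DataFrame
    role: str = "presence"

    def __post_init__(self) -> None:
        required = {"id", "x", "y"}
        if not required <= set(self.table.columns):
            raise ValueError(f"occurrence table needs columns {sorted(required)}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate occurrence ids")
        if self.role not in {"presence", "background"}:
            raise ValueError(f"bad role {self.role!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)


def load_occurrences(path: str | Path, role: str = "presence") -> OccurrenceTable:
    return OccurrenceTable(pd.read_csv(path), role=role)


def save_occurrences(occ: OccurrenceTable, path: str | Path) -> None:
    occ.table.to_csv(path, index=False)
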