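"""Weighted connectome container and file I/O.

A connectome is an undirected simple graph over brain regions (parcellation
nodes). Each edge carries two physical weights obtained from diffusion-MRI
tractography or from a growth simulation:

``tract_length``
    Average streamline length between the two regions, in mm (simulated
    connectomes use dimensionless unit-ball coordinates).
``tract_density``
    Streamline count between the two regions; at least 1 on any existing edge.

Two on-disk dialects are supported: a TSV edge list with columns
``node_u, node_v, tract_length, tract_density``, and a pair of symmetric
square CSV matrices (length matrix + density matrix) in which a zero entry
means "no edge". GraphML export is available for interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "ConnectomeError",
    "DialectError",
    "ValidationError",
    "read_connectome",
    "write_connectome",
    "prune_isolates",
    "summarize",
]

EDGE_LIST_COLUMNS = ("node_u", "node_v", "tract_length", "tract_density")

#: absolute tolerance for the symmetry check on matrix-pair inputs
SYMMETRY_ATOL = 1e-9


class ConnectomeError(ValueError):
    """Base class for connectome construction/parsing failures."""


class DialectError(ConnectomeError):
    """Malformed file in one of the supported dialects."""


class ValidationError(ConnectomeError):
    """Connectome violating a structural or weight invariant."""


@dataclass
class Connectome:
    """Undirected simple graph with per-edge tract length and density.

    Parameters
    ----------
    node_ids
        Opaque node labels; internal indices are assigned in this order
        (first-appearance order for files), which fixes all downstream
        tie-breaking and serialization.
    edges
        Mapping from index pairs ``(i, j)`` with ``i < j`` to
        ``(tract_length, tract_density)``.
    coordinates
        Optional ``(N, 3)`` array of node coordinates (mm or simulation
        units); carried through by simulators, ignored by the TSV dialect.
    """

    node_ids: list[str]
    edges: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._index = {label: i for i, label in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValidationError("duplicate node labels")
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.node_ids)
        for (i, j), (length, density) in self.edges.items():
            if i == j:
                raise ValidationError(f"self-loop on node index {i}")
            if not (0 <= i < j < n):
                raise ValidationError(f"edge ({i}, {j}) out of range or unordered")
            if not length > 0:
                raise ValidationError(f"non-positive tract_length {length!r} on ({i}, {j})")
            if not density >= 1:
                raise ValidationError(f"tract_density {density!r} < 1 on ({i}, {j})")
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (n, 3):
                raise ValidationError(f"coordinates shape {coords.shape} != ({n}, 3)")
            self.coordinates = coords

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes if self.n_nodes else 0.0

    def index_of(self, label: str) -> int:
        return self._index[label]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(u, v, tract_length, tract_density)`` as flat arrays."""
        if not self.edges:
            empty = np.empty(0)
            return empty.astype(np.int64), empty.astype(np.int64), empty, empty
        pairs = np.array(sorted(self.edges), dtype=np.int64)
        lengths = np.array([self.edges[tuple(p)][0] for p in pairs])
        densities = np.array([self.edges[tuple(p)][1] for p in pairs])
        return pairs[:, 0], pairs[:, 1], lengths, densities

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, label in enumerate(self.node_ids):
            attrs = {}
            if self.coordinates is not None:
                x, y, z = self.coordinates[i]
                attrs = {"x": float(x), "y": float(y), "z": float(z)}
            g.add_node(label, **attrs)
        for (i, j), (length, density) in self.edges.items():
            g.add_edge(
                self.node_ids[i],
                self.node_ids[j],
                tract_length=float(length),
                tract_density=float(density),
            )
        return g

    @classmethod
    def from_edge_records(
        cls,
        records: Iterable[tuple[str, str, float, float]],
        coordinates: Mapping[str, Sequence[float]] | None = None,
    ) -> "Connectome":
        """Build from ``(u, v, length, density)`` tuples, labels in first-appearance order."""
        node_ids: list[str] = []
        index: dict[str, int] = {}
        edges: dict[tuple[int, int], tuple[float, float]] = {}
        for u, v, length, density in records:
            for label in (u, v):
                if label not in index:
                    index[label] = len(node_ids)
                    node_ids.append(label)
            i, j = index[u], index[v]
            if i == j:
                raise ValidationError(f"self-loop on node {u!r}")
            key = (i, j) if i < j else (j, i)
            if key in edges:
                raise DialectError(f"duplicate edge between {u!r} and {v!r}")
            edges[key] = (float(length), float(density))
        coords = None
        if coordinates is not None:
            coords = np.array([coordinates[label] for label in node_ids], dtype=float)
        return cls(node_ids=node_ids, edges=edges, coordinates=coords)

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        return nx.is_connected(self.to_networkx())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_connectome(path, format: str = "edge_list") -> Connectome:
    """Read a connectome file.

    ``format="edge_list"`` expects a single TSV path; ``format="matrix_pair"``
    expects ``path`` to be a ``(length_csv, density_csv)`` pair of symmetric
    square CSV matrices with matching node labels, in which a zero entry in
    both matrices means "no edge". Only the upper triangle is consulted after
    the symmetry check (absolute tolerance 1e-9).
    """
    if format == "edge_list":
        return _read_edge_list(Path(path))
    if format == "matrix_pair":
        try:
            length_path, density_path = path
        except (TypeError, ValueError) as exc:
            raise DialectError(
                "matrix_pair expects a (length_csv, density_csv) pair of paths"
            ) from exc
        return _read_matrix_pair(Path(length_path), Path(density_path))
    raise ValueError(f"unknown format {format!r}")


def _read_edge_list(path: Path) -> Connectome:
    df = pd.read_csv(path, sep="\t", dtype={"node_u": str, "node_v": str})
    if tuple(df.columns) != EDGE_LIST_COLUMNS:
        raise DialectError(
            f"edge list must have columns {EDGE_LIST_COLUMNS}, got {tuple(df.columns)}"
        )
    records = (
        (row.node_u, row.node_v, row.tract_length, row.tract_density)
        for row in df.itertuples(index=False)
    )
    return Connectome.from_edge_records(records)


def _load_square_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy(dtype=float)
    labels = [str(c) for c in df.columns]
    if mat.shape[0] != mat.shape[1]:
        raise DialectError(f"{path}: matrix is {mat.shape}, not square")
    if [str(r) for r in df.index] != labels:
        raise DialectError(f"{path}: row and column labels differ")
    if not np.allclose(mat, mat.T, rtol=0.0, atol=SYMMETRY_ATOL):
        raise DialectError(f"{path}: matrix not symmetric to {SYMMETRY_ATOL:g}")
    if np.any(mat < 0):
        raise ValidationError(f"{path}: negative weight")
    return labels, mat


def _read_matrix_pair(length_path: Path, density_path: Path) -> Connectome:
    labels_l, lengths = _load_square_matrix(length_path)
    labels_d, densities = _load_square_matrix(density_path)
    if labels_l != labels_d:
        raise DialectError("length and density matrices have different node labels")
    if lengths.shape != densities.shape:
        raise DialectError("length and density matrices have different shapes")
    iu, ju = np.triu_indices(len(labels_l), k=1)
    edges: dict[tuple[int, int], tuple[float, float]] = {}
    for i, j in zip(iu, ju):
        length, density = lengths[i, j], densities[i, j]
        if (length > 0) != (density > 0):
            raise DialectError(
                f"edge ({labels_l[i]}, {labels_l[j]}) present in one matrix only"
            )
        if density > 0:
            edges[(int(i), int(j))] = (float(length), float(density))
    return Connectome(node_ids=list(labels_l), edges=edges)


def write_connectome(c: Connectome, path, format: str = "edge_list") -> None:
    """Write a connectome; ``read_connectome(write(c))`` round-trips weights to 1e-12."""
    if format == "edge_list":
        _write_edge_list(c, Path(path))
    elif format == "matrix_pair":
        try:
            length_path, density_path = path
        except (TypeError, ValueError) as exc:
            raise DialectError(
                "matrix_pair expects a (length_csv, density_csv) pair of paths"
            ) from exc
        _write_matrix_pair(c, Path(length_path), Path(density_path))
    elif format == "graphml":
        nx.write_graphml(c.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_edge_list(c: Connectome, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_LIST_COLUMNS) + "\n")
        for (i, j) in sorted(c.edges):
            length, density = c.edges[(i, j)]
            fh.write(f"{c.node_ids[i]}\t{c.node_ids[j]}\t{length!r}\t{density!r}\n")


def _write_matrix_pair(c: Connectome, length_path: Path, density_path: Path) -> None:
    n = c.n_nodes
    lengths = np.zeros((n, n))
    densities = np.zeros((n, n))
    for (i, j), (length, density) in c.edges.items():
        lengths[i, j] = lengths[j, i] = length
        densities[i, j] = densities[j, i] = density
    for mat, path in ((lengths, length_path), (densities, density_path)):
        pd.DataFrame(mat, index=c.node_ids, columns=c.node_ids).to_csv(
            path, float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# pruning and summaries
# ---------------------------------------------------------------------------

def prune_isolates(c: Connectome) -> Connectome:
    """Drop zero-degree nodes (regions forming no tracts).

    The attack normalization P = 1 with all edges present presumes a single
    connected component; if the pruned graph is still disconnected a warning
    is emitted but the connectome is returned as-is (the attack remains
    well defined).
    """
    deg = c.degrees()
    keep = np.flatnonzero(deg > 0) if c.n_edges else np.array([], dtype=int)
    if c.n_edges == 0 and c.n_nodes:
        warnings.warn("connectome has no edges; all nodes are isolates", stacklevel=2)
    old_to_new = {int(old): new for new, old in enumerate(keep)}
    node_ids = [c.node_ids[int(old)] for old in keep]
    edges = {
        (old_to_new[i], old_to_new[j]): w for (i, j), w in c.edges.items()
    }
    coords = c.coordinates[keep] if c.coordinates is not None else None
    pruned = Connectome(node_ids=node_ids, edges=edges, coordinates=coords)
    if pruned.n_nodes > 1 and not pruned.is_connected():
        warnings.warn(
            "pruned connectome is not a single connected component; "
            "P < 1 even with all edges present",
            stacklevel=2,
        )
    return pruned


def summarize(c: Connectome) -> dict:
    """Node count N, edge count E, and mean degree 2E/N."""
    return {"N": c.n_nodes, "E": c.n_edges, "mean_degree": c.mean_degree}
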