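"""Weighted connectome data model, I/O, thresholding and group averaging.

A connectome is a symmetric, zero-diagonal matrix of nonnegative integer
streamline counts over the nodes of a :class:`~pediconn.nodes.NodeTable`.
Matrices are stored dense (the default scheme is 68x68); an edge-list
format is supported for interchange.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nodes import NodeTable

__all__ = [
    "Connectome",
    "Subject",
    "Cohort",
    "load_connectome",
    "save_connectome",
    "apply_streamline_threshold",
    "group_average_at_sparsity",
]


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted, undirected structural network.

    ``weights[i, j]`` is the streamline count between regions ``i`` and
    ``j`` of ``node_table``; the matrix is symmetric with a zero
    diagonal and nonnegative entries.
    """

    weights: np.ndarray
    node_table: NodeTable
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        n = len(self.node_table)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} nodes")
        if np.any(w < 0):
            raise ValueError("negative edge weights are not allowed")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        if not np.array_equal(w, w.T):
            raise ValueError("connectivity matrix must be symmetric")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero undirected edges (symbol K)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return dataclasses.replace(self, weights=weights)


@dataclass(frozen=True)
class Subject:
    """Cohort member: identifier, diagnostic group, age, clinical scores.

    ``group`` is ``"TD"`` (typically developing control) or ``"ASD"``.
    Clinical scores (ABC, ADI-R, CARS, CABS, ...) are raw values and are
    typically present only for the clinical group.
    """

    subject_id: str
    group: str
    age: float
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("TD", "ASD"):
            raise ValueError(f"group must be 'TD' or 'ASD', got {self.group!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")


@dataclass
class Cohort:
    """Subjects plus their connectomes, all on one shared node table."""

    subjects: list[Subject]
    connectomes: dict[str, Connectome]
    node_table: NodeTable

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")
        missing = [i for i in ids if i not in self.connectomes]
        if missing:
            raise ValueError(f"missing connectomes for subjects: {missing}")
        for sid, conn in self.connectomes.items():
            if conn.node_table != self.node_table:
                raise ValueError(f"connectome {sid} uses a different node table")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return np.asarray([s.age for s in self.subjects], dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return np.asarray([s.group for s in self.subjects])

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, N, N) array of weights in subject order."""
        return np.stack(
            [self.connectomes[s.subject_id].weights for s in self.subjects]
        ).astype(float)

    def subset(self, group: str) -> "Cohort":
        subs = [s for s in self.subjects if s.group == group]
        return Cohort(
            subjects=subs,
            connectomes={s.subject_id: self.connectomes[s.subject_id] for s in subs},
            node_table=self.node_table,
        )


# ---------------------------------------------------------------------------
# I/O


def _load_dense(df: pd.DataFrame, node_table: NodeTable) -> np.ndarray:
    header = list(df.columns[1:])
    rows = list(df.iloc[:, 0])
    expected = list(node_table.abbreviations)
    if header != expected or rows != expected:
        raise ValueError(
            "dense matrix row/column labels do not match the node table "
            f"(first mismatch among {set(header) ^ set(expected) or set(rows) ^ set(expected)})"
        )
    w = df.iloc[:, 1:].to_numpy()
    if not np.array_equal(w, w.T):
        raise ValueError("dense connectivity matrix is asymmetric")
    return w


def _load_edge_list(df: pd.DataFrame, node_table: NodeTable) -> np.ndarray:
    n = len(node_table)
    w = np.zeros((n, n), dtype=np.int64)
    seen: set[tuple[int, int]] = set()
    for node_a, node_b, count in df.itertuples(index=False):
        i, j = node_table.index_of(str(node_a)), node_table.index_of(str(node_b))
        if i == j:
            raise ValueError(f"self-edge on node {node_a!r}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {node_a}-{node_b}")
        seen.add(key)
        w[i, j] = w[j, i] = count
    return w


def load_connectome(path, node_table: NodeTable, subject_id: str | None = None) -> Connectome:
    """Load a connectome from a dense labelled matrix or 3-column edge list.

    Dense format: TSV/CSV whose first row and first column hold the node
    abbreviations in node-table order.  Edge list: columns
    ``node_a, node_b, count``, one row per undirected pair; absent pairs
    are zero.  Unknown labels, asymmetry, duplicate pairs and negative
    counts are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["node_a", "node_b", "count"] and len(cols) == 3:
        w = _load_edge_list(df, node_table)
    else:
        w = _load_dense(df, node_table)
    return Connectome(
        weights=w,
        node_table=node_table,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def save_connectome(connectome: Connectome, path) -> None:
    """Write the dense labelled-matrix TSV/CSV form (integer cells)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    abbrs = list(connectome.node_table.abbreviations)
    df = pd.DataFrame(connectome.weights, columns=abbrs)
    df.insert(0, "node", abbrs)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Thresholding


def apply_streamline_threshold(connectome: Connectome, min_count: int = 5) -> Connectome:
    """Zero out edges with fewer than ``min_count`` streamlines.

    The threshold removes spurious low-count connections; an edge whose
    weight equals ``min_count`` exactly is kept ("minimum" denotes the
    smallest admissible value).  Idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    w = connectome.weights.copy()
    w[w < min_count] = 0
    return connectome.with_weights(w)


def group_average_at_sparsity(connectomes: list[Connectome], sparsity: float) -> Connectome:
    """Element-wise mean network, sparsified to the top fraction of edges.

    Keeps the ``round(sparsity * N*(N-1)/2)`` strongest undirected edges
    of the mean matrix and zeroes the rest.  Ties are broken by
    lexicographic (i, j) order so the output is reproducible.  Used to
    build the representative group network (e.g. at 15% sparsity) on
    which hubs are identified.
    """
    if not connectomes:
        raise ValueError("need at least one connectome to average")
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    table = connectomes[0].node_table
    for c in connectomes[1:]:
        if c.node_table != table:
            raise ValueError("all connectomes must share one node table")
    mean = np.mean([c.weights for c in connectomes], axis=0)
    n = mean.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k_keep = int(round(sparsity * n * (n - 1) / 2))
    # stable sort on (-weight, i, j): heaviest first, lexicographic ties
    order = np.lexsort((ju, iu, -mean[iu, ju]))
    keep = order[:k_keep]
    out = np.zeros_like(mean)
    out[iu[keep], ju[keep]] = mean[iu[keep], ju[keep]]
    out = out + out.T
    return Connectome(weights=out, node_table=table, subject_id="group_average")
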