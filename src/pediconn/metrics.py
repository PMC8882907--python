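"""Weighted graph measures for structural connectomes.

All measures use the standard weighted-connectome convention that a
stronger connection is a shorter one: each edge of weight ``w`` has
length ``d = 1/w``, and shortest paths are computed on those lengths.
Efficiencies are means of inverse shortest-path lengths, so a
disconnected pair contributes zero; the characteristic path length
averages finite lengths only.  These conventions keep every measure
defined on thresholded single-subject networks, which are frequently
disconnected.

Measures
--------
- network strength: mean nodal strength ``S_i = sum_j w_ij``
- global efficiency ``Eg``: mean of ``1/L_ij`` over ordered pairs
- local efficiency ``Eloc``: mean over nodes of the global efficiency of
  the subgraph induced by each node's neighbours
- characteristic path length ``Lp``: mean finite ``L_ij``
- nodal efficiency ``E_nodal(i)``: mean of ``1/L_ij`` over ``j != i``
- hubs: nodes whose nodal efficiency is at least one standard deviation
  above the across-node mean
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import Cohort, Connectome, group_average_at_sparsity

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "HubSet",
    "shortest_path_matrix",
    "global_efficiency",
    "local_efficiency",
    "characteristic_path_length",
    "network_strength",
    "nodal_efficiency",
    "compute_global_metrics",
    "compute_nodal_metrics",
    "identify_hubs",
    "group_hubs",
    "global_metrics_table",
    "nodal_metrics_table",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network scalars for one subject."""

    strength: float
    eg: float
    eloc: float
    lp: float

    def as_dict(self) -> dict[str, float]:
        return {"strength": self.strength, "Eg": self.eg, "Eloc": self.eloc, "Lp": self.lp}


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node vectors for one subject."""

    e_nodal: np.ndarray
    strength: np.ndarray


@dataclass(frozen=True)
class HubSet:
    """Nodes passing the mean + 1 SD nodal-efficiency rule."""

    hubs: tuple[int, ...]
    threshold: float


def _weights(connectome: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(connectome, Connectome):
        return connectome.weights.astype(float)
    return np.asarray(connectome, dtype=float)


def shortest_path_matrix(connectome: Connectome | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths with edge length 1/w.

    ``L[i, i] = 0``; unreachable pairs are ``+inf``.
    """
    w = _weights(connectome)
    n = w.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)


def _efficiency_from_lengths(lengths: np.ndarray) -> float:
    n = lengths.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(lengths)
    finite = off & np.isfinite(lengths) & (lengths > 0)
    inv[finite] = 1.0 / lengths[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(connectome: Connectome | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs (Eg)."""
    return _efficiency_from_lengths(shortest_path_matrix(connectome))


def local_efficiency(connectome: Connectome | np.ndarray) -> float:
    """Mean over nodes of Eg on each node's neighbour-induced subgraph (Eloc).

    The subgraph of node ``i`` contains the neighbours of ``i`` (not
    ``i`` itself) and the edges among them, with their original weights;
    a subgraph of fewer than two nodes has efficiency zero.
    """
    w = _weights(connectome)
    n = w.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        total += global_efficiency(w[np.ix_(nbrs, nbrs)])
    return total / n


def characteristic_path_length(connectome: Connectome | np.ndarray) -> float:
    """Mean finite shortest-path length over ordered pairs (Lp).

    Returns ``nan`` when no pair of nodes is connected (empty network);
    callers should treat that as undefined.
    """
    lengths = shortest_path_matrix(connectome)
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = lengths[off & np.isfinite(lengths)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def network_strength(connectome: Connectome | np.ndarray) -> float:
    """Mean nodal strength (1/N) * sum_i S_i with S_i = sum_j w_ij."""
    w = _weights(connectome)
    if w.shape[0] == 0:
        return 0.0
    return float(w.sum(axis=1).mean())


def nodal_efficiency(connectome: Connectome | np.ndarray) -> np.ndarray:
    """Per-node efficiency E_nodal(i) = mean_j 1/L_ij (j != i).

    The across-node mean of E_nodal equals Eg by construction.
    """
    lengths = shortest_path_matrix(connectome)
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(lengths)
    finite = off & np.isfinite(lengths) & (lengths > 0)
    inv[finite] = 1.0 / lengths[finite]
    return inv.sum(axis=1) / (n - 1)


def compute_global_metrics(connectome: Connectome | np.ndarray) -> GlobalMetrics:
    return GlobalMetrics(
        strength=network_strength(connectome),
        eg=global_efficiency(connectome),
        eloc=local_efficiency(connectome),
        lp=characteristic_path_length(connectome),
    )


def compute_nodal_metrics(connectome: Connectome | np.ndarray) -> NodalMetrics:
    w = _weights(connectome)
    return NodalMetrics(e_nodal=nodal_efficiency(w), strength=w.sum(axis=1))


def identify_hubs(nodal: NodalMetrics | np.ndarray) -> HubSet:
    """Hub rule: E_nodal at least one sample SD above the across-node mean.

    Uses the sample standard deviation (divisor N-1) and an inclusive
    threshold.  Degenerate all-equal input has SD zero, so every node
    passes; callers working with such networks should not interpret the
    result.
    """
    e = nodal.e_nodal if isinstance(nodal, NodalMetrics) else np.asarray(nodal, dtype=float)
    if e.size < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    threshold = float(e.mean() + e.std(ddof=1))
    return HubSet(hubs=tuple(int(i) for i in np.flatnonzero(e >= threshold)), threshold=threshold)


def group_hubs(cohort: Cohort, group: str, sparsity: float = 0.15) -> HubSet:
    """Hubs of a group's representative network.

    The group network is the element-wise mean of the group's matrices
    sparsified to the given fraction of strongest edges (default 15%),
    and hubs are identified on its nodal-efficiency profile.
    """
    sub = cohort.subset(group)
    avg = group_average_at_sparsity(
        [sub.connectomes[s.subject_id] for s in sub.subjects], sparsity
    )
    return identify_hubs(compute_nodal_metrics(avg))


def global_metrics_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-subject global measures: one row per subject."""
    rows = []
    for s in cohort.subjects:
        gm = compute_global_metrics(cohort.connectomes[s.subject_id])
        rows.append({"subject_id": s.subject_id, "group": s.group, "age": s.age, **gm.as_dict()})
    return pd.DataFrame(rows)


def nodal_metrics_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-subject x node measures: E_nodal and nodal strength."""
    table = cohort.node_table
    rows = []
    for s in cohort.subjects:
        nm = compute_nodal_metrics(cohort.connectomes[s.subject_id])
        for i in range(len(table)):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age": s.age,
                    "node": table.abbreviations[i],
                    "hemisphere": table.hemispheres[i],
                    "E_nodal": nm.e_nodal[i],
                    "strength": nm.strength[i],
                }
            )
    return pd.DataFrame(rows)
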