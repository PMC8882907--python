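import numpy as np
import pytest

from pediconn.connectome import Cohort, Connectome, Subject
from pediconn.nodes import NodeTable


def make_node_table(n: int) -> NodeTable:
    """Tiny node table with n nodes split across hemispheres."""
    half = (n + 1) // 2
    labels, abbrs, hemis = [], [], []
    for i in range(n):
        hemi = "L" if i < half else "R"
        labels.append(f"region{i}")
        abbrs.append(f"{hemi}.N{i}")
        hemis.append(hemi)
    return NodeTable(tuple(labels), tuple(abbrs), tuple(hemis))


def make_connectome(weights, subject_id="s"):
    w = np.asarray(weights)
    return Connectome(weights=w, node_table=make_node_table(w.shape[0]), subject_id=subject_id)


def floyd_warshall_oracle(weights: np.ndarray) -> np.ndarray:
    """Independent all-pairs shortest paths on lengths 1/w (pure python)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def random_graph(rng: np.random.Generator, n_nodes: int, density: float = 0.5) -> np.ndarray:
    """Random symmetric integer-weight graph, possibly disconnected."""
    w = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    iu, ju = np.triu_indices(n_nodes, k=1)
    on = rng.random(iu.size) < density
    w[iu[on], ju[on]] = rng.integers(1, 20, size=on.sum())
    return w + w.T


def tiny_cohort(
    n_td=4,
    n_asd=4,
    n_nodes=5,
    planted_edge=(0, 1),
    gap=30,
    base=20,
    ages=None,
    seed=0,
):
    """Hand-built cohort with one strongly group-separated edge.

    All template edges are nonzero in every subject (fully eligible);
    weights carry small integer jitter so no edge is degenerate.
    """
    rng = np.random.default_rng(seed)
    table = make_node_table(n_nodes)
    subjects, conns = [], {}
    k = 0
    for group, n in (("TD", n_td), ("ASD", n_asd)):
        for _ in range(n):
            sid = f"{group}{k}"
            age = 4.0 if ages is None else float(ages[k])
            iu, ju = np.triu_indices(n_nodes, k=1)
            w = np.zeros((n_nodes, n_nodes), dtype=np.int64)
            w[iu, ju] = base + rng.integers(0, 4, size=iu.size)
            i, j = planted_edge
            if group == "ASD":
                w[min(i, j), max(i, j)] += gap
            w = w + w.T
            subjects.append(Subject(subject_id=sid, group=group, age=age))
            conns[sid] = Connectome(weights=w, node_table=table, subject_id=sid)
            k += 1
    return Cohort(subjects=subjects, connectomes=conns, node_table=table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def path_abc():
    """3-node path A-B-C with both edge weights 4."""
    return make_connectome([[0, 4, 0], [4, 0, 4], [0, 4, 0]])


@pytest.fixture(scope="session")
def k4_uniform():
    """Complete 4-node graph with uniform weight 2."""
    w = np.full((4, 4), 2)
    np.fill_diagonal(w, 0)
    return make_connectome(w)
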