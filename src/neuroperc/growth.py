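"""Synthetic connectome generators: GCSP/EPD growth and comparison models.

The Early Path Dominance (EPD) simulator grows a network one edge at a time
under the Giant Cluster Self Preference rule (each new edge branches to a
new node with the Eq.-3 probability, otherwise fills a uniformly chosen
open spot inside the cluster) while embedding it in space:

* nodes originate uniformly in the unit ball at the step that recruits them;
* all coordinates present after an edge addition are inflated by a fixed
  factor (default 1.0001), so early edges end up longest;
* each edge is born with density 1 and multiplied by a fixed factor
  (default 1.001) at every subsequent addition, so early edges end up
  densest; densities are therefore strictly ordered by age, and an
  increasing-density attack replays growth exactly backwards.

Defaults are 727 nodes (Talairach-atlas parcellation size), alpha = 11, and
growth to a final mean degree of 100 so every run ends fully connected
(P = 1). Edge tract_length is the Euclidean distance between final
(fully inflated) coordinates.

Comparison generators: Erdos-Renyi G(N, M), (non)linear preferential
attachment, Watts-Strogatz small-world rings with chord-distance edge
lengths, and spatially embedded uniform random graphs. All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import Connectome
from .theory import GCSPParams

__all__ = [
    "GrowthTrajectory",
    "EPDConfig",
    "simulate_gcsp_growth",
    "simulate_epd",
    "erdos_renyi_gnm",
    "preferential_attachment",
    "watts_strogatz",
    "spatial_random",
    "clustering_and_pathlength",
]


@dataclass
class GrowthTrajectory:
    """(kappa = 2E/N, rho = n/N) recorded after every edge addition.

    ``n`` is the node count of the growing cluster for GCSP/EPD growth, or
    the giant-cluster size for the comparison generators; ``N`` is the final
    node count, used in both denominators throughout.
    """

    N: int
    kappa: np.ndarray
    rho: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("step\tkappa\trho\n")
            for step, (k, r) in enumerate(zip(self.kappa, self.rho), start=1):
                fh.write(f"{step}\t{float(k)!r}\t{float(r)!r}\n")


@dataclass(frozen=True)
class EPDConfig:
    """Early Path Dominance simulation parameters (defaults per the model definition)."""

    N: int = 727
    alpha: float = 11.0
    k_final: float = 100.0
    coord_scale: float = 1.0001
    density_scale: float = 1.001
    seed: int = 0


def _edge_target(N: int, k_final: float) -> int:
    target = round(k_final * N / 2)
    if target > N * (N - 1) // 2:
        raise ValueError(f"k_final={k_final} infeasible for N={N}")
    return target


def _grow_gcsp(
    N: int, alpha: float, n_edges: int, rng: random.Random
) -> tuple[list[tuple[int, int]], list[int], np.ndarray]:
    """Core GCSP growth loop.

    Returns the edge list in creation order, the node labels in recruitment
    order (labels drawn uniformly from the not-yet-placed pool), and the
    cluster size after each addition.
    """
    unplaced = list(range(N))
    first = unplaced.pop(rng.randrange(N))
    cluster = [first]
    recruit_order = [first]
    adj: list[set[int]] = [set() for _ in range(N)]
    edges: list[tuple[int, int]] = []
    sizes = np.empty(n_edges, dtype=np.int64)
    n, E = 1, 0
    for step in range(n_edges):
        spots_in = n * (n - 1) // 2 - E
        if n < N:
            branch_weight = n * (N - n) / alpha
            p_branch = 1.0 if spots_in == 0 else branch_weight / (spots_in + branch_weight)
        else:
            p_branch = 0.0
        if rng.random() < p_branch:
            new = unplaced.pop(rng.randrange(len(unplaced)))
            anchor = cluster[rng.randrange(n)]
            u, v = anchor, new
            cluster.append(new)
            recruit_order.append(new)
            n += 1
        else:
            while True:  # rejection-sample a uniformly random open in-cluster spot
                u = cluster[rng.randrange(n)]
                v = cluster[rng.randrange(n)]
                if u != v and v not in adj[u]:
                    break
        adj[u].add(v)
        adj[v].add(u)
        edges.append((u, v) if u < v else (v, u))
        E += 1
        sizes[step] = n
    return edges, recruit_order, sizes


def simulate_gcsp_growth(
    params: GCSPParams, k_final: float, seed: int
) -> tuple[nx.Graph, GrowthTrajectory]:
    """Grow a single-cluster network under the GCSP rule.

    Starts from one node; every step either recruits a new node (attached to
    a uniformly random cluster node) or fills a uniformly random open
    in-cluster spot. Exactly one non-singleton cluster exists at all times.
    """
    N = params.N
    if N is None or N < 2:
        raise ValueError("simulate_gcsp_growth requires finite N >= 2")
    n_edges = _edge_target(N, k_final)
    rng = random.Random(seed)
    edges, _, sizes = _grow_gcsp(N, params.alpha, n_edges, rng)
    g = nx.Graph()
    g.add_nodes_from(range(N))
    g.add_edges_from(edges)
    traj = GrowthTrajectory(
        N=N,
        kappa=2.0 * np.arange(1, n_edges + 1) / N,
        rho=sizes / N,
    )
    return g, traj


def simulate_epd(config: EPDConfig) -> tuple[Connectome, GrowthTrajectory]:
    """Run one Early Path Dominance simulation.

    Topology follows :func:`simulate_gcsp_growth`; space and weights follow
    the inflation rules described in the module docstring. Coordinate
    inflation is applied lazily as a per-birth-epoch scale factor; final
    coordinates equal naive per-step multiplication to 1e-9.
    """
    N = config.N
    n_edges = _edge_target(N, config.k_final)
    rng = random.Random(config.seed)
    edges, recruit_order, sizes = _grow_gcsp(N, config.alpha, n_edges, rng)

    # birth step of each node: the seed node exists before addition 1; the
    # node recruited by addition t is born at t. A node born at t is inflated
    # at additions t..T (the inflation following its own addition included).
    birth = np.empty(N, dtype=np.int64)
    birth[recruit_order[0]] = 1
    t = 0
    for u, v in edges:
        t += 1
        n_before = 1 if t == 1 else sizes[t - 2]
        if sizes[t - 1] > n_before:  # this addition recruited a node
            new = recruit_order[sizes[t - 1] - 1]
            birth[new] = t
    raw = np.empty((N, 3))
    for node in recruit_order:  # draw in recruitment order for reproducibility
        raw[node] = _unit_ball_point(rng)
    inflations = n_edges - birth + 1
    inflations[recruit_order[0]] = n_edges  # seed node: inflated once per addition
    recruited = set(recruit_order)
    if len(recruited) < N:
        # regions never recruited (possible below the default final <k>):
        # edgeless isolates, placed uninflated
        for node in range(N):
            if node not in recruited:
                raw[node] = _unit_ball_point(rng)
                inflations[node] = 0
    coords = raw * (config.coord_scale ** inflations)[:, None]

    densities = config.density_scale ** (n_edges - 1 - np.arange(n_edges))
    edge_dict: dict[tuple[int, int], tuple[float, float]] = {}
    for t, (u, v) in enumerate(edges):
        length = float(np.linalg.norm(coords[u] - coords[v]))
        edge_dict[(u, v)] = (length, float(densities[t]))

    connectome = Connectome(
        node_ids=[f"n{i}" for i in range(N)],
        edges=edge_dict,
        coordinates=coords,
    )
    traj = GrowthTrajectory(
        N=N,
        kappa=2.0 * np.arange(1, n_edges + 1) / N,
        rho=sizes / N,
    )
    return connectome, traj


def _unit_ball_point(rng: random.Random) -> np.ndarray:
    while True:
        p = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(-1, 1)])
        if p @ p <= 1.0:
            return p


# ---------------------------------------------------------------------------
# comparison generators
# ---------------------------------------------------------------------------

def erdos_renyi_gnm(N: int, M: int, seed: int) -> nx.Graph:
    """Uniform simple graph with exactly M edges (G(N, M))."""
    if M > N * (N - 1) // 2:
        raise ValueError(f"M={M} exceeds complete-graph capacity for N={N}")
    return nx.gnm_random_graph(N, M, seed=seed)


def preferential_attachment(
    N: int, m: int, exponent: float = 1.0, seed: int = 0
) -> tuple[nx.Graph, GrowthTrajectory]:
    """Growing network with degree^exponent attachment (exponent 1 = BA).

    Starts from m edgeless seed nodes; each arriving node attaches m edges
    to distinct existing nodes drawn with probability proportional to
    degree^exponent (uniform whenever all candidate weights vanish, which
    covers the first arrival and the exponent = 0 degenerate case).
    rho tracks the giant-cluster fraction after every edge addition.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if m >= N:
        raise ValueError(f"m={m} >= node count {N}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(N))
    degree = np.zeros(N)
    dsu_parent = list(range(N))
    dsu_size = [1] * N

    def find(x: int) -> int:
        while dsu_parent[x] != x:
            dsu_parent[x] = dsu_parent[dsu_parent[x]]
            x = dsu_parent[x]
        return x

    giant = 1
    kappa: list[float] = []
    rho: list[float] = []
    for new in range(m, N):
        weights = degree[:new] ** exponent if exponent > 0 else np.ones(new)
        targets: list[int] = []
        w = weights.copy()
        for _ in range(m):
            total = w.sum()
            if total <= 0:
                candidates = np.array(
                    [i for i in range(new) if i not in targets], dtype=np.int64
                )
                pick = int(rng.choice(candidates))
            else:
                pick = int(rng.choice(new, p=w / total))
            targets.append(pick)
            w[pick] = 0.0
        for pick in targets:
            g.add_edge(new, pick)
            degree[new] += 1
            degree[pick] += 1
            ra, rb = find(new), find(pick)
            if ra != rb:
                if dsu_size[ra] < dsu_size[rb]:
                    ra, rb = rb, ra
                dsu_parent[rb] = ra
                dsu_size[ra] += dsu_size[rb]
                giant = max(giant, dsu_size[ra])
            kappa.append(2.0 * g.number_of_edges() / N)
            rho.append(giant / N)
    traj = GrowthTrajectory(N=N, kappa=np.array(kappa), rho=np.array(rho))
    return g, traj


def watts_strogatz(N: int, k_ring: int, p_rewire: float, seed: int) -> Connectome:
    """Watts-Strogatz ring with chord-distance tract lengths.

    Nodes sit at angles 2*pi*i/N on the unit circle; each edge's
    tract_length is the chord between its endpoints and tract_density is 1.
    """
    if k_ring % 2 or not 0 < k_ring < N:
        raise ValueError(f"k_ring must be even and in (0, N), got {k_ring}")
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must be in [0, 1]")
    g = nx.watts_strogatz_graph(N, k_ring, p_rewire, seed=seed)
    angles = 2.0 * np.pi * np.arange(N) / N
    coords = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(N)])
    edges = {}
    for u, v in g.edges():
        i, j = (u, v) if u < v else (v, u)
        chord = float(np.linalg.norm(coords[i] - coords[j]))
        edges[(i, j)] = (chord, 1.0)
    return Connectome(
        node_ids=[f"n{i}" for i in range(N)], edges=edges, coordinates=coords
    )


def spatial_random(N: int, M: int, seed: int) -> Connectome:
    """Uniformly random edges between uniformly random unit-ball positions.

    M distinct node pairs are drawn uniformly; tract_length is the Euclidean
    distance between endpoints and tract_density is 1.
    """
    if M > N * (N - 1) // 2:
        raise ValueError(f"M={M} exceeds complete-graph capacity for N={N}")
    rng = np.random.default_rng(seed)
    coords = np.empty((N, 3))
    filled = 0
    while filled < N:  # rejection sampling into the unit ball
        draw = rng.uniform(-1, 1, size=(2 * (N - filled), 3))
        keep = draw[(draw**2).sum(axis=1) <= 1.0][: N - filled]
        coords[filled : filled + len(keep)] = keep
        filled += len(keep)
    iu, ju = np.triu_indices(N, k=1)
    chosen = rng.choice(len(iu), size=M, replace=False)
    edges = {}
    for idx in chosen:
        i, j = int(iu[idx]), int(ju[idx])
        edges[(i, j)] = (float(np.linalg.norm(coords[i] - coords[j])), 1.0)
    return Connectome(
        node_ids=[f"n{i}" for i in range(N)], edges=edges, coordinates=coords
    )


def clustering_and_pathlength(graph) -> dict:
    """Unweighted mean local clustering and mean shortest path length.

    Accepts a Connectome or networkx graph. On a disconnected graph the path
    length is computed on the giant cluster and a warning is emitted.
    """
    if isinstance(graph, Connectome):
        graph = graph.to_networkx()
    mean_clustering = nx.average_clustering(graph)
    if graph.number_of_nodes() < 2:
        raise ValueError("path length undefined for a single node")
    if nx.is_connected(graph):
        sub = graph
    else:
        warnings.warn(
            "graph is disconnected; path length computed on the giant cluster",
            stacklevel=2,
        )
        giant_nodes = max(nx.connected_components(graph), key=len)
        sub = graph.subgraph(giant_nodes)
    return {
        "mean_clustering": float(mean_clustering),
        "mean_shortest_path": float(nx.average_shortest_path_length(sub)),
    }
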