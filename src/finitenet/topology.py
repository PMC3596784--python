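"""Scale-free directed connectivity and degree-distribution power-law fits.

Graphs are grown by preferential attachment using the repeated-endpoint-list
algorithm (the efficient Barabasi-Albert construction): nodes are added one
at a time and each new node creates ``m`` edges whose endpoints are sampled
with probability proportional to current degree.  The undirected simple
graph is then given a direction by orienting every edge independently at
random (never both directions), producing the binary adjacency ``a_ij`` with
row ``i`` postsynaptic and column ``j`` presynaptic.  Self-connections never
occur.

Synaptic weights on existing edges are drawn from Normal(10, 3.5)
(magnitudes; nonpositive draws are redrawn) and the outgoing weights of
inhibitory presynaptic neurons are negated.

The degree distribution is summarised by a least-squares power-law fit
``log(count) ~ gamma * log(degree)`` on the raw degree histogram with zero
bins dropped.  The package's default degree convention is the in-degree
(number of presynaptic inputs per neuron); total and out-degree are
available as options.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DEFAULT_EDGES_PER_NODE",
    "ConnectivityGraph",
    "SynapticMatrix",
    "PowerLawFit",
    "NotFittableError",
    "generate_scale_free",
    "assign_weights",
    "fit_power_law",
]

#: Calibrated edges-per-node. The value is not dictated by the network model
#: itself; it is fixed so that (i) degree-histogram exponents of the seven
#: simulated sizes span the -1.0 .. -1.6 decade and (ii) simulated burst
#: rates grow with network size on the observed scale. See
#: scripts/calibrate.py for the calibration sweep.
DEFAULT_EDGES_PER_NODE = 5


class NotFittableError(ValueError):
    """Degree sequence too degenerate for a power-law fit."""


@dataclass(frozen=True)
class ConnectivityGraph:
    """Binary directed adjacency; ``adjacency[i, j] = 1`` means j -> i."""

    n: int
    adjacency: np.ndarray  # (n, n) uint8, row = postsynaptic
    m: int  # edges created per added node

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=np.uint8)
        if adj.shape != (self.n, self.n):
            raise ValueError("adjacency must be n x n")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-connections are not allowed")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def in_degrees(self) -> np.ndarray:
        """Number of presynaptic inputs per neuron (row sums)."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def total_degrees(self) -> np.ndarray:
        return self.in_degrees() + self.out_degrees()

    def degrees(self, mode: str = "in") -> np.ndarray:
        if mode == "in":
            return self.in_degrees()
        if mode == "out":
            return self.out_degrees()
        if mode == "total":
            return self.total_degrees()
        raise ValueError("degree mode must be 'in', 'out' or 'total'")


@dataclass(frozen=True)
class SynapticMatrix:
    """Signed synaptic weights; support equals the adjacency support."""

    s: np.ndarray  # (n, n) float, row = postsynaptic
    inhibitory_ids: frozenset

    @property
    def n(self) -> int:
        return self.s.shape[0]


def generate_scale_free(n: int, m: int = DEFAULT_EDGES_PER_NODE, seed: int = 0) -> ConnectivityGraph:
    """Grow a directed scale-free graph on ``n`` nodes, ``m`` edges per node.

    The undirected preferential-attachment graph starts from ``m`` unconnected
    seed nodes (so the total edge count is ``m * (n - m)``); each undirected
    edge is then oriented in a single random direction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError("need n > m")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0]))
    G = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    adj = np.zeros((n, n), dtype=np.uint8)
    edges = np.array(sorted(G.edges()))
    flips = rng.random(len(edges)) < 0.5
    for (uu, vv), flip in zip(edges, flips):
        pre, post = (uu, vv) if not flip else (vv, uu)
        adj[post, pre] = 1
    return ConnectivityGraph(n=n, adjacency=adj, m=m)


def assign_weights(
    graph: ConnectivityGraph,
    mean: float = 10.0,
    sd: float = 3.5,
    inhibitory_ids=(),
    seed: int = 0,
) -> SynapticMatrix:
    """Draw Normal(mean, sd) weight magnitudes on the graph's edges.

    Nonpositive draws are redrawn so magnitudes stay positive; outgoing
    weights of inhibitory presynaptic neurons (columns) are negated.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    inhibitory_ids = frozenset(int(i) for i in inhibitory_ids)
    if inhibitory_ids and (min(inhibitory_ids) < 0 or max(inhibitory_ids) >= graph.n):
        raise ValueError("inhibitory_ids must be valid node ids")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAB]))
    post, pre = np.nonzero(graph.adjacency)
    w = rng.normal(mean, sd, size=len(pre))
    bad = w <= 0
    while np.any(bad):
        w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = w <= 0
    s = np.zeros((graph.n, graph.n))
    s[post, pre] = w
    if inhibitory_ids:
        cols = sorted(inhibitory_ids)
        s[:, cols] = -np.abs(s[:, cols])
    return SynapticMatrix(s=s, inhibitory_ids=inhibitory_ids)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log(count) on log(degree): count ~ degree^gamma."""

    gamma: float
    intercept: float
    fit_degree_range: tuple[int, int]
    goodness: float  # r^2 of the log-log regression


def fit_power_law(degrees) -> PowerLawFit:
    """Fit ``P(m) = m^-gamma`` by least squares on the raw log-log histogram.

    The histogram uses one bin per observed degree value; zero-count bins
    drop out by construction and the zero degree (if any) is excluded.
    Returns the signed slope as ``gamma`` (negative for decaying
    distributions).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    vals, counts = np.unique(degrees, return_counts=True)
    keep = vals > 0
    vals, counts = vals[keep], counts[keep]
    if len(vals) < 3:
        raise NotFittableError(
            "power-law fit needs at least 3 distinct positive degree values"
        )
    x = np.log(vals.astype(float))
    y = np.log(counts.astype(float))
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((A @ np.array([slope, intercept]) - y) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(
        gamma=float(slope),
        intercept=float(intercept),
        fit_degree_range=(int(vals[0]), int(vals[-1])),
        goodness=r2,
    )
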