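"""Temporal small-worldness measures.

Implements the temporal clustering coefficient ``C`` (time-average of the
per-snapshot global clustering / transitivity), the temporal path length
``L`` (average duration of fastest time-respecting paths), the temporal
correlation coefficient ``TC`` (neighbourhood persistence between
consecutive snapshots), and the two unnormalized small-worldness ratios

    S    = C / L
    S_SB = TC / L        (the Sizemore-Bassett variant)

Conventions for degenerate denominators (all ratios are 0 when their
denominator vanishes) follow the standard limits and make the small worked
examples well-defined: a snapshot with no node of degree >= 2 has
clustering 0; a node isolated at step t or t+1 contributes 0 to that step's
persistence term.

Fastest temporal paths use at most one edge per time step, waiting at a
node is free, and travel starts at time 0; ``l_ij`` is the number of
elapsed snapshots, so in the static limit it reduces to hop count.  A pair
that cannot be reached within the horizon is assigned the maximum distance
``T`` (the default), or excluded from the average (``unreachable="drop"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .temporal_graph import TemporalGraph

__all__ = [
    "MeasureReport",
    "clustering_at",
    "local_clustering",
    "temporal_clustering",
    "fastest_path_times",
    "temporal_path_length",
    "temporal_correlation",
    "small_worldness",
]


@dataclass
class MeasureReport:
    """All temporal measures of one graph, plus the per-step and per-pair detail."""

    C: float
    L: float
    TC: float
    S: float
    S_SB: float
    per_step_clustering: np.ndarray = field(repr=False)
    pairwise_times: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self.L,
            "TC": self.TC,
            "S": self.S,
            "S_SB": self.S_SB,
            "per_step_clustering": self.per_step_clustering.tolist(),
            "pairwise_times": self.pairwise_times.tolist(),
        }


def _as_adjacency(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return a


def clustering_at(adjacency) -> float:
    """Global clustering (transitivity) of one snapshot.

    Ratio of ordered closed triplets ``trace(A^3)`` to ordered triplets
    ``sum_i k_i (k_i - 1)``; 0 when the graph has no triplet at all.
    """
    a = _as_adjacency(adjacency).astype(np.float64)
    k = a.sum(axis=1)
    denom = float((k * (k - 1.0)).sum())
    if denom == 0.0:
        return 0.0
    num = float(np.trace(a @ a @ a))
    return num / denom


def local_clustering(adjacency, i: int) -> float:
    """Fraction of realized links among the neighbours of node ``i`` (0 if k_i < 2)."""
    a = _as_adjacency(adjacency)
    nbrs = np.nonzero(a[i])[0]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = int(a[np.ix_(nbrs, nbrs)].sum()) // 2
    return 2.0 * links / (k * (k - 1))


def temporal_clustering(g: TemporalGraph) -> float:
    """Arithmetic mean of :func:`clustering_at` over all snapshots."""
    return float(np.mean([clustering_at(g.tensor[t]) for t in range(g.n_steps)]))


def fastest_path_times(g: TemporalGraph, return_reached: bool = False):
    """Matrix ``l_ij`` of fastest temporal path durations from every source.

    Layer expansion of reachable sets: ``R_0 = {i}`` and
    ``R_{t+1} = R_t ∪ neighbours-in-snapshot-t(R_t)``; ``l_ij`` is the
    smallest ``t >= 1`` with ``j in R_t``, ``l_ii = 0``, and ``T`` when ``j``
    is never reached.  Temporal reachability is time-directed, so the matrix
    is not symmetric in general.
    """
    T, N = g.n_steps, g.n_nodes
    times = np.full((N, N), T, dtype=np.int64)
    np.fill_diagonal(times, 0)
    reach = np.eye(N, dtype=bool)
    for t in range(T):
        a = g.tensor[t].astype(np.float32)
        new = reach | ((reach.astype(np.float32) @ a) > 0)
        newly = new & ~reach
        times[newly] = t + 1
        reach = new
        if reach.all():
            break
    if return_reached:
        return times, reach
    return times


def temporal_path_length(g: TemporalGraph, unreachable: str = "cap") -> float:
    """Mean of ``l_ij`` over ordered pairs ``i != j``.

    ``unreachable="cap"`` (default) counts never-reached pairs at the maximum
    distance ``T``; ``"drop"`` excludes them from the average.
    """
    if g.n_nodes < 2:
        raise ValueError("temporal path length needs at least 2 nodes")
    times, reached = fastest_path_times(g, return_reached=True)
    off = ~np.eye(g.n_nodes, dtype=bool)
    if unreachable == "cap":
        return float(times[off].mean())
    if unreachable == "drop":
        mask = off & reached
        if not mask.any():
            return float(g.n_steps)
        return float(times[mask].mean())
    raise ValueError("unreachable must be 'cap' or 'drop'")


def temporal_correlation(g: TemporalGraph) -> float:
    """Temporal correlation coefficient ``TC`` (mean over nodes of ``TC_i``)."""
    return float(np.mean(temporal_correlation_per_node(g)))


def temporal_correlation_per_node(g: TemporalGraph) -> np.ndarray:
    """Per-node persistence ``TC_i``; terms with an isolated endpoint step are 0."""
    if g.n_steps < 2:
        raise ValueError("temporal correlation needs at least 2 snapshots")
    a = g.tensor.astype(np.float64)
    overlap = (a[:-1] * a[1:]).sum(axis=2)  # (T-1, N)
    deg = a.sum(axis=2)  # (T, N)
    denom = np.sqrt(deg[:-1] * deg[1:])
    terms = np.divide(overlap, denom, out=np.zeros_like(overlap), where=denom > 0)
    return terms.sum(axis=0) / (g.n_steps - 1)


def small_worldness(g: TemporalGraph, unreachable: str = "cap") -> MeasureReport:
    """Compute every measure and both small-worldness ratios for ``g``."""
    if g.n_nodes < 2:
        raise ValueError("small-worldness needs at least 2 nodes")
    if g.n_steps < 2:
        raise ValueError("small-worldness needs at least 2 snapshots")
    per_step = np.array([clustering_at(g.tensor[t]) for t in range(g.n_steps)])
    C = float(per_step.mean())
    times = fastest_path_times(g)
    L = temporal_path_length(g, unreachable=unreachable)
    TC = temporal_correlation(g)
    S = 0.0 if C == 0.0 else C / L
    S_SB = 0.0 if TC == 0.0 else TC / L
    return MeasureReport(
        C=C, L=L, TC=TC, S=S, S_SB=S_SB,
        per_step_clustering=per_step, pairwise_times=times,
    )
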