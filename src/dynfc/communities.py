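"""Weighted modularity and fast-greedy (CNM-style) community detection.

Modularity of a partition of a weighted undirected graph is

    Q = 1/(2m) * sum_ij [ A_ij - k_i k_j / (2m) ] delta(c_i, c_j)

where A_ij is the edge weight between nodes i and j, k_i the weighted
degree of node i, m the total edge weight, and delta the Kronecker delta on
community labels.  The fast-greedy algorithm starts from singleton
communities and repeatedly merges the pair of communities with the largest
modularity gain, recording the full merge dendrogram; the returned partition
is the cut along the dendrogram with maximal Q.  Greedy agglomeration is
deterministic here: ties in the gain are broken by the lexicographically
smallest pair of community representatives (the minimal member label of each
community).

Thresholded correlation matrices enter as *weighted* adjacency — surviving
edges keep their r magnitude; they are not binarized.  Negative surviving
correlations are excluded by default (modularity is ill-defined for signed
weights); an ``absolute`` mode that uses |r| is provided.

For graphs of at most 10 nodes, :func:`brute_force_partition` enumerates
every set partition and returns the global Q maximizer; it exists as an
independent oracle for the greedy algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .connectivity import CorrelationResult

__all__ = [
    "Graph",
    "Partition",
    "build_graph",
    "modularity",
    "fast_greedy",
    "brute_force_partition",
]


@dataclass
class Graph:
    """Symmetric non-negative weighted graph with labelled nodes."""

    labels: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if self.W.shape != (n, n):
            raise ValueError(f"{n} labels for weight matrix {self.W.shape}")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("edge weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> float:
        """Total edge weight (half the sum of the adjacency matrix)."""
        return float(self.W.sum()) / 2.0

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=0)


@dataclass
class Partition:
    """A node-to-community assignment with its modularity Q.

    Community ids are contiguous integers starting at 0, ordered by first
    appearance over the node label order.
    """

    assignment: dict[str, int]
    Q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @classmethod
    def from_assignment(cls, assignment: dict[str, int], Q: float = np.nan,
                        canonical: bool = True) -> "Partition":
        if canonical:
            assignment = _canonical(assignment)
        return cls(assignment=dict(assignment), Q=float(Q))

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return out

    def as_array(self, labels: list[str]) -> np.ndarray:
        return np.array([self.assignment[lab] for lab in labels])


def _canonical(assignment: dict[str, int]) -> dict[str, int]:
    """Relabel community ids to 0..k-1 in order of first appearance."""
    seen: dict[int, int] = {}
    out = {}
    for node, c in assignment.items():
        if c not in seen:
            seen[c] = len(seen)
        out[node] = seen[c]
    return out


def build_graph(
    thresholded: CorrelationResult | np.ndarray,
    mode: str = "positive_only",
    labels: list[str] | None = None,
) -> Graph:
    """Turn an FDR-thresholded correlation matrix into a weighted graph.

    ``positive_only`` (default) drops surviving negative correlations;
    ``absolute`` uses their magnitudes.  Nodes isolated by thresholding are
    retained (they become singleton communities in detection).
    """
    if isinstance(thresholded, CorrelationResult):
        if thresholded.thresholded is None:
            raise ValueError("CorrelationResult has no thresholded matrix yet")
        M = thresholded.thresholded
        labels = list(thresholded.labels)
    else:
        M = np.asarray(thresholded, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(M.shape[0])]
    if mode == "positive_only":
        W = np.where(M > 0, M, 0.0)
    elif mode == "absolute":
        W = np.abs(M)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    if W.sum() == 0:
        raise ValueError("empty graph: no surviving edges")
    return Graph(labels=labels, W=W)


def _modularity_from_array(W: np.ndarray, c: np.ndarray, m: float) -> float:
    k = W.sum(axis=0)
    same = c[:, None] == c[None, :]
    return float(
        (W[same].sum() - (np.outer(k, k)[same].sum()) / (2.0 * m)) / (2.0 * m)
    )


def modularity(g: Graph, p: Partition | dict[str, int]) -> float:
    """Exact modularity Q of a partition of ``g``."""
    assignment = p.assignment if isinstance(p, Partition) else p
    missing = [lab for lab in g.labels if lab not in assignment]
    if missing:
        raise ValueError(f"nodes without community assignment: {missing}")
    if g.m <= 0:
        raise ValueError("modularity undefined for a graph with no edge weight")
    c = np.array([assignment[lab] for lab in g.labels])
    return _modularity_from_array(g.W, c, g.m)


@dataclass
class MergeStep:
    """One dendrogram step: which communities merged and Q afterwards."""

    step: int
    merged: tuple[int, int]
    delta_q: float
    q_after: float


def fast_greedy(
    g: Graph, return_history: bool = False
) -> Partition | tuple[Partition, list[MergeStep]]:
    """Agglomerative greedy modularity maximization.

    Starts from singletons; at each step merges the community pair with the
    largest modularity gain dQ = 2*(e_ij - a_i a_j) (e_ij: fraction of edge
    weight between the pair, a_i: fraction of degree in community i), even
    when the best gain is negative, so the dendrogram reaches a single
    community; the partition with maximal Q along the way is returned.
    """
    n = g.n_nodes
    m = g.m
    if m <= 0:
        raise ValueError("empty graph: no edge weight")
    E = g.W / (2.0 * m)              # pairwise weight fractions
    a = g.degrees / (2.0 * m)        # degree fractions per community
    members: list[set[int] | None] = [{i} for i in range(n)]
    reps: list[str | None] = [g.labels[i] for i in range(n)]
    active = set(range(n))
    assign = np.arange(n)

    q = float(-(a**2).sum())         # singleton partition, zero diagonal
    best_q = q
    best_assign = assign.copy()
    history: list[MergeStep] = []
    step = 0
    while len(active) > 1:
        best = None
        act = sorted(active)
        for ii, i in enumerate(act):
            for j in act[ii + 1:]:
                dq = 2.0 * (E[i, j] - a[i] * a[j])
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or dq > best[0] or (dq == best[0] and key < best[1]):
                    best = (dq, key, i, j)
        dq, _, i, j = best
        # merge j into i
        E[i, :] += E[j, :]
        E[:, i] += E[:, j]
        a[i] += a[j]
        members[i] |= members[j]
        reps[i] = min(reps[i], reps[j])
        members[j] = None
        reps[j] = None
        active.remove(j)
        assign[assign == j] = i
        q += dq
        step += 1
        if return_history:
            history.append(MergeStep(step=step, merged=(i, j), delta_q=dq,
                                     q_after=q))
        if q > best_q + 1e-15:
            best_q = q
            best_assign = assign.copy()

    assignment = {g.labels[i]: int(best_assign[i]) for i in range(n)}
    part = Partition.from_assignment(assignment, Q=best_q)
    return (part, history) if return_history else part


def _set_partitions(items: list[str]) -> Iterator[list[list[str]]]:
    """Enumerate all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_partition(g: Graph) -> Partition:
    """Global modularity maximizer by exhaustive set-partition enumeration.

    Only feasible for small graphs; refuses more than 10 nodes
    (Bell(10) = 115975 candidate partitions).
    """
    if g.n_nodes > 10:
        raise ValueError("brute force limited to graphs of <= 10 nodes")
    if g.m <= 0:
        raise ValueError("empty graph: no edge weight")
    W, m = g.W, g.m
    index = {lab: i for i, lab in enumerate(g.labels)}
    best_q = -np.inf
    best_blocks = None
    c = np.empty(g.n_nodes, dtype=int)
    for blocks in _set_partitions(g.labels):
        for cid, block in enumerate(blocks):
            for lab in block:
                c[index[lab]] = cid
        q = _modularity_from_array(W, c, m)
        if q > best_q:
            best_q = q
            best_blocks = [list(b) for b in blocks]
    assignment = {lab: cid for cid, block in enumerate(best_blocks)
                  for lab in block}
    full = {lab: assignment[lab] for lab in g.labels}
    return Partition.from_assignment(full, Q=best_q)
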