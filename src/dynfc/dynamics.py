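"""Temporal community alignment and network flexibility.

Community detection is run independently in each sliding window, so the
integer community ids of different windows are arbitrary ("label gauge").
A change of allegiance is only well defined after matching labels between
consecutive windows; :func:`align_labels` does this by greedy maximum
node-overlap matching (an optimal linear-assignment mode is available).
Alignment only renames communities — it never changes which nodes are
grouped together.

Flexibility of node i is the fraction of window-to-window transitions at
which it changes community:

    f_i = #{t : c_i(t+1) != c_i(t)} / (n_windows - 1)

and the flexibility of a network of N nodes is the mean F = 1/N * sum_i f_i.
The per-transition trace (fraction of nodes changing at each transition)
satisfies the double-counting identity mean_t(trace) = mean_i(f_i) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .communities import Partition, build_graph, fast_greedy
from .connectivity import WindowedConnectivity

__all__ = [
    "CommunitySequence",
    "FlexibilityResult",
    "detect_window_communities",
    "align_labels",
    "node_flexibility",
    "mean_flexibility",
    "transition_flexibility",
    "flexibility",
]

WHOLE_BRAIN = "WholeBrain"


@dataclass
class CommunitySequence:
    """One partition per window, on a common node set."""

    partitions: list[Partition]
    window_starts_s: list[float]
    window_length_s: float
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("empty community sequence")
        if len(self.window_starts_s) != len(self.partitions):
            raise ValueError("one window start per partition required")
        nodes = self.node_set
        for i, p in enumerate(self.partitions):
            if set(p.assignment) != nodes:
                raise ValueError(f"partition {i} has a different node set")

    @property
    def node_set(self) -> set[str]:
        return set(self.partitions[0].assignment)

    @property
    def n_windows(self) -> int:
        return len(self.partitions)


@dataclass
class FlexibilityResult:
    """Per-node flexibility, per-network means, and the transition trace."""

    f: pd.Series
    F_network: pd.Series
    per_transition: np.ndarray


def detect_window_communities(
    wc: WindowedConnectivity,
    mode: str = "positive_only",
    align: bool = True,
) -> CommunitySequence:
    """Run fast-greedy detection in every window of a dynamic analysis.

    Windows whose thresholded matrix has no surviving (positive-mode) edge
    get the all-singleton partition — FDR can empty a sparse window, and
    isolated nodes still count toward flexibility denominators.
    """
    parts = []
    labels = wc.results[0].labels
    for res in wc.results:
        try:
            parts.append(fast_greedy(build_graph(res, mode=mode)))
        except ValueError:
            singles = {lab: i for i, lab in enumerate(labels)}
            parts.append(Partition.from_assignment(singles, Q=0.0))
    seq = CommunitySequence(
        partitions=parts,
        window_starts_s=list(wc.spec.start_seconds(one_based=True)),
        window_length_s=wc.spec.window_s,
        aligned=False,
    )
    return align_labels(seq) if align and len(parts) > 1 else seq


def _match_greedy(prev: dict[int, set[str]], cur: dict[int, set[str]]):
    """Greedy maximum-overlap matching: repeatedly pair the (prev, cur)
    communities with the largest node overlap; ties by smallest ids."""
    overlaps = []
    for pc, pnodes in prev.items():
        for cc, cnodes in cur.items():
            ov = len(pnodes & cnodes)
            if ov > 0:
                overlaps.append((-ov, pc, cc))
    overlaps.sort()
    mapping: dict[int, int] = {}
    used_prev: set[int] = set()
    for neg_ov, pc, cc in overlaps:
        if cc not in mapping and pc not in used_prev:
            mapping[cc] = pc
            used_prev.add(pc)
    return mapping


def _match_optimal(prev: dict[int, set[str]], cur: dict[int, set[str]]):
    """Optimal one-to-one matching maximizing total node overlap."""
    pids, cids = sorted(prev), sorted(cur)
    cost = np.zeros((len(pids), len(cids)))
    for i, pc in enumerate(pids):
        for j, cc in enumerate(cids):
            cost[i, j] = -len(prev[pc] & cur[cc])
    rows, cols = scipy.optimize.linear_sum_assignment(cost)
    return {
        cids[j]: pids[i]
        for i, j in zip(rows, cols)
        if cost[i, j] < 0  # zero-overlap "matches" stay unmatched
    }


def align_labels(seq: CommunitySequence, method: str = "greedy") -> CommunitySequence:
    """Relabel community ids so they are comparable across windows.

    For each consecutive pair of windows the ids of window t+1 are renamed
    to maximize node overlap with window t; communities without any overlap
    get fresh ids.  Node groupings are unchanged — only the integer names
    move.
    """
    if method not in {"greedy", "optimal"}:
        raise ValueError(f"unknown alignment method {method!r}")
    if seq.n_windows < 2:
        raise ValueError("alignment needs at least 2 windows")
    match = _match_greedy if method == "greedy" else _match_optimal
    out = [replace(seq.partitions[0],
                   assignment=dict(seq.partitions[0].assignment))]
    next_fresh = max(out[0].assignment.values()) + 1
    for part in seq.partitions[1:]:
        prev_groups: dict[int, set[str]] = out[-1].communities()
        cur_groups = part.communities()
        mapping = match(prev_groups, cur_groups)
        renamed = {}
        for cc in sorted(cur_groups):
            if cc in mapping:
                renamed[cc] = mapping[cc]
            else:
                renamed[cc] = next_fresh
                next_fresh += 1
        new_assign = {node: renamed[c] for node, c in part.assignment.items()}
        out.append(Partition(assignment=new_assign, Q=part.Q))
    return CommunitySequence(
        partitions=out,
        window_starts_s=list(seq.window_starts_s),
        window_length_s=seq.window_length_s,
        aligned=True,
    )


def _assignment_matrix(seq: CommunitySequence) -> tuple[list[str], np.ndarray]:
    nodes = sorted(seq.node_set)
    mat = np.array(
        [[p.assignment[n] for n in nodes] for p in seq.partitions]
    )  # windows x nodes
    return nodes, mat


def _require_aligned(seq: CommunitySequence) -> None:
    if not seq.aligned:
        raise ValueError("sequence must be label-aligned first (align_labels)")
    if seq.n_windows < 2:
        raise ValueError("flexibility needs at least 2 windows")


def node_flexibility(seq: CommunitySequence) -> pd.Series:
    """Fraction of transitions at which each node changes community."""
    _require_aligned(seq)
    nodes, mat = _assignment_matrix(seq)
    changes = (np.diff(mat, axis=0) != 0).sum(axis=0)
    f = changes / (seq.n_windows - 1)
    return pd.Series(f, index=nodes, name="flexibility")


def mean_flexibility(
    f: pd.Series, grouping: dict[str, list[str]]
) -> pd.Series:
    """Mean flexibility per network, plus the whole-brain mean.

    ``grouping`` maps network name to its member node labels; every listed
    node must appear in ``f`` and no network may be empty.
    """
    out = {}
    for net, members in grouping.items():
        if not members:
            raise ValueError(f"network {net!r} has no member nodes")
        missing = [mbr for mbr in members if mbr not in f.index]
        if missing:
            raise ValueError(f"network {net!r} members not in f: {missing}")
        out[net] = float(f.loc[list(members)].mean())
    out[WHOLE_BRAIN] = float(f.mean())
    return pd.Series(out, name="mean_flexibility")


def transition_flexibility(seq: CommunitySequence) -> np.ndarray:
    """Fraction of nodes changing community at each window transition."""
    _require_aligned(seq)
    _, mat = _assignment_matrix(seq)
    return (np.diff(mat, axis=0) != 0).mean(axis=1)


def flexibility(
    seq: CommunitySequence, grouping: dict[str, list[str]] | None = None
) -> FlexibilityResult:
    """Node, network, and per-transition flexibility in one call."""
    f = node_flexibility(seq)
    F = mean_flexibility(f, grouping or {})
    return FlexibilityResult(
        f=f, F_network=F, per_transition=transition_flexibility(seq)
    )
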