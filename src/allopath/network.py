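"""Correlation-weighted residue networks and (sub)optimal allosteric paths.

Every residue (its Cα) is a node; an edge joins residues that are in
persistent contact and whose motions are correlated, with length

    d_ij = −ln |X_ij|

so strongly coupled residues are "close".  Lengths are scaled to integers
(×100, round half away from zero), the convention under which a suboptimal
path offset of 20 means 0.2 in raw −ln|X| units.  The optimal path between
two residues is the minimum-total-length path (Dijkstra with deterministic
tie-breaking); suboptimal paths are all simple paths within a fixed offset
of the optimum, enumerated by bounded depth-first search with an admissible
reverse-Dijkstra pruning bound.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Selection, Trajectory
from .correlation import DCCMatrix

__all__ = [
    "ContactMap",
    "ResidueGraph",
    "PathResult",
    "contact_map",
    "build_graph",
    "optimal_path",
    "suboptimal_paths",
    "path_table",
    "compare_pathways",
    "scaled_length",
]


def scaled_length(abs_corr: float, scale: int = 100) -> int:
    """Integer edge length ``round(scale · (−ln|X|))``, half away from zero."""
    if not (0.0 < abs_corr <= 1.0):
        raise ValueError("|X| must lie in (0, 1]")
    raw = -math.log(abs_corr) * scale
    return int(math.floor(raw + 0.5))  # raw ≥ 0, so this is half-away-from-zero


@dataclass
class ContactMap:
    """Symmetric boolean residue-residue contact matrix."""

    values: np.ndarray
    cutoff: float
    occupancy: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(v)):
            raise ValueError("contact map diagonal must be false")
        self.values = v


@dataclass
class ResidueGraph:
    """Contact-gated residue graph with −ln|X| edge weights.

    Wraps a :class:`networkx.Graph` whose nodes are residue indices with a
    ``label`` attribute and whose edges carry ``abs_corr``, ``raw_weight``
    (−ln|X|) and ``int_length`` (scaled integer) attributes.
    """

    graph: nx.Graph
    scale: int = 100

    @property
    def labels(self) -> dict[int, str]:
        return nx.get_node_attributes(self.graph, "label")

    def edge_list_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_i": i,
                "node_j": j,
                "abs_corr": d["abs_corr"],
                "raw_weight": d["raw_weight"],
                "int_length": d["int_length"],
            }
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "abs_corr", "raw_weight", "int_length"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class PathResult:
    """Optimal/suboptimal path report between one source/sink pair."""

    source: int
    sink: int
    optimal_path: list[int]
    optimal_length: int | None
    suboptimal_count: int = 0
    suboptimal_paths: list[list[int]] = field(default_factory=list)
    node_frequency: dict[int, int] = field(default_factory=dict)
    truncated: bool = False

    @property
    def found(self) -> bool:
        return self.optimal_length is not None

    @property
    def n_residues(self) -> int:
        return len(self.optimal_path)


def contact_map(
    traj: Trajectory,
    selection: Selection | None = None,
    cutoff: float = 4.5,
    occupancy: float = 0.75,
    mode: str = "heavy",
    ca_cutoff: float = 8.0,
    exclude_neighbors: int = 2,
    window: tuple[int, int] | None = None,
) -> ContactMap:
    """Residue contact map over a trajectory window.

    ``mode='heavy'``: residues are in contact in a frame when their minimum
    heavy-atom distance is ≤ ``cutoff`` (4.5 Å default).  ``mode='ca'`` uses
    the Cα–Cα distance with ``ca_cutoff`` (8.0 Å default).  A pair counts as
    a contact overall when the per-frame criterion holds in at least the
    ``occupancy`` fraction of frames.  Sequence neighbours within
    ``exclude_neighbors`` on the same chain are excluded.
    """
    if cutoff <= 0 or ca_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must be in (0, 1]")
    start, end = window if window is not None else (0, traj.n_frames)
    if end <= start:
        raise ValueError("empty frame window")
    frames = traj.frames[start:end]

    topo = traj.topology
    residues = topo.residues()
    if selection is not None:
        selection.validate(topo)
        wanted = {topo.atoms[i].residue_key for i in selection.indices}
        residues = [r for r in residues if r[0] in wanted]
    n = len(residues)
    if mode == "ca":
        ca_idx = []
        for key, resname, atom_idx in residues:
            cas = [i for i in atom_idx if topo.atoms[i].name == "CA"]
            if len(cas) != 1:
                raise ValueError(f"residue {key} lacks a unique CA atom for ca mode")
            ca_idx.append(cas[0])
        pts = frames[:, ca_idx, :]  # (F, N, 3)
        diff = pts[:, :, None, :] - pts[:, None, :, :]
        close = np.linalg.norm(diff, axis=-1) <= ca_cutoff
    elif mode == "heavy":
        groups = [
            [i for i in atom_idx if topo.atoms[i].element != "H"]
            for _, _, atom_idx in residues
        ]
        close = np.zeros((frames.shape[0], n, n), dtype=bool)
        for a in range(n):
            for b in range(a + 1, n):
                pa = frames[:, groups[a], :]
                pb = frames[:, groups[b], :]
                d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=-1)
                hit = d.min(axis=(1, 2)) <= cutoff
                close[:, a, b] = close[:, b, a] = hit
    else:
        raise ValueError(f"unknown contact mode {mode!r}")

    frac = close.mean(axis=0)
    contacts = frac >= occupancy
    np.fill_diagonal(contacts, False)

    # neighbour exclusion by sequence separation within a chain
    keys = [r[0] for r in residues]
    seqs = []
    for (chain, label) in keys:
        digits = "".join(c for c in label if c.isdigit() or c == "-")
        seqs.append((chain, int(digits)))
    for a in range(n):
        for b in range(n):
            if a != b and seqs[a][0] == seqs[b][0] and abs(seqs[a][1] - seqs[b][1]) <= exclude_neighbors:
                contacts[a, b] = False
    eff_cutoff = ca_cutoff if mode == "ca" else cutoff
    return ContactMap(values=contacts, cutoff=eff_cutoff, occupancy=occupancy)


def build_graph(
    dccm: DCCMatrix | np.ndarray,
    contacts: ContactMap | np.ndarray,
    scale: int = 100,
    labels: list[str] | None = None,
) -> ResidueGraph:
    """Residue graph with an edge per contact pair of nonzero correlation.

    Edge attributes: ``abs_corr`` = |X_ij|, ``raw_weight`` = −ln|X_ij|,
    ``int_length`` = round(scale · raw_weight).  A contact pair with
    |X| = 0 has infinite distance and produces no edge (with a warning).
    """
    corr = dccm.values if isinstance(dccm, DCCMatrix) else np.asarray(dccm, dtype=float)
    cmap = contacts.values if isinstance(contacts, ContactMap) else np.asarray(contacts, dtype=bool)
    if corr.shape != cmap.shape:
        raise ValueError("correlation matrix and contact map dimensions differ")
    if labels is None:
        labels = (
            list(dccm.residue_labels)
            if isinstance(dccm, DCCMatrix)
            else [str(i) for i in range(corr.shape[0])]
        )
    g = nx.Graph()
    for i in range(corr.shape[0]):
        g.add_node(i, label=labels[i])
    dropped = 0
    for i, j in zip(*np.nonzero(np.triu(cmap, k=1))):
        x = abs(float(corr[i, j]))
        if x == 0.0:
            dropped += 1
            continue
        raw = -math.log(min(x, 1.0))
        g.add_edge(
            int(i), int(j),
            abs_corr=x,
            raw_weight=raw,
            int_length=scaled_length(min(x, 1.0), scale),
        )
    if dropped:
        warnings.warn(
            f"{dropped} contact pair(s) with zero correlation dropped "
            "(infinite network distance)",
            stacklevel=2,
        )
    return ResidueGraph(graph=g, scale=scale)


def _dijkstra(
    g: nx.Graph, source: int, sink: int | None = None
) -> tuple[dict[int, int], dict[int, list[int]]]:
    """Dijkstra over ``int_length`` weights with deterministic tie-breaking.

    The priority key is ``(distance, hop count, path)``, so among equal-length
    routes the one with fewer nodes wins, then the lexicographically smallest
    node sequence.  Returns (distance, path) maps for all reached nodes.
    """
    dist: dict[int, int] = {}
    paths: dict[int, list[int]] = {}
    heap: list[tuple[int, int, tuple[int, ...]]] = [(0, 1, (source,))]
    while heap:
        d, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in dist:
            continue
        dist[node] = d
        paths[node] = list(path)
        if node == sink:
            break
        for nbr, attrs in sorted(g[node].items()):
            if nbr not in dist:
                heapq.heappush(heap, (d + attrs["int_length"], hops + 1, path + (nbr,)))
    return dist, paths


def optimal_path(graph: ResidueGraph, source: int, sink: int) -> PathResult:
    """Shortest (optimal) signalling path between two residues.

    A disconnected pair yields an explicit no-path result
    (``optimal_length is None``) rather than an exception.
    """
    g = graph.graph
    if source not in g or sink not in g:
        raise KeyError("source/sink not in graph")
    if source == sink:
        return PathResult(source=source, sink=sink, optimal_path=[source], optimal_length=0)
    dist, paths = _dijkstra(g, source, sink)
    if sink not in dist:
        return PathResult(source=source, sink=sink, optimal_path=[], optimal_length=None)
    return PathResult(
        source=source, sink=sink, optimal_path=paths[sink], optimal_length=dist[sink]
    )


def suboptimal_paths(
    graph: ResidueGraph,
    source: int,
    sink: int,
    offset: int = 20,
    max_paths: int = 10000,
) -> PathResult:
    """All simple paths within ``offset`` of the optimal length.

    Enumeration is a depth-first search over simple paths, pruned with the
    admissible bound ``current length + shortest remaining distance`` from a
    reverse Dijkstra, so it only explores prefixes that can still finish
    within budget.  ``suboptimal_count`` excludes the optimal path itself;
    ``node_frequency`` counts node occurrences across all enumerated paths
    (optimal included).  Hitting ``max_paths`` truncates and flags the result
    as a lower bound.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    best = optimal_path(graph, source, sink)
    if not best.found:
        return best
    g = graph.graph
    budget = best.optimal_length + offset
    # admissible heuristic: exact remaining distance to the sink
    dist_to_sink, _ = _dijkstra(g, sink)

    found: list[tuple[int, list[int]]] = []
    truncated = False

    def dfs(node: int, length: int, path: list[int], on_path: set[int]) -> bool:
        nonlocal truncated
        if node == sink:
            found.append((length, list(path)))
            if len(found) >= max_paths:
                truncated = True
                return False
            return True
        for nbr, attrs in sorted(g[node].items()):
            if nbr in on_path:
                continue
            nxt = length + attrs["int_length"]
            if nbr not in dist_to_sink or nxt + dist_to_sink[nbr] > budget:
                continue
            path.append(nbr)
            on_path.add(nbr)
            ok = dfs(nbr, nxt, path, on_path)
            path.pop()
            on_path.remove(nbr)
            if not ok:
                return False
        return True

    if source == sink:
        found.append((0, [source]))
    else:
        dfs(source, 0, [source], {source})

    freq: dict[int, int] = {}
    for _, path in found:
        for node in path:
            freq[node] = freq.get(node, 0) + 1
    return PathResult(
        source=source,
        sink=sink,
        optimal_path=best.optimal_path,
        optimal_length=best.optimal_length,
        suboptimal_count=max(len(found) - 1, 0),
        suboptimal_paths=[p for _, p in sorted(found, key=lambda t: (t[0], len(t[1]), t[1]))],
        node_frequency=freq,
        truncated=truncated,
    )


def path_table(
    graph: ResidueGraph,
    queries: list[tuple[int, int]],
    offset: int = 20,
    max_paths: int = 10000,
) -> pd.DataFrame:
    """One row per (source, sink) query: length, residue count, subopt count."""
    labels = graph.labels
    rows = []
    for source, sink in queries:
        res = suboptimal_paths(graph, source, sink, offset=offset, max_paths=max_paths)
        rows.append(
            {
                "source": labels.get(source, str(source)),
                "sink": labels.get(sink, str(sink)),
                "length": res.optimal_length if res.found else "no path",
                "n_residues": res.n_residues if res.found else 0,
                "suboptimal_count": res.suboptimal_count if res.found else 0,
                "truncated": res.truncated,
            }
        )
    return pd.DataFrame(rows, columns=["source", "sink", "length", "n_residues", "suboptimal_count", "truncated"])


def compare_pathways(a: PathResult, b: PathResult) -> str:
    """Three-criterion allosteric-strength comparison between two systems.

    A shorter optimal length, fewer involved residues, and more suboptimal
    paths each vote for a stronger allosteric relationship.  Unanimous
    (undissented) votes give ``'stronger_in_a'`` / ``'stronger_in_b'``;
    conflicting votes give ``'ambiguous_majority_a'`` /
    ``'ambiguous_majority_b'`` when one side still carries the majority, and
    plain ``'ambiguous'`` on a tie.
    """
    if not a.found or not b.found:
        return "ambiguous"
    votes: list[int] = []
    for va, vb, more_is_stronger in (
        (a.optimal_length, b.optimal_length, False),
        (a.n_residues, b.n_residues, False),
        (a.suboptimal_count, b.suboptimal_count, True),
    ):
        if va == vb:
            continue
        a_wins = (va > vb) if more_is_stronger else (va < vb)
        votes.append(1 if a_wins else -1)
    pro, con = votes.count(1), votes.count(-1)
    if pro and not con:
        return "stronger_in_a"
    if con and not pro:
        return "stronger_in_b"
    if pro > con:
        return "ambiguous_majority_a"
    if con > pro:
        return "ambiguous_majority_b"
    return "ambiguous"
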