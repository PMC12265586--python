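"""Protein structure networks (PSNs) and graphlet features.

A PSN has amino-acid residues as nodes and an edge between residues that
are close enough in the 3D structure (default: Cα–Cα within 6.0 Å).  A
folding pathway maps to a *dynamic* PSN — an ordered list of snapshots,
one per intermediate; for proxy-derived pathways the snapshots are
nested (each is an induced subgraph of the next).

Graphlets are the connected induced subgraphs on 2–4 nodes; there are 9
isomorphism classes:

    index 0  edge            (2 nodes)
    index 1  2-path          (3 nodes, P3)
    index 2  triangle        (3 nodes, K3)
    index 3  3-path          (4 nodes, P4)
    index 4  3-star          (4 nodes, claw)
    index 5  4-cycle         (4 nodes, C4)
    index 6  tailed triangle (4 nodes, paw)
    index 7  diamond         (4 nodes, K4 minus an edge)
    index 8  4-clique        (4 nodes, K4)

Counts are of induced occurrences, enumerated exactly.  Static features
are the 9 graphlet frequencies of a single PSN.  Dynamic features
resample the snapshot series to a fixed number of time bins and
concatenate per-bin frequency vectors plus an arrival histogram (the
normalized snapshot at which each graphlet class first appears; 1.0 if
never) — a per-snapshot feature scheme standing in for full dynamic
graphlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import Conformation, Pathway

__all__ = [
    "PSNParams", "PSN", "DynamicPSN", "GraphletVector", "GRAPHLET_NAMES",
    "build_psn", "build_dynamic_psn", "count_graphlets",
    "static_features", "dynamic_features",
]

GRAPHLET_NAMES = [
    "edge", "2-path", "triangle", "3-path", "3-star",
    "4-cycle", "tailed-triangle", "diamond", "4-clique",
]

# (n_edges, sorted degree sequence) -> class index, for connected
# induced subgraphs on 4 nodes
_FOUR_NODE_CLASS = {
    (3, (1, 1, 2, 2)): 3,   # path
    (3, (1, 1, 1, 3)): 4,   # star
    (4, (2, 2, 2, 2)): 5,   # cycle
    (4, (1, 2, 2, 3)): 6,   # tailed triangle
    (5, (2, 2, 3, 3)): 7,   # diamond
    (6, (3, 3, 3, 3)): 8,   # clique
}


@dataclass
class PSNParams:
    """Contact rule. ``ca``: Cα–Cα distance; ``any_atom``: minimum
    distance over all atom pairs (needs full-atom records)."""

    contact_mode: str = "ca"
    cutoff: float | None = None
    min_sequence_separation: int = 1

    def __post_init__(self) -> None:
        if self.contact_mode not in {"ca", "any_atom"}:
            raise ValueError("contact_mode must be 'ca' or 'any_atom'")
        if self.cutoff is None:
            self.cutoff = 6.0 if self.contact_mode == "ca" else 4.0
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")


@dataclass
class PSN:
    """Residue-contact graph; nodes are author residue numbers."""

    graph: nx.Graph
    snapshot_index: int | None = None

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DynamicPSN:
    """Ordered PSN snapshots for a folding pathway.  ``nested`` records
    whether node and edge sets grow monotonically (guaranteed only for
    proxy-derived pathways; validated, never forced)."""

    snapshots: list[PSN]
    nested: bool = field(init=False)

    def __post_init__(self) -> None:
        self.nested = all(
            a.nodes <= b.nodes and a.edges <= b.edges
            for a, b in zip(self.snapshots, self.snapshots[1:])
        )

    def __len__(self) -> int:
        return len(self.snapshots)


def build_psn(conf: Conformation, params: PSNParams | None = None) -> PSN:
    """Contact graph of one conformation: edge (i, j) iff
    |i − j| >= min_sequence_separation and the contact distance (per
    contact_mode) is <= cutoff."""
    params = params or PSNParams()
    if len(conf) < 1:
        raise ValueError("conformation has no residues")
    idx = conf.seq_indices
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in idx)
    if params.contact_mode == "ca":
        coords = conf.coords
        if len(conf) >= 2:
            dmat = squareform(pdist(coords))
            sep = np.abs(idx[:, None] - idx[None, :])
            ii, jj = np.nonzero((dmat <= params.cutoff)
                                & (sep >= params.min_sequence_separation))
            g.add_edges_from((int(idx[i]), int(idx[j]))
                             for i, j in zip(ii, jj) if i < j)
    else:
        res_atoms = []
        for r in conf.residues:
            if r.atoms is None:
                raise ValueError(
                    "any_atom contacts requested but residue "
                    f"{r.seq_index} has Cα-only data"
                )
            res_atoms.append(np.stack([c for _, c in r.atoms]))
        for i in range(len(conf)):
            for j in range(i + 1, len(conf)):
                if abs(int(idx[j]) - int(idx[i])) < params.min_sequence_separation:
                    continue
                diff = res_atoms[i][:, None, :] - res_atoms[j][None, :, :]
                if np.min(np.linalg.norm(diff, axis=-1)) <= params.cutoff:
                    g.add_edge(int(idx[i]), int(idx[j]))
    return PSN(graph=g)


def build_dynamic_psn(pathway: Pathway, params: PSNParams | None = None) -> DynamicPSN:
    """One PSN snapshot per pathway intermediate (each must hold exactly
    one conformation)."""
    confs = pathway.single_conformations()
    snapshots = []
    for pos, conf in enumerate(confs):
        psn = build_psn(conf, params)
        psn.snapshot_index = pos
        snapshots.append(psn)
    return DynamicPSN(snapshots=snapshots)


@dataclass
class GraphletVector:
    counts: np.ndarray
    frequencies: np.ndarray

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GraphletVector":
        counts = np.asarray(counts, dtype=np.int64)
        total = counts.sum()
        freq = counts / total if total > 0 else np.zeros(9)
        return cls(counts=counts, frequencies=freq)


def count_graphlets(psn: PSN) -> GraphletVector:
    """Exact counts of the 9 connected induced graphlets on 2–4 nodes.

    3-node classes come from neighbor-pair enumeration; 4-node classes
    from exact enumeration of connected 4-node subsets (ESU-style: each
    subset visited once), classified by edge count and degree sequence.
    """
    g = psn.graph
    counts = np.zeros(9, dtype=np.int64)
    counts[0] = g.number_of_edges()

    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    triangles = 0
    two_paths = 0
    for v, nbrs in adj.items():
        k = len(nbrs)
        two_paths += k * (k - 1) // 2
        nb = list(nbrs)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                if nb[b] in adj[nb[a]]:
                    triangles += 1
    triangles //= 3
    counts[2] = triangles
    counts[1] = two_paths - 3 * triangles

    # connected 4-node subsets, each enumerated exactly once
    order = {v: i for i, v in enumerate(sorted(g.nodes))}
    for s in _connected_subsets4(adj, order):
        m = 0
        deg = [0, 0, 0, 0]
        for a in range(4):
            for b in range(a + 1, 4):
                if s[b] in adj[s[a]]:
                    m += 1
                    deg[a] += 1
                    deg[b] += 1
        cls = _FOUR_NODE_CLASS.get((m, tuple(sorted(deg))))
        if cls is not None:  # disconnected induced subgraphs are skipped
            counts[cls] += 1
    return GraphletVector.from_counts(counts)


def _connected_subsets4(adj: dict, order: dict):
    """Yield every node subset of size 4 that induces a connected
    subgraph, exactly once (ESU enumeration rooted at the minimum node)."""
    for v in adj:
        ext = {u for u in adj[v] if order[u] > order[v]}
        _extend(adj, order, v, [v], ext, set(adj[v]), out := [])
        yield from out


def _extend(adj, order, root, sub, ext, nbrhood, out):
    if len(sub) == 4:
        out.append(tuple(sub))
        return
    ext = set(ext)
    while ext:
        w = ext.pop()
        # new extension: exclusive neighbors of w, beyond the root
        new_ext = ext | {u for u in adj[w]
                         if order[u] > order[root] and u not in nbrhood and u not in sub}
        _extend(adj, order, root, sub + [w], new_ext, nbrhood | adj[w], out)


def static_features(psn: PSN) -> np.ndarray:
    """The 9 graphlet frequencies of a single (static) PSN."""
    return count_graphlets(psn).frequencies.copy()


def dynamic_features(dpsn: DynamicPSN, n_bins: int = 10) -> np.ndarray:
    """Fixed-length feature vector of a dynamic PSN.

    Snapshots are resampled to n_bins time bins by nearest position (no
    graph interpolation); the per-bin 9-vectors of graphlet frequencies
    are concatenated, followed by a 9-long arrival histogram: for each
    graphlet class, (1-based index of the first snapshot where it
    appears) / (number of snapshots), or 1.0 if it never appears.
    Total length 9 * n_bins + 9.
    """
    if len(dpsn) < 1:
        raise ValueError("dynamic PSN has no snapshots")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    T = len(dpsn)
    gvs = [count_graphlets(s) for s in dpsn.snapshots]
    if n_bins == 1:
        bin_idx = [T - 1]
    else:
        bin_idx = [int(round(b * (T - 1) / (n_bins - 1))) for b in range(n_bins)]
    parts = [gvs[i].frequencies for i in bin_idx]
    arrival = np.ones(9)
    for cls in range(9):
        for t, gv in enumerate(gvs):
            if gv.counts[cls] > 0:
                arrival[cls] = (t + 1) / T
                break
    return np.concatenate(parts + [arrival])
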