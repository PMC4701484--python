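"""Tag collapsing, mismatch networks and error-tag removal.

A *tag* is the collapsed consensus of identical 80 + 80 nt paired-end reads;
its per-line read counts are the raw material of reference-free SNP
discovery.  Tags are pooled across the whole panel, singleton artefacts are
removed, and the survivors are linked into *networks*: connected components
of the graph whose edges join tags differing by at most two substitutions on
each end.  A network can mix the two alleles of one locus with homeologous
or paralogous copies from elsewhere in a polyploid genome — separating those
is the job of :mod:`radnet.allelic_call`.

Error tags are then pruned with an error tolerance rate (ETR): a low-count
tag connected to a much higher-count neighbour is treated as a sequencing
error derivative of that neighbour when count_low/(count_low + count_high)
falls at or below the ETR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "Tag",
    "Network",
    "collapse_reads",
    "filter_singletons",
    "pair_mismatches",
    "build_networks",
    "filter_error_tags",
    "filter_network_size",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Tag:
    """A distinct (r1, r2) sequence pair with per-line read counts."""

    seq_r1: str
    seq_r2: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def n_lines(self) -> int:
        return sum(1 for c in self.counts.values() if c >= 1)

    @property
    def key(self) -> Tuple[str, str]:
        return (self.seq_r1, self.seq_r2)


@dataclass
class Network:
    """A connected component of tags linked by <=2 mismatches per end.

    ``edges`` holds (i, j, mm_r1, mm_r2) with local tag indices i < j.
    """

    tags: List[Tag]
    edges: List[Tuple[int, int, int, int]]

    @property
    def n_tags(self) -> int:
        return len(self.tags)


def collapse_reads(stream: Iterable[tuple]) -> List[Tag]:
    """Collapse a (line_id, ReadPair) stream into a tag table.

    One Tag per distinct (r1, r2) pair; per-line counts are read
    multiplicities.  All reads must share one length per end.
    """
    table: Dict[Tuple[str, str], Dict[str, int]] = {}
    len_r1 = len_r2 = None
    for line_id, pair in stream:
        if len_r1 is None:
            len_r1, len_r2 = len(pair.r1), len(pair.r2)
        elif len(pair.r1) != len_r1 or len(pair.r2) != len_r2:
            raise ValueError(
                f"unequal read lengths: expected {len_r1}+{len_r2} nt, got "
                f"{len(pair.r1)}+{len(pair.r2)} nt for line {line_id!r}"
            )
        counts = table.setdefault((pair.r1, pair.r2), {})
        counts[line_id] = counts.get(line_id, 0) + 1
    # deterministic order: lexicographic on sequences
    return [Tag(r1, r2, table[(r1, r2)]) for r1, r2 in sorted(table)]


def filter_singletons(tags: Sequence[Tag]) -> List[Tag]:
    """Drop sequencing-error tags: keep a tag only if it has >=2 reads in
    total *and* is seen in >=2 distinct lines."""
    return [t for t in tags if t.total_count >= 2 and t.n_lines >= 2]


def pair_mismatches(tag_a: Tag, tag_b: Tag) -> Tuple[int, int]:
    """Ungapped Hamming mismatches per end between two tags."""
    if len(tag_a.seq_r1) != len(tag_b.seq_r1) or len(tag_a.seq_r2) != len(tag_b.seq_r2):
        raise ValueError("tags have unequal lengths; cannot count mismatches")
    mm1 = sum(a != b for a, b in zip(tag_a.seq_r1, tag_b.seq_r1))
    mm2 = sum(a != b for a, b in zip(tag_a.seq_r2, tag_b.seq_r2))
    return mm1, mm2


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """One-hot encode equal-length sequences -> (n, 5*L) float32."""
    n = len(seqs)
    L = len(seqs[0])
    codes = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    lut = np.full(256, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    codes = lut[codes]
    onehot = np.zeros((n, L, 5), dtype=np.float32)
    np.put_along_axis(onehot, codes[:, :, None].astype(np.int64), 1.0, axis=2)
    return onehot.reshape(n, L * 5)


def _mismatch_matrix(seqs: Sequence[str]) -> np.ndarray:
    """All-pairs Hamming distances via one-hot matmul (identical bases match)."""
    onehot = _encode(seqs)
    L = len(seqs[0])
    matches = onehot @ onehot.T
    return np.rint(L - matches).astype(np.int16)


def _adjacency_edges(tags: Sequence[Tag], max_mm_per_end: int):
    """Edge list (i, j, mm1, mm2), i<j, linking tags within the per-end bound."""
    if len(tags) < 2:
        return []
    mm1 = _mismatch_matrix([t.seq_r1 for t in tags])
    mm2 = _mismatch_matrix([t.seq_r2 for t in tags])
    ok = (mm1 <= max_mm_per_end) & (mm2 <= max_mm_per_end)
    ii, jj = np.where(np.triu(ok, k=1))
    return [
        (int(i), int(j), int(mm1[i, j]), int(mm2[i, j]))
        for i, j in zip(ii, jj)
        if mm1[i, j] + mm2[i, j] >= 1
    ]


def build_networks(tags: Sequence[Tag], max_mm_per_end: int = 2) -> List[Network]:
    """Partition the tag table into connected components of the mismatch graph.

    An edge joins two tags when each end differs by at most
    ``max_mm_per_end`` substitutions (and the tags are not identical).
    Components are returned in deterministic order (sorted by the smallest
    member's sequences); singleton components are included so that the output
    partitions the input.
    """
    tags = list(tags)
    edges = _adjacency_edges(tags, max_mm_per_end)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(tags)))
    graph.add_edges_from((i, j) for i, j, _a, _b in edges)
    networks = []
    for component in nx.connected_components(graph):
        idx = sorted(component)
        local = {g: l for l, g in enumerate(idx)}
        net_edges = [
            (local[i], local[j], a, b) for i, j, a, b in edges if i in local and j in local
        ]
        networks.append(Network([tags[g] for g in idx], sorted(net_edges)))
    networks.sort(key=lambda n: n.tags[0].key)
    return networks


def filter_error_tags(network: Network, etr: float = 0.03) -> List[Network]:
    """Remove error tags from one network and re-split the remainder.

    On every edge (A, B) with total_count(A) <= total_count(B), tag A is an
    error derivative of B when count_A / (count_A + count_B) <= etr.  Removal
    is done in simultaneous sweeps — every tag flagged by at least one edge of
    the current graph is dropped, edges are recomputed, and the sweep repeats
    until a fixed point — which makes the result independent of edge order.
    Removal can disconnect a component, so the survivors are re-split into
    connected components before size filtering.
    """
    if not 0.0 <= etr < 0.5:
        raise ValueError(f"etr must be in [0, 0.5), got {etr}")
    alive = list(range(len(network.tags)))
    totals = [t.total_count for t in network.tags]
    edges = network.edges
    while True:
        alive_set = set(alive)
        flagged = set()
        for i, j, _a, _b in edges:
            if i not in alive_set or j not in alive_set:
                continue
            lo, hi = (i, j) if totals[i] <= totals[j] else (j, i)
            denom = totals[lo] + totals[hi]
            if denom and totals[lo] / denom <= etr:
                flagged.add(lo)
        if not flagged:
            break
        alive = [i for i in alive if i not in flagged]
    kept = [network.tags[i] for i in alive]
    if not kept:
        return []
    # re-derive components among the survivors
    graph = nx.Graph()
    graph.add_nodes_from(alive)
    alive_set = set(alive)
    for i, j, _a, _b in edges:
        if i in alive_set and j in alive_set:
            graph.add_edge(i, j)
    out = []
    for component in nx.connected_components(graph):
        idx = sorted(component)
        local = {g: l for l, g in enumerate(idx)}
        net_edges = sorted(
            (local[i], local[j], a, b)
            for i, j, a, b in edges
            if i in local and j in local
        )
        out.append(Network([network.tags[g] for g in idx], net_edges))
    out.sort(key=lambda n: n.tags[0].key)
    return out


def filter_network_size(
    networks: Iterable[Network], min_tags: int = 2, max_tags: int = 10
) -> List[Network]:
    """Keep networks with min_tags <= |tags| <= max_tags (default 2..10)."""
    return [n for n in networks if min_tags <= n.n_tags <= max_tags]
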