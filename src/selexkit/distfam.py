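"""Pairwise distances and family calling for aptamer sequences/structures.

Sequences are compared by Levenshtein edit distance (substitutions,
insertions, deletions at unit cost) on the variable region; predicted
secondary structures are compared by ordered tree edit distance
(Zhang-Shasha, unit costs) on a P/U-labelled tree encoding of the
dot-bracket: each base pair becomes an internal ``P`` node, each unpaired
base a ``U`` leaf, all hanging under a virtual root ``R``.

A threshold graph connects sequences at distance <= d; its connected
components of size >= 2 are the families (singletons are reported apart).
Merging components across increasing thresholds yields a single-linkage
dendrogram whose integer merge heights are the smallest distances at
which sub-families join.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from numba import njit

from .errors import InputError
from .seqio import SequenceRecord

DEFAULT_SEQUENCE_THRESHOLD = 1
DEFAULT_STRUCTURE_THRESHOLD_RANGE = (3, 6)


# ---------------------------------------------------------------------------
# Sequence edit distance
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit costs."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def edit_distance_bounded(a: str, b: str, k: int) -> int | None:
    """Distance if <= k, else None (banded computation)."""
    if abs(len(a) - len(b)) > k:
        return None
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    return None if d < 0 else d


# ---------------------------------------------------------------------------
# Structure trees and Zhang-Shasha tree edit distance
# ---------------------------------------------------------------------------

@dataclass
class StructureTree:
    """Ordered rooted tree encoding of a dot-bracket structure."""

    label: str
    children: list["StructureTree"] = field(default_factory=list)

    @property
    def node_count(self) -> int:
        return 1 + sum(c.node_count for c in self.children)


def structure_to_tree(dot_bracket: str) -> StructureTree:
    """P/U tree under a virtual root; child order follows 5'->3'."""
    root = StructureTree("R")
    stack = [root]
    for ch in dot_bracket:
        if ch == "(":
            node = StructureTree("P")
            stack[-1].children.append(node)
            stack.append(node)
        elif ch == ")":
            if len(stack) == 1:
                raise InputError(f"unbalanced dot-bracket: {dot_bracket!r}")
            stack.pop()
        elif ch == ".":
            stack[-1].children.append(StructureTree("U"))
        else:
            raise InputError(f"invalid character {ch!r} in dot-bracket")
    if len(stack) != 1:
        raise InputError(f"unbalanced dot-bracket: {dot_bracket!r}")
    return root


def _postorder(tree: StructureTree):
    """(labels, leftmost-leaf indices, keyroots) in postorder numbering."""
    labels: list[str] = []
    lml: list[int] = []

    def walk(node: StructureTree) -> int:
        first_leaf = None
        for child in node.children:
            leaf = walk(child)
            if first_leaf is None:
                first_leaf = leaf
        idx = len(labels)
        labels.append(node.label)
        lml.append(first_leaf if first_leaf is not None else idx)
        return lml[idx]

    walk(tree)
    n = len(labels)
    seen: set[int] = set()
    keyroots = []
    for i in range(n - 1, -1, -1):
        if lml[i] not in seen:
            keyroots.append(i)
            seen.add(lml[i])
    return labels, lml, sorted(keyroots)


@njit(cache=True)
def _zss_kernel(labels1, l1, kr1, labels2, l2, kr2):  # pragma: no cover - jit
    n1, n2 = labels1.shape[0], labels2.shape[0]
    td = np.zeros((n1, n2), dtype=np.int32)
    fd = np.zeros((n1 + 1, n2 + 1), dtype=np.int32)
    for a in range(kr1.shape[0]):
        k1 = kr1[a]
        for b in range(kr2.shape[0]):
            k2 = kr2[b]
            # forest distance between subtrees rooted at k1, k2
            i0, j0 = l1[k1], l2[k2]
            m, n = k1 - i0 + 2, k2 - j0 + 2
            fd[0, 0] = 0
            for di in range(1, m):
                fd[di, 0] = fd[di - 1, 0] + 1
            for dj in range(1, n):
                fd[0, dj] = fd[0, dj - 1] + 1
            for di in range(1, m):
                i = i0 + di - 1
                for dj in range(1, n):
                    j = j0 + dj - 1
                    if l1[i] == i0 and l2[j] == j0:
                        rel = 0 if labels1[i] == labels2[j] else 1
                        best = fd[di - 1, dj - 1] + rel
                        if fd[di - 1, dj] + 1 < best:
                            best = fd[di - 1, dj] + 1
                        if fd[di, dj - 1] + 1 < best:
                            best = fd[di, dj - 1] + 1
                        fd[di, dj] = best
                        td[i, j] = best
                    else:
                        best = fd[l1[i] - i0, l2[j] - j0] + td[i, j]
                        if fd[di - 1, dj] + 1 < best:
                            best = fd[di - 1, dj] + 1
                        if fd[di, dj - 1] + 1 < best:
                            best = fd[di, dj - 1] + 1
                        fd[di, dj] = best
    return td[n1 - 1, n2 - 1]


_LABEL_CODE = {"R": 0, "P": 1, "U": 2}


def _encode(tree: StructureTree):
    labels, lml, keyroots = _postorder(tree)
    return (
        np.array([_LABEL_CODE[l] for l in labels], dtype=np.int8),
        np.array(lml, dtype=np.int32),
        np.array(keyroots, dtype=np.int32),
    )


def tree_edit_distance(t1: StructureTree, t2: StructureTree) -> int:
    """Ordered tree edit distance (Zhang-Shasha), unit costs."""
    return int(_zss_kernel(*_encode(t1), *_encode(t2)))


def structure_distance(dot1: str, dot2: str) -> int:
    """Tree edit distance between two dot-bracket structures."""
    return tree_edit_distance(structure_to_tree(dot1), structure_to_tree(dot2))


# ---------------------------------------------------------------------------
# Distance graphs
# ---------------------------------------------------------------------------

@dataclass
class DistanceGraph:
    """Sparse symmetric pair distances (<= d_max) among sequence ids."""

    metric: str  # "edit" | "tree"
    d_max: int
    nodes: list[int]
    edges: dict[tuple[int, int], int]  # (id1<id2) -> distance

    def edges_at(self, d: int) -> Iterable[tuple[int, int, int]]:
        if d > self.d_max:
            raise InputError(f"threshold {d} exceeds computed d_max {self.d_max}")
        return ((a, b, dist) for (a, b), dist in self.edges.items() if dist <= d)

    def graph_at(self, d: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, dist in self.edges_at(d):
            g.add_edge(a, b, distance=dist)
        return g


def _metric_strings(records: Sequence[SequenceRecord], metric: str,
                    full_length: bool = False) -> dict[int, str]:
    if metric == "edit":
        return {r.id: (r.full_rna if full_length else r.variable_region_dna)
                for r in records}
    if metric == "tree":
        missing = [r.id for r in records if r.structure is None]
        if missing:
            raise InputError(f"records lack structures for tree metric: {missing}")
        return {r.id: r.structure.dot_bracket for r in records}
    raise InputError(f"unknown metric: {metric}")


def build_distance_graph(
    records: Sequence[SequenceRecord], metric: str, d_max: int,
    full_length: bool = False,
) -> DistanceGraph:
    """All unordered pair distances <= d_max among the records.

    Pairs whose lengths differ by more than d_max are skipped outright
    (the length difference lower-bounds both metrics), which is exact.
    Identical strings are deduplicated before the quadratic pass.
    """
    strings = _metric_strings(records, metric, full_length)
    ids = sorted(strings)
    # dedupe: distance depends only on the string pair
    by_string: dict[str, list[int]] = {}
    for i in ids:
        by_string.setdefault(strings[i], []).append(i)
    uniq = sorted(by_string)
    edges: dict[tuple[int, int], int] = {}

    def add_edge(a: int, b: int, d: int) -> None:
        edges[(a, b) if a < b else (b, a)] = d

    # zero-distance edges among identical strings (chained is enough for
    # components, but store the full clique for graph faithfulness)
    for s, members in by_string.items():
        for a, b in itertools.combinations(members, 2):
            add_edge(a, b, 0)

    if metric == "tree":
        trees = {s: _encode(structure_to_tree(s)) for s in uniq}
    for x, y in itertools.combinations(uniq, 2):
        if abs(len(x) - len(y)) > d_max:
            continue
        if metric == "edit":
            d = edit_distance_bounded(x, y, d_max)
        else:
            d = int(_zss_kernel(*trees[x], *trees[y]))
            d = d if d <= d_max else None
        if d is None:
            continue
        for a in by_string[x]:
            for b in by_string[y]:
                add_edge(a, b, d)
    return DistanceGraph(metric=metric, d_max=d_max, nodes=ids, edges=edges)


# ---------------------------------------------------------------------------
# Families (threshold components) and dendrograms
# ---------------------------------------------------------------------------

@dataclass
class Family:
    kind: str  # "sequence" | "structure"
    threshold: int
    members: list[int]
    label: str = ""
    representative_id: int | None = None


def components_at_threshold(
    graph: DistanceGraph, d: int
) -> tuple[list[list[int]], list[int]]:
    """Connected components of the <=d subgraph: (families, singletons).

    Components are sorted by size descending then smallest member id;
    members sorted ascending.  Size-1 components are returned separately.
    """
    g = graph.graph_at(d)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    families = [c for c in comps if len(c) >= 2]
    singletons = sorted(c[0] for c in comps if len(c) == 1)
    return families, singletons


@dataclass
class Dendrogram:
    """Single-linkage merge structure over integer distances."""

    leaves: list[int]
    merges: list[tuple[int, frozenset, frozenset]]  # (height, comp_a, comp_b)
    complete: bool  # all leaves connected at the graph's d_max

    @property
    def merge_heights(self) -> list[int]:
        return [m[0] for m in self.merges]

    def to_newick(self) -> str:
        name: dict[frozenset, str] = {}
        for leaf in self.leaves:
            name[frozenset([leaf])] = str(leaf)
        height: dict[frozenset, int] = {frozenset([l]): 0 for l in self.leaves}
        for h, a, b in self.merges:
            merged = a | b
            la = (height[a], name[a])
            lb = (height[b], name[b])
            name[merged] = "({}:{},{}:{})".format(
                la[1], h - la[0], lb[1], h - lb[0])
            height[merged] = h
        roots = [k for k in name if not any(k < other for other in name)]
        if len(roots) == 1:
            return name[roots[0]] + ";"
        return "(" + ",".join(name[r] + ":0" for r in sorted(roots, key=min)) + ");"


def build_dendrogram(graph: DistanceGraph) -> Dendrogram:
    """Single-linkage dendrogram by union-find over distance-sorted edges.

    Merge heights equal the minimal threshold at which components join;
    ``complete`` is False when the graph stays disconnected at d_max
    (a partial dendrogram).
    """
    parent: dict[int, int] = {i: i for i in graph.nodes}
    members: dict[int, frozenset] = {i: frozenset([i]) for i in graph.nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[tuple[int, frozenset, frozenset]] = []
    for (a, b), dist in sorted(graph.edges.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        merges.append((dist, members[ra], members[rb]))
        parent[rb] = ra
        members[ra] = members[ra] | members[rb]
    complete = len({find(i) for i in graph.nodes}) <= 1
    return Dendrogram(leaves=list(graph.nodes), merges=merges, complete=complete)


def roman_numeral(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def letter_label(n: int) -> str:
    """1 -> A, 26 -> Z, 27 -> AA, ..."""
    out = []
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out.append(chr(ord("A") + rem))
    return "".join(reversed(out))


def _order_by_reads(families: list[list[int]],
                    reads: Mapping[int, int]) -> list[list[int]]:
    return sorted(families,
                  key=lambda c: (-sum(reads[i] for i in c), c[0]))


def call_sequence_families(
    records: Sequence[SequenceRecord],
    threshold: int = DEFAULT_SEQUENCE_THRESHOLD,
    graph: DistanceGraph | None = None,
) -> list[Family]:
    """Components at edit distance <= threshold, labelled I, II, ... in
    descending total-read order; labels written onto the records."""
    if graph is None:
        graph = build_distance_graph(records, "edit", threshold)
    comps, _ = components_at_threshold(graph, threshold)
    reads = {r.id: r.total_reads for r in records}
    by_id = {r.id: r for r in records}
    families = []
    for idx, comp in enumerate(_order_by_reads(comps, reads), start=1):
        fam = Family(kind="sequence", threshold=threshold,
                     members=comp, label=roman_numeral(idx))
        for i in comp:
            by_id[i].sequence_family = fam.label
        families.append(fam)
    return families


def call_structure_families(
    records: Sequence[SequenceRecord],
    threshold_range: tuple[int, int] = DEFAULT_STRUCTURE_THRESHOLD_RANGE,
    graph: DistanceGraph | None = None,
) -> list[Family]:
    """Structure families with per-family adaptive thresholds.

    Base families are tree-distance components at the low end of the
    range; each family then absorbs nearby singletons by raising its own
    threshold stepwise up to the high end, stopping before a step that
    would merge it with another family's members.  Families are processed
    (and labelled A, B, ...) in descending total-read order.
    """
    lo, hi = threshold_range
    if lo > hi:
        raise InputError("threshold range must be (low, high) with low <= high")
    if graph is None:
        graph = build_distance_graph(records, "tree", hi)
    base, _ = components_at_threshold(graph, lo)
    reads = {r.id: r.total_reads for r in records}
    by_id = {r.id: r for r in records}
    base = _order_by_reads(base, reads)
    base_membership: dict[int, int] = {}
    for fi, comp in enumerate(base):
        for i in comp:
            base_membership[i] = fi

    claimed: set[int] = set()
    families: list[Family] = []
    for fi, comp in enumerate(base):
        accepted = set(comp)
        accepted_t = lo
        for t in range(lo + 1, hi + 1):
            g = graph.graph_at(t)
            grown: set[int] = set()
            for i in comp:
                grown.update(nx.node_connected_component(g, i))
            foreign = any(
                (base_membership.get(i, fi) != fi) or (i in claimed and i not in accepted)
                for i in grown
            )
            if foreign:
                break
            accepted, accepted_t = grown, t
        fam = Family(kind="structure", threshold=accepted_t,
                     members=sorted(accepted), label=letter_label(fi + 1))
        for i in fam.members:
            by_id[i].structure_family = fam.label
        claimed.update(fam.members)
        families.append(fam)
    return families


def call_families(
    records: Sequence[SequenceRecord],
    sequence_threshold: int = DEFAULT_SEQUENCE_THRESHOLD,
    structure_threshold_range: tuple[int, int] = DEFAULT_STRUCTURE_THRESHOLD_RANGE,
    with_structures: bool = True,
) -> tuple[list[Family], list[Family]]:
    """Label records with sequence and (optionally) structure families."""
    seq_fams = call_sequence_families(records, sequence_threshold)
    struct_fams = call_structure_families(records, structure_threshold_range) \
        if with_structures else []
    return seq_fams, struct_fams


def edges_to_frame(graph: DistanceGraph):
    """Edge list as a 3-column table (id1, id2, distance)."""
    import pandas as pd

    rows = [(a, b, d) for (a, b), d in sorted(graph.edges.items())]
    return pd.DataFrame(rows, columns=["id1", "id2", "distance"])
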