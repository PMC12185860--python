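"""Oriented contig-graph adjacency and depth-first linearization.

An assembly graph is bidirected: a link ``(a, oa) -> (b, ob)`` can equally
be traversed as ``(b, flip(ob)) -> (a, flip(oa))``.  We materialize both
directions of every link on *oriented nodes* (segment id, orientation) and
linearize with an iterative depth-first search, emitting each segment once,
at first visit, in the orientation in which it was first reached.  Following
each path to its end before backtracking keeps overlapping contigs — and
therefore the reads mapped to them — adjacent in the final order, which is
exactly the locality a bounded-window compressor can exploit.

Tie-breaks are fixed so the order is a pure function of the GFA bytes:
successors sort by descending overlap length (more shared sequence across
the junction), then descending segment length, then ascending id; roots are
in-degree-0 forward-oriented nodes taken longest-first, with the longest
unvisited segment as fallback inside fully cyclic components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import ContigGraph

__all__ = ["ContigOrder", "build_adjacency", "dfs_order", "order_equivalence_oracle"]

ORACLE_MAX_SEGMENTS = 12


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass
class ContigOrder:
    """Linearization of every segment as (segment id, traversal orientation).

    ``rank`` maps segment id to its position; a bijection onto
    ``0..n_segments-1``.  ``orientation`` records how the DFS first reached
    each segment; downstream, a '-' orientation flips that contig's read
    block so reads stay collinear with the traversal.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def rank(self) -> dict[str, int]:
        return {seg: i for i, (seg, _) in enumerate(self.entries)}

    @property
    def orientation(self) -> dict[str, str]:
        return {seg: o for seg, o in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _oriented_edges(graph: ContigGraph) -> set[tuple[str, str, str, str]]:
    """Deduplicated oriented edges: each link plus its mirrored traversal.

    Deduplication makes graphs whose GFA writes a link in both directions
    (one L line per direction) identical to graphs that write it once.
    """
    edges: set[tuple[str, str, str, str]] = set()
    for link in graph.links:
        edges.add((link.from_id, link.from_orient, link.to_id, link.to_orient))
        edges.add((link.to_id, _flip(link.to_orient), link.from_id, _flip(link.from_orient)))
    return edges


def _edge_overlap(graph: ContigGraph) -> dict[tuple[str, str, str, str], int]:
    """Max overlap length per oriented edge (and its mirror)."""
    ov: dict[tuple[str, str, str, str], int] = {}
    for link in graph.links:
        fwd = (link.from_id, link.from_orient, link.to_id, link.to_orient)
        rev = (link.to_id, _flip(link.to_orient), link.from_id, _flip(link.from_orient))
        for key in (fwd, rev):
            ov[key] = max(ov.get(key, 0), link.overlap_len)
    return ov


def _successor_sort_key(graph: ContigGraph, overlaps, node):
    def key(succ: tuple[str, str]):
        seg, orient = succ
        edge = (node[0], node[1], seg, orient)
        return (-overlaps.get(edge, 0), -graph.segments[seg].length, seg, orient)

    return key


def build_adjacency(graph: ContigGraph, strict: bool = True) -> ContigGraph:
    """Populate ``graph.adjacency`` with deterministically ordered successor
    lists over oriented nodes; returns the same graph object.

    Every link contributes its forward traversal and the mirrored reverse
    traversal (bidirected symmetry).  Successors sort by descending overlap
    length, then descending segment length, then ascending id.
    """
    for link in graph.links:
        for seg_id in (link.from_id, link.to_id):
            if seg_id not in graph.segments:
                if strict:
                    raise KeyError(f"link references unknown segment {seg_id!r}")
                from .io_formats import GfaSegment

                graph.segments[seg_id] = GfaSegment(seg_id, 0, None)
    adjacency: dict[tuple[str, str], list[tuple[str, str]]] = {}
    overlaps = _edge_overlap(graph)
    for fid, fo, tid, to in _oriented_edges(graph):
        adjacency.setdefault((fid, fo), []).append((tid, to))
    for node, succs in adjacency.items():
        succs.sort(key=_successor_sort_key(graph, overlaps, node))
    graph.adjacency = adjacency
    return graph


def _root_nodes(graph: ContigGraph) -> list[tuple[str, str]]:
    """Forward-oriented nodes with no incoming oriented edge, longest first.

    Starting at path ends maximizes uninterrupted runs through the graph.
    """
    assert graph.adjacency is not None
    indeg: dict[tuple[str, str], int] = {}
    for _, succs in graph.adjacency.items():
        for succ in succs:
            indeg[succ] = indeg.get(succ, 0) + 1
    roots = [
        (seg_id, "+")
        for seg_id in graph.segments
        if indeg.get((seg_id, "+"), 0) == 0
    ]
    roots.sort(key=lambda n: (-graph.segments[n[0]].length, n[0]))
    return roots


def dfs_order(graph: ContigGraph) -> ContigOrder:
    """Linearize by iterative depth-first search over oriented nodes.

    Each segment is emitted exactly once, at first visit, with the
    orientation in which it was first reached; the visited set is keyed on
    segment ids so cycles and opposite-orientation re-entries terminate.
    After the in-degree-0 roots are exhausted, remaining components
    (isolated segments, cycles) are rooted at their longest unvisited
    segment until every segment appears.
    """
    if graph.adjacency is None:
        build_adjacency(graph)
    assert graph.adjacency is not None
    order = ContigOrder()
    visited: set[str] = set()

    def run_from(root: tuple[str, str]) -> None:
        stack = [root]
        while stack:
            seg, orient = stack.pop()
            if seg in visited:
                continue
            visited.add(seg)
            order.entries.append((seg, orient))
            # push successors reversed so the best-sorted one is expanded first
            for succ in reversed(graph.adjacency.get((seg, orient), [])):
                if succ[0] not in visited:
                    stack.append(succ)

    for root in _root_nodes(graph):
        if root[0] not in visited:
            run_from(root)
    # leftover components have no in-degree-0 entry point (cycles) or are
    # isolated under a nonstandard orientation pattern
    remaining = sorted(
        (s for s in graph.segments if s not in visited),
        key=lambda s: (-graph.segments[s].length, s),
    )
    for seg in remaining:
        if seg not in visited:
            run_from((seg, "+"))
    return order


def order_equivalence_oracle(graph: ContigGraph, order: ContigOrder) -> bool:
    """Brute-force recursive DFS with identical tie-breaks; compares with
    ``order``.  Refuses graphs above ``ORACLE_MAX_SEGMENTS`` segments — the
    oracle exists to cross-check small cases, not to scale."""
    if graph.n_segments > ORACLE_MAX_SEGMENTS:
        raise ValueError(
            f"oracle limited to {ORACLE_MAX_SEGMENTS} segments, "
            f"got {graph.n_segments}"
        )
    if graph.adjacency is None:
        build_adjacency(graph)
    assert graph.adjacency is not None
    entries: list[tuple[str, str]] = []
    visited: set[str] = set()

    def recurse(seg: str, orient: str) -> None:
        if seg in visited:
            return
        visited.add(seg)
        entries.append((seg, orient))
        for succ_seg, succ_orient in graph.adjacency.get((seg, orient), []):
            recurse(succ_seg, succ_orient)

    for root_seg, root_orient in _root_nodes(graph):
        recurse(root_seg, root_orient)
    for seg in sorted(
        graph.segments, key=lambda s: (-graph.segments[s].length, s)
    ):
        recurse(seg, "+")
    return entries == order.entries
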