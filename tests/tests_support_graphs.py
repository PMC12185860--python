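"""Shared helpers for building small contig graphs in tests."""

from seqorder.io_formats import ContigGraph, GfaLink, GfaSegment


def graph_from(segments, links):
    g = ContigGraph()
    for sid, length in segments:
        g.segments[sid] = GfaSegment(sid, length)
    for link in links:
        g.links.append(GfaLink(*link))
    return g


def random_contig_graph(rng, max_segments=10):
    """Seeded random graph: random lengths, orientations and overlaps,
    including disconnected, cyclic and self-loop cases."""
    n = int(rng.integers(0, max_segments + 1))
    segments = [(f"s{i}", int(rng.integers(1, 100))) for i in range(n)]
    links = []
    if n:
        for _ in range(int(rng.integers(0, 2 * n + 1))):
            a, b = rng.integers(0, n, size=2)
            links.append(
                (
                    f"s{a}",
                    "+-"[int(rng.integers(0, 2))],
                    f"s{b}",
                    "+-"[int(rng.integers(0, 2))],
                    int(rng.integers(0, 500)),
                )
            )
    return graph_from(segments, links)
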