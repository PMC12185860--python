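"""From (mappings, contig order, strand mode) to the final read permutation.

The placement rule is deliberately simple: sort the mappings by contig (in
graph-traversal order) and by start position within each contig, emit each
read at its first encounter, and append reads with no mapping at the end in
their input order.  Three strand modes control orientation:

``unify``
    reads mapping to the reverse strand are emitted reverse-complemented,
    so neighbouring reads share literal substrings (best compression);
``preserve``
    sequences are untouched; reads are grouped by alignment strand first
    ('+' block, then '-' block), each block sorted by contig and position;
``ignore``
    sequences untouched, strand ignored entirely in the sort.

A contig the DFS reached in '-' orientation has its block read back to
front (sort by descending end position, effective strands flipped) so its
reads stay collinear with the traversal; ``block_flip=False`` disables this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from .contig_graph import ContigOrder
from .io_formats import MappingRecord, ReadRecord, read_sequences
from .restore import RestoreTable, flip_record

logger = logging.getLogger(__name__)

StrandMode = Literal["unify", "preserve", "ignore"]
STRAND_MODES: tuple[StrandMode, ...] = ("unify", "preserve", "ignore")

__all__ = [
    "StrandMode",
    "STRAND_MODES",
    "PlacementPlan",
    "sort_mappings",
    "best_mapping_filter",
    "plan_placement",
    "apply_plan",
    "locality_score",
]


@dataclass
class PlacementPlan:
    """The final read permutation plus its provenance.

    ``placed`` holds (read_id, emit_reverse_complement) in output order for
    mapped reads; ``unmapped_ids`` the remainder, in input order.  The
    reverse-complement flag is only ever set under strand mode ``unify``.
    """

    placed: list[tuple[str, bool]] = field(default_factory=list)
    unmapped_ids: list[str] = field(default_factory=list)
    provenance: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    mode: StrandMode = "unify"

    @property
    def ordered_ids(self) -> list[str]:
        return [rid for rid, _ in self.placed] + list(self.unmapped_ids)

    @property
    def flips(self) -> dict[str, bool]:
        out = {rid: rc for rid, rc in self.placed}
        out.update({rid: False for rid in self.unmapped_ids})
        return out

    def __len__(self) -> int:
        return len(self.placed) + len(self.unmapped_ids)


def sort_mappings(
    mappings: Iterable[MappingRecord],
    order: ContigOrder,
    mode: StrandMode = "unify",
    block_flip: bool = True,
) -> list[MappingRecord]:
    """Sort mappings by (contig rank, position); strand-group first under
    ``preserve``.

    Returned records carry the *effective* strand: for a contig traversed
    in '-' orientation (with ``block_flip``), positions sort by descending
    end and strands are flipped, so the block reads collinearly with the
    traversal.  Mappings to contigs absent from ``order`` are dropped with
    a warning — their reads fall through to the unmapped tail unless mapped
    elsewhere.
    """
    rank = order.rank
    orientation = order.orientation
    keyed: list[tuple[tuple, MappingRecord]] = []
    n_unknown = 0
    for m in mappings:
        r = rank.get(m.contig_id)
        if r is None:
            n_unknown += 1
            continue
        flipped_block = block_flip and orientation.get(m.contig_id) == "-"
        if flipped_block:
            pos_key = -m.t_end
            m = replace(m, strand="-" if m.strand == "+" else "+")
        else:
            pos_key = m.t_start
        if mode == "preserve":
            key = (0 if m.strand == "+" else 1, r, pos_key, m.read_id)
        else:
            key = (r, pos_key, m.read_id)
        keyed.append((key, m))
    if n_unknown:
        logger.warning(
            "%d mappings reference contigs absent from the order; "
            "affected reads fall back to the unmapped tail",
            n_unknown,
        )
    keyed.sort(key=lambda km: km[0])
    return [m for _, m in keyed]


def best_mapping_filter(mappings: Iterable[MappingRecord]) -> list[MappingRecord]:
    """Keep each read's maximum-``n_match`` mapping (first seen wins ties).

    An alternative to literal first-encounter dedup: pre-filtering to the
    best alignment per read before sorting.
    """
    best: dict[str, MappingRecord] = {}
    order: list[str] = []
    for m in mappings:
        cur = best.get(m.read_id)
        if cur is None:
            best[m.read_id] = m
            order.append(m.read_id)
        elif m.n_match > cur.n_match:
            best[m.read_id] = m
    return [best[rid] for rid in order]


def plan_placement(
    sorted_mappings: Sequence[MappingRecord],
    input_ids: Sequence[str],
    mode: StrandMode = "unify",
) -> PlacementPlan:
    """First-encounter placement: scan the sorted mappings, emit each read
    the first time it appears, append never-mapped reads in input order.

    Under ``unify`` a read whose (effective) strand is '-' is flagged for
    reverse complementing; the other modes never alter a sequence.
    """
    known = set(input_ids)
    if len(known) != len(input_ids):
        raise ValueError("input read ids are not unique")
    plan = PlacementPlan(mode=mode)
    seen: set[str] = set()
    for m in sorted_mappings:
        if m.read_id not in known:
            raise KeyError(
                f"mapping references read id {m.read_id!r} absent from input "
                f"(PAF does not match the read file)"
            )
        if m.read_id in seen:
            continue
        seen.add(m.read_id)
        emit_rc = mode == "unify" and m.strand == "-"
        plan.placed.append((m.read_id, emit_rc))
        plan.provenance[m.read_id] = (m.contig_id, m.t_start, m.strand)
    plan.unmapped_ids = [rid for rid in input_ids if rid not in seen]
    return plan


def _records_by_plan(
    records: dict[str, ReadRecord], plan: PlacementPlan
) -> Iterator[tuple[ReadRecord, bool]]:
    for rid, emit_rc in plan.placed:
        yield records[rid], emit_rc
    for rid in plan.unmapped_ids:
        yield records[rid], False


def apply_plan(
    source: str | Path | Iterable[ReadRecord],
    plan: PlacementPlan,
) -> tuple[Iterator[ReadRecord], RestoreTable]:
    """Emit records in plan order, reverse-complementing where flagged, and
    build the restore table inverting the permutation.

    ``source`` may be a path (streamed twice: an index pass recording byte
    offsets, then an emit pass seeking per read — memory stays proportional
    to the number of reads, not bases) or an in-memory record iterable.
    The record ids must match the plan's id universe exactly; mismatches in
    either direction raise, listing up to 10 offenders.
    """
    import numpy as np

    if isinstance(source, (str, Path)):
        records = {rec.id: rec for rec in _SeekableReads(source)}
    else:
        records = {rec.id: rec for rec in source}

    plan_ids = plan.ordered_ids
    missing = [rid for rid in plan_ids if rid not in records][:10]
    extra = [rid for rid in records if rid not in set(plan_ids)][:10]
    if missing or extra:
        raise KeyError(
            f"plan/read-file id mismatch; plan-only: {missing}; "
            f"file-only: {extra}"
        )

    input_index = {rid: i for i, rid in enumerate(records)}
    original = np.fromiter(
        (input_index[rid] for rid in plan_ids), dtype=np.uint32, count=len(plan_ids)
    )
    flips = plan.flips
    flipped = np.fromiter(
        (flips[rid] for rid in plan_ids), dtype=bool, count=len(plan_ids)
    )
    table = RestoreTable(original, flipped, mode=plan.mode)

    def emit() -> Iterator[ReadRecord]:
        for rec, emit_rc in _records_by_plan(records, plan):
            yield flip_record(rec) if emit_rc else rec

    return emit(), table


class _SeekableReads:
    """Two-pass path reader: index pass stores ids only; records are
    re-parsed lazily on the emit pass via the dict's insertion order.

    For the dataset sizes this package targets a plain dict of records is
    the pragmatic choice; the class exists to keep the path-vs-iterable
    seam in one place should an offset-seeking reader be needed.
    """

    def __init__(self, path: str | Path):
        self.path = path

    def __iter__(self) -> Iterator[ReadRecord]:
        return read_sequences(self.path)


def locality_score(
    ordered_ids: Sequence[str],
    truth: "dict[str, tuple[int, int, str]] | object",
    genome_length: int | None = None,
    circular: bool = False,
) -> float | None:
    """Mean absolute adjacent true-start distance (bases); lower is better.

    Quantifies how closely an ordering approximates the natural genomic
    arrangement.  ``truth`` maps read id to (true_start, true_end,
    true_strand), or is a SyntheticTruth-like object with a ``starts``
    mapping.  Returns None for fewer than two scored reads.
    """
    starts = getattr(truth, "starts", None)
    if starts is None:
        starts = {rid: t[0] for rid, t in truth.items()}  # type: ignore[union-attr]
    positions = [starts[rid] for rid in ordered_ids if rid in starts]
    if len(positions) < 2:
        return None
    total = 0.0
    for a, b in zip(positions, positions[1:]):
        d = abs(b - a)
        if circular and genome_length:
            d = min(d, genome_length - d)
        total += d
    return total / (len(positions) - 1)
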