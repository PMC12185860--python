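"""End-to-end orchestration: sort, restore, digest-check, benchmarking, and
optional invocation of an external assembler/mapper chain.

The core pipeline — parse GFA/PAF, linearize the contig graph, place the
reads, write the reordered file plus restore table — has no external-binary
dependency.  External assembly (minimap2 all-vs-all → miniasm → minimap2
mapping, by default) is additive glue driven by configurable command
templates; the pipeline is equally usable with user-supplied GFA/PAF files
or with the built-in simulator's truth files.

Every run ends with a digest check: the order-invariant dataset digest of
the output must equal that of the input (canonical digests when strand mode
is ``unify``, since reverse complementing is then allowed).  On mismatch
the output is removed and the run aborts — the tool never leaves behind a
file it cannot vouch for.
"""

from __future__ import annotations

import json
import logging
import shlex
import string
import subprocess
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .contig_graph import build_adjacency, dfs_order
from .io_formats import (
    ReadRecord,
    parse_gfa,
    parse_paf,
    read_sequences,
    write_sequences,
)
from .read_ordering import (
    StrandMode,
    apply_plan,
    best_mapping_filter,
    plan_placement,
    sort_mappings,
)
from .restore import dataset_digest, write_restore_table

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "IntegrityError",
    "ExternalToolError",
    "run_sort",
    "subsample_longest",
    "run_external_assembly",
    "run_bench",
    "DEFAULT_TEMPLATES",
]


class IntegrityError(RuntimeError):
    """Digest mismatch between input and output: data-integrity failure."""


class ExternalToolError(RuntimeError):
    """An external assembler/mapper/compressor exited non-zero."""


DEFAULT_TEMPLATES = {
    "overlap": "minimap2 -x ava-ont -t {threads} {reads} {reads} -o {out}",
    "assemble": "miniasm -f {reads} {overlaps} > {out}",
    "map": "minimap2 -x map-ont -t {threads} {contigs} {reads} -o {out}",
}


@dataclass
class PipelineConfig:
    """One sort run's full configuration.

    Exactly one graph/mapping source: explicit ``gfa``+``paf`` paths, or
    ``external`` (run the assembler/mapper templates).  ``subsample_coverage``
    with ``genome_size_estimate`` limits only the assembly input; the sorted
    output always contains every read.
    """

    reads: Path
    gfa: Path | None = None
    paf: Path | None = None
    source: str = "files"  # files | external
    mode: StrandMode = "unify"
    out: Path = Path("reordered.fasta")
    restore_out: Path | None = None
    order_out: Path | None = None
    report_out: Path | None = None
    out_format: str | None = None  # None → match input
    keep: str = "primary_only"
    best_mapping: bool = False
    block_flip: bool = True
    subsample_coverage: float | None = None
    genome_size_estimate: int | None = None
    templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    workdir: Path | None = None
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.reads = Path(self.reads)
        if self.source == "files":
            if self.gfa is None or self.paf is None:
                raise ValueError("source='files' requires both --gfa and --paf")
        elif self.source != "external":
            raise ValueError(f"unknown source {self.source!r}")
        if self.subsample_coverage is not None and self.subsample_coverage <= 0:
            raise ValueError("subsample coverage must be positive")


def _detect_format(path: Path) -> str:
    from .io_formats import open_text, sniff_format

    with open_text(path) as fh:
        return sniff_format(fh) or "fasta"


def run_sort(cfg: PipelineConfig) -> dict:
    """Execute parse → DFS order → sort → place → emit → digest check.

    Returns the report dict (also written to ``cfg.report_out`` when set):
    read counts, mapped/unmapped counts, strand mode, input/output digests
    and the digest-match boolean.  A mismatch removes the output and raises
    :class:`IntegrityError`.
    """
    t0 = time.time()
    if cfg.source == "external":
        gfa_path, paf_path = run_external_assembly(cfg.reads, cfg)
    else:
        gfa_path, paf_path = Path(cfg.gfa), Path(cfg.paf)

    graph = parse_gfa(gfa_path)
    build_adjacency(graph)
    order = dfs_order(graph)
    if cfg.order_out:
        with open(cfg.order_out, "w") as fh:
            fh.write("rank\tsegment\torientation\n")
            for i, (seg, orient) in enumerate(order.entries):
                fh.write(f"{i}\t{seg}\t{orient}\n")

    mappings = list(parse_paf(paf_path, keep=cfg.keep))
    if cfg.best_mapping:
        mappings = best_mapping_filter(mappings)
    sorted_mappings = sort_mappings(
        mappings, order, mode=cfg.mode, block_flip=cfg.block_flip
    )

    records = list(read_sequences(cfg.reads))
    input_ids = [r.id for r in records]
    plan = plan_placement(sorted_mappings, input_ids, mode=cfg.mode)
    emitted, table = apply_plan(records, plan)

    fmt = cfg.out_format or _detect_format(cfg.reads)
    out_records = list(emitted)
    write_sequences(out_records, cfg.out, format=fmt)
    if cfg.restore_out:
        write_restore_table(table, cfg.restore_out)

    canonical = cfg.mode == "unify"
    digest_in = dataset_digest(records, canonical=canonical)
    digest_out = dataset_digest(out_records, canonical=canonical)
    match = digest_in.digest == digest_out.digest
    report = {
        "reads": len(records),
        "mappings": len(mappings),
        "placed": len(plan.placed),
        "unmapped": len(plan.unmapped_ids),
        "contigs": graph.n_segments,
        "mode": cfg.mode,
        "canonical_digest": canonical,
        "digest_in": digest_in.hex,
        "digest_out": digest_out.hex,
        "digest_match": match,
        "out": str(cfg.out),
        "elapsed_s": round(time.time() - t0, 3),
    }
    if cfg.report_out:
        Path(cfg.report_out).write_text(json.dumps(report, indent=2) + "\n")
    if not match:
        Path(cfg.out).unlink(missing_ok=True)
        raise IntegrityError(
            f"dataset digest mismatch ({digest_in.hex} != {digest_out.hex}); "
            f"output removed"
        )
    logger.info(
        "sorted %d reads (%d placed, %d unmapped) across %d contigs in %.2fs",
        report["reads"], report["placed"], report["unmapped"],
        report["contigs"], report["elapsed_s"],
    )
    return report


def subsample_longest(
    records: Iterable[ReadRecord],
    genome_size_estimate: int,
    target_coverage: float,
) -> list[ReadRecord]:
    """Longest-reads-first prefix reaching ``target_coverage ×`` the genome
    size estimate; used only to lighten the external assembly step.

    Ties in length break by ascending id.  If the whole dataset falls short
    of the target, everything is returned with a warning.
    """
    if genome_size_estimate <= 0:
        raise ValueError("genome_size_estimate must be positive")
    ranked = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    target = target_coverage * genome_size_estimate
    out: list[ReadRecord] = []
    total = 0
    for rec in ranked:
        if total >= target:
            break
        out.append(rec)
        total += len(rec.sequence)
    if total < target:
        logger.warning(
            "dataset holds %.1f bases < target %.1f; using all reads", total, target
        )
        return ranked
    if not out and ranked:
        out = ranked[:1]
    return out


class _CheckedFormatter(string.Formatter):
    def __init__(self, allowed: set[str]):
        self.allowed = allowed

    def get_value(self, key, args, kwargs):
        if key not in kwargs:
            raise ValueError(f"unknown placeholder {{{key}}} in command template")
        return kwargs[key]


def render_template(template: str, **values: object) -> str:
    """Substitute {placeholders}; unknown placeholders are config errors."""
    return _CheckedFormatter(set(values)).vformat(template, (), values)


def _run_shell(cmd: str, log_path: Path) -> None:
    logger.info("external: %s", cmd)
    proc = subprocess.run(
        cmd, shell=True, capture_output=True, text=True
    )
    log_path.write_text(proc.stderr or "")
    if proc.returncode != 0:
        raise ExternalToolError(
            f"command failed ({proc.returncode}): {cmd}\n{proc.stderr[-2000:]}"
        )


def run_external_assembly(reads: Path, cfg: PipelineConfig) -> tuple[Path, Path]:
    """Run the configured overlap → assemble → map chain; return (gfa, paf).

    Thin subprocess glue: command templates with {reads}/{overlaps}/
    {contigs}/{out}/{threads} placeholders, defaulting to minimap2's
    all-vs-all preset, miniasm, and a minimap2 mapping of all reads onto
    the unitig sequences extracted from the GFA.  Intermediates live under
    the work directory; assembly and mapping may see a subsampled read set
    but the caller always sorts the full one.
    """
    work = Path(cfg.workdir or Path(cfg.out).parent / "seqorder_work")
    work.mkdir(parents=True, exist_ok=True)

    asm_reads = Path(reads)
    if cfg.subsample_coverage is not None:
        if not cfg.genome_size_estimate:
            raise ValueError("subsampling requires a genome size estimate")
        subset = subsample_longest(
            read_sequences(reads), cfg.genome_size_estimate, cfg.subsample_coverage
        )
        asm_reads = work / "assembly_input.fasta"
        write_sequences(subset, asm_reads, format="fasta")

    overlaps = work / "overlaps.paf"
    gfa = work / "assembly.gfa"
    paf = work / "reads_to_contigs.paf"
    contigs = work / "contigs.fasta"

    _run_shell(
        render_template(
            cfg.templates["overlap"],
            reads=shlex.quote(str(asm_reads)),
            out=shlex.quote(str(overlaps)),
            threads=cfg.threads,
        ),
        work / "overlap.log",
    )
    _run_shell(
        render_template(
            cfg.templates["assemble"],
            reads=shlex.quote(str(asm_reads)),
            overlaps=shlex.quote(str(overlaps)),
            out=shlex.quote(str(gfa)),
        ),
        work / "assemble.log",
    )
    graph = parse_gfa(gfa)
    if not graph.segments:
        raise ExternalToolError(
            "assembly produced no contigs (empty GFA); consider more coverage "
            "or different overlap/assembly parameters"
        )
    contig_records = [
        ReadRecord(seg.id, seg.sequence)
        for seg in graph.segments.values()
        if seg.sequence
    ]
    write_sequences(contig_records, contigs, format="fasta")
    _run_shell(
        render_template(
            cfg.templates["map"],
            contigs=shlex.quote(str(contigs)),
            reads=shlex.quote(str(reads)),
            out=shlex.quote(str(paf)),
            threads=cfg.threads,
        ),
        work / "map.log",
    )
    return gfa, paf


def _deflate_size(path: Path, level: int = 6) -> int:
    comp = zlib.compressobj(level)
    total = 0
    with open(path, "rb") as fh:
        while chunk := fh.read(1 << 20):
            total += len(comp.compress(chunk))
    total += len(comp.flush())
    return total


def run_bench(
    files: Sequence[Path],
    compressors: Sequence[tuple[str, str]] = (),
    deflate_levels: Sequence[int] = (1, 6, 9),
) -> list[dict]:
    """Compress each file with the built-in DEFLATE backend (and any external
    compressor templates) and tabulate sizes and ratios.

    ``compressors`` is (name, template) pairs; templates see {input} and
    must write the compressed stream to stdout.  A failing template marks
    its row failed and the run continues.  Ratio = original / compressed.
    """
    rows: list[dict] = []
    for path in files:
        path = Path(path)
        original = path.stat().st_size
        for level in deflate_levels:
            size = _deflate_size(path, level)
            rows.append(
                {
                    "file": str(path),
                    "compressor": "deflate",
                    "level": level,
                    "original_bytes": original,
                    "compressed_bytes": size,
                    "ratio": round(original / size, 4) if size else None,
                    "status": "ok",
                }
            )
        for name, template in compressors:
            try:
                cmd = render_template(template, input=shlex.quote(str(path)))
                proc = subprocess.run(cmd, shell=True, capture_output=True)
                if proc.returncode != 0:
                    raise ExternalToolError(proc.stderr.decode()[-500:])
                size = len(proc.stdout)
                rows.append(
                    {
                        "file": str(path),
                        "compressor": name,
                        "level": None,
                        "original_bytes": original,
                        "compressed_bytes": size,
                        "ratio": round(original / size, 4) if size else None,
                        "status": "ok",
                    }
                )
            except Exception as exc:  # row-level failure, run continues
                rows.append(
                    {
                        "file": str(path),
                        "compressor": name,
                        "level": None,
                        "original_bytes": original,
                        "compressed_bytes": None,
                        "ratio": None,
                        "status": f"failed: {exc}",
                    }
                )
    return rows


def bench_table(rows: list[dict]) -> str:
    """Render bench rows as TSV."""
    cols = ["file", "compressor", "level", "original_bytes",
            "compressed_bytes", "ratio", "status"]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join("" if row[c] is None else str(row[c]) for c in cols))
    return "\n".join(lines) + "\n"
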