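"""Seeded simulator: genome, error-bearing strand-aware reads, and matching
truth assembly (GFA) and truth mappings (PAF).

The generator exists so the whole reorder→restore pipeline can be exercised
and oracle-tested without external assemblers, mappers or downloads.  It
emulates a long-read sequencing run at its simplest: a uniform-random
genome with optional planted exact repeats, reads with lognormal lengths
sampled at uniform start positions until a target coverage is reached,
a fair coin for strand ('-' reads are stored reverse-complemented, as a
sequencer emits the strand it actually read), and independent per-base
substitution/insertion/deletion errors.  Low error rates stand in for HiFi
data, ~5-10% for ONT.  Each read carries an error-free truth interval, which
downstream tests use as a placement oracle.

Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io_formats import ContigGraph, GfaLink, GfaSegment, MappingRecord, ReadRecord
from .restore import reverse_complement

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "TruthAssembly",
    "simulate_genome",
    "sample_reads",
    "build_truth_assembly",
    "emit_truth_paf",
    "shuffle_reads",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
MIN_READ_LENGTH = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``read_length_sd`` is the log-space standard deviation of the lognormal
    length distribution; lengths are clipped to [200, genome_length].
    Error rates are per-base probabilities, each capped at 0.2.

    ``emission_jitter`` controls the order reads appear in the emitted file:
    reads are written sorted by (true start + Gaussian noise with standard
    deviation ``emission_jitter * genome_length``).  The default of 0.1
    gives the input file weak residual positional structure — much worse
    than a genome-sweep order, much better than a uniform shuffle — so that
    input order, shuffled order and reordered output are three genuinely
    distinct locality regimes.  ``None`` emits reads in raw i.i.d. sampling
    order, which is statistically indistinguishable from a shuffle.
    """

    genome_length: int = 100_000
    n_repeats: int = 0
    repeat_length: int = 2_000
    coverage: float = 20.0
    mean_read_length: int = 1_000
    read_length_sd: float = 0.25
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    emission_jitter: float | None = 0.1
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.mean_read_length <= 0:
            raise ValueError("genome_length and mean_read_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length_sd < 0:
            raise ValueError("read_length_sd must be non-negative")
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= rate <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.n_repeats * self.repeat_length >= self.genome_length / 2:
            raise ValueError("repeats may not occupy half the genome")


class TruthRead(NamedTuple):
    read_id: str
    true_start: int
    true_end: int  # exclusive; may exceed genome_length when circular (wrap)
    true_strand: str
    truth_contig: str | None = None


@dataclass
class SyntheticTruth:
    """Per-read error-free coordinates; the oracle for placement tests."""

    genome_length: int
    circular: bool
    reads: list[TruthRead] = field(default_factory=list)

    @property
    def starts(self) -> dict[str, int]:
        return {t.read_id: t.true_start for t in self.reads}

    def by_id(self) -> dict[str, TruthRead]:
        return {t.read_id: t for t in self.reads}


class TruthAssembly(NamedTuple):
    """Truth contigs with their graph and genomic offsets."""

    records: list[ReadRecord]
    graph: ContigGraph
    offsets: dict[str, int]


def simulate_genome(cfg: SimulationConfig) -> str:
    """Uniform-random ACGT genome with ``n_repeats`` planted exact copies of
    one random ``repeat_length`` motif at non-overlapping seeded positions.

    Deterministic given the seed; raises after bounded retries if the
    repeats cannot be placed without overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = rng.choice(_BASES, size=cfg.genome_length)
    if cfg.n_repeats:
        motif = rng.choice(_BASES, size=cfg.repeat_length)
        placed: list[int] = []
        for _ in range(cfg.n_repeats):
            ok = None
            for _attempt in range(1000):
                pos = int(rng.integers(0, cfg.genome_length - cfg.repeat_length + 1))
                if all(
                    pos + cfg.repeat_length <= p or p + cfg.repeat_length <= pos
                    for p in placed
                ):
                    ok = pos
                    break
            if ok is None:
                raise RuntimeError(
                    "could not place non-overlapping repeats after 1000 tries"
                )
            placed.append(ok)
            genome[ok : ok + cfg.repeat_length] = motif
    return genome.tobytes().decode()


def _inject_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Single left-to-right pass: per base — delete, else maybe substitute;
    then maybe insert a random base after it."""
    if cfg.sub_rate == cfg.ins_rate == cfg.del_rate == 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    n = len(seq)
    # draw all randomness vectorized for speed
    dels = rng.random(n) < cfg.del_rate
    subs = rng.random(n) < cfg.sub_rate
    inss = rng.random(n) < cfg.ins_rate
    sub_choice = rng.integers(0, 3, size=n)
    ins_choice = rng.integers(0, 4, size=n)
    for i, ch in enumerate(seq):
        if not dels[i]:
            if subs[i]:
                alternatives = bases.replace(ch.upper(), "") or bases
                ch = alternatives[sub_choice[i] % len(alternatives)]
            out.append(ch)
        if inss[i]:
            out.append(bases[ins_choice[i]])
    return "".join(out)


def sample_reads(
    genome: str, cfg: SimulationConfig
) -> tuple[list[ReadRecord], SyntheticTruth]:
    """Sample reads until total bases reach ``coverage * genome_length``.

    Starts are uniform; strand is Bernoulli(0.5); a '-' read is stored as
    the reverse complement of its genomic window (errors applied to the
    emitted strand).  Truth intervals are error-free genome coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    G = cfg.genome_length
    sigma = cfg.read_length_sd
    mu = np.log(cfg.mean_read_length) - sigma**2 / 2
    records: list[ReadRecord] = []
    truth = SyntheticTruth(genome_length=G, circular=cfg.circular)
    total = 0
    target = cfg.coverage * G
    i = 0
    doubled = genome + genome  # for circular wrap-around slicing
    while total < target:
        length = int(np.clip(round(rng.lognormal(mu, sigma)), MIN_READ_LENGTH, G))
        if cfg.circular:
            start = int(rng.integers(0, G))
        else:
            start = int(rng.integers(0, G - length + 1))
        end = start + length
        window = doubled[start:end] if cfg.circular else genome[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        emitted = window if strand == "+" else reverse_complement(window)
        emitted = _inject_errors(emitted, cfg, rng)
        rid = f"read{i:06d}"
        records.append(ReadRecord(rid, emitted, description=f"pos={start} strand={strand}"))
        truth.reads.append(TruthRead(rid, start, end, strand))
        total += length
        i += 1
    if cfg.emission_jitter is not None and len(records) > 1:
        noise = rng.normal(0.0, cfg.emission_jitter * G, size=len(records))
        keys = np.array([t.true_start for t in truth.reads]) + noise
        perm = np.argsort(keys, kind="stable")
        records = [records[i] for i in perm]
        truth.reads = [truth.reads[i] for i in perm]
    return records, truth


def build_truth_assembly(
    genome: str,
    n_contigs: int = 4,
    link_overlap: int = 0,
    circular: bool = False,
    branching: bool = False,
) -> TruthAssembly:
    """Cut the genome into ``n_contigs`` consecutive windows overlapping by
    ``link_overlap`` and link them into a path ('+'/'+' L lines), plus a
    closing link when circular.

    ``branching`` rewires the links so the first contig points at both the
    second and the third (a fork), for traversal tests.  Stands in for a
    real overlap-layout assembly: the truth contigs are exact genome
    windows, so truth mappings can be emitted by arithmetic.
    """
    G = len(genome)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    # window length w solves n*w - (n-1)*overlap >= G
    w = -(-(G + (n_contigs - 1) * link_overlap) // n_contigs)
    if w <= link_overlap:
        raise ValueError("genome too short for this many overlapping contigs")
    records: list[ReadRecord] = []
    offsets: dict[str, int] = {}
    graph = ContigGraph()
    for i in range(n_contigs):
        start = min(i * (w - link_overlap), G - w)
        seq = genome[start : start + w]
        cid = f"ctg{i + 1}"
        records.append(ReadRecord(cid, seq))
        offsets[cid] = start
        graph.segments[cid] = GfaSegment(cid, len(seq), seq)
    ids = [r.id for r in records]
    if branching:
        if n_contigs < 3:
            raise ValueError("branching variant needs >= 3 contigs")
        graph.links.append(GfaLink(ids[0], "+", ids[1], "+", link_overlap))
        graph.links.append(GfaLink(ids[0], "+", ids[2], "+", max(link_overlap - 1, 0)))
        for i in range(2, n_contigs - 1):
            graph.links.append(GfaLink(ids[i], "+", ids[i + 1], "+", link_overlap))
    else:
        for i in range(n_contigs - 1):
            graph.links.append(GfaLink(ids[i], "+", ids[i + 1], "+", link_overlap))
        if circular and n_contigs > 1:
            graph.links.append(GfaLink(ids[-1], "+", ids[0], "+", link_overlap))
    return TruthAssembly(records, graph, offsets)


def emit_truth_paf(
    truth: SyntheticTruth,
    assembly: TruthAssembly,
    withhold_fraction: float = 0.0,
    seed: int = 0,
) -> list[MappingRecord]:
    """Map each read to the truth contig covering its start, by arithmetic.

    ``t_start`` is the read's true start minus the contig's genomic offset
    (the interval end is clipped to the contig); strand and match count come
    from the truth.  ``withhold_fraction`` removes an exact seeded fraction
    of reads from the output to exercise the unmapped path.
    """
    # choose, per read start, the contig whose window covers it (last window
    # starting at or before the read start)
    items = sorted(assembly.offsets.items(), key=lambda kv: kv[1])
    contig_starts = [off for _, off in items]
    contig_ids = [cid for cid, _ in items]
    lengths = {cid: assembly.graph.segments[cid].length for cid in contig_ids}

    mappings: list[MappingRecord] = []
    for t in truth.reads:
        start_mod = t.true_start % truth.genome_length
        # binary search: rightmost contig with offset <= start
        lo, hi = 0, len(contig_starts) - 1
        idx = 0
        while lo <= hi:
            mid = (lo + hi) // 2
            if contig_starts[mid] <= start_mod:
                idx = mid
                lo = mid + 1
            else:
                hi = mid - 1
        cid = contig_ids[idx]
        off = contig_starts[idx]
        clen = lengths[cid]
        t_start = start_mod - off
        if t_start >= clen:  # start in a gap (cannot happen with tiling windows)
            continue
        read_span = t.true_end - t.true_start
        t_end = min(t_start + read_span, clen)
        mappings.append(
            MappingRecord(
                read_id=t.read_id,
                read_len=read_span,
                strand=t.true_strand,
                contig_id=cid,
                contig_len=clen,
                t_start=t_start,
                t_end=t_end,
                n_match=read_span,
                is_primary=True,
            )
        )
    if withhold_fraction:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        n_drop = int(round(withhold_fraction * len(mappings)))
        drop = set(rng.choice(len(mappings), size=n_drop, replace=False).tolist())
        mappings = [m for i, m in enumerate(mappings) if i not in drop]
    return mappings


def shuffle_reads(records: Sequence[ReadRecord], seed: int = 0) -> list[ReadRecord]:
    """Uniform seeded permutation; the record multiset is unchanged."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


def write_dataset(cfg: SimulationConfig, outdir: str | Path,
                  n_contigs: int = 4, link_overlap: int = 0,
                  withhold_fraction: float = 0.0) -> dict[str, Path]:
    """Simulate and write reads.fasta, truth.gfa, truth.paf, truth.tsv and
    config.json under ``outdir``; returns the paths."""
    from .io_formats import format_paf_line, write_sequences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    reads, truth = sample_reads(genome, cfg)
    assembly = build_truth_assembly(
        genome, n_contigs=n_contigs, link_overlap=link_overlap, circular=cfg.circular
    )
    paf = emit_truth_paf(truth, assembly, withhold_fraction, seed=cfg.seed)

    paths = {
        "reads": outdir / "reads.fasta",
        "gfa": outdir / "truth.gfa",
        "paf": outdir / "truth.paf",
        "tsv": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_sequences(reads, paths["reads"], format="fasta")
    with open(paths["gfa"], "w") as fh:
        for seg in assembly.graph.segments.values():
            fh.write(f"S\t{seg.id}\t{seg.sequence}\n")
        for link in assembly.graph.links:
            fh.write(
                f"L\t{link.from_id}\t{link.from_orient}\t{link.to_id}\t"
                f"{link.to_orient}\t{link.overlap_len}M\n"
            )
    with open(paths["paf"], "w") as fh:
        for m in paf:
            fh.write(format_paf_line(m) + "\n")
    with open(paths["tsv"], "w") as fh:
        fh.write("read_id\ttrue_start\ttrue_end\ttrue_strand\n")
        for t in truth.reads:
            fh.write(f"{t.read_id}\t{t.true_start}\t{t.true_end}\t{t.true_strand}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    return paths
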