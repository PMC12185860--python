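"""Measure what reordering buys a generic compressor.

Compresses the same 50x error-free dataset with stdlib DEFLATE three ways:
shuffled, in its (weakly structured) simulated input order, and reordered
with strand unification.
"""

import io
import zlib

from seqorder import apply_plan, build_adjacency, dfs_order, plan_placement, sort_mappings
from seqorder.io_formats import write_sequences
from seqorder.synthetic import (
    SimulationConfig,
    build_truth_assembly,
    emit_truth_paf,
    sample_reads,
    shuffle_reads,
    simulate_genome,
)


def deflate_size(records):
    buf = io.StringIO()
    write_sequences(records, buf, format="fasta")
    return len(zlib.compress(buf.getvalue().encode(), 6))


cfg = SimulationConfig(genome_length=100_000, coverage=50.0, seed=1)
genome = simulate_genome(cfg)
reads, truth = sample_reads(genome, cfg)
assembly = build_truth_assembly(genome, n_contigs=4, link_overlap=50)
order = dfs_order(build_adjacency(assembly.graph))
plan = plan_placement(sort_mappings(emit_truth_paf(truth, assembly), order),
                      [r.id for r in reads], mode="unify")
reordered, _ = apply_plan(reads, plan)

sizes = {
    "shuffled": deflate_size(shuffle_reads(reads, seed=1)),
    "input order": deflate_size(reads),
    "reordered+unified": deflate_size(list(reordered)),
}
raw = sum(len(r.sequence) for r in reads)
print(f"raw bases: {raw}")
for name, size in sizes.items():
    print(f"{name:>18}: {size:>8} bytes  ({raw / size:5.1f}x vs raw bases)")
print()
print("With overlapping reads adjacent and on one strand, DEFLATE's 32 KB "
      "window spans dozens of near-identical reads, so the reordered file "
      "compresses roughly an order of magnitude smaller than the shuffled one.")
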