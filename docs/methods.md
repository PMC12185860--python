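# Methods

## Rationale

Generic compressors model redundancy within a bounded context window
(32 KB for DEFLATE, megabytes for zstd/xz at high levels). In a shuffled
read file, reads covering the same locus are separated by roughly
`file_size / coverage` bytes on average — far beyond any window — and half
of the overlapping pairs are on opposite strands, sharing no literal
substring. `seqorder` removes both obstacles by permuting (and optionally
reverse-complementing) reads so that genomic neighbours become file
neighbours. The permutation is recorded, so the transformation is exactly
invertible; the sequences themselves are never edited.

## Pipeline model

**Inputs.** Reads (FASTA or 4-line FASTQ, plain or gzip; gzip is sniffed
from magic bytes, never the filename), a contig graph (GFA1 `S`/`L` lines;
`LN:i` accepted in place of a sequence; other record types ignored), and
read-to-contig mappings (PAF, ≥12 tab-separated columns; coordinates kept
0-based half-open throughout; rows tagged `tp:A:S`/`tp:A:I` dropped by
default, configurable). Duplicate read ids are rejected by default — the
restore table and first-encounter dedup assume id uniqueness — or suffixed
internally when explicitly allowed.

**Graph linearization.** Links are bidirected: `(a,oa)→(b,ob)` implies the
traversal `(b,flip(ob))→(a,flip(oa))`. Both directions are materialized on
oriented nodes and de-duplicated, so GFAs that write each link once and
those that write both directions linearize identically. The DFS is
iterative (recursion depth never bounds graph size) and emits a segment at
first visit with the orientation of arrival; the visited set is keyed on
segment ids, so cycles and opposite-orientation re-entries terminate.
Deterministic choices, fixed so identical GFA bytes give identical orders:

- *Successor order*: descending overlap length, then descending successor
  length, then ascending id. Larger overlap means more sequence shared
  across the junction, hence better local redundancy.
- *Roots*: forward-oriented nodes `(s,+)` with zero in-degree in the
  oriented adjacency, processed longest-first — starting at path ends
  maximizes uninterrupted runs. Components without such a node (cycles)
  are rooted at their longest unvisited segment in `+`.

A brute-force recursive DFS with the same keys serves as an equivalence
oracle in tests (refusing graphs above 12 segments; it exists to check
small cases, not to scale).

**Placement.** Mappings are sorted by `(contig rank, t_start, read_id)` —
under `preserve`, strand group first, `+` before `-` (the within-group
order is a fixed convention; nothing downstream depends on which group
leads). A contig the DFS reached in `-` orientation has its block reversed
(sort by descending `t_end`, effective strands flipped) so its reads stay
collinear with the traversal; `--no-block-flip` disables this. Each read is
emitted at its first encounter in that sorted stream — literal
first-encounter semantics even when a later mapping has more matches; a
`--best-mapping` option pre-filters to each read's maximum-match mapping
instead. Reads absent from the PAF (or mapped only to contigs missing from
the graph) are appended at the end in input order: they are few in
practice, and content-based ordering of the unmapped tail costs more than
it saves.

**Strand modes.** `unify` (default): reverse-strand reads are emitted as
their reverse complement, quality strings reversed in step; the only
transformation ever applied to sequence bytes, and recorded per read.
`preserve`/`ignore`: no byte of any sequence changes, and all flip bits
are zero (enforced at serialization).

## Losslessness machinery

**Restore table.** Binary sidecar: 8-byte magic, version byte, strand-mode
byte, uint64 count, then `n` little-endian uint32 original indices, then
`ceil(n/8)` bytes of flip bits (LSB-first). Size is exactly
`18 + 4n + ceil(n/8)` bytes — 4 bytes + 1 bit per read, so ~40 MB + 1.25 MB
for 10 M reads, negligible next to the data. Loading validates magic,
version, exact file size, index range and the permutation property; a
corrupted index block therefore cannot silently misorder a restore (a
single flipped byte either leaves the permutation — impossible without a
collision — or fails one of the checks). Flip-bit corruption is *not*
detectable within this layout; the dataset digest is the end-to-end guard.
32-bit indices cap input at 2³² reads; the version byte reserves room for
a 64-bit variant.

**Digest.** Per record, the 128-bit MD5 of the uppercased sequence
(canonical form — the lexicographic minimum of sequence and reverse
complement — when strand changes are allowed); record hashes are summed
modulo 2¹²⁸. Addition is commutative, so the digest is invariant under any
permutation, and canonicalization makes it invariant under any per-read
strand flip; any content change shifts it (collision resistance is MD5's —
ample for an integrity check against accidental corruption, not an
adversary). Headers and quality are excluded by design (the check concerns
the sequences); `--digest-strict` hashes full records byte-for-byte
instead. Every `sort` run verifies input digest == output digest and
deletes the output on mismatch.

## Synthetic data: what it emulates, and what it does not

The simulator produces the study conditions under which the pipeline's
properties are asserted:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 100 000 bp | uniform-random ACGT genome |
| `n_repeats`, `repeat_length` | 0, 2 000 bp | exact planted repeat copies (< half the genome) |
| `coverage` | 20× | sampling stops once total bases ≥ coverage × genome |
| `mean_read_length` | 1 000 bp | lognormal mean (arithmetic scale) |
| `read_length_sd` | 0.25 | log-space σ; lengths clipped to [200, genome] |
| `sub/ins/del_rate` | 0 | per-base error probabilities, each ≤ 0.2 |
| `emission_jitter` | 0.1 | see below |
| `circular` | false | wrap-around sampling and modular distances |

Starts are uniform; strand is Bernoulli(0.5) and reverse-strand reads are
stored reverse-complemented, as a sequencer emits the strand it read —
this is what makes the strand-mode comparison meaningful. Errors are
injected in one left-to-right pass (delete, else substitute; then insert),
substitutions never redraw the original base, and truth intervals stay
error-free. Error-free defaults stand in for HiFi-like data; rates of
5–10% approximate ONT. The truth assembly cuts the genome into consecutive
overlapping windows linked as a path (optionally circular or with a fork
for traversal tests), and truth mappings are emitted by coordinate
arithmetic — a perfect assembler and mapper.

`emission_jitter` controls the order reads appear in the simulated *file*:
sorted by `true_start + N(0, jitter·G)`. The default 0.1 leaves the input
weakly structured — on a 100 kb genome at 20×, mean adjacent true-start
distance ≈ 10 kb, versus ≈ 50 bp after reordering and ≈ 33 kb shuffled —
so "reordered", "input order" and "shuffled" are three genuinely distinct
locality regimes that can be compared strictly. `None` gives raw i.i.d.
sampling order, which is statistically a shuffle.

What passing tests on this generator do **not** show: robustness to real
error profiles (homopolymer bias, chimeras, adapters, quality-correlated
errors), to fragmented or misassembled draft graphs, to multi-mapping
ambiguity in repeat-rich genomes, or to the scale (10⁶–10⁷ reads,
gigabases) of production datasets. The generator's assembler and mapper
are exact; real miniasm/minimap2 output is noisier, and compression gains
on real ONT data are correspondingly smaller than the error-free figures
printed by the examples.

## Numerical and design choices

- Reverse complement uses the full IUPAC table, case-preserving per
  position after reversal; non-IUPAC characters pass through (one warning
  per process). Canonical forms uppercase first, so softmasking never
  affects digests.
- Sort keys always end in `read_id`, and subsampling ties break by
  ascending id: every ordering is a pure function of its inputs.
- `subsample_longest` (longest reads first until the coverage target)
  affects only the external assembly input — the sorted output always
  contains every read.
- External assembler/mapper/compressor invocations are plain command
  templates with checked placeholders; the core pipeline has zero
  external-binary dependencies, and template failures surface stderr
  (assembly) or mark a bench row failed (compression).
- Degenerate inputs: empty files are valid everywhere (an empty restore
  table is 18 bytes); an empty mapping list yields the identity-with-
  appended-unmapped plan; a single-segment or fully cyclic graph
  linearizes via the fallback root; locality is undefined (None) below
  two placed reads.
- Problem sizes in tests and the acceptance script — 100 kb genomes at
  20–50×, ≈2 000–5 000 reads, 200 random oracle graphs — are chosen so the
  full suite exercises every path in seconds while keeping each property's
  signal (e.g. the ~10× locality separation between regimes) far above
  noise.

## Known limitations

- FASTQ is supported but quality strings travel verbatim; no separation or
  recompression of the quality stream is attempted, so FASTQ gains are
  smaller than FASTA gains.
- One read is one atomic unit: chimeric reads are placed once, by their
  first-encountered alignment.
- No GFA2, SAM/BAM, or multi-line FASTQ; no BGZF random access.
- The digest guards integrity, not authenticity.
- `best_mapping_filter` keys ties on first appearance in the PAF stream,
  which for minimap2 output is its own ranking order.
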