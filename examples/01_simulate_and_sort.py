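"""Simulate a small long-read dataset and reorder it along its truth assembly.

Builds a 100 kb genome sequenced to 20x, cuts it into a 4-contig truth
assembly with truth mappings, runs the sort pipeline, and prints the report.
"""

import json
import tempfile
from pathlib import Path

from seqorder import PipelineConfig, run_sort
from seqorder.synthetic import SimulationConfig, write_dataset

workdir = Path(tempfile.mkdtemp(prefix="seqorder_example_"))
paths = write_dataset(
    SimulationConfig(genome_length=100_000, coverage=20.0, seed=1),
    workdir / "sim",
    n_contigs=4,
    link_overlap=50,
)

report = run_sort(
    PipelineConfig(
        reads=paths["reads"],
        gfa=paths["gfa"],
        paf=paths["paf"],
        mode="unify",
        out=workdir / "reordered.fasta",
        restore_out=workdir / "reordered.restore",
    )
)
print(json.dumps(report, indent=2))
print()
print(
    f"All {report['reads']} reads were placed along {report['contigs']} contigs "
    f"({report['unmapped']} unmapped), and the canonical dataset digest of the "
    f"output matches the input ({report['digest_match']}): no sequence content "
    f"was lost or altered beyond reverse complementing."
)
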