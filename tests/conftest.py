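import pytest

from seqorder.contig_graph import build_adjacency, dfs_order
from seqorder.read_ordering import plan_placement, sort_mappings
from seqorder.synthetic import (
    SimulationConfig,
    build_truth_assembly,
    emit_truth_paf,
    sample_reads,
    simulate_genome,
)


@pytest.fixture
def small_dataset():
    """One seeded 20x dataset with truth assembly and truth mappings."""
    return make_dataset(seed=7)


def make_dataset(seed=0, coverage=20.0, genome_length=100_000, n_contigs=4,
                 link_overlap=50, withhold_fraction=0.0, **cfg_kwargs):
    cfg = SimulationConfig(
        genome_length=genome_length, coverage=coverage, seed=seed, **cfg_kwargs
    )
    genome = simulate_genome(cfg)
    reads, truth = sample_reads(genome, cfg)
    assembly = build_truth_assembly(
        genome, n_contigs=n_contigs, link_overlap=link_overlap, circular=cfg.circular
    )
    paf = emit_truth_paf(truth, assembly, withhold_fraction, seed=seed)
    return {
        "cfg": cfg,
        "genome": genome,
        "reads": reads,
        "truth": truth,
        "assembly": assembly,
        "paf": paf,
    }


def reorder_ids(dataset, mode="unify"):
    """Run graph linearization + placement; return the PlacementPlan."""
    order = dfs_order(build_adjacency(dataset["assembly"].graph))
    sorted_maps = sort_mappings(dataset["paf"], order, mode=mode)
    return plan_placement(
        sorted_maps, [r.id for r in dataset["reads"]], mode=mode
    )
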