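import pytest

from conftest import make_dataset, reorder_ids
from seqorder.contig_graph import ContigOrder
from seqorder.io_formats import MappingRecord, ReadRecord
from seqorder.read_ordering import (
    apply_plan,
    best_mapping_filter,
    locality_score,
    plan_placement,
    sort_mappings,
)
from seqorder.restore import canonical_form, restore_input


def M(read_id, contig, strand, t_start, t_end=None, n_match=50, contig_len=100_000):
    return MappingRecord(
        read_id, 1000, strand, contig, contig_len, t_start,
        t_end if t_end is not None else t_start + 100, n_match,
    )


ORDER = ContigOrder([("u1", "+"), ("u2", "+"), ("u3", "+")])


def test_sort_by_contig_rank_then_position():
    maps = [M("r1", "u2", "+", 50), M("r2", "u1", "+", 10), M("r3", "u1", "+", 5)]
    assert [m.read_id for m in sort_mappings(maps, ORDER)] == ["r3", "r2", "r1"]


def test_preserve_mode_groups_plus_strand_first():
    maps = [M("r1", "u1", "-", 5), M("r2", "u1", "+", 50)]
    assert [m.read_id for m in sort_mappings(maps, ORDER, mode="preserve")] == [
        "r2", "r1",
    ]


def test_sort_empty():
    assert sort_mappings([], ORDER) == []


def test_unknown_contig_routed_to_unmapped():
    maps = [M("r1", "nope", "+", 5), M("r2", "u1", "+", 5)]
    sorted_maps = sort_mappings(maps, ORDER)
    assert [m.read_id for m in sorted_maps] == ["r2"]
    plan = plan_placement(sorted_maps, ["r1", "r2"])
    assert plan.unmapped_ids == ["r1"]


def test_reverse_traversed_contig_block_flips():
    order = ContigOrder([("u1", "-")])
    maps = [M("a", "u1", "+", 10, 200), M("b", "u1", "+", 300, 400)]
    sorted_maps = sort_mappings(maps, order)
    # descending t_end: b (400) before a (200); strands flipped
    assert [m.read_id for m in sorted_maps] == ["b", "a"]
    assert {m.strand for m in sorted_maps} == {"-"}
    # with block flip disabled the original key and strands apply
    plain = sort_mappings(maps, order, block_flip=False)
    assert [m.read_id for m in plain] == ["a", "b"]
    assert {m.strand for m in plain} == {"+"}


def test_first_encounter_dedup_and_unmapped_appended():
    maps = sort_mappings(
        [M("r1", "u1", "+", 10), M("r1", "u3", "+", 4)], ORDER
    )
    plan = plan_placement(maps, ["r1", "r2", "r3"])
    assert plan.placed == [("r1", False)]
    assert plan.provenance["r1"][0] == "u1"  # first encounter wins
    assert plan.unmapped_ids == ["r2", "r3"]  # input order


def test_unify_flags_reverse_strand_reads_only_in_unify():
    maps = sort_mappings([M("r1", "u1", "-", 5)], ORDER)
    assert plan_placement(maps, ["r1"], mode="unify").placed == [("r1", True)]
    for mode in ("preserve", "ignore"):
        assert plan_placement(maps, ["r1"], mode=mode).placed == [("r1", False)]


def test_plan_rejects_unknown_read_id():
    maps = sort_mappings([M("ghost", "u1", "+", 5)], ORDER)
    with pytest.raises(KeyError, match="ghost"):
        plan_placement(maps, ["r1"])


def test_best_mapping_filter_keeps_max_match():
    maps = [M("r1", "u1", "+", 10, n_match=50), M("r1", "u2", "+", 5, n_match=90)]
    best = best_mapping_filter(maps)
    assert len(best) == 1 and best[0].contig_id == "u2"


def test_apply_plan_identity_and_flip():
    recs = [ReadRecord("r1", "AACG"), ReadRecord("r2", "TTGG")]
    identity = plan_placement([], ["r1", "r2"])
    out, table = apply_plan(recs, identity)
    assert list(out) == recs and not table.flipped.any()

    maps = sort_mappings([M("r1", "u1", "-", 5)], ORDER)
    plan = plan_placement(maps, ["r1", "r2"], mode="unify")
    out, table = apply_plan(recs, plan)
    out = list(out)
    assert out[0].sequence == "CGTT" and table.flipped[0]
    assert out[1] == recs[1]


def test_apply_plan_id_mismatch_lists_offenders():
    plan = plan_placement([], ["r1", "r2"])
    with pytest.raises(KeyError, match="r2"):
        apply_plan([ReadRecord("r1", "A"), ReadRecord("rX", "A")], plan)


def test_fastq_quality_reversed_with_flip():
    recs = [ReadRecord("r1", "AACG", quality="IJKL")]
    maps = sort_mappings([M("r1", "u1", "-", 5)], ORDER)
    out, _ = apply_plan(recs, plan_placement(maps, ["r1"], mode="unify"))
    (rec,) = list(out)
    assert rec.sequence == "CGTT" and rec.quality == "LKJI"


@pytest.mark.parametrize("mode", ["unify", "preserve", "ignore"])
def test_permutation_invariance_on_pathological_paf(mode):
    """Read-id multiset survives duplicate mappings and unknown contigs."""
    ds = make_dataset(seed=11, coverage=5, genome_length=30_000)
    paf = ds["paf"] + ds["paf"][:50]  # duplicates
    paf.append(M("read000000", "unknown_ctg", "+", 1))
    from seqorder.contig_graph import build_adjacency, dfs_order

    order = dfs_order(build_adjacency(ds["assembly"].graph))
    plan = plan_placement(
        sort_mappings(paf, order, mode=mode), [r.id for r in ds["reads"]], mode=mode
    )
    assert sorted(plan.ordered_ids) == sorted(r.id for r in ds["reads"])


@pytest.mark.parametrize("mode", ["preserve", "ignore"])
def test_non_unify_modes_never_alter_sequences(mode):
    ds = make_dataset(seed=12, coverage=5, genome_length=30_000)
    plan = reorder_ids(ds, mode=mode)
    out, table = apply_plan(ds["reads"], plan)
    by_id = {r.id: r for r in ds["reads"]}
    for rec in out:
        assert rec.sequence == by_id[rec.id].sequence
    assert not table.flipped.any()


def test_unify_changes_only_by_reverse_complement():
    ds = make_dataset(seed=13, coverage=5, genome_length=30_000)
    plan = reorder_ids(ds, mode="unify")
    out, _ = apply_plan(ds["reads"], plan)
    by_id = {r.id: r for r in ds["reads"]}
    for rec in out:
        assert canonical_form(rec.sequence) == canonical_form(by_id[rec.id].sequence)


def test_end_to_end_restore_identity():
    ds = make_dataset(seed=14, coverage=10)
    plan = reorder_ids(ds, mode="unify")
    out, table = apply_plan(ds["reads"], plan)
    assert restore_input(list(out), table) == ds["reads"]


# ---------------------------------------------------------------------------
# locality


def test_locality_arithmetic_and_degenerate_cases():
    truth = {"a": (0, 10, "+"), "b": (100, 110, "+"), "c": (200, 210, "+")}
    assert locality_score(["a", "b", "c"], truth) == 100.0
    assert locality_score(["a"], truth) is None
    assert locality_score([], truth) is None


def test_locality_circular_uses_modular_distance():
    truth = {"a": (10, 20, "+"), "b": (990, 995, "+")}
    assert locality_score(["a", "b"], truth, genome_length=1000, circular=True) == 20.0


def test_shuffled_score_exceeds_truth_order_score():
    from seqorder.synthetic import shuffle_reads

    ds = make_dataset(seed=15, coverage=10, genome_length=50_000)
    truth_order = sorted(ds["reads"], key=lambda r: ds["truth"].starts[r.id])
    shuffled = shuffle_reads(ds["reads"], seed=15)
    lo_truth = locality_score([r.id for r in truth_order], ds["truth"])
    lo_shuffled = locality_score([r.id for r in shuffled], ds["truth"])
    assert lo_shuffled > lo_truth
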