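import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqorder.io_formats import ReadRecord
from seqorder.restore import (
    HEADER_BYTES,
    RestoreTable,
    RestoreTableError,
    canonical_form,
    dataset_digest,
    expected_table_size,
    flip_record,
    position_overhead_bytes,
    read_restore_table,
    restore_input,
    reverse_complement,
    write_restore_table,
)

_dna = st.text(alphabet="ACGTNacgtn", min_size=0, max_size=80)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AACG", "CGTT"), ("acgTN", "NAcgt"), ("", "")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@settings(max_examples=100, derandomize=True)
@given(_dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    assert len(reverse_complement(seq)) == len(seq)


def test_reverse_complement_passes_unknown_chars_through():
    assert reverse_complement("AXG") == "CXT"


@pytest.mark.parametrize("seq,expected", [("TTTT", "AAAA"), ("ACGT", "ACGT")])
def test_canonical_form_examples(seq, expected):
    assert canonical_form(seq) == expected


@settings(max_examples=100, derandomize=True)
@given(_dna)
def test_canonical_form_strand_invariant(seq):
    assert canonical_form(seq) == canonical_form(reverse_complement(seq))
    assert canonical_form(seq) == canonical_form(seq.lower())


# ---------------------------------------------------------------------------
# digest


def records(*seqs):
    return [ReadRecord(f"r{i}", s) for i, s in enumerate(seqs)]


def test_digest_order_invariant():
    a = records("ACGT", "GGTT", "TTAA")
    b = [a[2], a[0], a[1]]
    assert dataset_digest(a).digest == dataset_digest(b).digest


def test_digest_canonical_invariant_under_revcomp():
    a = records("ACCGT", "GGTTC", "TTAAG")
    flipped = [flip_record(r) for r in a]
    assert (
        dataset_digest(a, canonical=True).digest
        == dataset_digest(flipped, canonical=True).digest
    )
    # non-canonical digest does change when a non-palindrome flips
    assert (
        dataset_digest(a, canonical=False).digest
        != dataset_digest(flipped, canonical=False).digest
    )


def test_digest_detects_content_change():
    a = records("ACGT", "GGTT")
    b = records("ACGT", "GGTA")
    assert dataset_digest(a).digest != dataset_digest(b).digest


def test_strict_digest_covers_headers_and_case():
    a = [ReadRecord("r1", "ACGT", "desc")]
    b = [ReadRecord("r1", "ACGT", "other")]
    assert dataset_digest(a).digest == dataset_digest(b).digest
    assert dataset_digest(a, strict=True).digest != dataset_digest(b, strict=True).digest
    assert (
        dataset_digest([ReadRecord("r", "acgt")]).digest
        == dataset_digest([ReadRecord("r", "ACGT")]).digest
    )


# ---------------------------------------------------------------------------
# restore table


def make_table(n, rng, mode="unify"):
    perm = rng.permutation(n).astype(np.uint32)
    flips = rng.random(n) < 0.5 if mode == "unify" else np.zeros(n, bool)
    return RestoreTable(perm, flips, mode=mode)


def test_table_size_formula_for_20_random_n(tmp_path):
    """Serialized size is exactly 18 + 4n + ceil(n/8) bytes."""
    rng = np.random.default_rng(0)
    for n in rng.integers(0, 5000, size=20):
        n = int(n)
        path = tmp_path / f"t{n}.bin"
        write_restore_table(make_table(n, rng), path)
        assert path.stat().st_size == HEADER_BYTES + 4 * n + (n + 7) // 8
        assert path.stat().st_size == expected_table_size(n)


def test_table_roundtrip_bit_exact(tmp_path):
    rng = np.random.default_rng(1)
    for mode in ("unify", "preserve", "ignore"):
        t = make_table(257, rng, mode)
        path = tmp_path / f"{mode}.bin"
        write_restore_table(t, path)
        back = read_restore_table(path)
        assert back.mode == mode
        assert np.array_equal(back.original_index, t.original_index)
        assert np.array_equal(back.flipped, t.flipped)


def test_empty_table_is_18_bytes(tmp_path):
    path = tmp_path / "e.bin"
    write_restore_table(RestoreTable(np.array([], np.uint32), np.array([], bool)), path)
    assert path.stat().st_size == 18
    assert read_restore_table(path).n_reads == 0


def test_index_block_corruption_always_detected(tmp_path):
    """Flipping any single byte of the header or index block must raise at
    load; corruption is never silently misordered."""
    rng = np.random.default_rng(2)
    n = 64
    path = tmp_path / "c.bin"
    write_restore_table(make_table(n, rng), path)
    data = bytearray(path.read_bytes())
    for offset in range(HEADER_BYTES + 4 * n):
        corrupt = bytearray(data)
        corrupt[offset] ^= 0x5A
        bad = tmp_path / "bad.bin"
        bad.write_bytes(bytes(corrupt))
        with pytest.raises(RestoreTableError):
            read_restore_table(bad)


def test_flip_bits_rejected_outside_unify():
    with pytest.raises(RestoreTableError, match="flip"):
        RestoreTable(
            np.arange(4, dtype=np.uint32), np.array([1, 0, 0, 0], bool), mode="preserve"
        ).validate()


def test_restore_input_inverts_permutation_and_flips():
    recs = [ReadRecord(f"r{i}", s, quality="ABCD"[: len(s)])
            for i, s in enumerate(["AACG", "GGGT", "TTTT"])]
    # output order: r2, r0(flipped), r1
    table = RestoreTable(
        np.array([2, 0, 1], np.uint32), np.array([False, True, False]), mode="unify"
    )
    shuffled = [recs[2], flip_record(recs[0]), recs[1]]
    assert restore_input(shuffled, table) == recs


def test_restore_input_identity_and_single_flip():
    recs = [ReadRecord("a", "AACG")]
    ident = RestoreTable(np.array([0], np.uint32), np.array([False]))
    assert restore_input(recs, ident) == recs
    flip = RestoreTable(np.array([0], np.uint32), np.array([True]))
    assert restore_input(recs, flip)[0].sequence == "CGTT"


def test_restore_input_length_mismatch():
    table = RestoreTable(np.arange(3, dtype=np.uint32), np.zeros(3, bool))
    with pytest.raises(RestoreTableError, match="3"):
        restore_input([ReadRecord("a", "A")], table)


# ---------------------------------------------------------------------------
# overhead arithmetic


@pytest.mark.parametrize(
    "n,pos_bits,flag_bits,expected",
    [
        (10_000_000, 32, 0, 40_000_000),
        (10_000_000, 0, 1, 1_250_000),
        (0, 32, 1, 0),
        (3, 0, 1, 1),  # rounds up to whole bytes
    ],
)
def test_position_overhead_bytes(n, pos_bits, flag_bits, expected):
    assert position_overhead_bytes(n, pos_bits, flag_bits) == expected
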