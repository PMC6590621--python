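import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import null_config
from mitosplice import precursor_index as pi
from mitosplice.model import AlignedRead, Chromosome, GenomeModel, SampleTotals, Transcript
from mitosplice.pipeline import precursor_analysis, precursor_indices, simulate_in_memory


def mito_model(units, length=1000, circular=True):
    return GenomeModel(
        [Chromosome("MT", length, circular=circular, compartment="mito")],
        [Transcript(u, u, "MT", "+", ((s, e),)) for u, s, e in units],
    )


def test_enumerate_adjacent_pairs():
    model = mito_model([("A", 0, 100), ("B", 100, 180), ("C", 185, 300)])
    pairs = pi.enumerate_border_pairs(model)
    assert [(p.upstream_transcript_id, p.downstream_transcript_id) for p in pairs] == [
        ("A", "B"),
        ("B", "C"),
    ]
    assert pairs[0].upstream_end == 100 and pairs[0].downstream_start == 100
    assert pairs[1].upstream_end == 180 and pairs[1].downstream_start == 185


def test_single_transcript_has_no_pairs():
    assert pi.enumerate_border_pairs(mito_model([("A", 0, 100)])) == []


def test_include_origin_adds_wraparound_pair():
    model = mito_model([("A", 0, 100), ("B", 100, 180), ("C", 185, 300)])
    pairs = pi.enumerate_border_pairs(model, include_origin=True)
    assert pairs[-1].upstream_transcript_id == "C"
    assert pairs[-1].downstream_transcript_id == "A"


def test_overlapping_units_error_names_offenders():
    model = mito_model([("A", 0, 100), ("B", 90, 180)])
    with pytest.raises(ValueError, match="A.*B"):
        pi.enumerate_border_pairs(model)


ABUT = pi.BorderPair("A", "B", 100, 100, "MT")


def read(a, b):
    return AlignedRead(f"r{a}-{b}", "MT", ((a, b),))


@pytest.mark.parametrize(
    "block,counted",
    [
        ((94, 106), True),   # 6 nt on both sides
        ((95, 106), False),  # upstream overlap 5
        ((94, 105), False),  # downstream overlap 5
        ((60, 100), False),  # mature read: ends exactly at the border
        ((100, 150), False),  # starts exactly at the border
    ],
)
def test_border_spanning_rule_at_threshold(block, counted):
    assert pi.count_border_spanning([read(*block)], ABUT, 6) == int(counted)


def test_gapped_reads_are_not_border_spanners():
    gapped = AlignedRead("g", "MT", ((80, 120), (300, 310)))
    assert pi.count_border_spanning([gapped], ABUT, 6) == 0


def test_gap_border_requires_overlap_of_both_units():
    pair = pi.BorderPair("A", "B", 100, 105, "MT")
    assert pi.count_border_spanning([read(94, 111)], pair, 6) == 1
    # a read inside the gap region only does not span
    assert pi.count_border_spanning([read(100, 105)], pair, 1) == 0


def test_brute_force_equivalence_on_random_reads():
    """Vectorized/stream counting agrees with a literal per-read rule check."""
    rng = np.random.default_rng(17)
    pair = pi.BorderPair("A", "B", 500, 503, "MT")
    reads = [read(int(a), int(a) + int(l))
             for a, l in zip(rng.integers(380, 620, 1000), rng.integers(20, 120, 1000))]
    for m in (1, 6, 20):
        brute = sum(
            1
            for r in reads
            if (pair.upstream_end - r.blocks[0][0]) >= m
            and (r.blocks[0][1] - pair.downstream_start) >= m
        )
        assert pi.count_border_spanning(reads, pair, m) == brute


@settings(derandomize=True, max_examples=30)
@given(st.integers(1, 40))
def test_counts_non_increasing_in_min_overlap(m):
    rng = np.random.default_rng(5)
    reads = [read(int(a), int(a) + 50) for a in rng.integers(430, 570, 300)]
    pair = pi.BorderPair("A", "B", 500, 500, "MT")
    assert pi.count_border_spanning(reads, pair, m) >= pi.count_border_spanning(
        reads, pair, m + 1
    )


def totals(U, mito_U):
    return SampleTotals("s", total_reads=U, gapped_reads=0, ungapped_reads=U,
                        mito_reads=mito_U, mito_ungapped_reads=mito_U)


def test_normalization_arithmetic():
    norm, mean_index = pi.normalize_border_coverage(
        {"A|B": 20}, totals(100_000, 5_000), scale=1e6
    )
    assert norm["A|B"] == pytest.approx(4000.0)
    assert mean_index == pytest.approx(4000.0)


def test_normalization_is_depth_invariant():
    n1, i1 = pi.normalize_border_coverage({"A|B": 20}, totals(100_000, 5_000))
    n2, i2 = pi.normalize_border_coverage({"A|B": 40}, totals(200_000, 10_000))
    assert i1 == pytest.approx(i2)


def test_zero_counts_give_zero_index_and_inconsistency_errors():
    _, idx = pi.normalize_border_coverage({"A|B": 0, "B|C": 0}, totals(1000, 0))
    assert idx == 0.0
    with pytest.raises(ValueError):
        pi.normalize_border_coverage({"A|B": 3}, totals(1000, 0))


def test_compare_identical_index_vectors():
    indices = {"c1": 5.0, "c2": 5.0, "l1": 5.0, "l2": 5.0}
    conditions = {"c1": "con", "c2": "con", "l1": "ldl", "l2": "ldl"}
    cmp = pi.compare_precursor(indices, conditions, order=("con", "ldl"))
    assert cmp.t == 0.0 and cmp.p == 1.0


def test_specificity_zero_precursor_fraction_gives_zero_index():
    cfg = null_config(seed=41, reads=20_000, precursor_fraction={"con": 0.0, "ldl": 0.0})
    exp = simulate_in_memory(cfg)
    assert all(v == 0.0 for v in precursor_indices(exp).values())


def test_strong_precursor_shift_is_detected():
    cfg = null_config(
        seed=43, reads=100_000, precursor_fraction={"con": 0.02, "ldl": 0.20}
    )
    exp = simulate_in_memory(cfg)
    indices, cmp = precursor_analysis(exp, order=("con", "ldl"))
    assert cmp.p < 0.05
    assert cmp.mean_b / cmp.mean_a == pytest.approx(10.0, rel=0.35)
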