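from pathlib import Path

import pytest

from mitosplice import alignment_io
from mitosplice.model import AlignedRead, Chromosome, GenomeModel, Transcript
from mitosplice.synthetic import SimConfig, build_toy_genome, simulate_sample, write_gtf


@pytest.fixture()
def gtf_file(tmp_path, toy_genome):
    path = tmp_path / "annotation.gtf"
    write_gtf(toy_genome, path)
    return path


def test_gtf_round_trip_coordinates(gtf_file, toy_genome):
    model = alignment_io.read_annotation(gtf_file)
    by_id = {t.transcript_id: t for t in model.transcripts}
    for tx in toy_genome.transcripts:
        assert by_id[tx.transcript_id].exons == tx.exons
        assert by_id[tx.transcript_id].gene_id == tx.gene_id
        assert by_id[tx.transcript_id].biotype == tx.biotype


def test_gtf_one_based_inclusive_becomes_half_open(tmp_path):
    gtf = tmp_path / "one.gtf"
    gtf.write_text(
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    model = alignment_io.read_annotation(gtf)
    assert model.transcripts[0].exons == ((100, 200),)


def test_out_of_order_exons_are_sorted(tmp_path):
    gtf = tmp_path / "two.gtf"
    gtf.write_text(
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    model = alignment_io.read_annotation(gtf)
    assert model.transcripts[0].exons == ((100, 200), (300, 400))


def test_mito_compartment_inferred_from_name(tmp_path):
    gtf = tmp_path / "mt.gtf"
    gtf.write_text('MT\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    model = alignment_io.read_annotation(gtf)
    chrom = model.chromosome("MT")
    assert chrom.compartment == "mito" and chrom.circular


@pytest.mark.parametrize(
    "start,cigar,expected",
    [
        (10, [(0, 100)], ((10, 110),)),                      # 100M at 1-based 11
        (0, [(0, 50), (3, 200), (0, 50)], ((0, 50), (250, 300))),  # 50M200N50M
        (0, [(0, 30), (2, 5), (0, 70)], ((0, 105),)),        # deletion stays in-block
        (0, [(4, 5), (0, 20), (1, 3), (0, 10)], ((0, 30),)),  # soft clip + insertion
    ],
)
def test_blocks_from_cigar(start, cigar, expected):
    assert alignment_io.blocks_from_cigar(start, cigar) == expected


def test_classification_and_junction_extraction():
    single = AlignedRead("r1", "chr1", ((0, 50),))
    double = AlignedRead("r2", "chr1", ((0, 50), (250, 300)))
    triple = AlignedRead("r3", "chr1", ((0, 10), (20, 30), (40, 50)))
    assert alignment_io.classify_read(single) == "ungapped"
    assert alignment_io.classify_read(double) == "gapped"
    assert alignment_io.extract_junctions(single) == []
    [j] = alignment_io.extract_junctions(double)
    assert (j.donor_end, j.acceptor_start) == (50, 250)
    keys = alignment_io.extract_junctions(triple)
    assert [(k.donor_end, k.acceptor_start) for k in keys] == [(10, 20), (30, 40)]
    # junction count is always block count - 1
    assert len(keys) == len(triple.blocks) - 1


@pytest.fixture()
def two_gene_model():
    return GenomeModel(
        [Chromosome("chr1", 1000)],
        [
            Transcript("tA", "A", "chr1", "+", ((100, 300),)),
            Transcript("tB", "B", "chr1", "+", ((250, 500),)),  # overlaps A
        ],
    )


def test_union_mode_counting_rules(two_gene_model):
    reads = [
        AlignedRead("in_a", "chr1", ((110, 160),)),
        AlignedRead("a_and_b", "chr1", ((260, 290),)),  # in both genes
        AlignedRead("intergenic", "chr1", ((600, 650),)),
    ]
    counts = alignment_io.count_gene_reads(reads, two_gene_model, "s")
    assert counts.gene_counts == {"A": 1}
    assert counts.ambiguous == 1
    assert counts.no_feature == 1
    # partition: assigned + ambiguous + no_feature = total
    assert counts.gene_assigned() + counts.ambiguous + counts.no_feature == 3


def test_tally_example(two_gene_model):
    reads = (
        [AlignedRead(f"a{i}", "chr1", ((110, 160),)) for i in range(10)]
        + [AlignedRead(f"b{i}", "chr1", ((400, 450),)) for i in range(5)]
        + [AlignedRead(f"n{i}", "chr1", ((600, 650),)) for i in range(3)]
    )
    counts = alignment_io.count_gene_reads(reads, two_gene_model, "s")
    assert counts.gene_counts == {"A": 10, "B": 5}
    assert counts.no_feature == 3
    assert counts.totals.total_reads == 18


def test_sam_round_trip_reproduces_simulator_blocks(tmp_path, toy_genome):
    cfg = SimConfig(seed=11, reads_per_sample=2_000)
    sr = simulate_sample(toy_genome, cfg, "ldl", 1)
    sam = tmp_path / "s.sam"
    sr.write_sam(sam)
    parsed = {r.read_id: r.blocks for r in alignment_io.read_alignments(sam, sr.sample_id)}
    original = {r.read_id: r.blocks for r in sr.iter_alignments()}
    assert parsed == original


def test_sam_round_trip_count_tables_are_identical(tmp_path, toy_genome):
    cfg = SimConfig(seed=12, reads_per_sample=3_000)
    sr = simulate_sample(toy_genome, cfg, "con", 2)
    sam = tmp_path / "s.sam"
    sr.write_sam(sam)
    via_sam = alignment_io.sample_counts_from_sam(sam, toy_genome, sr.sample_id)
    via_arrays = sr.counts()
    assert via_sam.junction_counts == via_arrays.junction_counts
    assert via_sam.gene_counts == via_arrays.gene_counts
    assert via_sam.totals.__dict__ == via_arrays.totals.__dict__
    assert (via_sam.no_feature, via_sam.ambiguous) == (
        via_arrays.no_feature,
        via_arrays.ambiguous,
    )


def test_writers_produce_parseable_tables(tmp_path, toy_genome):
    cfg = SimConfig(seed=13, reads_per_sample=1_000)
    counts = simulate_sample(toy_genome, cfg, "con", 0).counts()
    bed = tmp_path / "junctions.bed"
    tsv = tmp_path / "genes.tsv"
    alignment_io.write_junction_bed(counts, bed)
    alignment_io.write_gene_counts(counts, tsv)
    bed_lines = [l.split("\t") for l in bed.read_text().splitlines()]
    assert sum(int(f[4]) for f in bed_lines) == counts.totals.gapped_reads
    assert "__ambiguous" in tsv.read_text()
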