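import numpy as np
import pandas as pd
import pytest

from conftest import null_config
from mitosplice.model import MITO
from mitosplice.synthetic import (
    FULL_ISOFORM,
    MITO_CHROM,
    NUCLEAR_GENE,
    SHORT_ISOFORM,
    SimConfig,
    anchor_coordinate,
    build_toy_genome,
    project_to_genome,
    simulate_experiment,
    simulate_sample,
)


def mito_units(genome):
    return sorted(genome.transcripts_on(MITO_CHROM), key=lambda t: t.start)


def test_mito_units_are_near_abutting_and_ordered(toy_genome):
    units = mito_units(toy_genome)
    assert len(units) >= 6
    for a, b in zip(units, units[1:]):
        assert a.end <= b.start
        assert b.start - a.end <= 5
    # at least one short tRNA-like unit flanked by two long units
    assert any(
        m.spliced_length < 100 <= min(a.spliced_length, b.spliced_length)
        and m.biotype == "Mt_tRNA"
        for a, m, b in zip(units, units[1:], units[2:])
    )


def test_nuclear_junctions_partition_at_anchor(toy_genome):
    anchor = anchor_coordinate(toy_genome)
    junctions = {
        j for t in toy_genome.transcripts if t.gene_id == NUCLEAR_GENE for j in t.junctions()
    }
    upstream = {j for j in junctions if j.donor_end < anchor}
    downstream = junctions - upstream
    assert upstream and downstream
    # the 3'-only isoform uses only downstream junctions
    short = next(t for t in toy_genome.transcripts if t.transcript_id == SHORT_ISOFORM)
    assert set(short.junctions()) == downstream


def test_genome_is_deterministic():
    cfg = SimConfig(seed=9)
    g1, seq1 = build_toy_genome(cfg)
    g2, seq2 = build_toy_genome(cfg)
    assert g1.transcripts == g2.transcripts
    assert seq1 == seq2
    assert [c.__dict__ for c in g1.chromosomes] == [c.__dict__ for c in g2.chromosomes]


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(read_length=10).validate()
    with pytest.raises(ValueError):
        SimConfig(mito_fraction={"con": 1.2, "ldl": 0.1}).validate()
    with pytest.raises(ValueError):
        SimConfig(
            isoform_mixture={
                "con": {FULL_ISOFORM: 0.7, SHORT_ISOFORM: 0.2},
                "ldl": {FULL_ISOFORM: 0.5, SHORT_ISOFORM: 0.5},
            }
        ).validate()
    # a read length exceeding the shortest mature mito unit is rejected
    cfg = SimConfig(read_length=80)
    with pytest.raises(ValueError):
        build_toy_genome(cfg)


def test_project_to_genome_splits_at_junctions(toy_genome):
    full = next(t for t in toy_genome.transcripts if t.transcript_id == FULL_ISOFORM)
    (s0, e0), (s1, e1) = full.exons[:2]
    blocks = project_to_genome(full.exons, e0 - s0 - 10, 30)
    assert blocks == ((e0 - 10, e0), (s1, s1 + 20))
    assert project_to_genome(full.exons, 0, 50) == ((s0, s0 + 50),)


def test_zero_reads_gives_empty_sample(toy_genome):
    cfg = SimConfig(seed=1, reads_per_sample=0)
    sr = simulate_sample(toy_genome, cfg, "con", 0)
    assert sr.n == 0
    counts = sr.counts()
    assert counts.totals.total_reads == 0
    assert not counts.junction_counts and not counts.gene_counts


def test_mature_reads_never_cross_borders(toy_genome):
    cfg = null_config(seed=2, reads=10_000, precursor_fraction={"con": 0.0, "ldl": 0.0})
    sr = simulate_sample(toy_genome, cfg, "con", 0)
    units = mito_units(toy_genome)
    R = cfg.read_length
    for read in sr.iter_alignments():
        if read.chromosome != MITO_CHROM:
            continue
        a, b = read.blocks[0]
        assert any(u.start <= a and b <= u.end for u in units)


def test_degenerate_mito_fraction_one(toy_genome):
    cfg = null_config(seed=4, reads=10_000, mito_fraction={"con": 1.0, "ldl": 1.0})
    sr = simulate_sample(toy_genome, cfg, "con", 0)
    assert sr.is_mito.all()
    assert sr.counts().totals.mito_reads == 10_000


def test_truth_counts_conserve_reads(small_experiment):
    for sr in small_experiment.samples:
        truth = sr.truth_rows()
        primary = truth[truth.kind.isin(["isoform", "mito_unit", "precursor"])]
        assert primary["count"].sum() == sr.n


def test_same_seed_gives_identical_truth_tables(tmp_path):
    cfg = SimConfig(seed=5, reads_per_sample=2_000)
    simulate_experiment(cfg, tmp_path / "a")
    simulate_experiment(cfg, tmp_path / "b")
    assert (tmp_path / "a" / "truth.tsv").read_bytes() == (
        tmp_path / "b" / "truth.tsv"
    ).read_bytes()
    with pytest.raises(FileExistsError):
        simulate_experiment(cfg, tmp_path / "a")


def test_experiment_layout_and_manifest(tmp_path):
    cfg = SimConfig(seed=6, reads_per_sample=100)
    manifest = simulate_experiment(cfg, tmp_path)
    assert len(manifest) == 8
    assert sorted(manifest.condition.unique()) == ["con", "ldl"]
    for row in manifest.itertuples():
        assert (tmp_path / row.path).exists()


def test_realized_mito_fraction_tracks_design(toy_genome):
    """Per-sample mitochondrial read share lands within +/-0.01 of the design."""
    cfg = SimConfig(seed=7, reads_per_sample=100_000)
    for condition, target in cfg.mito_fraction.items():
        for rep in range(cfg.n_replicates_per_condition):
            sr = simulate_sample(toy_genome, cfg, condition, rep)
            assert sr.is_mito.mean() == pytest.approx(target, abs=0.01)


def test_junction_truth_matches_binomial_expectation(toy_genome):
    """Realized junction counts stay within 3 binomial SDs of the closed form.

    E[count(j)] = sum over isoforms containing j of
    n_iso * (read_length - 1) / (spliced_length - read_length + 1).
    """
    cfg = null_config(seed=8, reads=50_000)
    sr = simulate_sample(toy_genome, cfg, "con", 0)
    counts = sr.counts()
    R = cfg.read_length
    n_iso = {
        tx.transcript_id: int(((~sr.is_mito) & (sr.iso_idx == i)).sum())
        for i, tx in enumerate(sr.isoforms)
    }
    all_junctions = {j for tx in sr.isoforms for j in tx.junctions()}
    for j in all_junctions:
        expected = sum(
            n_iso[tx.transcript_id] * (R - 1) / (tx.spliced_length - R + 1)
            for tx in sr.isoforms
            if j in set(tx.junctions())
        )
        sd = np.sqrt(expected)  # binomial, p small
        assert abs(counts.junction_counts[j] - expected) <= 3 * sd
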