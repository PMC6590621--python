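"""Synthetic two-compartment genome and aligned-read simulator.

The generator emulates a bulk RNA-seq study design at desk scale: two conditions
("con" vs "ldl") with quadruplicate samples of single-end reads, a multi-isoform
nuclear gene whose isoform mixture shifts between conditions (so upstream and
downstream junction usage move reciprocally), and a circular mitochondrial
chromosome of ordered, (near-)abutting single-exon transcript units.  A
controllable fraction of mitochondrial reads derives from the unprocessed
polycistronic precursor and may therefore span unit borders; mature reads never
do.  Every sample is accompanied by its ground truth, so each downstream
statistic has an exact oracle.

Reads are emitted as already-aligned SAM records (match/skip CIGARs only, MAPQ
255); sequencing errors, quality values and alignment itself are out of scope.
All simulated transcripts sit on the plus strand and no read wraps the circular
origin, which is placed inside a transcript-free spacer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    MITO,
    NUCLEAR,
    AlignedRead,
    Chromosome,
    GenomeModel,
    JunctionKey,
    SampleCounts,
    SampleTotals,
    Transcript,
)

NUCLEAR_CHROM = "chr1"
MITO_CHROM = "MT"
NUCLEAR_GENE = "NUC1"
FULL_ISOFORM = "NUC1-FL"    # uses every junction of the gene
SHORT_ISOFORM = "NUC1-SH"   # 3'-only isoform starting at the anchor exon

# nuclear gene geometry: 9 exons x 200 nt, introns 300 nt, anchor = exon 5
_N_EXONS = 9
_EXON_LEN = 200
_INTRON_LEN = 300
_GENE_START = 500
_ANCHOR_EXON = 4  # 0-based index: junctions before it are "upstream"

# mitochondrial transcript units: (id, length, biotype, gap to previous unit)
_MITO_UNITS = (
    ("MT-RU1", 900, "Mt_rRNA", 0),
    ("MT-TU1", 70, "Mt_tRNA", 0),
    ("MT-PU1", 1000, "protein_coding", 0),
    ("MT-TU2", 68, "Mt_tRNA", 3),
    ("MT-PU2", 850, "protein_coding", 0),
    ("MT-PU3", 1100, "protein_coding", 0),
    ("MT-PU4", 950, "protein_coding", 0),
)
_MITO_LEADING_SPACER = 300   # transcript-free region around the circular origin
_MITO_TRAILING_SPACER = 300


@dataclass
class SimConfig:
    """Study design knobs; defaults reproduce the emulated experiment.

    ``mito_fraction``, ``isoform_mixture`` and ``precursor_fraction`` are maps
    keyed by condition label; the three must share the same label set.
    """

    n_replicates_per_condition: int = 4
    reads_per_sample: int = 50_000
    read_length: int = 50
    mito_fraction: dict[str, float] = field(
        default_factory=lambda: {"con": 0.045, "ldl": 0.112}
    )
    isoform_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "con": {FULL_ISOFORM: 0.8, SHORT_ISOFORM: 0.2},
            "ldl": {FULL_ISOFORM: 0.5, SHORT_ISOFORM: 0.5},
        }
    )
    precursor_fraction: dict[str, float] = field(
        default_factory=lambda: {"con": 0.05, "ldl": 0.05}
    )
    seed: int = 0

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.mito_fraction)

    def validate(self, genome: "GenomeModel | None" = None) -> None:
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        labels = set(self.mito_fraction)
        if len(labels) < 2:
            raise ValueError("need at least two conditions")
        if set(self.isoform_mixture) != labels or set(self.precursor_fraction) != labels:
            raise ValueError("condition labels differ between parameter maps")
        for name, m in [("mito_fraction", self.mito_fraction),
                        ("precursor_fraction", self.precursor_fraction)]:
            for cond, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{cond}] outside [0, 1]")
        iso_ids = None
        for cond, mix in self.isoform_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"isoform_mixture[{cond}] does not sum to 1")
            if any(p < 0 or p > 1 for p in mix.values()):
                raise ValueError(f"isoform_mixture[{cond}] outside [0, 1]")
            if iso_ids is None:
                iso_ids = tuple(mix)
            elif tuple(mix) != iso_ids:
                raise ValueError("isoform sets differ between conditions")
        if genome is not None:
            by_id = {t.transcript_id: t for t in genome.transcripts}
            for iso in iso_ids:
                tx = by_id.get(iso)
                if tx is None:
                    raise ValueError(f"isoform {iso} not in genome")
                if tx.spliced_length < self.read_length:
                    raise ValueError(
                        f"isoform {iso} shorter than read_length {self.read_length}"
                    )
            for tx in genome.transcripts:
                chrom = genome.chromosome(tx.chromosome)
                if chrom.compartment == MITO and tx.spliced_length < self.read_length:
                    raise ValueError(
                        f"mature unit {tx.transcript_id} shorter than the read length"
                    )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_replicates_per_condition": self.n_replicates_per_condition,
                    "reads_per_sample": self.reads_per_sample,
                    "read_length": self.read_length,
                    "mito_fraction": dict(self.mito_fraction),
                    "isoform_mixture": {c: dict(m) for c, m in self.isoform_mixture.items()},
                    "precursor_fraction": dict(self.precursor_fraction),
                    "seed": self.seed,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _rng(config: SimConfig, *tokens: str | int) -> np.random.Generator:
    """Deterministic per-stream RNG: seed + stable hashes of the stream tokens."""
    entropy = [config.seed & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            entropy.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
        else:
            entropy.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def build_toy_genome(config: SimConfig) -> tuple[GenomeModel, dict[str, str]]:
    """Construct the toy two-compartment genome and its reference sequences.

    Returns the annotation model and a name -> sequence dict.  The layout is
    fixed; sequences are random but deterministic for a given config seed.
    """
    exons = tuple(
        (
            _GENE_START + k * (_EXON_LEN + _INTRON_LEN),
            _GENE_START + k * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN,
        )
        for k in range(_N_EXONS)
    )
    transcripts = [
        Transcript(FULL_ISOFORM, NUCLEAR_GENE, NUCLEAR_CHROM, "+", exons),
        Transcript(SHORT_ISOFORM, NUCLEAR_GENE, NUCLEAR_CHROM, "+", exons[_ANCHOR_EXON:]),
    ]
    nuclear_len = exons[-1][1] + 500

    pos = _MITO_LEADING_SPACER
    for unit_id, length, biotype, gap in _MITO_UNITS:
        pos += gap
        transcripts.append(
            Transcript(unit_id, unit_id, MITO_CHROM, "+", ((pos, pos + length),), biotype)
        )
        pos += length
    mito_len = pos + _MITO_TRAILING_SPACER

    genome = GenomeModel(
        chromosomes=[
            Chromosome(NUCLEAR_CHROM, nuclear_len, circular=False, compartment=NUCLEAR),
            Chromosome(MITO_CHROM, mito_len, circular=True, compartment=MITO),
        ],
        transcripts=transcripts,
    )
    config.validate(genome)
    rng = _rng(config, "reference-sequence")
    bases = np.array(list("ACGT"))
    sequences = {
        c.name: "".join(bases[rng.integers(0, 4, c.length)]) for c in genome.chromosomes
    }
    return genome, sequences


def anchor_coordinate(genome: GenomeModel) -> int:
    """Genomic start of the anchor exon separating upstream from downstream junctions."""
    full = next(t for t in genome.transcripts if t.transcript_id == FULL_ISOFORM)
    return full.exons[_ANCHOR_EXON][0]


def project_to_genome(
    exons: tuple[tuple[int, int], ...], t_start: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map a spliced-coordinate interval [t_start, t_start+length) to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    remaining = length
    offset = t_start
    for start, end in exons:
        exon_len = end - start
        if offset >= exon_len:
            offset -= exon_len
            continue
        take = min(exon_len - offset, remaining)
        blocks.append((start + offset, start + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("interval exceeds spliced transcript length")
    return tuple(blocks)


@dataclass
class SampleReads:
    """One simulated sample held as column arrays (fast path for counting).

    ``iter_alignments()`` materialises the identical reads as AlignedRead
    objects, and ``write_sam`` emits them as a coordinate-sorted SAM file; the
    array route and the SAM round trip yield the same count tables exactly.
    """

    sample_id: str
    condition: str
    replicate: int
    read_length: int
    genome: GenomeModel
    isoforms: list[Transcript]
    mito_units: list[Transcript]
    is_mito: np.ndarray      # bool[n]
    iso_idx: np.ndarray      # int, -1 for mito reads
    t_start: np.ndarray      # spliced start for nuclear reads, -1 otherwise
    is_precursor: np.ndarray  # bool, False for nuclear reads
    unit_idx: np.ndarray     # mature unit index, -1 otherwise
    g_start: np.ndarray      # genomic start for mito reads, -1 otherwise

    @property
    def n(self) -> int:
        return int(self.is_mito.size)

    # --- junction geometry helpers -------------------------------------------------
    def _iso_junction_info(self):
        """Per isoform: spliced junction positions and their genomic JunctionKeys."""
        out = []
        for tx in self.isoforms:
            lens = np.array([e - s for s, e in tx.exons])
            spliced_pos = np.cumsum(lens)[:-1]
            out.append((spliced_pos, tx.junctions()))
        return out

    def counts(self) -> SampleCounts:
        """Vectorized per-sample count tables (junctions, genes, totals)."""
        R = self.read_length
        n = self.n
        junction_counts: dict[JunctionKey, int] = {}
        gapped_mask = np.zeros(n, dtype=bool)
        for i, (spliced_pos, keys) in enumerate(self._iso_junction_info()):
            sel = (~self.is_mito) & (self.iso_idx == i)
            if not sel.any():
                continue
            starts = self.t_start[sel]
            sel_idx = np.flatnonzero(sel)
            for p, key in zip(spliced_pos, keys):
                covered = (starts > p - R) & (starts < p)
                c = int(covered.sum())
                if c:
                    junction_counts[key] = junction_counts.get(key, 0) + c
                    gapped_mask[sel_idx[covered]] = True

        gene_counts: dict[str, int] = {}
        no_feature = 0
        ambiguous = 0
        n_nuclear = int((~self.is_mito).sum())
        if n_nuclear:
            gene_counts[self.isoforms[0].gene_id] = n_nuclear

        unit_starts = np.array([u.start for u in self.mito_units])
        unit_ends = np.array([u.end for u in self.mito_units])
        mature = self.is_mito & ~self.is_precursor
        if mature.any():
            idx, cnt = np.unique(self.unit_idx[mature], return_counts=True)
            for i, c in zip(idx, cnt):
                gid = self.mito_units[int(i)].gene_id
                gene_counts[gid] = gene_counts.get(gid, 0) + int(c)
        prec = self.is_mito & self.is_precursor
        if prec.any():
            a = self.g_start[prec]
            first = np.searchsorted(unit_ends, a, side="right")
            last = np.searchsorted(unit_starts, a + R, side="left") - 1
            n_overlap = last - first + 1
            no_feature += int((n_overlap <= 0).sum())
            ambiguous += int((n_overlap >= 2).sum())
            single = n_overlap == 1
            if single.any():
                idx, cnt = np.unique(first[single], return_counts=True)
                for i, c in zip(idx, cnt):
                    gid = self.mito_units[int(i)].gene_id
                    gene_counts[gid] = gene_counts.get(gid, 0) + int(c)

        n_mito = int(self.is_mito.sum())
        gapped = int(gapped_mask.sum())
        totals = SampleTotals(
            sample_id=self.sample_id,
            total_reads=n,
            gapped_reads=gapped,
            ungapped_reads=n - gapped,
            mito_reads=n_mito,
            mito_ungapped_reads=n_mito,  # simulated mito reads are single-block
        )
        totals.validate()
        return SampleCounts(
            sample_id=self.sample_id,
            totals=totals,
            junction_counts=junction_counts,
            gene_counts=gene_counts,
            no_feature=no_feature,
            ambiguous=ambiguous,
        )

    def border_span_counts(self, pairs, min_overlap: int = 6) -> dict[int, int]:
        """Reads spanning each border pair by >= min_overlap nt on both sides.

        Keyed by index into ``pairs`` (BorderPair objects from precursor_index).
        """
        R = self.read_length
        a = self.g_start[self.is_mito]
        out: dict[int, int] = {}
        for k, pair in enumerate(pairs):
            lo = pair.downstream_start + min_overlap - R
            hi = pair.upstream_end - min_overlap
            out[k] = int(((a >= lo) & (a <= hi)).sum()) if hi >= lo else 0
        return out

    def truth_rows(self, border_min_overlap: int = 6) -> pd.DataFrame:
        """Ground-truth counts for this sample as a long-format table."""
        rows: list[tuple[str, str, int, str, str, int]] = []

        def add(kind: str, key: str, count: int) -> None:
            rows.append(
                (self.sample_id, self.condition, self.replicate, kind, key, int(count))
            )

        for i, tx in enumerate(self.isoforms):
            add("isoform", tx.transcript_id, ((~self.is_mito) & (self.iso_idx == i)).sum())
        mature = self.is_mito & ~self.is_precursor
        for i, unit in enumerate(self.mito_units):
            add("mito_unit", unit.transcript_id, (mature & (self.unit_idx == i)).sum())
        add("precursor", "precursor", (self.is_mito & self.is_precursor).sum())

        sc = self.counts()
        for key, c in sorted(
            sc.junction_counts.items(), key=lambda kv: (kv[0].donor_end, kv[0].acceptor_start)
        ):
            add("junction", f"{key.chromosome}:{key.donor_end}-{key.acceptor_start}", c)

        from .precursor_index import enumerate_border_pairs  # local import: avoid cycle

        pairs = enumerate_border_pairs(self.genome)
        for k, c in self.border_span_counts(pairs, border_min_overlap).items():
            p = pairs[k]
            add("border", f"{p.upstream_transcript_id}|{p.downstream_transcript_id}", c)
        return pd.DataFrame(
            rows, columns=["sample_id", "condition", "replicate", "kind", "key", "count"]
        )

    # --- read materialisation ------------------------------------------------------
    def iter_alignments(self):
        R = self.read_length
        iso_exons = [tx.exons for tx in self.isoforms]
        for i in range(self.n):
            rid = f"{self.sample_id}:r{i:07d}"
            if self.is_mito[i]:
                a = int(self.g_start[i])
                yield AlignedRead(rid, MITO_CHROM, ((a, a + R),), "+", self.sample_id)
            else:
                blocks = project_to_genome(
                    iso_exons[int(self.iso_idx[i])], int(self.t_start[i]), R
                )
                yield AlignedRead(rid, NUCLEAR_CHROM, blocks, "+", self.sample_id)

    def write_sam(self, path: str | Path) -> None:
        path = Path(path)
        if path.exists():
            raise FileExistsError(path)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c.name, "LN": c.length} for c in self.genome.chromosomes],
        }
        ref_ids = {c.name: k for k, c in enumerate(self.genome.chromosomes)}
        reads = sorted(
            self.iter_alignments(), key=lambda r: (ref_ids[r.chromosome], r.start)
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for r in reads:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = r.read_id
                seg.flag = 0
                seg.reference_id = ref_ids[r.chromosome]
                seg.reference_start = r.start
                seg.mapping_quality = 255
                cigar = []
                prev_end = None
                for s, e in r.blocks:
                    if prev_end is not None:
                        cigar.append((3, s - prev_end))  # N: reference skip
                    cigar.append((0, e - s))             # M: alignment match
                    prev_end = e
                seg.cigartuples = cigar
                out.write(seg)


def simulate_sample(
    genome: GenomeModel, config: SimConfig, condition: str, replicate: int
) -> SampleReads:
    """Draw one sample's reads.

    Each read picks its compartment by a Bernoulli(mito_fraction) draw; nuclear
    reads pick an isoform from the condition's mixture and a uniform start on the
    spliced transcript; mitochondrial reads are either precursor-derived (uniform
    on the mitochondrial genome, may span unit borders) or mature (unit chosen
    proportional to length, start uniform within the unit).
    """
    config.validate(genome)
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if not 0 <= replicate < config.n_replicates_per_condition:
        raise ValueError("replicate out of range")
    R = config.read_length
    n = config.reads_per_sample
    rng = _rng(config, "sample", condition, replicate)
    sample_id = f"{condition}_{replicate + 1}"

    isoform_ids = list(config.isoform_mixture[condition])
    by_id = {t.transcript_id: t for t in genome.transcripts}
    isoforms = [by_id[i] for i in isoform_ids]
    mito_units = sorted(
        (t for t in genome.transcripts
         if genome.chromosome(t.chromosome).compartment == MITO),
        key=lambda t: t.start,
    )
    mito_chrom = genome.mito_chromosomes()[0]

    is_mito = rng.random(n) < config.mito_fraction[condition]
    iso_idx = np.full(n, -1, dtype=np.int64)
    t_start = np.full(n, -1, dtype=np.int64)
    is_precursor = np.zeros(n, dtype=bool)
    unit_idx = np.full(n, -1, dtype=np.int64)
    g_start = np.full(n, -1, dtype=np.int64)

    nuc = np.flatnonzero(~is_mito)
    if nuc.size:
        probs = np.array([config.isoform_mixture[condition][i] for i in isoform_ids])
        iso_idx[nuc] = rng.choice(len(isoforms), size=nuc.size, p=probs)
        for i, tx in enumerate(isoforms):
            sel = nuc[iso_idx[nuc] == i]
            if sel.size:
                t_start[sel] = rng.integers(0, tx.spliced_length - R + 1, sel.size)

    mito = np.flatnonzero(is_mito)
    if mito.size:
        is_precursor[mito] = rng.random(mito.size) < config.precursor_fraction[condition]
        prec = mito[is_precursor[mito]]
        if prec.size:
            g_start[prec] = rng.integers(0, mito_chrom.length - R + 1, prec.size)
        mat = mito[~is_precursor[mito]]
        if mat.size:
            lengths = np.array([u.spliced_length for u in mito_units], dtype=float)
            unit_idx[mat] = rng.choice(len(mito_units), size=mat.size, p=lengths / lengths.sum())
            for i, unit in enumerate(mito_units):
                sel = mat[unit_idx[mat] == i]
                if sel.size:
                    g_start[sel] = unit.start + rng.integers(0, unit.spliced_length - R + 1, sel.size)

    return SampleReads(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        read_length=R,
        genome=genome,
        isoforms=isoforms,
        mito_units=mito_units,
        is_mito=is_mito,
        iso_idx=iso_idx,
        t_start=t_start,
        is_precursor=is_precursor,
        unit_idx=unit_idx,
        g_start=g_start,
    )


def simulate_samples(config: SimConfig, genome: GenomeModel | None = None):
    """Yield SampleReads for every (condition, replicate) of the design."""
    if genome is None:
        genome, _ = build_toy_genome(config)
    for condition in config.conditions:
        for replicate in range(config.n_replicates_per_condition):
            yield simulate_sample(genome, config, condition, replicate)


def write_gtf(genome: GenomeModel, path: str | Path) -> None:
    """Emit the annotation as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx in genome.transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{tx.biotype}";'
            )
            fh.write(
                f"{tx.chromosome}\tmitosplice_sim\ttranscript\t{tx.start + 1}\t{tx.end}"
                f"\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chromosome}\tmitosplice_sim\texon\t{s + 1}\t{e}"
                    f"\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def simulate_experiment(config: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate the full design and write reference, annotation, SAMs and truth.

    Returns the sample manifest (sample_id, condition, replicate, path).  Fails
    rather than overwriting any pre-existing output file.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, sequences = build_toy_genome(config)

    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.tsv",
        "config": outdir / "config.yaml",
    }
    for p in paths.values():
        if p.exists():
            raise FileExistsError(p)

    write_fasta(sequences, paths["fasta"])
    write_gtf(genome, paths["gtf"])
    config.to_yaml(paths["config"])

    manifest_rows = []
    truth_frames = []
    for sr in simulate_samples(config, genome):
        sam_path = outdir / f"{sr.sample_id}.sam"
        sr.write_sam(sam_path)
        manifest_rows.append(
            {
                "sample_id": sr.sample_id,
                "condition": sr.condition,
                "replicate": sr.replicate,
                "path": sam_path.name,
            }
        )
        truth_frames.append(sr.truth_rows())

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(paths["truth"], sep="\t", index=False)
    return manifest
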