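"""Synthetic hybrid-genome ChIP datasets with known allelic ground truth.

The generator emulates the data model of an allele-specific ChIP-seq study in
reciprocal F1 hybrid mouse ESC lines (JB1 = JF1 mother x B6 father, BJ1 = the
reciprocal cross): two haplotypes differing only by point SNPs (about one per
250 bp), male autosome-only analysis, 50 bp single-end reads, binding peaks
that carry planted hexamer-motif architectures, per-peak allelic read
fractions for five truth categories, sequencing error and duplicate reads.

Truth categories and the B6-read fraction they imply per line (f = the
configured mono-allelic fraction, 0.95 by default):

==============  =========  =========
category        JB1        BJ1
==============  =========  =========
biallelic       0.5        0.5
maternal        1 - f      f          (maternal allele is JF1 in JB1, B6 in BJ1)
paternal        f          1 - f
B6_specific     f          f          (genotype-driven, same in both lines)
JF1_specific    1 - f      1 - f
==============  =========  =========

All randomness flows from one seed through a documented stream order
(reference, planting, then reads per cell line), so a fixed seed gives
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allelic_reads import ReadPlacement, write_placements_tsv, write_sam
from .intervals import GenomicInterval, write_bed
from .motif_analysis import CANONICAL_MOTIF, VARIANT_MOTIF
from .pseudogenome import (
    HaplotypeGenome,
    SnpRecord,
    apply_snps,
    reverse_complement,
    write_fasta,
    write_vcf,
)

CATEGORIES = ("biallelic", "maternal", "paternal", "B6_specific", "JF1_specific")

# RNG stream order: child k of the config seed drives stage k.
_STAGE_REFERENCE = 0
_STAGE_PLANTING = 1
_STAGE_READS = {"JB1": 2, "BJ1": 3}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    n_chromosomes: int = 2
    chrom_length: int = 50_000
    snp_density: float = 1 / 250
    n_peaks_per_category: int = 4
    peak_width: int = 300
    reads_per_peak_per_line: int = 100
    allelic_fraction_mono: float = 0.95
    read_length: int = 50
    error_rate: float = 0.001
    duplicate_fraction: float = 0.05
    ensure_peak_snp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_density", "error_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.allelic_fraction_mono <= 1.0:
            raise ValueError("allelic_fraction_mono must be in [0.5, 1]")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("chromosome count/length must be positive")
        if self.read_length > self.peak_width:
            raise ValueError("read_length must not exceed peak_width")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )

    def b6_fraction(self, category: str, cell_line: str) -> float:
        f = self.allelic_fraction_mono
        table = {
            "biallelic": {"JB1": 0.5, "BJ1": 0.5},
            "maternal": {"JB1": 1 - f, "BJ1": f},
            "paternal": {"JB1": f, "BJ1": 1 - f},
            "B6_specific": {"JB1": f, "BJ1": f},
            "JF1_specific": {"JB1": 1 - f, "BJ1": 1 - f},
        }
        return table[category][cell_line]


@dataclass
class SimTruth:
    """Ground truth for one simulated peak."""

    peak_id: str
    category: str
    true_b6_fraction: dict[str, float]
    planted_motifs: list[tuple[int, str, str]]  # (peak offset, strand, motif_id)
    disrupting_snp: tuple[int, str] | None = None  # (pos, allele losing the motif)


@dataclass
class SimDataset:
    config: SimConfig
    b6: HaplotypeGenome
    jf1: HaplotypeGenome
    peaks: list[GenomicInterval]
    snps: list[SnpRecord]
    truth: list[SimTruth]
    reads: dict[str, list[ReadPlacement]] = field(default_factory=dict)


def make_reference(config: SimConfig) -> HaplotypeGenome:
    """Uniform-base reference haplotype; deterministic for a fixed seed."""
    rng = config.rng(_STAGE_REFERENCE)
    seqs = {}
    for i in range(config.n_chromosomes):
        draw = rng.integers(0, 4, size=config.chrom_length)
        seqs[f"chr{i + 1}"] = _BASES[draw].tobytes().decode("ascii")
    return HaplotypeGenome(label="B6", sequences=seqs)


def _break_motif_base(hexamer_fwd: str, strand: str) -> tuple[int, str, str]:
    """Forward-strand offset/base change destroying the motif's CpG cytosine.

    Returns (offset within hexamer 0-based on forward strand, intact forward
    base, broken forward base). The CpG cytosine sits at motif position 4; on
    the minus strand that maps to forward offset 2 and a G>T change.
    """
    if strand == "+":
        return 3, hexamer_fwd[3], "A"  # motif position 4, C>A
    return 2, hexamer_fwd[2], "T"  # complement of the C>A change


def plant_peaks_and_snps(
    reference: HaplotypeGenome, config: SimConfig
) -> tuple[HaplotypeGenome, list[GenomicInterval], list[SnpRecord], list[SimTruth]]:
    """Place peaks, write motif architectures into the reference, place SNPs.

    Every peak receives one to four motif occurrences with a mix of close
    (< 38 bp gap) and distant spacings. Strain-specific peaks carry one SNP in
    a motif CpG whose non-permissive allele destroys the motif: for a
    B6-specific peak the intact motif sits in the reference and the JF1 allele
    breaks it; for a JF1-specific peak the reference carries the broken
    hexamer and the JF1 allele restores it. Background SNPs fall at
    ``snp_density`` outside motif footprints, and (unless ``ensure_peak_snp``
    is off) every peak is guaranteed at least one SNP so it can be
    informative. Returns the motif-bearing B6 genome, peaks, SNPs and truth.
    """
    rng = config.rng(_STAGE_PLANTING)
    n_total = 5 * config.n_peaks_per_category
    stride = config.peak_width + 700
    per_chrom = int(np.ceil(n_total / config.n_chromosomes))
    if 200 + per_chrom * stride > config.chrom_length:
        raise ValueError(
            f"genome too small for {n_total} peaks of width {config.peak_width}"
        )

    chrom_seqs = {c: bytearray(s, "ascii") for c, s in reference.sequences.items()}
    chrom_names = list(chrom_seqs)

    categories = np.repeat(np.arange(5), config.n_peaks_per_category)
    categories = categories[rng.permutation(n_total)]

    peaks: list[GenomicInterval] = []
    truth: list[SimTruth] = []
    snps: list[SnpRecord] = []
    motif_spans: list[tuple[str, int, int]] = []  # forbidden zones for bg SNPs
    snp_positions: set[tuple[str, int]] = set()

    for idx in range(n_total):
        chrom = chrom_names[idx % config.n_chromosomes]
        slot = idx // config.n_chromosomes
        start = 200 + slot * stride + 1  # 1-based
        end = start + config.peak_width - 1
        category = CATEGORIES[categories[idx]]
        peak_id = f"peak_{idx + 1:04d}_{category}"
        peak = GenomicInterval(chrom, start, end, peak_id)
        seq = chrom_seqs[chrom]

        n_motifs = int(rng.integers(1, 5))
        planted: list[tuple[int, str, str]] = []
        offset = int(rng.integers(10, 40))
        for m_i in range(n_motifs):
            if offset + 6 > config.peak_width - 10:
                break
            motif_id = CANONICAL_MOTIF if rng.random() < 0.8 else VARIANT_MOTIF
            strand = "+" if rng.random() < 0.5 else "-"
            hexamer = motif_id if strand == "+" else reverse_complement(motif_id)
            gpos0 = start - 1 + offset  # 0-based genomic
            seq[gpos0 : gpos0 + 6] = hexamer.encode("ascii")
            planted.append((offset, strand, motif_id))
            motif_spans.append((chrom, gpos0 + 1, gpos0 + 6))
            gap = int(rng.integers(2, 38)) if rng.random() < 0.6 else int(
                rng.integers(45, 90)
            )
            offset += 6 + gap

        disrupting: tuple[int, str] | None = None
        if category in ("B6_specific", "JF1_specific"):
            offset0, strand0, motif_id0 = planted[0]
            hexamer = motif_id0 if strand0 == "+" else reverse_complement(motif_id0)
            rel, intact_base, broken_base = _break_motif_base(hexamer, strand0)
            gpos = start + offset0 + rel  # 1-based genomic position of the SNP
            if category == "B6_specific":
                # reference keeps the motif; the JF1 allele destroys it
                snp = SnpRecord(chrom, gpos, intact_base, broken_base)
                disrupting = (gpos, "JF1")
            else:
                # reference carries the broken hexamer; JF1 restores the motif
                seq[gpos - 1] = ord(broken_base)
                snp = SnpRecord(chrom, gpos, broken_base, intact_base)
                disrupting = (gpos, "B6")
            snps.append(snp)
            snp_positions.add((chrom, gpos))

        peaks.append(peak)
        truth.append(
            SimTruth(
                peak_id=peak_id,
                category=category,
                true_b6_fraction={
                    line: config.b6_fraction(category, line) for line in ("JB1", "BJ1")
                },
                planted_motifs=planted,
                disrupting_snp=disrupting,
            )
        )

    # Background SNPs at snp_density, outside motif footprints.
    forbidden: dict[str, set[int]] = {c: set() for c in chrom_names}
    for chrom, s, e in motif_spans:
        forbidden[chrom].update(range(s, e + 1))
    base_order = "ACGT"
    for chrom in chrom_names:
        length = len(chrom_seqs[chrom])
        hit = np.flatnonzero(rng.random(length) < config.snp_density)
        for p0 in hit:
            pos = int(p0) + 1
            if pos in forbidden[chrom] or (chrom, pos) in snp_positions:
                continue
            ref_base = chr(chrom_seqs[chrom][pos - 1])
            alt = base_order[
                (base_order.index(ref_base) + int(rng.integers(1, 4))) % 4
            ]
            snps.append(SnpRecord(chrom, pos, ref_base, alt))
            snp_positions.add((chrom, pos))

    # Guarantee every peak overlaps at least one SNP in its read-coverable
    # core: a SNP within read_length of a peak edge is reachable by only a
    # handful of in-peak read starts, which would starve the peak of
    # informative reads no matter how deep the sequencing.
    if config.ensure_peak_snp:
        L = config.read_length
        for peak in peaks:
            core_lo = peak.start + L - 1
            core_hi = peak.end - L + 1
            if any(
                (peak.chrom, p) in snp_positions
                for p in range(core_lo, core_hi + 1)
            ):
                continue
            candidates = [
                p
                for p in range(core_lo, core_hi + 1)
                if p not in forbidden[peak.chrom]
                and (peak.chrom, p) not in snp_positions
            ]
            pos = int(candidates[int(rng.integers(0, len(candidates)))])
            ref_base = chr(chrom_seqs[peak.chrom][pos - 1])
            alt = base_order[
                (base_order.index(ref_base) + int(rng.integers(1, 4))) % 4
            ]
            snps.append(SnpRecord(peak.chrom, pos, ref_base, alt))
            snp_positions.add((peak.chrom, pos))

    snps.sort(key=lambda s: (s.chrom, s.pos))
    b6 = HaplotypeGenome(
        label="B6", sequences={c: s.decode("ascii") for c, s in chrom_seqs.items()}
    )
    return b6, peaks, snps, truth


def simulate_reads(
    genomes: dict[str, HaplotypeGenome],
    peaks: Sequence[GenomicInterval],
    truth: Sequence[SimTruth],
    config: SimConfig,
    cell_line: str,
) -> list[ReadPlacement]:
    """Draw 50 bp single-end reads per peak for one cell line.

    Read starts are uniform over the peak; the source haplotype follows the
    line- and category-dependent B6 fraction; strands are symmetric; per-base
    substitution errors occur at ``error_rate``; a ``duplicate_fraction`` of
    exact copies is appended.
    """
    if cell_line not in _STAGE_READS:
        raise ValueError(f"unknown cell line {cell_line!r}")
    rng = config.rng(_STAGE_READS[cell_line])
    truth_by_id = {t.peak_id: t for t in truth}
    L = config.read_length
    reads: list[ReadPlacement] = []
    for peak in peaks:
        t = truth_by_id[peak.name]
        frac_b6 = t.true_b6_fraction[cell_line]
        n = config.reads_per_peak_per_line
        hap_is_b6 = rng.random(n) < frac_b6
        starts = rng.integers(peak.start, peak.end - L + 2, size=n)
        minus = rng.random(n) < 0.5
        for i in range(n):
            hap = genomes["B6"] if hap_is_b6[i] else genomes["JF1"]
            s = int(starts[i])
            fwd = hap.fetch(peak.chrom, s, s + L - 1)
            if config.error_rate > 0:
                err = np.flatnonzero(rng.random(L) < config.error_rate)
                if err.size:
                    b = bytearray(fwd, "ascii")
                    for j in err:
                        old = "ACGT".index(chr(b[j]))
                        b[j] = ord("ACGT"[(old + int(rng.integers(1, 4))) % 4])
                    fwd = b.decode("ascii")
            strand = "-" if minus[i] else "+"
            seq = reverse_complement(fwd) if strand == "-" else fwd
            reads.append(
                ReadPlacement(
                    read_id=f"{cell_line}:{peak.name}:{i}",
                    chrom=peak.chrom,
                    start=s,
                    strand=strand,
                    sequence=seq,
                )
            )
    n_dup = int(round(config.duplicate_fraction * len(reads)))
    if n_dup:
        picks = rng.integers(0, len(reads), size=n_dup)
        for k, idx in enumerate(picks):
            src = reads[int(idx)]
            reads.append(
                ReadPlacement(
                    read_id=f"{src.read_id}:dup{k}",
                    chrom=src.chrom,
                    start=src.start,
                    strand=src.strand,
                    sequence=src.sequence,
                )
            )
    return reads


def simulate_dataset(config: SimConfig) -> SimDataset:
    """End-to-end seeded simulation: genomes, peaks, SNPs, truth and reads."""
    reference = make_reference(config)
    b6, peaks, snps, truth = plant_peaks_and_snps(reference, config)
    jf1 = apply_snps(b6, snps, "JF1")
    genomes = {"B6": b6, "JF1": jf1}
    reads = {
        line: simulate_reads(genomes, peaks, truth, config, line)
        for line in ("JB1", "BJ1")
    }
    return SimDataset(
        config=config, b6=b6, jf1=jf1, peaks=peaks, snps=snps, truth=truth, reads=reads
    )


def write_dataset(ds: SimDataset, outdir: str | Path, sam: bool = True) -> None:
    """Write the dataset in standard on-disk formats (FASTA/VCF/BED/SAM/TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.b6, outdir / "b6.fa")
    write_fasta(ds.jf1, outdir / "jf1.fa")
    write_vcf(ds.snps, ds.b6.lengths(), outdir / "snps.vcf")
    write_bed(ds.peaks, outdir / "peaks.bed")
    for line, reads in ds.reads.items():
        if sam:
            write_sam(reads, ds.b6.lengths(), outdir / f"reads_{line.lower()}.sam")
        write_placements_tsv(reads, outdir / f"reads_{line.lower()}.tsv")
    truth_rows = []
    for t in ds.truth:
        truth_rows.append(
            {
                "peak_id": t.peak_id,
                "category": t.category,
                "b6_fraction_jb1": t.true_b6_fraction["JB1"],
                "b6_fraction_bj1": t.true_b6_fraction["BJ1"],
                "planted_motifs": ";".join(
                    f"{o}:{s}:{m}" for o, s, m in t.planted_motifs
                ),
                "disrupting_snp": (
                    f"{t.disrupting_snp[0]}:{t.disrupting_snp[1]}"
                    if t.disrupting_snp
                    else ""
                ),
            }
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
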