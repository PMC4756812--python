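"""Haplotype (pseudo)genome construction from a reference plus an SNV set.

The two hybrid haplotypes (C57BL/6 reference, "B6", and the JF1 alternate) differ
only by single-nucleotide substitutions, so the JF1 genome is the reference with
each SNP's alternate allele substituted in place. Coordinates are 1-based
inclusive throughout this module; lowercase/soft-masked sequence is uppercased on
load so downstream motif scanning never misses masked bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One biallelic single-nucleotide difference between the haplotypes.

    ``allele_b6`` is the reference-assembly (B6) base, ``allele_jf1`` the
    alternate. ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    allele_b6: str
    allele_jf1: str
    id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.allele_b6 not in _BASES or self.allele_jf1 not in _BASES:
            raise ValueError(
                f"SNP alleles must be single A/C/G/T bases: "
                f"{self.allele_b6}/{self.allele_jf1}"
            )
        if self.allele_b6 == self.allele_jf1:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} is not biallelic")

    def allele(self, label: str) -> str:
        return self.allele_b6 if label == "B6" else self.allele_jf1


@dataclass
class HaplotypeGenome:
    """A named haplotype as a chromosome -> uppercase sequence map."""

    label: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the closed 1-based interval [start, end]."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start - 1 : end]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def read_fasta(path: str | Path, label: str) -> HaplotypeGenome:
    """Load a FASTA file as a haplotype genome (sequences uppercased)."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return HaplotypeGenome(label=label, sequences=seqs)


def write_fasta(genome: HaplotypeGenome, path: str | Path, width: int = 60) -> None:
    """Write the genome as FASTA, line-wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_snps(vcf_path: str | Path) -> list[SnpRecord]:
    """Load biallelic SNVs from a VCF; REF is the B6 allele, ALT the JF1 allele.

    Indels (REF or ALT longer than one base) and multi-allelic records are
    skipped with a logged count; output is sorted by (chrom, pos).
    """
    snps: list[SnpRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                n_skipped += 1
                continue
            snps.append(
                SnpRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    allele_b6=rec.ref.upper(),
                    allele_jf1=alts[0].upper(),
                    id=rec.id or "",
                )
            )
    if n_skipped:
        logger.info("load_snps: skipped %d non-SNV/multi-allelic records", n_skipped)
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


def write_vcf(
    snps: Iterable[SnpRecord],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write SNPs as a minimal VCF 4.2 (REF = B6 allele, ALT = JF1 allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            sid = s.id or "."
            fh.write(
                f"{s.chrom}\t{s.pos}\t{sid}\t{s.allele_b6}\t{s.allele_jf1}"
                f"\t.\t.\t.\n"
            )


def apply_snps(
    reference: HaplotypeGenome,
    snps: Iterable[SnpRecord],
    target_label: str,
    ref_haplotype: str = "B6",
) -> HaplotypeGenome:
    """Substitute the target haplotype's alleles into the reference.

    The reference base at every SNP must equal the reference-side allele;
    a mismatch signals an inconsistent SNP table and raises with the offending
    record. Chromosome lengths are preserved (SNV-only divergence).
    """
    out = {c: bytearray(s, "ascii") for c, s in reference.sequences.items()}
    bad: list[str] = []
    for snp in snps:
        if snp.chrom not in out:
            raise KeyError(f"SNP chromosome {snp.chrom!r} not in reference")
        seq = out[snp.chrom]
        if snp.pos > len(seq):
            raise IndexError(
                f"SNP {snp.chrom}:{snp.pos} beyond chromosome end ({len(seq)} bp)"
            )
        expected = snp.allele(ref_haplotype)
        actual = chr(seq[snp.pos - 1])
        if actual != expected:
            bad.append(f"{snp.chrom}:{snp.pos} ref={actual} expected={expected}")
            continue
        seq[snp.pos - 1] = ord(snp.allele(target_label))
    if bad:
        raise ValueError(
            "reference-base mismatch for SNPs (inconsistent SNP table): "
            + "; ".join(bad[:10])
        )
    return HaplotypeGenome(
        label=target_label, sequences={c: s.decode("ascii") for c, s in out.items()}
    )
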