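"""Haplotype assignment of ChIP-seq reads and per-peak allelic counts.

A read placed on the genome is compared base-by-base against both haplotypes
(Hamming distance at its placement; the reverse-complement is taken first for
minus-strand reads). Reads overlapping at least one distinguishing SNP are
*informative* (IR); an informative read is *allele-specific* (ASR) for the
haplotype it matches under the mode's mismatch contract:

* stringent mode — zero mismatches tolerated, so an informative read matches
  exactly one haplotype (it must disagree with the other at the SNP);
* control mode — up to three mismatches tolerated, used to calibrate residual
  mapping bias.  Under the default "alignment" semantics a read is counted for
  *every* haplotype it matches within the bound (an informative clean read then
  counts for both, pushing the control percentage j toward 50); the alternative
  "vote" semantics gives a single call decided by the SNP bases, confirmed only
  when the candidate-haplotype mismatch total is within the bound.

Duplicate reads are removed positionally (chrom, start, strand), and reads
overlapping indels can be excluded, mirroring the standard single-end cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .intervals import GenomicInterval
from .pseudogenome import HaplotypeGenome, SnpRecord, reverse_complement

Mode = Literal["stringent", "control"]

#: mismatch bound per assignment mode
MISMATCH_BOUND: dict[str, int] = {"stringent": 0, "control": 3}

CELL_LINES = ("JB1", "BJ1")


@dataclass(frozen=True)
class ReadPlacement:
    """A single-end read with its genomic placement.

    ``sequence`` holds the bases as sequenced; for a minus-strand read the
    forward-strand genome projection is its reverse complement. ``start`` is
    the 1-based leftmost aligned position.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def forward_sequence(self) -> str:
        """The read projected onto the forward genome strand."""
        if self.strand == "-":
            return reverse_complement(self.sequence)
        return self.sequence


@dataclass(frozen=True)
class AlleleAssignment:
    read_id: str
    mm_b6: int
    mm_jf1: int
    n_snps_overlapped: int
    call: str  # B6 | JF1 | non_informative | ambiguous
    mode: str


class SnpIndex:
    """Range-queryable index of SNPs, per chromosome, by position."""

    def __init__(self, snps: Sequence[SnpRecord]):
        by_chrom: dict[str, list[SnpRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s)
        self._pos: dict[str, np.ndarray] = {}
        self._recs: dict[str, list[SnpRecord]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda s: s.pos)
            self._recs[chrom] = recs
            self._pos[chrom] = np.array([s.pos for s in recs], dtype=np.int64)

    def overlapping(self, chrom: str, start: int, end: int) -> list[SnpRecord]:
        """SNPs with start <= pos <= end on ``chrom``."""
        pos = self._pos.get(chrom)
        if pos is None:
            return []
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return self._recs[chrom][lo:hi]


def mismatches_at_placement(read: ReadPlacement, genome: HaplotypeGenome) -> int:
    """Hamming distance between the read and the genome at its placement."""
    ref = genome.fetch(read.chrom, read.start, read.end)
    seq = read.forward_sequence
    return sum(a != b for a, b in zip(seq, ref))


def dedup(placements: Iterable[ReadPlacement]) -> list[ReadPlacement]:
    """Keep one representative per (chrom, start, strand), in stable order."""
    seen: set[tuple[str, int, str]] = set()
    out: list[ReadPlacement] = []
    for p in placements:
        key = (p.chrom, p.start, p.strand)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def exclude_indel_overlap(
    placements: Iterable[ReadPlacement],
    indel_intervals: Sequence[GenomicInterval],
) -> list[ReadPlacement]:
    """Drop reads whose footprint intersects any indel interval (closed coords)."""
    trees: dict[str, IntervalTree] = {}
    for iv in indel_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1)
    out = []
    for p in placements:
        tree = trees.get(p.chrom)
        if tree is None or not tree.overlap(p.start, p.end + 1):
            out.append(p)
    return out


def assign_allele(
    read: ReadPlacement,
    b6: HaplotypeGenome,
    jf1: HaplotypeGenome,
    snp_index: SnpIndex,
    mode: Mode,
) -> AlleleAssignment:
    """Assign a read to a haplotype by SNP-base vote plus mismatch bound.

    A read overlapping no SNP is non-informative. Otherwise the sequenced base
    at every overlapped SNP votes: all-B6 bases nominate B6, all-JF1 nominate
    JF1, anything mixed is ambiguous. The nominee is confirmed only when the
    total mismatch count against that haplotype is within the mode's bound.
    """
    if mode not in MISMATCH_BOUND:
        raise ValueError(f"unknown mode {mode!r}")
    bound = MISMATCH_BOUND[mode]
    mm_b6 = mismatches_at_placement(read, b6)
    mm_jf1 = mismatches_at_placement(read, jf1)
    snps = snp_index.overlapping(read.chrom, read.start, read.end)
    if not snps:
        return AlleleAssignment(read.read_id, mm_b6, mm_jf1, 0, "non_informative", mode)
    fwd = read.forward_sequence
    bases = [fwd[s.pos - read.start] for s in snps]
    if all(b == s.allele_b6 for b, s in zip(bases, snps)):
        candidate, mm = "B6", mm_b6
    elif all(b == s.allele_jf1 for b, s in zip(bases, snps)):
        candidate, mm = "JF1", mm_jf1
    else:
        return AlleleAssignment(read.read_id, mm_b6, mm_jf1, len(snps), "ambiguous", mode)
    call = candidate if mm <= bound else "ambiguous"
    return AlleleAssignment(read.read_id, mm_b6, mm_jf1, len(snps), call, mode)


def tally_peaks(
    peaks: Sequence[GenomicInterval],
    placements: Sequence[ReadPlacement],
    b6: HaplotypeGenome,
    jf1: HaplotypeGenome,
    snp_index: SnpIndex,
    control_semantics: Literal["alignment", "vote"] = "alignment",
) -> pd.DataFrame:
    """Per-peak informative/allele-specific counts in both modes.

    A read contributes to a peak when its footprint intersects the peak by at
    least one base. Stringent counts come from the 0-mismatch vote contract
    (ambiguous and non-informative reads are excluded from IR as well as ASR,
    so IR = ASR_B6 + ASR_JF1 by construction). Control counts follow
    ``control_semantics``:

    * ``"alignment"`` (default): an informative read is counted for every
      haplotype it matches within 3 mismatches — possibly both;
    * ``"vote"``: single call per read, as in stringent mode but with bound 3.

    Returns one row per peak with columns ir, asr_b6, asr_jf1, ir_c, asr_c_b6,
    asr_c_jf1.
    """
    bound_c = MISMATCH_BOUND["control"]
    rows = []
    # Pre-assign each read once; peak attribution afterwards.
    assignments = []
    for p in placements:
        a_str = assign_allele(p, b6, jf1, snp_index, "stringent")
        if control_semantics == "vote":
            a_ctl = assign_allele(p, b6, jf1, snp_index, "control")
            ctl_b6 = a_ctl.call == "B6"
            ctl_jf1 = a_ctl.call == "JF1"
        else:
            informative = a_str.n_snps_overlapped > 0
            ctl_b6 = informative and a_str.mm_b6 <= bound_c
            ctl_jf1 = informative and a_str.mm_jf1 <= bound_c
        assignments.append((p, a_str, ctl_b6, ctl_jf1))

    for peak in peaks:
        asr_b6 = asr_jf1 = asr_c_b6 = asr_c_jf1 = 0
        for p, a_str, ctl_b6, ctl_jf1 in assignments:
            if p.chrom != peak.chrom or p.end < peak.start or p.start > peak.end:
                continue
            if a_str.call == "B6":
                asr_b6 += 1
            elif a_str.call == "JF1":
                asr_jf1 += 1
            asr_c_b6 += ctl_b6
            asr_c_jf1 += ctl_jf1
        rows.append(
            {
                "peak_id": peak.name,
                "chrom": peak.chrom,
                "ir": asr_b6 + asr_jf1,
                "asr_b6": asr_b6,
                "asr_jf1": asr_jf1,
                "ir_c": asr_c_b6 + asr_c_jf1,
                "asr_c_b6": asr_c_b6,
                "asr_c_jf1": asr_c_jf1,
            }
        )
    return pd.DataFrame(rows)


# --- I/O ------------------------------------------------------------------


def write_sam(
    placements: Iterable[ReadPlacement],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write placements as an unmapped-free plain-text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {c: i for i, c in enumerate(contig_lengths)}
        for p in placements:
            a = pysam.AlignedSegment()
            a.query_name = p.read_id
            a.reference_id = tid[p.chrom]
            a.reference_start = p.start - 1
            a.flag = 16 if p.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = f"{len(p.sequence)}M"
            # SAM stores the forward-strand projection
            a.query_sequence = p.forward_sequence
            out.write(a)


def read_sam(path: str | Path) -> list[ReadPlacement]:
    """Read placements from SAM; only full-length matches are modeled."""
    out: list[ReadPlacement] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence
            if strand == "-":
                seq = reverse_complement(seq)
            out.append(
                ReadPlacement(
                    read_id=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start + 1,
                    strand=strand,
                    sequence=seq,
                )
            )
    return out


def write_placements_tsv(placements: Iterable[ReadPlacement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": p.read_id,
                "chrom": p.chrom,
                "start": p.start,
                "strand": p.strand,
                "sequence": p.sequence,
            }
            for p in placements
        ]
    ).to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> list[ReadPlacement]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ReadPlacement(r.read_id, r.chrom, int(r.start), r.strand, r.sequence)
        for r in df.itertuples()
    ]
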