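"""Strand-aware ZFP57 motif scanning, disruption calling and cluster analysis.

ZFP57 binds the methylated hexamer TGCCGC and the single-base variant GGCCGC.
This module scans sequences for these motifs on both strands (a minus-strand
hit means the forward sequence contains the motif's reverse complement),
detects SNPs that destroy a motif on one haplotype (allele-string comparison
over +/-5 bp windows), measures pair spacing/orientation, chains hits into
clusters of motifs less than a gap threshold (38 bp) apart, and quantifies how
much denser such clusters are inside peak regions than genome-wide.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .pseudogenome import HaplotypeGenome, SnpRecord, reverse_complement

logger = logging.getLogger(__name__)

CANONICAL_MOTIF = "TGCCGC"
VARIANT_MOTIF = "GGCCGC"
CLUSTER_GAP_BP = 38


@dataclass(frozen=True)
class MotifDefinition:
    """A hexamer binding motif; ``cpg_offset`` is the 1-based position of the
    CpG cytosine within the motif (4 for both canonical variants)."""

    motif_id: str
    sequence: str
    cpg_offset: int = 4

    def __post_init__(self) -> None:
        if len(self.sequence) != 6:
            raise ValueError(f"motif {self.motif_id} must be a hexamer")
        if "CG" not in self.sequence:
            raise ValueError(f"motif {self.motif_id} lacks a CpG dinucleotide")


DEFAULT_MOTIF_SET = (
    MotifDefinition("TGCCGC", CANONICAL_MOTIF),
    MotifDefinition("GGCCGC", VARIANT_MOTIF),
)


def motif_set_from_strings(motifs: Iterable[str]) -> tuple[MotifDefinition, ...]:
    return tuple(MotifDefinition(m, m) for m in motifs)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence; ``start`` is 1-based on the forward strand."""

    seq_id: str
    start: int
    strand: str
    motif_id: str = field(compare=False)

    @property
    def end(self) -> int:
        return self.start + 5


@dataclass(frozen=True)
class MotifCluster:
    """Maximal chain of >=2 hits with consecutive gaps below the threshold."""

    hits: tuple[MotifHit, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.hits[0].start, max(h.end for h in self.hits))

    @property
    def size(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class DisruptionCall:
    """A SNP that destroys a motif occurrence on one haplotype."""

    snp: SnpRecord
    lost_in: str  # haplotype label lacking the motif
    motif_id: str
    motif_position_affected: int  # 1..6 within the motif
    permissive_allele_hits: tuple[MotifHit, ...]
    nonpermissive_allele_hits: tuple[MotifHit, ...]


def scan_motifs(
    sequence: str,
    motif_set: Sequence[MotifDefinition] = DEFAULT_MOTIF_SET,
    seq_id: str = "",
) -> list[MotifHit]:
    """All motif occurrences on both strands, sorted by start then strand.

    Overlapping hits are all reported; N never matches. A forward-strand
    substring equal to a motif's reverse complement is a minus-strand hit.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for m in motif_set:
        # a palindromic motif legitimately yields a +/- hit pair per position
        targets = [(m.sequence, "+"), (reverse_complement(m.sequence), "-")]
        for pattern, strand in targets:
            for match in re.finditer(f"(?={re.escape(pattern)})", seq):
                hits.append(MotifHit(seq_id, match.start() + 1, strand, m.motif_id))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return hits


def pair_gap(hit1: MotifHit, hit2: MotifHit) -> int:
    """Intervening bases between two hits; negative when they overlap."""
    if hit1.seq_id != hit2.seq_id:
        raise ValueError("hits lie on different sequences")
    if hit1.start > hit2.start:
        hit1, hit2 = hit2, hit1
    return hit2.start - hit1.end - 1


def pair_orientation(hit1: MotifHit, hit2: MotifHit) -> str:
    """'direct' for same-strand pairs, 'inverted' otherwise."""
    if hit1.seq_id != hit2.seq_id:
        raise ValueError("hits lie on different sequences")
    return "direct" if hit1.strand == hit2.strand else "inverted"


def find_clusters(
    hits: Sequence[MotifHit],
    gap_threshold: int = CLUSTER_GAP_BP,
    convention: str = "gap",
) -> list[MotifCluster]:
    """Single-linkage chaining of hits into clusters of size >= 2.

    Consecutive hits join one cluster when their separation is strictly below
    ``gap_threshold``. The default ``convention="gap"`` measures intervening
    bases (hit2.start - hit1.end - 1); ``"start"`` measures start-to-start.
    """
    if convention not in ("gap", "start"):
        raise ValueError(f"unknown distance convention {convention!r}")
    clusters: list[MotifCluster] = []
    current: list[MotifHit] = []
    max_end = -1
    prev_start = -1
    for h in sorted(hits, key=lambda h: (h.seq_id, h.start, h.strand)):
        if current and h.seq_id == current[-1].seq_id:
            sep = (h.start - max_end - 1) if convention == "gap" else (h.start - prev_start)
            linked = sep < gap_threshold
        else:
            linked = False
        if linked:
            current.append(h)
        else:
            if len(current) >= 2:
                clusters.append(MotifCluster(tuple(current)))
            current = [h]
        max_end = h.end if not linked else max(max_end, h.end)
        prev_start = h.start
    if len(current) >= 2:
        clusters.append(MotifCluster(tuple(current)))
    return clusters


def peak_motif_summary(
    peaks: Sequence[GenomicInterval],
    genome: HaplotypeGenome,
    motif_set: Sequence[MotifDefinition] = DEFAULT_MOTIF_SET,
    gap_threshold: int = CLUSTER_GAP_BP,
) -> dict:
    """Cohort summary of motif content across peaks.

    Returns per-peak hit counts, the mean +/- sample SD of motifs/peak, the
    fraction of peaks with >= 2 motifs containing at least one pair closer
    than the gap threshold, and peak counts bucketed by which motif variants
    they contain.
    """
    per_peak = []
    motif_ids = [m.motif_id for m in motif_set]
    content_counts: dict[str, int] = {}
    if len(motif_ids) == 2:
        buckets = [f"{motif_ids[0]}_only", f"{motif_ids[1]}_only", "both", "neither"]
        content_counts = {b: 0 for b in buckets}
    for peak in peaks:
        seq = genome.fetch(peak.chrom, peak.start, peak.end)
        hits = scan_motifs(seq, motif_set, seq_id=peak.name or peak.chrom)
        gaps = [pair_gap(a, b) for a, b in zip(hits, hits[1:])]
        has_close_pair = any(g < gap_threshold for g in gaps)
        ids_present = {h.motif_id for h in hits}
        if len(motif_ids) == 2:
            if ids_present == {motif_ids[0]}:
                content_counts[f"{motif_ids[0]}_only"] += 1
            elif ids_present == {motif_ids[1]}:
                content_counts[f"{motif_ids[1]}_only"] += 1
            elif not ids_present:
                content_counts["neither"] += 1
            else:
                content_counts["both"] += 1
        per_peak.append(
            {
                "peak_id": peak.name,
                "n_hits": len(hits),
                "has_close_pair": has_close_pair,
            }
        )
    df = pd.DataFrame(per_peak)
    n_hits = df["n_hits"].to_numpy(dtype=float) if len(df) else np.array([])
    multi = df[df["n_hits"] >= 2] if len(df) else df
    return {
        "per_peak": df,
        "mean_motifs_per_peak": float(np.mean(n_hits)) if len(n_hits) else math.nan,
        "sd_motifs_per_peak": (
            float(np.std(n_hits, ddof=1)) if len(n_hits) > 1 else math.nan
        ),
        "frac_close_pair_of_multi": (
            float(multi["has_close_pair"].mean()) if len(multi) else math.nan
        ),
        "content_counts": content_counts,
    }


def cluster_enrichment(
    bp_per_cluster_regions: float, bp_per_cluster_genome: float
) -> tuple[float, int]:
    """Fold enrichment of cluster density in regions over the genome.

    Densities are expressed as bases of sequence per cluster (smaller means
    denser). Returns the raw fold and its half-up-rounded report value.
    """
    if bp_per_cluster_regions <= 0 or bp_per_cluster_genome <= 0:
        raise ValueError("densities must be positive")
    fold = bp_per_cluster_genome / bp_per_cluster_regions
    return fold, int(math.floor(fold + 0.5))


def cluster_density(
    sequences: Iterable[tuple[str, str]],
    motif_set: Sequence[MotifDefinition] = DEFAULT_MOTIF_SET,
    gap_threshold: int = CLUSTER_GAP_BP,
) -> tuple[int, int, float]:
    """Clusters and bp-per-cluster over (seq_id, sequence) pairs.

    The denominator is the total non-N scanned length. Returns
    (n_clusters, total_bp, bp_per_cluster); bp_per_cluster is inf when no
    cluster is found.
    """
    n_clusters = 0
    total_bp = 0
    for seq_id, seq in sequences:
        total_bp += len(seq) - seq.upper().count("N")
        hits = scan_motifs(seq, motif_set, seq_id=seq_id)
        n_clusters += len(find_clusters(hits, gap_threshold))
    bp_per = total_bp / n_clusters if n_clusters else math.inf
    return n_clusters, total_bp, bp_per


def snp_disruption(
    snp: SnpRecord,
    b6: HaplotypeGenome,
    jf1: HaplotypeGenome,
    motif_set: Sequence[MotifDefinition] = DEFAULT_MOTIF_SET,
    flank: int = 5,
) -> DisruptionCall | None:
    """Call a motif-disrupting SNP from the +/-flank allele strings.

    The window around the SNP is extracted from each haplotype and scanned;
    only hits covering the SNP position count. When exactly one allele carries
    a covering occurrence the SNP disrupts the motif on the other allele.
    """
    if flank < 5:
        raise ValueError("flank must be >= 5 so any covering hexamer fits")
    chrom_len = len(b6.sequences[snp.chrom])
    wstart = snp.pos - flank
    wend = snp.pos + flank
    if wstart < 1 or wend > chrom_len:
        logger.warning(
            "snp_disruption: window for %s:%d truncated by contig edge",
            snp.chrom,
            snp.pos,
        )
        wstart = max(1, wstart)
        wend = min(chrom_len, wend)
    center = snp.pos - wstart + 1  # 1-based within the window

    def covering_hits(genome: HaplotypeGenome) -> tuple[MotifHit, ...]:
        window = genome.fetch(snp.chrom, wstart, wend)
        hits = scan_motifs(window, motif_set, seq_id=f"{snp.chrom}:{snp.pos}")
        return tuple(h for h in hits if h.start <= center <= h.end)

    hits_b6 = covering_hits(b6)
    hits_jf1 = covering_hits(jf1)
    if bool(hits_b6) == bool(hits_jf1):
        return None
    if hits_b6:
        permissive, lost_in, perm_hits, nonperm_hits = "B6", "JF1", hits_b6, hits_jf1
    else:
        permissive, lost_in, perm_hits, nonperm_hits = "JF1", "B6", hits_jf1, hits_b6
    hit = perm_hits[0]
    if hit.strand == "+":
        position = center - hit.start + 1
    else:
        position = hit.end - center + 1
    return DisruptionCall(
        snp=snp,
        lost_in=lost_in,
        motif_id=hit.motif_id,
        motif_position_affected=position,
        permissive_allele_hits=perm_hits,
        nonpermissive_allele_hits=nonperm_hits,
    )
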