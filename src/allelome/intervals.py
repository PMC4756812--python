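"""Genomic intervals with explicit coordinate conventions.

Internally every interval is 1-based and inclusive on both ends (the VCF/FASTA
convention). BED files are 0-based half-open; the conversion happens only here,
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval ``[start, end]``, 1-based."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        """Number of bases covered, inclusive of both ends."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the closed intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into 1-based closed intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
        na_filter=False,
        engine="python",
        on_bad_lines="error",
    )
    return [
        GenomicInterval(r.chrom, int(r.start) + 1, int(r.end), str(r.name))
        for r in df.itertuples()
    ]


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")


def merge_overlap_filter(
    primary: Sequence[GenomicInterval],
    others: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Keep intervals of ``primary`` that hit >=1 interval in every other set."""
    kept = []
    for iv in primary:
        if all(any(iv.overlaps(o) for o in oset) for oset in others):
            kept.append(iv)
    return kept
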