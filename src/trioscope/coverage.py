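"""Per-region depth profiles and coverage summaries over alignments.

Depth counts reference-aligned bases: reads spanning a deletion still
cover the deleted positions, soft-clipped bases do not count. Summaries
report min, max, median (average-of-middle-two for even lengths) and mean.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .model import CoverageSummary, GenomicRegion
from .region_io import ContigNotFoundError, PathLike

__all__ = [
    "depth_profile",
    "summarize",
    "flag_low_coverage",
    "write_summary_csv",
    "write_summary_bed",
]


def depth_profile(
    alignments: PathLike, region: GenomicRegion, min_mapq: int = 0
) -> np.ndarray:
    """Integer read depth at every position of ``region`` (length equals
    the region length)."""
    profile = np.zeros(len(region), dtype=np.int64)
    with pysam.AlignmentFile(str(alignments)) as bam:
        if region.contig not in bam.references:
            raise ContigNotFoundError(
                f"contig {region.contig!r} absent from {alignments}"
            )
        for read in bam.fetch(region.contig, region.start, region.end):
            if read.is_unmapped or read.is_secondary or read.mapping_quality < min_mapq:
                continue
            # reference-aligned blocks: M/=/X and D advance, S/I do not cover
            for block_start, block_end in read.get_blocks():
                s = max(block_start, region.start)
                e = min(block_end, region.end)
                if s < e:
                    profile[s - region.start : e - region.start] += 1
            if read.cigartuples:
                # get_blocks omits deletions; add D-spanned positions back
                ref_pos = read.reference_start
                for op, length in read.cigartuples:
                    if op in (0, 7, 8):  # M, =, X
                        ref_pos += length
                    elif op == 3:  # N
                        ref_pos += length
                    elif op == 2:  # D: read still covers these positions
                        s = max(ref_pos, region.start)
                        e = min(ref_pos + length, region.end)
                        if s < e:
                            profile[s - region.start : e - region.start] += 1
                        ref_pos += length
    return profile


def summarize(profile: np.ndarray, region: GenomicRegion) -> CoverageSummary:
    """Min/max/median/mean of a depth profile."""
    if len(profile) == 0:
        raise ValueError(f"empty depth profile for {region}")
    return CoverageSummary(
        region=region,
        min=int(profile.min()),
        max=int(profile.max()),
        median=float(np.median(profile)),
        mean=float(profile.mean()),
    )


def flag_low_coverage(
    exons: Sequence[GenomicRegion],
    profiles: Sequence[np.ndarray],
    threshold: int = 10,
) -> list[tuple[GenomicRegion, float]]:
    """Exons containing any base below ``threshold``, with the affected
    fraction of the exon."""
    out = []
    for exon, profile in zip(exons, profiles):
        below = int((profile < threshold).sum())
        if below:
            out.append((exon, below / len(profile)))
    return out


def write_summary_csv(summaries: Sequence[CoverageSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["contig", "start", "end", "min", "max", "median", "mean"])
        for s in summaries:
            writer.writerow(
                [s.region.contig, s.region.start, s.region.end,
                 s.min, s.max, s.median, f"{s.mean:.4f}"]
            )


def write_summary_bed(summaries: Sequence[CoverageSummary], path: str | Path) -> None:
    """BED with score = mean depth."""
    with open(path, "w") as fh:
        for s in summaries:
            fh.write(
                f"{s.region.contig}\t{s.region.start}\t{s.region.end}"
                f"\tcoverage\t{s.mean:.2f}\n"
            )
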