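"""ROH islands: top-percentile loci of cross-individual ROH overlap.

The overlap track counts *individuals* (not segments) covering each analysed
site; the island threshold is the nearest-rank percentile of the per-site
count distribution, with ties at the threshold included.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import Intervals
from .segments import ROHCallSet, merged_intervals


@dataclass(frozen=True)
class Island:
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_count: float
    max_count: int


@dataclass
class IslandTrack:
    chrom: np.ndarray
    pos: np.ndarray
    count: np.ndarray
    percentile: float | None = None
    threshold: int | None = None
    islands: list[Island] = field(default_factory=list)

    def write_bedgraph(self, path) -> None:
        pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "start": self.pos - 1,
                "end": self.pos,
                "count": self.count,
            }
        ).to_csv(path, sep="\t", header=False, index=False)


def overlap_track(calls: ROHCallSet, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Number of individuals with >=1 segment covering each analysed site.

    Segments of one individual are unioned first so an individual never
    contributes more than 1 at any site. Implemented as an endpoint sweep
    (searchsorted difference array), O((n_seg + n_site) log n_site).
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    if n == 0:
        return counts
    # per-chromosome contiguous index ranges
    chrom_str = chrom.astype(str)
    blocks: dict[str, tuple[int, int]] = {}
    i = 0
    while i < n:
        j = i
        while j < n and chrom_str[j] == chrom_str[i]:
            j += 1
        blocks[chrom_str[i]] = (i, j)
        i = j
    diff = np.zeros(n + 1, dtype=np.int64)
    for sample in calls.samples:
        for c, s, e in merged_intervals(calls.for_sample(sample)):
            if c not in blocks:
                continue
            lo, hi = blocks[c]
            p = pos[lo:hi]
            a = lo + np.searchsorted(p, s, side="left")
            b = lo + np.searchsorted(p, e, side="right")
            diff[a] += 1
            diff[b] -= 1
    return np.cumsum(diff[:-1])


def nearest_rank_threshold(counts: np.ndarray, percentile: float) -> int:
    """Smallest value with at least ``percentile`` % of observations <= it."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    srt = np.sort(np.asarray(counts))
    n = srt.shape[0]
    if n == 0:
        raise ValueError("empty track")
    k = int(np.ceil(percentile / 100.0 * n))
    return int(srt[max(k, 1) - 1])


def call_islands(
    track: IslandTrack,
    percentile: float,
    max_merge_gap_bp: int = 0,
    include_zero_sites: bool = True,
) -> IslandTrack:
    """Threshold the track at the nearest-rank percentile and merge islands.

    Sites with zero overlap are part of the percentile distribution by
    default (``include_zero_sites``); a threshold of 0 never qualifies a
    site, so an all-zero track yields no islands. Qualifying sites merge
    when adjacent in the analysed site list, or across non-qualifying sites
    when the bp gap is <= ``max_merge_gap_bp``.
    """
    counts = track.count
    dist = counts if include_zero_sites else counts[counts > 0]
    if dist.size == 0:
        return IslandTrack(track.chrom, track.pos, counts, percentile, 0, [])
    thr = nearest_rank_threshold(dist, percentile)
    qualify = (counts >= max(thr, 1)) & (counts > 0)
    islands: list[Island] = []
    chrom_str = track.chrom.astype(str)
    idx = np.flatnonzero(qualify)
    if idx.size:
        group_start = idx[0]
        prev = idx[0]
        for i in idx[1:].tolist() + [-1]:
            contiguous = (
                i != -1
                and chrom_str[i] == chrom_str[prev]
                and (
                    i == prev + 1
                    or (track.pos[i] - track.pos[prev]) <= max_merge_gap_bp
                )
            )
            if not contiguous:
                block = np.arange(group_start, prev + 1)
                block = block[qualify[block]]
                islands.append(
                    Island(
                        chrom=str(chrom_str[group_start]),
                        start=int(track.pos[group_start]),
                        end=int(track.pos[prev]),
                        n_sites=int(block.size),
                        mean_count=float(counts[block].mean()),
                        max_count=int(counts[block].max()),
                    )
                )
                group_start = i
            prev = i
    return IslandTrack(track.chrom, track.pos, counts, percentile, thr, islands)


def build_track(calls: ROHCallSet, chrom: np.ndarray, pos: np.ndarray) -> IslandTrack:
    return IslandTrack(
        np.asarray(chrom, dtype=object),
        np.asarray(pos, dtype=np.int64),
        overlap_track(calls, chrom, pos),
    )


def annotate_genes(islands: Sequence[Island], gene_intervals: Intervals) -> pd.DataFrame:
    """Genes overlapping each island by >=1 bp, deduplicated, island order kept."""
    rows = []
    names = (
        gene_intervals.name
        if gene_intervals.name is not None
        else np.array([""] * len(gene_intervals), dtype=object)
    )
    gchrom = gene_intervals.chrom.astype(str)
    for k, isl in enumerate(islands):
        seen: set[str] = set()
        for g in range(len(gene_intervals)):
            if gchrom[g] != isl.chrom:
                continue
            g_start, g_end = int(gene_intervals.start[g]), int(gene_intervals.end[g])
            if g_start <= isl.end and isl.start <= g_end:
                name = str(names[g]) or f"{gchrom[g]}:{g_start}-{g_end}"
                if name in seen:
                    continue
                seen.add(name)
                overlap = min(isl.end, g_end) - max(isl.start, g_start) + 1
                rows.append(
                    {
                        "island": f"{isl.chrom}:{isl.start}-{isl.end}",
                        "island_index": k,
                        "gene": name,
                        "overlap_bp": overlap,
                    }
                )
    return pd.DataFrame(rows, columns=["island", "island_index", "gene", "overlap_bp"])


def islands_to_intervals(islands: Sequence[Island]) -> Intervals:
    if not islands:
        return Intervals.empty()
    return Intervals(
        chrom=np.array([i.chrom for i in islands], dtype=object),
        start=np.array([i.start for i in islands], dtype=np.int64),
        end=np.array([i.end for i in islands], dtype=np.int64),
        name=np.array(
            [f"island_{k}|max={i.max_count}" for k, i in enumerate(islands)], dtype=object
        ),
    )
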