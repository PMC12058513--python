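"""ROH segment containers shared by both callers."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ROHSegment:
    """One called homozygous run (1-based inclusive coordinates)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_sites: int
    caller: str
    score: float | None = None
    n_het: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")
        if self.n_sites < 1:
            raise ValueError("segment with no sites")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ROHSegment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


class ROHCallSet:
    """Segments from one caller run plus the sample universe.

    The sample universe matters for cohort means: individuals with zero
    qualifying segments still contribute (0, 0).
    """

    def __init__(
        self,
        segments: Iterable[ROHSegment] = (),
        samples: Sequence[str] | None = None,
        validate: bool = True,
    ):
        self.segments: list[ROHSegment] = sorted(
            segments, key=lambda s: (s.sample, str(s.chrom), s.start)
        )
        if samples is None:
            samples = sorted({s.sample for s in self.segments})
        self.samples = list(samples)
        if validate:
            self._validate()

    def _validate(self) -> None:
        prev: ROHSegment | None = None
        for seg in self.segments:
            if prev is not None and prev.sample == seg.sample and prev.chrom == seg.chrom:
                if seg.start <= prev.end:
                    raise ValueError(
                        f"overlapping segments for {seg.sample} on {seg.chrom}: "
                        f"{prev.start}-{prev.end} vs {seg.start}-{seg.end}"
                    )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[ROHSegment]:
        return iter(self.segments)

    def for_sample(self, sample: str, min_length_bp: int = 0) -> list[ROHSegment]:
        return [
            s for s in self.segments if s.sample == sample and s.length >= min_length_bp
        ]

    def total_bp(self, sample: str, min_length_bp: int = 0) -> int:
        return sum(s.length for s in self.for_sample(sample, min_length_bp))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [s.sample for s in self.segments],
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "length_bp": [s.length for s in self.segments],
                "n_sites": [s.n_sites for s in self.segments],
                "n_het": [s.n_het for s in self.segments],
                "caller": [s.caller for s in self.segments],
                "score": [s.score for s in self.segments],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, samples: Sequence[str] | None = None) -> "ROHCallSet":
        df = pd.read_csv(path, sep="\t")
        segs = [
            ROHSegment(
                sample=str(r["sample"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                n_sites=int(r["n_sites"]),
                caller=str(r.get("caller", "unknown")),
                score=None if pd.isna(r.get("score")) else float(r["score"]),
                n_het=int(r.get("n_het", 0) if not pd.isna(r.get("n_het", 0)) else 0),
            )
            for _, r in df.iterrows()
        ]
        return cls(segs, samples=samples)

    def write_bed(self, path) -> None:
        """0-based half-open BED with sample in the name column."""
        df = self.to_dataframe()
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"] - 1,
                "end": df["end"],
                "name": df["sample"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


def merged_intervals(segments: Sequence[ROHSegment]) -> list[tuple[str, int, int]]:
    """Union of segment intervals (per chromosome), 1-based inclusive."""
    out: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by_chrom.setdefault(str(s.chrom), []).append((s.start, s.end))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out
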