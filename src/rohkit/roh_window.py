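"""Sliding-window homozygosity scanner with a per-window heterozygote allowance.

A window of ``window_snp`` consecutive SNPs counts as homozygous when it
contains at most ``window_het`` heterozygous and ``window_missing`` missing
calls. Each SNP's hit proportion is the fraction of windows containing it
that are homozygous; SNPs at or above ``hit_threshold`` are ROH-eligible and
maximal eligible runs become segments after gap/length/count/density checks.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenotypeMatrix
from .segments import ROHCallSet, ROHSegment


@dataclass
class WindowParams:
    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 100
    min_length_kb: float = 100.0
    max_gap_kb: float = 1000.0
    density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snp < 1:
            raise ValueError("window_snp must be >= 1")
        if self.window_het < 0:
            raise ValueError("window_het must be >= 0")
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit_threshold must be in (0, 1]")
        if self.min_snp < 1:
            raise ValueError("min_snp must be >= 1")

    @classmethod
    def for_length_class(cls, min_length_kb: float, **kwargs) -> "WindowParams":
        """Parameters for a minimal-length class.

        The 100 Kb class scales min_snp down to 25 so the default 100-SNP
        floor does not suppress short calls at array-like density.
        """
        min_snp = kwargs.pop("min_snp", 25 if min_length_kb <= 100 else 100)
        return cls(min_length_kb=min_length_kb, min_snp=min_snp, **kwargs)


def window_scan(codes: np.ndarray, params: WindowParams) -> np.ndarray:
    """Per-SNP hit proportion for one sample's arm unit (O(n) rolling count).

    Arms with fewer SNPs than window_snp are scored over the single available
    window spanning the whole arm.
    """
    codes = np.asarray(codes)
    n = codes.shape[0]
    het = (codes == 1).astype(np.int64)
    mis = (codes == -1).astype(np.int64)
    w = min(params.window_snp, n)
    n_windows = n - w + 1
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    win_het = chet[w:] - chet[:-w]
    win_mis = cmis[w:] - cmis[:-w]
    ok = ((win_het <= params.window_het) & (win_mis <= params.window_missing)).astype(np.int64)
    cok = np.concatenate([[0], np.cumsum(ok)])
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n_windows - 1)
    hits = cok[hi + 1] - cok[lo]
    total = hi - lo + 1
    return hits / total


def call_segments(
    hit_proportions: np.ndarray,
    codes: np.ndarray,
    pos: np.ndarray,
    params: WindowParams,
    sample: str,
    chrom: str,
) -> list[ROHSegment]:
    """Segments from eligible-SNP runs.

    Runs split at inter-SNP gaps > max_gap_kb and are kept iff they satisfy
    min_snp, min_length_kb, and the kb-per-SNP density cap. Note the density
    cap is the one non-monotone rule: merging runs under a larger het
    allowance can raise mean spacing past it.
    """
    eligible = np.asarray(hit_proportions) >= params.hit_threshold
    pos = np.asarray(pos)
    codes = np.asarray(codes)
    max_gap_bp = params.max_gap_kb * 1000.0
    out: list[ROHSegment] = []
    n = eligible.shape[0]
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and eligible[j + 1]
            and (pos[j + 1] - pos[j]) <= max_gap_bp
        ):
            j += 1
        n_sites = j - i + 1
        length = int(pos[j] - pos[i] + 1)
        if (
            n_sites >= params.min_snp
            and length >= params.min_length_kb * 1000.0
            and (length / 1000.0) / n_sites <= params.density_kb_per_snp
        ):
            out.append(
                ROHSegment(
                    sample=sample,
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_sites=n_sites,
                    caller="window",
                    n_het=int((codes[i : j + 1] == 1).sum()),
                )
            )
        i = j + 1
    return out


def call_roh_window(gm: GenotypeMatrix, params: WindowParams | None = None) -> ROHCallSet:
    """Run the window scanner over every sample and arm unit."""
    params = params or WindowParams()
    segments: list[ROHSegment] = []
    for label, idx in gm.units():
        chrom = str(gm.chrom[idx[0]])
        pos = gm.pos[idx]
        for s, sample in enumerate(gm.samples):
            codes = gm.calls[idx, s]
            props = window_scan(codes, params)
            segments.extend(call_segments(props, codes, pos, params, sample, chrom))
    return ROHCallSet(segments, samples=list(gm.samples))


def het_sweep(
    gm: GenotypeMatrix,
    params: WindowParams | None = None,
    H_values: Sequence[int] = (1, 2, 3, 4),
    length_classes_kb: Sequence[float] = (100.0, 1500.0),
) -> pd.DataFrame:
    """Vary only the heterozygote allowance; report per-class cohort means.

    Returns one row per (window_het, class) with the across-individual mean
    NROH and SROH (bp).
    """
    from .roh_profile import nroh_sroh

    base = params or WindowParams()
    rows = []
    for H in H_values:
        for kb in length_classes_kb:
            p = WindowParams.for_length_class(
                kb,
                window_snp=base.window_snp,
                window_het=int(H),
                window_missing=base.window_missing,
                hit_threshold=base.hit_threshold,
                max_gap_kb=base.max_gap_kb,
                density_kb_per_snp=base.density_kb_per_snp,
            )
            calls = call_roh_window(gm, p)
            stats = nroh_sroh(calls, int(kb * 1000))
            rows.append(
                {
                    "window_het": int(H),
                    "min_length_kb": kb,
                    "mean_nroh": float(stats["nroh"].mean()),
                    "mean_sroh": float(stats["sroh"].mean()),
                }
            )
    return pd.DataFrame(rows)
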