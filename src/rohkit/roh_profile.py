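"""Per-individual and cohort ROH summary statistics (NROH, SROH, F_ROH, bins)."""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segments import ROHCallSet

LENGTH_CLASSES_BP = (100_000, 300_000, 1_500_000)

#: GRCh37 autosomal genome length, for comparability with published F_ROH.
GRCH37_AUTOSOME_BP = 2_881_033_286


def nroh_sroh(calls: ROHCallSet, min_length_bp: int) -> pd.DataFrame:
    """Per-individual segment count and summed length above a threshold.

    Individuals in the call set's sample universe with no qualifying segment
    report (0, 0).
    """
    nroh = {s: 0 for s in calls.samples}
    sroh = {s: 0 for s in calls.samples}
    for seg in calls:
        if seg.length >= min_length_bp:
            nroh[seg.sample] += 1
            sroh[seg.sample] += seg.length
    return pd.DataFrame(
        {
            "sample": list(calls.samples),
            "nroh": [nroh[s] for s in calls.samples],
            "sroh": [sroh[s] for s in calls.samples],
        }
    )


def f_roh(
    calls: ROHCallSet, min_length_bp: int, autosome_length_bp: int
) -> pd.DataFrame:
    """Genomic inbreeding coefficient: SROH / total autosomal length."""
    if autosome_length_bp <= 0:
        raise ValueError("autosome_length_bp must be > 0")
    df = nroh_sroh(calls, min_length_bp)
    df["f_roh"] = df["sroh"] / float(autosome_length_bp)
    return df[["sample", "f_roh"]]


def analyzed_autosome_length(gm) -> int:
    """Summed span of the analysed arm units (first to last site, inclusive).

    Default denominator for F_ROH on synthetic genomes; pass
    :data:`GRCH37_AUTOSOME_BP` instead for comparability with published
    values computed against the full autosomal genome.
    """
    total = 0
    for _label, idx in gm.units():
        total += int(gm.pos[idx[-1]] - gm.pos[idx[0]] + 1)
    return total


def length_bins(calls: ROHCallSet, bin_edges: Sequence[int]) -> pd.DataFrame:
    """Segment counts per length bin.

    Bins are half-open [lo, hi) with the last edge opening an unbounded top
    bin; segments shorter than the first edge land in an explicit underflow
    bucket. Total count is conserved.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if edges.ndim != 1 or edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing and nonempty")
    labels = ["underflow"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo},{hi})")
    labels.append(f">={edges[-1]}")
    counts = {lab: 0 for lab in labels}
    for seg in calls:
        k = int(np.searchsorted(edges, seg.length, side="right"))
        counts[labels[k]] += 1
    return pd.DataFrame({"bin": labels, "count": [counts[lab] for lab in labels]})


def profile(
    calls: ROHCallSet,
    autosome_length_bp: int,
    length_classes_bp: Sequence[int] = LENGTH_CLASSES_BP,
    froh_min_length_bp: int | None = None,
) -> pd.DataFrame:
    """Tidy per-individual table: one row per (individual, class)."""
    frames = []
    froh_min = froh_min_length_bp if froh_min_length_bp is not None else min(length_classes_bp)
    froh = f_roh(calls, froh_min, autosome_length_bp).set_index("sample")["f_roh"]
    for min_len in length_classes_bp:
        df = nroh_sroh(calls, int(min_len))
        df["min_length_bp"] = int(min_len)
        df["f_roh"] = df["sample"].map(froh)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[
        ["sample", "min_length_bp", "nroh", "sroh", "f_roh"]
    ]


def cohort_summary(profiles: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Cohort means per condition label from :func:`profile` outputs."""
    rows = []
    for label, df in profiles.items():
        for min_len, grp in df.groupby("min_length_bp"):
            rows.append(
                {
                    "condition": label,
                    "min_length_bp": int(min_len),
                    "mean_nroh": float(grp["nroh"].mean()),
                    "mean_sroh": float(grp["sroh"].mean()),
                }
            )
    return pd.DataFrame(rows)
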