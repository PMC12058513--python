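"""Variant-site filters and region exclusions applied before ROH calling.

Rules run cohort-wide in a fixed order (biallelic SNP -> allele frequency ->
missingness); allele-frequency bounds are inclusive on both ends.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenotypeMatrix, Intervals

_BASES = frozenset("ACGT")


@dataclass
class FilterParams:
    af_min: float = 0.05
    af_max: float = 0.95
    require_biallelic_snp: bool = True
    exclude_missing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_min <= self.af_max <= 1.0):
            raise ValueError("need 0 <= af_min <= af_max <= 1")


def filter_sites(
    gm: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the site filters; return the retained matrix and a removal report.

    The report has one row per rule (sites_removed counts sites failing that
    rule among the survivors of the previous one) plus a 'retained' row.
    """
    params = params or FilterParams()
    keep = np.ones(gm.n_sites, dtype=bool)
    report_rows = []

    if params.require_biallelic_snp:
        bial = np.array(
            [
                len(r) == 1 and len(a) == 1 and r in _BASES and a in _BASES and r != a
                for r, a in zip(gm.ref, gm.alt)
            ],
            dtype=bool,
        )
        removed = int((keep & ~bial).sum())
        keep &= bial
        report_rows.append(("biallelic_snp", removed))

    af = gm.af if gm.af is not None else gm.compute_af()
    af_ok = (af >= params.af_min) & (af <= params.af_max)
    removed = int((keep & ~af_ok).sum())
    keep &= af_ok
    report_rows.append(("allele_frequency", removed))

    if params.exclude_missing:
        no_missing = ~(gm.calls < 0).any(axis=1)
        removed = int((keep & ~no_missing).sum())
        keep &= no_missing
        report_rows.append(("missing", removed))

    report_rows.append(("retained", int(keep.sum())))
    report = pd.DataFrame(report_rows, columns=["rule", "sites"])
    return gm.take(np.flatnonzero(keep)), report


def split_arms_and_exclude(gm: GenotypeMatrix, excluded_regions: Intervals) -> GenotypeMatrix:
    """Drop sites inside excluded intervals and label arm units at the gaps.

    Interval bounds are inclusive. Each chromosome with exclusions is
    partitioned into contiguous analysis units ("arms") so no downstream
    segment can span an excluded gap; chromosomes with no exclusions (or no
    sites on one side) degrade to a single unit.
    """
    chrom_str = gm.chrom.astype(str)
    gm_chroms = set(chrom_str.tolist())
    per_chrom = excluded_regions.by_chrom()
    for c in per_chrom:
        if c not in gm_chroms:
            warnings.warn(f"excluded region on {c!r} overlaps no sites; ignored")

    inside = excluded_regions.covers(gm.chrom, gm.pos)
    sub = gm.take(np.flatnonzero(~inside))
    sub_chrom = sub.chrom.astype(str)
    arm = np.empty(sub.n_sites, dtype=object)
    for c in np.unique(sub_chrom) if sub.n_sites else []:
        sel = sub_chrom == c
        if c in per_chrom:
            starts, _ends = per_chrom[c]
            arm_idx = np.searchsorted(starts, sub.pos[sel], side="right")
            arm[sel] = [f"{c}.arm{k}" for k in arm_idx]
        else:
            arm[sel] = c
    sub.arm = arm if sub.n_sites else None
    return sub


def trim_to_mask(gm: GenotypeMatrix, array_mask: Intervals) -> GenotypeMatrix:
    """Restrict to sites covered by the array mask (set intersection)."""
    covered = array_mask.covers(gm.chrom, gm.pos)
    return gm.take(np.flatnonzero(covered))
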