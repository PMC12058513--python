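"""Mendelian-inconsistency detection in families and recurrent-site removal."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenotypeMatrix, Intervals, Pedigree

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNINFORMATIVE = "uninformative"

_VALID = frozenset({-1, 0, 1, 2})


def trio_check(father_code: int, mother_code: int, child_code: int) -> str:
    """Classify one trio genotype combination.

    Uninformative when any member is missing; otherwise inconsistent iff the
    child dosage is impossible under biallelic Mendelian transmission.
    Symmetric in father/mother.
    """
    for code in (father_code, mother_code, child_code):
        if code not in _VALID:
            raise ValueError(f"invalid genotype code {code}")
    if -1 in (father_code, mother_code, child_code):
        return UNINFORMATIVE
    f, m, c = father_code, mother_code, child_code
    if c == 0 and (f == 2 or m == 2):
        return INCONSISTENT
    if c == 2 and (f == 0 or m == 0):
        return INCONSISTENT
    if c == 1 and ((f == 0 and m == 0) or (f == 2 and m == 2)):
        return INCONSISTENT
    return CONSISTENT


def _inconsistent_mask(f: np.ndarray, m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised trio_check over informative sites only."""
    return (
        ((c == 0) & ((f == 2) | (m == 2)))
        | ((c == 2) & ((f == 0) | (m == 0)))
        | ((c == 1) & (((f == 0) & (m == 0)) | ((f == 2) & (m == 2))))
    )


@dataclass
class MendelReport:
    chrom: np.ndarray
    pos: np.ndarray
    n_informative: np.ndarray
    n_inconsistent: np.ndarray
    n_families_inconsistent: np.ndarray
    flagged: np.ndarray
    recurrence_min: int
    rate_min: float

    @property
    def error_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_informative > 0,
                self.n_inconsistent / np.maximum(self.n_informative, 1),
                0.0,
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "pos": self.pos,
                "informative": self.n_informative,
                "inconsistent": self.n_inconsistent,
                "families_inconsistent": self.n_families_inconsistent,
                "rate": self.error_rate,
                "flagged": self.flagged,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def flagged_sites(self) -> set[tuple[str, int]]:
        return {
            (str(c), int(p))
            for c, p, fl in zip(self.chrom, self.pos, self.flagged)
            if fl
        }

    def flagged_intervals(self) -> Intervals:
        idx = np.flatnonzero(self.flagged)
        if idx.size == 0:
            return Intervals.empty()
        return Intervals(
            chrom=self.chrom[idx],
            start=self.pos[idx],
            end=self.pos[idx],
            name=np.array(["mendel_flagged"] * idx.size, dtype=object),
        )


def site_error_scan(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    recurrence_min: int = 2,
    rate_min: float = 0.05,
) -> MendelReport:
    """Evaluate every resolvable (father, mother, child) trio at every site.

    Multi-generation families contribute one trio per non-founder. A site is
    flagged when inconsistencies recur in >= ``recurrence_min`` distinct
    families OR its per-site error rate is >= ``rate_min`` (disjunction).
    """
    trios = [
        t for t in pedigree.trios() if all(iid in gm.samples for iid in t)
    ]
    n = gm.n_sites
    n_inf = np.zeros(n, dtype=np.int64)
    n_inc = np.zeros(n, dtype=np.int64)
    fam_inc: dict[str, np.ndarray] = {}
    if not trios:
        warnings.warn("pedigree contains no complete genotyped trio")
    for fa, mo, ch in trios:
        f = gm.calls[:, gm.sample_index(fa)]
        m = gm.calls[:, gm.sample_index(mo)]
        c = gm.calls[:, gm.sample_index(ch)]
        informative = (f >= 0) & (m >= 0) & (c >= 0)
        inconsistent = informative & _inconsistent_mask(f, m, c)
        n_inf += informative
        n_inc += inconsistent
        fid = pedigree.family_of(ch)
        if fid not in fam_inc:
            fam_inc[fid] = np.zeros(n, dtype=bool)
        fam_inc[fid] |= inconsistent
    n_fam = np.zeros(n, dtype=np.int64)
    for mask in fam_inc.values():
        n_fam += mask
    with np.errstate(invalid="ignore"):
        rate = np.where(n_inf > 0, n_inc / np.maximum(n_inf, 1), 0.0)
    flagged = (n_fam >= recurrence_min) | ((rate >= rate_min) & (n_inf > 0) & (n_inc > 0))
    return MendelReport(
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        n_informative=n_inf,
        n_inconsistent=n_inc,
        n_families_inconsistent=n_fam,
        flagged=flagged,
        recurrence_min=recurrence_min,
        rate_min=rate_min,
    )


def remove_flagged_sites(gm: GenotypeMatrix, report: MendelReport) -> GenotypeMatrix:
    """Drop flagged sites, matched by (chrom, pos) so the flag set can come
    from a different cohort sharing the site coordinate space."""
    bad = report.flagged_sites()
    if not bad:
        return gm.take(np.arange(gm.n_sites))
    keep = np.array(
        [(str(c), int(p)) not in bad for c, p in zip(gm.chrom, gm.pos)], dtype=bool
    )
    return gm.take(np.flatnonzero(keep))
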