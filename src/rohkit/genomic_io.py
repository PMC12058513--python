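"""Core containers and format I/O.

Internal coordinates are 1-based inclusive (VCF convention) everywhere;
BED's 0-based half-open convention is converted only at read/write time.

Genotypes are unphased dosage codes: 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class FormatError(ValueError):
    """Malformed input file."""


class VcfParseError(FormatError):
    """Unreadable or non-conforming VCF record."""


class MapCoverageError(KeyError):
    """Genetic map does not cover the requested chromosome."""


class PedigreeError(ValueError):
    """Inconsistent pedigree structure."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sites x samples table of diploid genotype codes.

    Sites are stored in contiguous per-chromosome blocks with strictly
    increasing positions; ``arm`` optionally carries an analysis-unit label
    per site (set by arm splitting) so downstream callers never join runs
    across an excluded gap.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    samples: list[str]
    af: np.ndarray | None = None
    arm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = list(self.samples)
        n = self.pos.shape[0]
        if self.calls.shape != (n, len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_sites={n}, n_samples={len(self.samples)})"
            )
        for arr, name in ((self.chrom, "chrom"), (self.ref, "ref"), (self.alt, "alt")):
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_sites {n}")
        self._check_sorted()
        if self.af is None:
            self.af = self.compute_af()
        else:
            self.af = np.asarray(self.af, dtype=float)
            if self.af.shape[0] != n:
                raise ValueError("af length mismatch")
            if n and ((self.af < 0).any() or (self.af > 1).any()):
                raise ValueError("alt_af outside [0, 1]")
        if self.arm is not None:
            self.arm = np.asarray(self.arm, dtype=object)
            if self.arm.shape[0] != n:
                raise ValueError("arm length mismatch")

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i in range(self.pos.shape[0]):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} occurs in non-contiguous blocks")
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c!r} at index {i}"
                )

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def compute_af(self) -> np.ndarray:
        """Alternate-allele frequency from non-missing calls per site."""
        ok = self.calls >= 0
        alt = np.where(ok, self.calls, 0).sum(axis=1).astype(float)
        denom = 2.0 * ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(denom > 0, alt / np.maximum(denom, 1), 0.0)
        return af

    def sample_index(self, iid: str) -> int:
        return self.samples.index(iid)

    def take(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset sites (preserving order) -- idx must be sorted site indices."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[idx],
            samples=list(self.samples),
            af=None if self.af is None else self.af[idx],
            arm=None if self.arm is None else self.arm[idx],
        )

    def units(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (label, site-index array) per analysis unit.

        Units are contiguous runs of equal ``arm`` label when arm splitting
        has been applied, otherwise whole chromosomes.
        """
        labels = self.arm if self.arm is not None else self.chrom
        n = self.n_sites
        i = 0
        while i < n:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            yield str(labels[i]), np.arange(i, j)
            i = j

    def chrom_spans(self) -> dict[str, tuple[int, int]]:
        spans: dict[str, tuple[int, int]] = {}
        for i in range(self.n_sites):
            c = str(self.chrom[i])
            p = int(self.pos[i])
            lo, hi = spans.get(c, (p, p))
            spans[c] = (min(lo, p), max(hi, p))
        return spans

    def equal_calls(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.n_sites == other.n_sites
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.calls == other.calls))
        )


# ---------------------------------------------------------------------------
# GeneticMap
# ---------------------------------------------------------------------------

class GeneticMap:
    """Per-chromosome monotone position -> cumulative-cM lookup.

    Linear interpolation between anchors; constant before the first anchor;
    constant-rate extrapolation (``default_rate`` cM/Mb) beyond the last.
    """

    def __init__(
        self,
        anchors: Mapping[str, tuple[Sequence[float], Sequence[float]]],
        default_rate: float = 1.0,
    ) -> None:
        self.default_rate = float(default_rate)
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in anchors.items():
            p = np.asarray(pos, dtype=float)
            c = np.asarray(cm, dtype=float)
            if p.shape != c.shape or p.ndim != 1 or p.size == 0:
                raise ValueError(f"bad anchors for {chrom!r}")
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"anchor positions not strictly increasing on {chrom!r}")
            if np.any(np.diff(c) < 0):
                raise ValueError(f"cumulative cM decreasing on {chrom!r}")
            self._anchors[str(chrom)] = (p, c)

    @property
    def chroms(self) -> list[str]:
        return list(self._anchors)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._anchors

    def cm(self, chrom: str, pos) -> np.ndarray:
        """Cumulative cM at physical position(s)."""
        if chrom not in self._anchors:
            raise MapCoverageError(f"chromosome {chrom!r} not in genetic map")
        p, c = self._anchors[chrom]
        q = np.atleast_1d(np.asarray(pos, dtype=float))
        out = np.interp(q, p, c)
        beyond = q > p[-1]
        if beyond.any():
            out[beyond] = c[-1] + self.default_rate * (q[beyond] - p[-1]) / 1e6
        return out if np.ndim(pos) else out[0]

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int], rate: float = 1.0) -> "GeneticMap":
        """Constant-rate map: ``rate`` cM/Mb on each chromosome."""
        anchors = {
            c: ([1.0, float(length)], [0.0, rate * (length - 1) / 1e6])
            for c, length in chrom_lengths.items()
        }
        return cls(anchors, default_rate=rate)

    @classmethod
    def read_tsv(cls, path, default_rate: float = 1.0) -> "GeneticMap":
        rows: dict[str, list[tuple[float, float]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: expected 3 columns")
                try:
                    pos, cm = float(parts[1]), float(parts[2])
                except ValueError:
                    if ln == 1:  # header row
                        continue
                    raise FormatError(f"{path}:{ln}: non-numeric map entry")
                rows.setdefault(parts[0], []).append((pos, cm))
        anchors = {
            c: (np.array([p for p, _ in v]), np.array([m for _, m in v]))
            for c, v in rows.items()
        }
        return cls(anchors, default_rate=default_rate)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tcM\n")
            for chrom, (p, c) in self._anchors.items():
                for pi, ci in zip(p, c):
                    fh.write(f"{chrom}\t{int(pi)}\t{ci:.8g}\n")


def interpolate_cM(gmap: GeneticMap, chrom: str, pos) -> float:
    """Functional wrapper around :meth:`GeneticMap.cm`."""
    return gmap.cm(chrom, pos)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    fid: str
    iid: str
    father: str | None = None
    mother: str | None = None
    sex: int = 0
    phenotype: int = -9


class Pedigree:
    """Founder/offspring graph for transmission simulation and Mendel checks."""

    def __init__(self, individuals: Sequence[Individual]) -> None:
        self.individuals = list(individuals)
        self._by_iid = {ind.iid: ind for ind in self.individuals}
        if len(self._by_iid) != len(self.individuals):
            raise PedigreeError("duplicate individual ids")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._by_iid:
                    raise PedigreeError(
                        f"{ind.iid}: referenced parent {parent!r} absent from pedigree"
                    )
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"{ind.iid}: exactly one parent missing")
        self._topo = self._toposort()

    def _toposort(self) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            st = state.get(iid, 0)
            if st == 1:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            if st == 2:
                return
            state[iid] = 1
            ind = self._by_iid[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            state[iid] = 2
            order.append(ind)

        for ind in self.individuals:
            visit(ind.iid)
        return order

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_iid[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_iid

    @property
    def iids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    def topological(self) -> list[Individual]:
        """Individuals ordered so parents precede children."""
        return list(self._topo)

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.father is None]

    def offspring(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.father is not None]

    def trios(self) -> list[tuple[str, str, str]]:
        """(father, mother, child) iid triples; one per non-founder."""
        return [
            (ind.father, ind.mother, ind.iid)
            for ind in self.individuals
            if ind.father is not None
        ]

    def family_of(self, iid: str) -> str:
        return self._by_iid[iid].fid

    @classmethod
    def read_fam(cls, path) -> "Pedigree":
        inds = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(f"{path}:{ln}: FAM needs 6 columns")
                fid, iid, fa, mo, sex, phe = parts[:6]
                inds.append(
                    Individual(
                        fid=fid,
                        iid=iid,
                        father=None if fa == "0" else fa,
                        mother=None if mo == "0" else mo,
                        sex=int(sex),
                        phenotype=int(float(phe)),
                    )
                )
        return cls(inds)

    def write_fam(self, path) -> None:
        with open(path, "w") as fh:
            for ind in self.individuals:
                fh.write(
                    f"{ind.fid}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}"
                    f"\t{ind.sex}\t{ind.phenotype}\n"
                )


# ---------------------------------------------------------------------------
# Intervals (BED / GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Intervals:
    """Interval set, 1-based inclusive coordinates internally."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.name is not None:
            self.name = np.asarray(self.name, dtype=object)
        if np.any(self.end < self.start):
            raise FormatError("interval end < start")

    def __len__(self) -> int:
        return int(self.chrom.shape[0])

    @classmethod
    def empty(cls) -> "Intervals":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                   np.array([], dtype=np.int64))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends) sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(self.chrom.astype(str)) if len(self) else []:
            m = self.chrom.astype(str) == c
            order = np.argsort(self.start[m], kind="stable")
            out[c] = (self.start[m][order], self.end[m][order])
        return out

    def covers(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: is each (chrom, pos) inside any interval (inclusive)?"""
        mask = np.zeros(pos.shape[0], dtype=bool)
        for c, (starts, ends) in self.by_chrom().items():
            sel = chrom.astype(str) == c
            if not sel.any():
                continue
            p = pos[sel]
            # interval index whose start is the rightmost <= p
            k = np.searchsorted(starts, p, side="right") - 1
            hit = np.zeros(p.shape[0], dtype=bool)
            # ends may not be sorted if intervals nest; check a few predecessors
            run_max_end = np.maximum.accumulate(ends)
            ok = k >= 0
            hit[ok] = p[ok] <= run_max_end[k[ok]]
            # refine: run_max_end can overcount only when intervals overlap and a
            # *later-starting* interval ends earlier; the accumulate handles it.
            mask[sel] = hit
        return mask

    def write_bed(self, path, extra: pd.DataFrame | None = None) -> None:
        cols = {
            "chrom": self.chrom.astype(str),
            "start": self.start - 1,  # to 0-based half-open
            "end": self.end,
        }
        if self.name is not None:
            cols["name"] = self.name.astype(str)
        df = pd.DataFrame(cols)
        if extra is not None:
            df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", header=False, index=False)


def read_intervals(path, fmt: str | None = None) -> Intervals:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    GFF3 ``gene`` records carry their name (gene_name=/Name=/ID= attribute);
    when no gene records exist every feature line is kept.
    """
    if fmt is None:
        s = str(path).lower()
        fmt = "gff3" if s.endswith((".gff", ".gff3")) else "bed"
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown interval format {fmt!r}")
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if fmt == "bed":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
                start0, end0 = int(parts[1]), int(parts[2])
                if end0 < start0:
                    raise FormatError(f"{path}:{ln}: end < start")
                name = parts[3] if len(parts) > 3 else ""
                rows.append((parts[0], start0 + 1, end0, name))
            else:
                if len(parts) < 9:
                    raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
                start, end = int(parts[3]), int(parts[4])
                if end < start:
                    raise FormatError(f"{path}:{ln}: end < start")
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("gene_name") or attrs.get("Name") or attrs.get("ID") or ""
                rows.append((parts[0], start, end, parts[2], name))
    if fmt == "gff3":
        genes = [r for r in rows if r[3] == "gene"]
        if genes:
            rows = genes
        rows = [(c, s, e, n) for c, s, e, _t, n in rows]
    if not rows:
        return Intervals.empty()
    return Intervals(
        chrom=np.array([r[0] for r in rows], dtype=object),
        start=np.array([r[1] for r in rows], dtype=np.int64),
        end=np.array([r[2] for r in rows], dtype=np.int64),
        name=np.array([r[3] for r in rows], dtype=object),
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, multiallelic: str = "skip") -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``multiallelic`` = "skip" drops records with !=1 ALT allele; "error"
    rejects the file. alt_af comes from INFO/AF when present, otherwise it is
    recomputed from the non-missing calls.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF reading") from exc
    if multiallelic not in {"skip", "error"}:
        raise ValueError("multiallelic must be 'skip' or 'error'")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    afs: list[float] = []
    codes: list[np.ndarray] = []
    any_af_missing = False
    lut = np.array([0, 1, 2, MISSING], dtype=np.int8)  # gts012 order
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    try:
        for rec_idx, variant in enumerate(vcf, start=1):
            if len(variant.ALT) != 1:
                if multiallelic == "error":
                    raise VcfParseError(
                        f"{path}: record {rec_idx} ({variant.CHROM}:{variant.POS}) "
                        "is multiallelic"
                    )
                continue
            gts = variant.genotypes
            for g in gts:
                if len(g) != 3:  # [allele_a, allele_b, phased]
                    raise VcfParseError(
                        f"{path}: record {rec_idx} has non-diploid GT"
                    )
            chroms.append(variant.CHROM)
            poss.append(variant.POS)
            refs.append(variant.REF)
            alts.append(variant.ALT[0])
            af = variant.INFO.get("AF")
            if af is None:
                any_af_missing = True
                afs.append(np.nan)
            else:
                afs.append(float(af))
            codes.append(lut[np.asarray(variant.gt_types, dtype=np.int64)])
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: parse failure: {exc}") from exc
    calls = (
        np.vstack(codes) if codes else np.zeros((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
        samples=samples,
        af=None,
    )
    if not any_af_missing and codes:
        gm.af = np.array(afs, dtype=float)
    return gm


def write_vcf(gm: GenotypeMatrix, path, chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write a VCFv4.2 with GT-only genotypes and declared contigs."""
    spans = gm.chrom_spans()
    lengths = dict(chrom_lengths) if chrom_lengths else {c: hi for c, (_, hi) in spans.items()}
    # preserve chromosome order of appearance
    seen: list[str] = []
    for c in gm.chrom:
        if str(c) not in seen:
            seen.append(str(c))
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=rohkit\n")
    for c in seen:
        buf.write(f"##contig=<ID={c},length={lengths.get(c, spans.get(c, (1, 1))[1])}>\n")
    buf.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(gm.samples))
    buf.write("\n")
    af = gm.af if gm.af is not None else gm.compute_af()
    for i in range(gm.n_sites):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[i])
        buf.write(
            f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t"
            f"AF={af[i]:.10g}\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
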