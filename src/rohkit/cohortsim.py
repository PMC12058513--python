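"""Synthetic cohort generator with known planted autozygosity.

Founder haplotypes are drawn per-site from the configured allele-frequency
law; autozygosity is planted by copying one haplotype over the other inside
chosen intervals (exact truth intervals for recovery tests). Offspring are
recombinant mosaics under the Haldane (Poisson, no-interference) model with
crossover positions uniform on the cM scale. Genotypes leave the simulator
as unphased dosage codes; haplotypes exist only in here.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genomic_io import (
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Intervals,
    MapCoverageError,
    Pedigree,
    PedigreeError,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# role -> (father_role, mother_role, sex); roles are per-family local names.
FAMILY_TEMPLATES: dict[str, list[tuple[str, str | None, str | None, int]]] = {
    "trio": [
        ("fa", None, None, 1),
        ("mo", None, None, 2),
        ("c1", "fa", "mo", 1),
    ],
    "septet": [
        ("pgf", None, None, 1),
        ("pgm", None, None, 2),
        ("mgf", None, None, 1),
        ("mgm", None, None, 2),
        ("fa", "pgf", "pgm", 1),
        ("mo", "mgf", "mgm", 2),
        ("c1", "fa", "mo", 1),
    ],
    "octet": [
        ("pgf", None, None, 1),
        ("pgm", None, None, 2),
        ("mgf", None, None, 1),
        ("mgm", None, None, 2),
        ("fa", "pgf", "pgm", 1),
        ("mo", "mgf", "mgm", 2),
        ("c1", "fa", "mo", 1),
        ("c2", "fa", "mo", 2),
    ],
}


@dataclass
class SegmentLaw:
    """Length law for planted autozygous segments of one regime."""

    count: int
    law: str = "uniform"  # fixed | uniform | exponential
    length_bp: float = 300_000.0  # fixed value, or mean for 'exponential'
    min_bp: float = 100_000.0
    max_bp: float = 1_500_000.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError("segment count must be >= 0")
        if self.law not in {"fixed", "uniform", "exponential"}:
            raise ConfigError(f"unknown length law {self.law!r}")
        if self.length_bp <= 0 or self.min_bp <= 0 or self.max_bp < self.min_bp:
            raise ConfigError("segment lengths must be positive with min <= max")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.law == "fixed":
            lengths = np.full(n, self.length_bp)
        elif self.law == "uniform":
            lengths = rng.uniform(self.min_bp, self.max_bp, size=n)
        else:  # truncated exponential, placeholder default (true law unknown)
            lengths = np.clip(
                rng.exponential(self.length_bp, size=n), self.min_bp, self.max_bp
            )
        return np.maximum(lengths.astype(np.int64), 1)


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int]
    seed: int = 0
    n_founders: int = 0  # unrelated singletons on top of pedigree members
    pedigree_spec: dict[str, int] = field(default_factory=dict)
    site_density: float = 100.0  # sites per Mb
    af_law: tuple[float, float] = (1.0, 1.0)  # Beta shape parameters
    planted_segments: list[SegmentLaw] = field(default_factory=list)
    het_error_rate: float = 0.0  # spurious hets per Mb per sample (paper: ~4.5)
    bad_site_fraction: float = 0.0
    bad_site_error_prob: float = 0.0
    array_mask_fraction: float = 0.25
    map_rate_cm_per_mb: float = 1.0
    fixed_spacing: bool = False
    poisson_sites: bool = False

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must be nonempty")
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {c!r} has non-positive length")
        if self.site_density <= 0:
            raise ConfigError("site_density must be > 0")
        if self.af_law[0] <= 0 or self.af_law[1] <= 0:
            raise ConfigError("Beta shape parameters must be > 0")
        for name, value in (
            ("bad_site_fraction", self.bad_site_fraction),
            ("bad_site_error_prob", self.bad_site_error_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.array_mask_fraction <= 1.0:
            raise ConfigError("array_mask_fraction must be in (0, 1]")
        if self.het_error_rate < 0:
            raise ConfigError("het_error_rate must be >= 0")
        for tmpl in self.pedigree_spec:
            if tmpl not in FAMILY_TEMPLATES:
                raise ConfigError(f"unknown family template {tmpl!r}")
        if isinstance(self.planted_segments, Sequence):
            self.planted_segments = [
                s if isinstance(s, SegmentLaw) else SegmentLaw(**s)
                for s in self.planted_segments
            ]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["planted_segments"] = [SegmentLaw(**s) for s in d.get("planted_segments", [])]
        if "af_law" in d:
            d["af_law"] = tuple(d["af_law"])
        return cls(**d)

    @property
    def genome_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))


@dataclass
class SiteTable:
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    af: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    def chrom_block(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom.astype(str) == chrom)


@dataclass
class TruthSet:
    """Ground truth: planted intervals, systematic bad sites, genotype flips."""

    planted: list[tuple[str, str, int, int]] = field(default_factory=list)
    error_sites: list[tuple[str, int]] = field(default_factory=list)
    per_genotype_flips: list[tuple[str, str, int, int, int]] = field(default_factory=list)

    def planted_for(self, sample: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for smp, c, s, e in self.planted if smp == sample]

    def planted_bp(self, sample: str) -> int:
        return sum(e - s + 1 for _c, s, e in self.planted_for(sample))

    def planted_intervals(self) -> Intervals:
        if not self.planted:
            return Intervals.empty()
        return Intervals(
            chrom=np.array([c for _s, c, _a, _b in self.planted], dtype=object),
            start=np.array([a for _s, _c, a, _b in self.planted], dtype=np.int64),
            end=np.array([b for _s, _c, _a, b in self.planted], dtype=np.int64),
            name=np.array([s for s, _c, _a, _b in self.planted], dtype=object),
        )

    def validate(self, sites: SiteTable | None = None) -> None:
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for smp, c, s, e in self.planted:
            by_key.setdefault((smp, c), []).append((s, e))
        for ivs in by_key.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError("planted intervals overlap")
        if sites is not None:
            site_keys = set(zip(sites.chrom.astype(str), sites.pos.tolist()))
            for _smp, c, p, _o, _n in self.per_genotype_flips:
                if (str(c), int(p)) not in site_keys:
                    raise ValueError(f"flip at unknown site {c}:{p}")


_BASE = np.array(list("ACGT"), dtype=object)


def simulate_sites(config: SimConfig, rng: np.random.Generator | None = None) -> SiteTable:
    """Draw the site table: per-chromosome positions, alleles, allele frequencies."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    for chrom, length in config.chrom_lengths.items():
        n = config.site_density * length / 1e6
        n = int(rng.poisson(n)) if config.poisson_sites else int(round(n))
        n = max(n, 1)
        if n > length:
            raise ConfigError(f"site density exceeds 1/bp on {chrom!r}")
        if config.fixed_spacing:
            spacing = length / n
            pos = np.round(spacing * np.arange(1, n + 1)).astype(np.int64)
            pos = np.minimum(pos, length)
        else:
            pos = np.array([], dtype=np.int64)
            while pos.size < n:
                extra = rng.integers(1, length + 1, size=int(1.2 * (n - pos.size)) + 8)
                pos = np.unique(np.concatenate([pos, extra]))
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        chroms.append(np.full(n, chrom, dtype=object))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    n_total = pos.shape[0]
    af = np.clip(rng.beta(config.af_law[0], config.af_law[1], size=n_total), 1e-4, 1 - 1e-4)
    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    return SiteTable(chrom=chrom, pos=pos, ref=_BASE[ref_idx], alt=_BASE[alt_idx], af=af)


def _plant_segments(
    sites: SiteTable,
    config: SimConfig,
    rng: np.random.Generator,
    haps: np.ndarray,
    sample: str,
    truth: TruthSet,
) -> None:
    """Copy haplotype 0 over haplotype 1 inside drawn intervals for one sample."""
    chrom_names = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    existing: dict[str, list[tuple[int, int]]] = {}
    for law in config.planted_segments:
        seg_lengths = law.draw(rng, law.count)
        for L in seg_lengths:
            if int(L) > max(config.chrom_lengths.values()):
                raise ConfigError(
                    f"planted segment of {int(L)} bp longer than every chromosome"
                )
            placed = False
            for _attempt in range(200):
                c = chrom_names[rng.choice(len(chrom_names), p=weights)]
                clen = config.chrom_lengths[c]
                if int(L) > clen:
                    continue
                start = int(rng.integers(1, clen - int(L) + 2))
                end = start + int(L) - 1
                if any(s <= end and start <= e for s, e in existing.get(c, [])):
                    continue
                existing.setdefault(c, []).append((start, end))
                block = sites.chrom_block(c)
                p = sites.pos[block]
                sel = block[(p >= start) & (p <= end)]
                haps[1, sel] = haps[0, sel]
                truth.planted.append((sample, c, start, end))
                placed = True
                break
            if not placed:
                raise ConfigError(
                    f"could not place a {int(L)} bp planted segment for {sample} "
                    "(genome too crowded)"
                )
    for key in existing:
        existing[key].sort()


def simulate_founders(
    sites: SiteTable,
    config: SimConfig,
    founder_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], TruthSet]:
    """Founder haplotypes (Hardy-Weinberg at alt_af) with planted autozygosity.

    Returns {sample: (2, n_sites) int8 haplotypes} and the truth set.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = TruthSet()
    haps: dict[str, np.ndarray] = {}
    n = sites.n_sites
    for sample in founder_ids:
        h = (rng.random((2, n)) < sites.af).astype(np.int8)
        _plant_segments(sites, config, rng, h, sample, truth)
        haps[sample] = h
    truth.validate()
    return haps, truth


def build_pedigree(config: SimConfig) -> Pedigree:
    """Pedigree from the family templates plus unrelated singletons."""
    inds: list[Individual] = []
    fam_no = 0
    for tmpl, n_fam in config.pedigree_spec.items():
        for _ in range(int(n_fam)):
            fam_no += 1
            fid = f"FAM{fam_no:04d}"
            for role, fa, mo, sex in FAMILY_TEMPLATES[tmpl]:
                inds.append(
                    Individual(
                        fid=fid,
                        iid=f"{fid}_{role}",
                        father=f"{fid}_{fa}" if fa else None,
                        mother=f"{fid}_{mo}" if mo else None,
                        sex=sex,
                    )
                )
    for k in range(1, config.n_founders + 1):
        inds.append(Individual(fid=f"SNG{k:04d}", iid=f"S{k:04d}", sex=1 + (k % 2)))
    return Pedigree(inds)


def _gamete(
    parent_haps: np.ndarray,
    site_cm: np.ndarray,
    span_cm: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete for a single chromosome (Haldane model)."""
    lo, hi = span_cm
    n_x = int(rng.poisson(max(hi - lo, 0.0) / 100.0))
    start = int(rng.integers(0, 2))
    if n_x == 0:
        return parent_haps[start].copy()
    points = np.sort(rng.uniform(lo, hi, size=n_x))
    source = (start + np.searchsorted(points, site_cm, side="right")) % 2
    return np.where(source == 0, parent_haps[0], parent_haps[1]).astype(np.int8)


def transmit_pedigree(
    founder_haps: dict[str, np.ndarray],
    pedigree: Pedigree,
    sites: SiteTable,
    gmap: GeneticMap,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Haplotypes for every pedigree member by Mendelian transmission.

    Crossover counts are Poisson in the chromosome's map length (cM/100);
    crossover positions are uniform on the cM scale. Before error injection
    every trio is Mendelian-consistent at every site by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    haps = {k: v for k, v in founder_haps.items()}
    chrom_names = [str(c) for c in dict.fromkeys(sites.chrom.astype(str))]
    blocks = {c: sites.chrom_block(c) for c in chrom_names}
    site_cm: dict[str, np.ndarray] = {}
    spans: dict[str, tuple[float, float]] = {}
    for c in chrom_names:
        if c not in gmap:
            raise MapCoverageError(f"genetic map does not cover chromosome {c!r}")
        cmv = gmap.cm(c, sites.pos[blocks[c]])
        site_cm[c] = cmv
        spans[c] = (float(cmv[0]), float(cmv[-1]))
    for ind in pedigree.topological():
        if ind.father is None:
            if ind.iid not in haps:
                raise PedigreeError(f"founder {ind.iid!r} has no simulated haplotypes")
            continue
        for parent in (ind.father, ind.mother):
            if parent not in haps:
                raise PedigreeError(f"missing parent {parent!r} for {ind.iid!r}")
        n = sites.n_sites
        child = np.empty((2, n), dtype=np.int8)
        for which, parent in enumerate((ind.father, ind.mother)):
            ph = haps[parent]
            for c in chrom_names:
                b = blocks[c]
                child[which, b] = _gamete(ph[:, b], site_cm[c], spans[c], rng)
        haps[ind.iid] = child
    return haps


def genotypes_from_haps(
    haps: Mapping[str, np.ndarray],
    sites: SiteTable,
    sample_order: Sequence[str],
) -> GenotypeMatrix:
    calls = np.stack([haps[s].sum(axis=0) for s in sample_order], axis=1).astype(np.int8)
    return GenotypeMatrix(
        chrom=sites.chrom,
        pos=sites.pos,
        ref=sites.ref,
        alt=sites.alt,
        calls=calls,
        samples=list(sample_order),
        af=None,  # cohort AF recomputed from the calls themselves
    )


def inject_errors(
    gm: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Flip genotypes per the error model; every flip is recorded.

    Spurious-heterozygote errors: per sample, Poisson(het_error_rate x
    genome Mb) homozygous sites flipped to het, uniformly over that sample's
    homozygous sites. Bad sites: a fixed random fraction of sites where each
    sample's genotype flips symmetrically (hom->het, het->random hom) with
    ``bad_site_error_prob``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = truth if truth is not None else TruthSet()
    calls = gm.calls.copy()
    genome_mb = config.genome_bp / 1e6
    n_sites, n_samples = calls.shape

    def record(site_idx: int, sample_idx: int, orig: int, new: int) -> None:
        truth.per_genotype_flips.append(
            (
                gm.samples[sample_idx],
                str(gm.chrom[site_idx]),
                int(gm.pos[site_idx]),
                int(orig),
                int(new),
            )
        )

    if config.het_error_rate > 0:
        for s in range(n_samples):
            n_flip = int(rng.poisson(config.het_error_rate * genome_mb))
            hom = np.flatnonzero((calls[:, s] == 0) | (calls[:, s] == 2))
            n_flip = min(n_flip, hom.size)
            if n_flip == 0:
                continue
            pick = rng.choice(hom, size=n_flip, replace=False)
            for i in np.sort(pick):
                record(int(i), s, int(calls[i, s]), 1)
                calls[i, s] = 1

    if config.bad_site_fraction > 0 and config.bad_site_error_prob > 0:
        n_bad = int(round(config.bad_site_fraction * n_sites))
        bad = np.sort(rng.choice(n_sites, size=n_bad, replace=False))
        truth.error_sites.extend(
            (str(gm.chrom[i]), int(gm.pos[i])) for i in bad
        )
        for s in range(n_samples):
            hit = bad[rng.random(n_bad) < config.bad_site_error_prob]
            for i in hit:
                orig = int(calls[i, s])
                new = 1 if orig in (0, 2) else int(rng.choice([0, 2]))
                record(int(i), s, orig, new)
                calls[i, s] = new

    out = GenotypeMatrix(
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        calls=calls,
        samples=list(gm.samples),
        af=None,
        arm=gm.arm,
    )
    return out, truth


def make_array_mask(
    sites: SiteTable, config: SimConfig, rng: np.random.Generator | None = None
) -> Intervals:
    """Uniform random site subsample standing in for an array manifest.

    Selects floor(fraction x n_sites) sites without replacement, sorted;
    1-bp intervals suitable for BED export.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if not 0.0 < config.array_mask_fraction <= 1.0:
        raise ConfigError("array_mask_fraction must be in (0, 1]")
    n = sites.n_sites
    k = int(np.floor(config.array_mask_fraction * n))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return Intervals(
        chrom=sites.chrom[idx],
        start=sites.pos[idx],
        end=sites.pos[idx],
        name=np.array(["array_site"] * k, dtype=object),
    )


@dataclass
class SimResult:
    gm: GenotypeMatrix
    truth: TruthSet
    pedigree: Pedigree
    gmap: GeneticMap
    mask: Intervals
    clean_gm: GenotypeMatrix  # genotypes before error injection
    sites: SiteTable


def simulate_cohort(config: SimConfig) -> SimResult:
    """Full pipeline: sites -> founders -> transmission -> errors -> mask.

    One seeded generator drives every step, so a fixed seed reproduces the
    whole cohort bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    sites = simulate_sites(config, rng)
    pedigree = build_pedigree(config)
    gmap = GeneticMap.uniform(config.chrom_lengths, rate=config.map_rate_cm_per_mb)
    founder_ids = [ind.iid for ind in pedigree.founders()]
    founder_haps, truth = simulate_founders(sites, config, founder_ids, rng)
    haps = transmit_pedigree(founder_haps, pedigree, sites, gmap, rng)
    clean_gm = genotypes_from_haps(haps, sites, pedigree.iids)
    gm, truth = inject_errors(clean_gm, config, rng, truth)
    mask = make_array_mask(sites, config, rng)
    truth.validate(sites)
    return SimResult(
        gm=gm,
        truth=truth,
        pedigree=pedigree,
        gmap=gmap,
        mask=mask,
        clean_gm=clean_gm,
        sites=sites,
    )
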