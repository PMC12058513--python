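"""Two-state autozygosity HMM caller.

States: HW (0, Hardy-Weinberg / non-autozygous) and AZ (1, autozygous).
Emissions mix HWE vs allele-frequency genotype priors with a symmetric
observation-error channel of total mass e = 10^(-phred/10); transitions use
an exponential kernel over the genetic-map distance between adjacent sites,
rescaled to bp-equivalents at ``fallback_rec_rate`` cM/Mb.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import GeneticMap, GenotypeMatrix
from .segments import ROHCallSet, ROHSegment

HW, AZ = 0, 1

NEG_INF = -np.inf


@dataclass
class HmmParams:
    gt_error_phred: float = 30.0
    hw_to_az: float = 6.7e-8
    az_to_hw: float = 5e-9
    fallback_rec_rate: float = 1.0  # cM/Mb when no genetic map is supplied
    viterbi: bool = True

    def __post_init__(self) -> None:
        if self.gt_error_phred < 0:
            raise ValueError("gt_error_phred must be >= 0")
        if self.hw_to_az <= 0 or self.az_to_hw <= 0:
            raise ValueError("transition intensities must be > 0")
        if self.fallback_rec_rate <= 0:
            raise ValueError("fallback_rec_rate must be > 0")

    @property
    def gt_error(self) -> float:
        return 10.0 ** (-self.gt_error_phred / 10.0)

    def stationary(self) -> np.ndarray:
        """Stationary distribution [P(HW), P(AZ)] of the per-bp intensities."""
        a, b = self.hw_to_az, self.az_to_hw
        return np.array([b / (a + b), a / (a + b)])


def emission_probs(genotype_code: int, alt_af: float, gt_error: float) -> tuple[float, float]:
    """(P(obs | HW), P(obs | AZ)) for one observed genotype.

    True-genotype priors (f = alt_af): HW uses HWE [(1-f)^2, 2f(1-f), f^2];
    AZ uses [(1-f), 0, f]. The observation channel keeps the true code with
    probability 1-e and emits each wrong code with probability e/2.
    """
    if not 0.0 < alt_af < 1.0:
        raise ValueError(f"monomorphic site (alt_af={alt_af}); AF-filter first")
    if genotype_code not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {genotype_code}")
    p = _emission_matrix(
        np.array([genotype_code], dtype=np.int8), np.array([alt_af]), gt_error
    )
    return float(p[0, HW]), float(p[0, AZ])


def _emission_matrix(codes: np.ndarray, af: np.ndarray, e: float) -> np.ndarray:
    """(n_sites, 2) emission probabilities for one sample's observed codes.

    Missing codes (-1) are uninformative: probability 1 under both states.
    """
    f = af
    prior_hw = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)
    prior_az = np.stack([1 - f, np.zeros_like(f), f], axis=1)
    # channel[t, o]: P(observe o | true t)
    channel = np.full((3, 3), e / 2.0)
    np.fill_diagonal(channel, 1.0 - e)
    obs_hw = prior_hw @ channel  # (n, 3) over observed codes
    obs_az = prior_az @ channel
    n = codes.shape[0]
    out = np.ones((n, 2))
    ok = codes >= 0
    idx = np.where(ok)[0]
    out[idx, HW] = obs_hw[idx, codes[idx]]
    out[idx, AZ] = obs_az[idx, codes[idx]]
    return out


def gap_bp_equivalent(
    pos: np.ndarray,
    chrom: str,
    params: HmmParams,
    gmap: GeneticMap | None = None,
) -> np.ndarray:
    """Inter-site distances in bp-equivalents (cM gap / fallback rate).

    Without a map this is the physical distance; with a uniform map at the
    fallback rate the two coincide.
    """
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    if gmap is None:
        return np.diff(pos).astype(float)
    cm = gmap.cm(chrom, pos)
    return np.maximum(np.diff(cm), 0.0) / params.fallback_rec_rate * 1e6


def transition_probs(
    pos_i: int,
    pos_j: int,
    params: HmmParams,
    gmap: GeneticMap | None = None,
    chrom: str | None = None,
) -> np.ndarray:
    """2x2 transition matrix between two consecutive sites of one arm unit."""
    if pos_j <= pos_i:
        raise ValueError("pos_j must exceed pos_i")
    d = gap_bp_equivalent(np.array([pos_i, pos_j]), chrom or "", params, gmap)[0]
    return _transition_matrices(np.array([d]), params)[0]


def _transition_matrices(d: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n, 2, 2) transition matrices for an array of gap distances."""
    p01 = -np.expm1(-params.hw_to_az * d)  # HW -> AZ
    p10 = -np.expm1(-params.az_to_hw * d)  # AZ -> HW
    out = np.empty((d.shape[0], 2, 2))
    out[:, HW, HW] = 1.0 - p01
    out[:, HW, AZ] = p01
    out[:, AZ, HW] = p10
    out[:, AZ, AZ] = 1.0 - p10
    return out


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def viterbi_decode(
    codes: np.ndarray,
    af: np.ndarray,
    pos: np.ndarray,
    params: HmmParams | None = None,
    gmap: GeneticMap | None = None,
    chrom: str | None = None,
) -> np.ndarray:
    """Maximum-probability state path (0=HW, 1=AZ) for one sample's arm unit.

    ``codes`` may be 1-D (one sample) or (n_sites, n_samples); the decode is
    vectorised across samples and returns an array of the same shape.
    """
    params = params or HmmParams()
    codes = np.asarray(codes, dtype=np.int8)
    one_dim = codes.ndim == 1
    if one_dim:
        codes = codes[:, None]
    n, n_samples = codes.shape
    if n < 1:
        raise ValueError("need at least one site")
    af = np.asarray(af, dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("monomorphic site in HMM input; AF-filter first")
    e = params.gt_error
    lemis = np.empty((n, n_samples, 2))
    for s in range(n_samples):
        lemis[:, s, :] = _log(_emission_matrix(codes[:, s], af, e))
    d = gap_bp_equivalent(np.asarray(pos), chrom or "", params, gmap) if n > 1 else np.empty(0)
    ltrans = _log(_transition_matrices(d, params))  # (n-1, 2, 2)
    linit = _log(params.stationary())

    delta = linit[None, :] + lemis[0]  # (n_samples, 2)
    ptr = np.empty((n, n_samples, 2), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, :, None] + ltrans[i - 1][None, :, :]  # (S, from, to)
        ptr[i] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + lemis[i]
    states = np.empty((n, n_samples), dtype=np.int8)
    states[-1] = np.argmax(delta, axis=1)
    for i in range(n - 1, 0, -1):
        states[i - 1] = np.take_along_axis(
            ptr[i], states[i][:, None].astype(np.int8), axis=1
        )[:, 0]
    return states[:, 0] if one_dim else states


def posterior_decode(
    codes: np.ndarray,
    af: np.ndarray,
    pos: np.ndarray,
    params: HmmParams | None = None,
    gmap: GeneticMap | None = None,
    chrom: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-backward per-site AZ posterior and its argmax path (diagnostic)."""
    params = params or HmmParams()
    codes = np.asarray(codes, dtype=np.int8)
    if codes.ndim != 1:
        raise ValueError("posterior_decode handles one sample at a time")
    n = codes.shape[0]
    af = np.asarray(af, dtype=float)
    emis = _emission_matrix(codes, af, params.gt_error)
    trans = _transition_matrices(
        gap_bp_equivalent(np.asarray(pos), chrom or "", params, gmap) if n > 1 else np.empty(0),
        params,
    )
    fwd = np.empty((n, 2))
    scale = np.empty(n)
    fwd[0] = params.stationary() * emis[0]
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for i in range(1, n):
        fwd[i] = (fwd[i - 1] @ trans[i - 1]) * emis[i]
        scale[i] = fwd[i].sum()
        fwd[i] /= scale[i]
    bwd = np.empty((n, 2))
    bwd[-1] = 1.0
    for i in range(n - 2, -1, -1):
        bwd[i] = (trans[i] @ (emis[i + 1] * bwd[i + 1])) / scale[i + 1]
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post[:, AZ], (post[:, AZ] > 0.5).astype(np.int8)


def call_roh_hmm(
    gm: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    params: HmmParams | None = None,
) -> ROHCallSet:
    """Call ROH per sample per arm unit; maximal AZ runs become segments.

    Segment coordinates are the outermost AZ-labelled site positions.
    """
    params = params or HmmParams()
    segments: list[ROHSegment] = []
    for label, idx in gm.units():
        chrom = str(gm.chrom[idx[0]])
        codes = gm.calls[idx]
        af = gm.af[idx]
        pos = gm.pos[idx]
        if params.viterbi:
            states = viterbi_decode(codes, af, pos, params, gmap, chrom)
        else:
            states = np.empty_like(codes)
            for s in range(gm.n_samples):
                _, states[:, s] = posterior_decode(codes[:, s], af, pos, params, gmap, chrom)
        for s, sample in enumerate(gm.samples):
            segments.extend(
                _runs_to_segments(states[:, s], pos, codes[:, s], chrom, sample)
            )
    return ROHCallSet(segments, samples=list(gm.samples))


def _runs_to_segments(
    states: np.ndarray,
    pos: np.ndarray,
    codes: np.ndarray,
    chrom: str,
    sample: str,
) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    az = states == AZ
    if not az.any():
        return out
    boundaries = np.flatnonzero(np.diff(az.astype(np.int8)))
    starts = [0] if az[0] else []
    starts += [int(b) + 1 for b in boundaries if az[b + 1]]
    ends = [int(b) for b in boundaries if az[b]]
    ends += [len(az) - 1] if az[-1] else []
    for i0, i1 in zip(starts, ends):
        out.append(
            ROHSegment(
                sample=sample,
                chrom=chrom,
                start=int(pos[i0]),
                end=int(pos[i1]),
                n_sites=i1 - i0 + 1,
                caller="hmm",
                n_het=int((codes[i0 : i1 + 1] == 1).sum()),
            )
        )
    return out
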