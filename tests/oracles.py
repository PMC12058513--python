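"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration / naive recounting and
must stay independent of the implementations they check.
"""
from __future__ import annotations

import numpy as np

from rohkit.roh_hmm import HmmParams, emission_probs, transition_probs


def brute_force_viterbi(codes, af, pos, params: HmmParams, gmap=None, chrom=None):
    """Best state path by exhaustive enumeration over all 2^n paths.

    Returns (paths_achieving_max, best_logprob); more than one path signals
    a tie. Uses the scalar emission/transition functions site by site.
    """
    n = len(codes)
    e = params.gt_error
    lemis = np.array(
        [np.log(emission_probs(int(c), float(f), e)) for c, f in zip(codes, af)]
    )  # (n, 2)
    ltrans = [
        np.log(transition_probs(int(pos[i - 1]), int(pos[i]), params, gmap, chrom))
        for i in range(1, n)
    ]
    linit = np.log(params.stationary())
    n_paths = 2**n
    bits = ((np.arange(n_paths)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    lp = linit[bits[:, 0]] + lemis[0, bits[:, 0]]
    for i in range(1, n):
        lp = lp + ltrans[i - 1][bits[:, i - 1], bits[:, i]] + lemis[i, bits[:, i]]
    best = lp.max()
    winners = bits[np.isclose(lp, best, rtol=0, atol=1e-12)]
    return winners, float(best)


def path_logprob(path, codes, af, pos, params: HmmParams, gmap=None, chrom=None) -> float:
    n = len(codes)
    e = params.gt_error
    lp = float(np.log(params.stationary())[path[0]])
    lp += float(np.log(emission_probs(int(codes[0]), float(af[0]), e)[path[0]]))
    for i in range(1, n):
        t = transition_probs(int(pos[i - 1]), int(pos[i]), params, gmap, chrom)
        lp += float(np.log(t[path[i - 1], path[i]]))
        lp += float(np.log(emission_probs(int(codes[i]), float(af[i]), e)[path[i]]))
    return lp


def naive_window_props(codes, window_snp, window_het, window_missing):
    """O(n*w) per-SNP hit proportion by literal window recounting."""
    codes = np.asarray(codes)
    n = len(codes)
    w = min(window_snp, n)
    windows = []
    for s in range(n - w + 1):
        chunk = codes[s : s + w]
        ok = (chunk == 1).sum() <= window_het and (chunk == -1).sum() <= window_missing
        windows.append((s, s + w - 1, ok))
    props = np.empty(n)
    for i in range(n):
        covering = [ok for s, e, ok in windows if s <= i <= e]
        props[i] = sum(covering) / len(covering)
    return props


def gamete_trio_oracle(f: int, m: int, c: int) -> str:
    """Trio consistency by exhaustive gamete enumeration."""
    if -1 in (f, m, c):
        return "uninformative"
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    possible = {a + b for a in gametes[f] for b in gametes[m]}
    return "consistent" if c in possible else "inconsistent"


def naive_overlap_counts(calls, chrom, pos):
    """Per-site individual counts by literal containment testing."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    counts = np.zeros(len(pos), dtype=int)
    for i in range(len(pos)):
        c, p = str(chrom[i]), int(pos[i])
        n = 0
        for sample in calls.samples:
            if any(
                str(seg.chrom) == c and seg.start <= p <= seg.end
                for seg in calls.for_sample(sample)
            ):
                n += 1
        counts[i] = n
    return counts
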