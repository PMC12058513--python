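"""Comparative experiment orchestration.

Covers the pipeline's headline comparisons: all-sites vs array-trimmed
calling, the heterozygote-allowance sweep, density-matched pruning averaged
over iterations, and Mendelian-filtered reruns.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import GeneticMap, GenotypeMatrix, Intervals, Pedigree
from .pedigree_qc import remove_flagged_sites, site_error_scan
from .roh_hmm import HmmParams, call_roh_hmm
from .roh_profile import nroh_sroh
from .roh_window import WindowParams, call_roh_window


@dataclass
class ExperimentPlan:
    callers: Sequence[str] = ("hmm", "window")
    region_sets: Sequence[str] = ("all_sites",)
    window_het_values: Sequence[int] = (1,)
    length_classes_kb: Sequence[float] = (100.0, 1500.0)
    prune_target_site_count: int | None = None
    prune_iterations: int = 10
    seed: int = 0
    mendel_filter: bool = False

    def __post_init__(self) -> None:
        for c in self.callers:
            if c not in {"hmm", "window"}:
                raise ValueError(f"unknown caller {c!r}")
        for r in self.region_sets:
            if r not in {"all_sites", "array_mask"}:
                raise ValueError(f"unknown region set {r!r}")
        if self.prune_iterations < 1:
            raise ValueError("prune_iterations must be >= 1")


def _call(
    gm: GenotypeMatrix,
    caller: str,
    gmap: GeneticMap | None,
    hmm_params: HmmParams | None,
    window_params: WindowParams | None,
):
    if caller == "hmm":
        return call_roh_hmm(gm, gmap, hmm_params)
    return call_roh_window(gm, window_params)


def density_prune_run(
    gm: GenotypeMatrix,
    target_site_count: int,
    n_iterations: int,
    seed: int,
    caller: str = "hmm",
    gmap: GeneticMap | None = None,
    hmm_params: HmmParams | None = None,
    window_params: WindowParams | None = None,
    length_classes_kb: Sequence[float] = (100.0, 1500.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random site-subsample iterations, recalled and averaged.

    Each iteration samples ``target_site_count`` sites uniformly without
    replacement under a seed derived as ``seed + iteration`` (so iterations
    are individually reproducible), reruns calling and profiling, and the
    per-class NROH means are averaged within iteration across individuals
    first, then across iterations.
    """
    if target_site_count > gm.n_sites:
        raise ValueError(
            f"target_site_count {target_site_count} exceeds available sites {gm.n_sites}"
        )
    per_iter_rows = []
    for it in range(n_iterations):
        rng = np.random.default_rng(seed + it)
        idx = np.sort(rng.choice(gm.n_sites, size=target_site_count, replace=False))
        sub = gm.take(idx)
        calls = _call(sub, caller, gmap, hmm_params, window_params)
        for kb in length_classes_kb:
            stats = nroh_sroh(calls, int(kb * 1000))
            per_iter_rows.append(
                {
                    "iteration": it,
                    "min_length_kb": kb,
                    "mean_nroh": float(stats["nroh"].mean()),
                    "mean_sroh": float(stats["sroh"].mean()),
                }
            )
    per_iter = pd.DataFrame(per_iter_rows)
    summary = (
        per_iter.groupby("min_length_kb")[["mean_nroh", "mean_sroh"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "min_length_kb",
        "mean_nroh",
        "sd_nroh",
        "mean_sroh",
        "sd_sroh",
    ]
    return summary, per_iter


def _digest(gm: GenotypeMatrix) -> str:
    h = hashlib.sha256()
    h.update(gm.pos.tobytes())
    h.update(gm.calls.tobytes())
    h.update("|".join(gm.samples).encode())
    return h.hexdigest()[:16]


def comparison_report(
    plan: ExperimentPlan,
    gm: GenotypeMatrix,
    gmap: GeneticMap | None = None,
    array_mask: Intervals | None = None,
    pedigree: Pedigree | None = None,
    hmm_params: HmmParams | None = None,
    window_params: WindowParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cohort-summary table: one row per (caller, region set, het option, class)."""
    from .site_filter import trim_to_mask

    base_window = window_params or WindowParams()
    if plan.mendel_filter:
        if pedigree is None:
            raise ValueError("mendel_filter requires a pedigree")
        report = site_error_scan(gm, pedigree)
        gm = remove_flagged_sites(gm, report)
    rows = []
    for region in plan.region_sets:
        if region == "array_mask":
            if array_mask is None:
                raise ValueError("array_mask region set requires a mask")
            region_gm = trim_to_mask(gm, array_mask)
        else:
            region_gm = gm
        for caller in plan.callers:
            het_values = plan.window_het_values if caller == "window" else (None,)
            for H in het_values:
                for kb in plan.length_classes_kb:
                    if caller == "window":
                        wp = WindowParams.for_length_class(
                            kb,
                            window_snp=base_window.window_snp,
                            window_het=int(H),
                            window_missing=base_window.window_missing,
                            hit_threshold=base_window.hit_threshold,
                            max_gap_kb=base_window.max_gap_kb,
                            density_kb_per_snp=base_window.density_kb_per_snp,
                        )
                        calls = call_roh_window(region_gm, wp)
                    else:
                        calls = call_roh_hmm(region_gm, gmap, hmm_params)
                    stats = nroh_sroh(calls, int(kb * 1000))
                    rows.append(
                        {
                            "caller": caller,
                            "region_set": region,
                            "window_het": -1 if H is None else int(H),
                            "min_length_kb": kb,
                            "mean_nroh": float(stats["nroh"].mean()),
                            "mean_sroh": float(stats["sroh"].mean()),
                        }
                    )
    manifest = {
        "seed": plan.seed,
        "callers": list(plan.callers),
        "region_sets": list(plan.region_sets),
        "window_het_values": [int(h) for h in plan.window_het_values],
        "length_classes_kb": [float(k) for k in plan.length_classes_kb],
        "mendel_filter": bool(plan.mendel_filter),
        "input_digest": _digest(gm),
        "hmm_params": vars(hmm_params or HmmParams()),
        "window_params": vars(base_window),
    }
    return pd.DataFrame(rows), manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
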