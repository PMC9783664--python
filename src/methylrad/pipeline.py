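"""End-to-end DMR pipeline: filter, smooth, threshold, call, permute, adjust."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DMR, MethylationMatrix, SmoothedProfile, TStatTrack
from .dmr import compute_tstats, filter_coverage, find_regions, quantile_cutoffs
from .permutation import (
    NullAreaPool,
    PermutationPlan,
    assign_pvalues,
    null_areas,
    permute_labels,
)
from .smoothing import SmoothParams, smooth_all

__all__ = ["DmrPipelineResult", "call_dmrs"]


@dataclass
class DmrPipelineResult:
    dmrs: list[DMR]
    profile: SmoothedProfile
    track: TStatTrack
    cutoffs: tuple[float, float]
    pool: NullAreaPool


def call_dmrs(
    matrix: MethylationMatrix,
    case_group: str,
    control_group: str,
    smooth_params: SmoothParams | None = None,
    min_cov: int = 10,
    min_samples: int = 3,
    q_low: float = 0.01,
    q_high: float = 0.99,
    max_gap: int = 300,
    min_cpgs_region: int = 3,
    sd_floor_quantile: float = 0.75,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    add_one: bool = False,
) -> DmrPipelineResult:
    """Run the whole comparison and return p/q-annotated DMRs.

    Steps: coverage filter (min_cov x in >= min_samples samples per group),
    per-sample local-likelihood smoothing, case-minus-control t statistics,
    1%/99% quantile thresholds, region finding, balanced label-permutation
    null of region areas (smoothing reused, cutoffs recomputed per
    permutation), pooled-null p-values and BH adjustment.
    """
    smooth_params = smooth_params or SmoothParams()
    filtered = filter_coverage(matrix, min_cov=min_cov, min_samples=min_samples)
    profile = smooth_all(filtered, smooth_params)
    track = compute_tstats(
        profile, case_group, control_group, sd_floor_quantile=sd_floor_quantile
    )
    cutoffs = quantile_cutoffs(track, q_low, q_high)
    dmrs = find_regions(track, cutoffs, max_gap=max_gap, min_cpgs_region=min_cpgs_region)
    track.cutoff_low, track.cutoff_high = cutoffs
    plan = PermutationPlan(n_perm=n_perm, seed=seed, exhaustive=exhaustive)
    assignments = permute_labels(profile.groups, plan)
    pool = null_areas(
        profile,
        assignments,
        case_group,
        control_group,
        q_low=q_low,
        q_high=q_high,
        max_gap=max_gap,
        min_cpgs_region=min_cpgs_region,
        sd_floor_quantile=sd_floor_quantile,
    )
    dmrs = assign_pvalues(dmrs, pool, add_one=add_one)
    return DmrPipelineResult(
        dmrs=dmrs, profile=profile, track=track, cutoffs=cutoffs, pool=pool
    )
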