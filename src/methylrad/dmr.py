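"""Per-CpG group t statistics, quantile thresholds and DMR detection.

The comparison statistic at each retained CpG is a two-sample t on the
smoothed fractions, case (irradiated) minus control (sham), with the pooled
within-group standard deviation floored at its genome-wide 75th percentile
so near-constant sites cannot blow up the ratio.  Region thresholds are the
empirical 1st/99th percentiles of the t distribution; regions are maximal
runs of consecutive retained CpGs beyond a threshold (inclusive), broken at
gaps larger than ``max_gap`` bp, and summarised by their CpG count, mean
smoothed difference and area (sum of |t|).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .core import DMR, MethylationMatrix, SmoothedProfile, TStatTrack

__all__ = [
    "filter_coverage",
    "compute_tstats",
    "quantile_cutoffs",
    "find_regions",
    "select_significant",
    "select_top",
    "count_directions",
]


def filter_coverage(
    matrix: MethylationMatrix, min_cov: int = 10, min_samples: int = 3
) -> MethylationMatrix:
    """Retain sites with >= ``min_samples`` samples at >= ``min_cov``x in *each* group.

    Requiring the quorum per group (rather than overall) keeps both group
    means estimable at every retained site.  Site order is preserved.
    """
    keep = np.ones(matrix.n_sites, dtype=bool)
    for g in matrix.group_names:
        idx = matrix.sample_indices(g)
        if len(idx) < min_samples:
            raise ValueError(
                f"group {g!r} has {len(idx)} samples < min_samples={min_samples}; "
                "coverage filter unsatisfiable"
            )
        keep &= (matrix.coverage[:, idx] >= min_cov).sum(axis=1) >= min_samples
    return matrix.subset_sites(keep)


def compute_tstats(
    profile: SmoothedProfile,
    case_group: str,
    control_group: str,
    sd_floor_quantile: float = 0.75,
    groups: Mapping[str, str] | None = None,
) -> TStatTrack:
    """Signed per-site t statistics, oriented case minus control.

    t = (mean_case - mean_control) / (sd_pool * sqrt(1/n1 + 1/n2)) with the
    pooled sd floored at its ``sd_floor_quantile`` quantile across all sites.
    ``groups`` optionally overrides the profile's sample->group map (used by
    permutation inference to relabel without touching the smoothing).
    """
    labels = dict(profile.groups if groups is None else groups)
    idx1 = np.asarray(
        [i for i, s in enumerate(profile.samples) if labels[s] == case_group]
    )
    idx2 = np.asarray(
        [i for i, s in enumerate(profile.samples) if labels[s] == control_group]
    )
    if len(idx1) == 0 or len(idx2) == 0:
        raise KeyError(f"groups {case_group!r}/{control_group!r} not found")
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each group needs >= 2 samples for a t statistic")
    a = profile.smoothed[:, idx1]
    b = profile.smoothed[:, idx2]
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    var_pool = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    sd_pool = np.sqrt(var_pool)
    floor = float(np.quantile(sd_pool, sd_floor_quantile))
    if floor <= 0:
        # degenerate: (near-)constant profile everywhere; avoid 0/0
        floor = max(float(sd_pool.max()), np.finfo(float).tiny)
    sd = np.maximum(sd_pool, floor)
    t = diff / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    return TStatTrack(sites=profile.sites, tstat=t, mean_diff=diff)


def quantile_cutoffs(
    track: TStatTrack | np.ndarray, q_low: float = 0.01, q_high: float = 0.99
) -> tuple[float, float]:
    """Empirical (type-7, linear interpolation) quantiles of the t track."""
    t = track.tstat if isinstance(track, TStatTrack) else np.asarray(track, dtype=float)
    if len(t) == 0:
        raise ValueError("empty t-statistic track")
    if len(t) < 100:
        warnings.warn(
            f"only {len(t)} retained sites; quantile cutoffs are unstable", stacklevel=2
        )
    lo, hi = np.quantile(t, [q_low, q_high])  # numpy default = type 7
    return float(lo), float(hi)


def find_regions(
    track: TStatTrack,
    cutoffs: tuple[float, float],
    max_gap: int = 300,
    min_cpgs_region: int = 3,
) -> list[DMR]:
    """Maximal qualifying runs of consecutive retained CpGs.

    A hyper (hypo) region is a maximal run of consecutive retained CpGs on
    one chromosome, all with t >= cutoff_high (t <= cutoff_low, both
    inclusive), with consecutive members at most ``max_gap`` bp apart.  Runs
    shorter than ``min_cpgs_region`` CpGs are discarded.  p and q are unset.
    """
    cutoff_low, cutoff_high = cutoffs
    chrom = track.sites["chrom"].to_numpy()
    pos = track.sites["pos"].to_numpy()
    t = track.tstat
    dmrs: list[DMR] = []
    for direction, mask in (
        ("hyper", t >= cutoff_high),
        ("hypo", t <= cutoff_low),
    ):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        # break runs on: non-consecutive track index, chromosome change,
        # or bp gap exceeding max_gap
        brk = (
            (np.diff(idx) != 1)
            | (chrom[idx[1:]] != chrom[idx[:-1]])
            | ((pos[idx[1:]] - pos[idx[:-1]]) > max_gap)
        )
        starts = np.concatenate(([0], np.flatnonzero(brk) + 1))
        ends = np.concatenate((np.flatnonzero(brk), [len(idx) - 1]))
        for s, e in zip(starts, ends):
            members = idx[s : e + 1]
            if len(members) < min_cpgs_region:
                continue
            dmrs.append(
                DMR(
                    chrom=str(chrom[members[0]]),
                    start=int(pos[members[0]]),
                    end=int(pos[members[-1]]),
                    n_cpgs=len(members),
                    direction=direction,
                    mean_diff=float(track.mean_diff[members].mean()),
                    area=float(np.abs(t[members]).sum()),
                )
            )
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.end))
    for i, d in enumerate(dmrs):
        d.id = f"dmr_{i + 1:05d}"
    return dmrs


def _require_p(dmrs: Sequence[DMR]) -> None:
    unset = [d.id for d in dmrs if d.p is None]
    if unset:
        raise ValueError(f"p-value unset on DMRs: {unset}")


def select_significant(dmrs: Sequence[DMR], alpha: float = 0.05) -> list[DMR]:
    """DMRs with permutation p strictly below ``alpha`` (order preserved)."""
    _require_p(dmrs)
    return [d for d in dmrs if d.p < alpha]


def select_top(
    dmrs: Sequence[DMR], alpha: float = 0.05, min_abs_diff: float = 0.25
) -> list[DMR]:
    """The validation-candidate filter: p < alpha AND |mean_diff| > min_abs_diff."""
    _require_p(dmrs)
    return [d for d in dmrs if d.p < alpha and abs(d.mean_diff) > min_abs_diff]


def count_directions(dmrs: Sequence[DMR]) -> tuple[int, int]:
    """(n_hyper, n_hypo); the two tallies always sum to len(dmrs)."""
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    return n_hyper, len(dmrs) - n_hyper
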