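"""Label-permutation null for region areas, permutation p-values and BH FDR.

Significance of a region's area is assessed against a pooled null: group
labels are reassigned (balanced, preserving group sizes, identity excluded),
t statistics and their quantile cutoffs are recomputed for each relabelling,
regions are re-called, and all resulting areas are pooled.  A region's
p-value is the plain fraction of pooled null areas >= its observed area
(ties count against the region), optionally with an add-one correction.
Smoothing is label-free and is therefore computed once and shared by every
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .core import DMR, SmoothedProfile
from .dmr import compute_tstats, find_regions, quantile_cutoffs

__all__ = [
    "PermutationPlan",
    "NullAreaPool",
    "permute_labels",
    "null_areas",
    "permutation_pvalue",
    "assign_pvalues",
    "bh_adjust",
]


@dataclass(frozen=True)
class PermutationPlan:
    """How to draw balanced label reassignments.

    n_perm:
        Number of permutations (default 1000, matching routine practice for
        this analysis).  Ignored when ``exhaustive`` is set.
    seed:
        Seed of the whole plan.  Permutation i is generated from an
        independent counter-based substream (seed, i), so the sequence is
        reproducible regardless of execution order.
    exhaustive:
        Enumerate every non-identity balanced split instead of sampling
        (only sensible for small designs, e.g. the 69 splits of a 4-vs-4).
    """

    n_perm: int = 1000
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not self.exhaustive and self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class NullAreaPool:
    """All region areas pooled across permutations."""

    areas: np.ndarray
    per_perm_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")


def permute_labels(
    groups: dict[str, str], plan: PermutationPlan
) -> list[dict[str, str]]:
    """Balanced label reassignments of a two-group design.

    Each assignment maps sample -> group with the original group sizes
    preserved; the observed assignment is excluded.  Sampled draws are
    uniform over the remaining C(n1+n2, n1) - 1 splits, with replacement
    across iterations; ``plan.exhaustive`` enumerates them instead.
    """
    names: list[str] = []
    for s in groups:
        if groups[s] not in names:
            names.append(groups[s])
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    g1, g2 = names
    samples = sorted(groups)
    observed = frozenset(s for s in samples if groups[s] == g1)
    n1 = len(observed)
    n_splits = comb(len(samples), n1) - 1
    if n_splits < 1:
        raise ValueError("no non-identity balanced split exists for this design")

    def as_assignment(case_set: frozenset[str]) -> dict[str, str]:
        return {s: (g1 if s in case_set else g2) for s in samples}

    if plan.exhaustive:
        return [
            as_assignment(frozenset(c))
            for c in combinations(samples, n1)
            if frozenset(c) != observed
        ]

    assignments = []
    for i in range(plan.n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(plan.seed, spawn_key=(i,)))
        while True:
            chosen = frozenset(rng.choice(samples, size=n1, replace=False).tolist())
            if chosen != observed:
                break
        assignments.append(as_assignment(chosen))
    return assignments


def null_areas(
    profile: SmoothedProfile,
    assignments: Sequence[dict[str, str]],
    case_group: str,
    control_group: str,
    q_low: float = 0.01,
    q_high: float = 0.99,
    max_gap: int = 300,
    min_cpgs_region: int = 3,
    sd_floor_quantile: float = 0.75,
) -> NullAreaPool:
    """Re-call regions under each relabelling and pool every area.

    Quantile cutoffs are recomputed within each permutation (they are defined
    as quantiles of that permutation's t distribution), which keeps observed
    and null region-calling exchangeable.
    """
    areas: list[float] = []
    counts: list[int] = []
    for labels in assignments:
        track = compute_tstats(
            profile,
            case_group,
            control_group,
            sd_floor_quantile=sd_floor_quantile,
            groups=labels,
        )
        cuts = quantile_cutoffs(track, q_low, q_high)
        regions = find_regions(track, cuts, max_gap=max_gap, min_cpgs_region=min_cpgs_region)
        areas.extend(r.area for r in regions)
        counts.append(len(regions))
    return NullAreaPool(areas=np.asarray(areas, dtype=float), per_perm_counts=counts)


def permutation_pvalue(
    observed_area: float, pool: NullAreaPool, add_one: bool = False
) -> float:
    """Fraction of pooled null areas >= the observed area.

    The plain fraction can be 0; ``add_one`` switches to (b+1)/(n+1), which
    never is.
    """
    n = len(pool.areas)
    if n == 0:
        raise ValueError("empty null-area pool; run permutations first")
    b = int((pool.areas >= observed_area).sum())
    return (b + 1) / (n + 1) if add_one else b / n


def assign_pvalues(
    dmrs: Sequence[DMR], pool: NullAreaPool, add_one: bool = False
) -> list[DMR]:
    """Set p (pooled-null fraction) and q (BH) on every DMR, in place."""
    dmrs = list(dmrs)
    if dmrs:
        ps = [permutation_pvalue(d.area, pool, add_one=add_one) for d in dmrs]
        qs = bh_adjust(ps)
        for d, p, q in zip(dmrs, ps, qs):
            d.p = float(p)
            d.q = float(q)
    return dmrs


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p's, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q
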