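"""Global 5mC%% quantification from a colorimetric ELISA.

The assay reads optical density at 450 nm for a dilution series of a
methylated-DNA standard and for the DNA samples.  The standard curve is a
zero-intercept least-squares line of blank-subtracted OD against the amount
of 5mC (the quantification formula subtracts the negative-control OD, so the
curve is forced through the blank).  Sample 5mC content, as a percentage of
input DNA, is then

    5mC% = (sample OD - NC OD) / (slope * DNA ng) * 100
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElisaPlate",
    "GlobalMethylationResult",
    "fit_standard_slope",
    "compute_5mc_percent",
    "summarize_by_group",
]


@dataclass
class ElisaPlate:
    """One plate: standards (ng 5mC, OD), negative-control OD and samples."""

    standards: list[tuple[float, float]]
    nc_od: float
    samples: list[tuple[str, float, float]]  # (id, od, dna_ng)

    def __post_init__(self) -> None:
        if len(self.standards) < 2:
            raise ValueError("need at least 2 standards")
        amounts = [a for a, _ in self.standards]
        if len(set(amounts)) < 2:
            raise ValueError("standards must span at least 2 distinct amounts")
        vals = [v for pair in self.standards for v in pair] + [self.nc_od]
        vals += [od for _, od, _ in self.samples]
        if not np.isfinite(vals).all():
            raise ValueError("ODs and amounts must be finite")
        if any(dna <= 0 for _, _, dna in self.samples):
            raise ValueError("dna_ng must be > 0")


@dataclass
class GlobalMethylationResult:
    """Per-sample 5mC%% plus group mean +/- SEM (sd/sqrt(n), ddof=1)."""

    per_sample: pd.DataFrame  # id, five_mc_percent, group
    summary: pd.DataFrame  # group, n, mean, sem, single_member


def fit_standard_slope(
    standards: Sequence[tuple[float, float]], nc_od: float
) -> float:
    """Slope (OD per ng 5mC) of the zero-intercept standard curve.

    Least squares of (OD - NC OD) against amount with the intercept fixed at
    0: slope = sum(a_i * y_i) / sum(a_i^2).  A non-positive slope indicates a
    failed plate and is reported with a warning, not an error.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need at least 2 standards to fit a slope")
    amounts = np.asarray([a for a, _ in standards], dtype=float)
    ods = np.asarray([od for _, od in standards], dtype=float)
    if not (np.isfinite(amounts).all() and np.isfinite(ods).all() and np.isfinite(nc_od)):
        raise ValueError("standards and nc_od must be finite")
    if np.unique(amounts).size < 2:
        raise ValueError("all standard amounts identical; slope undefined")
    y = ods - nc_od
    slope = float(np.dot(amounts, y) / np.dot(amounts, amounts))
    if slope <= 0:
        warnings.warn(f"standard-curve slope is non-positive ({slope:.4g})", stacklevel=2)
    return slope


def compute_5mc_percent(
    sample_od: float | np.ndarray,
    nc_od: float,
    slope: float,
    dna_ng: float | np.ndarray,
) -> float | np.ndarray:
    """Apply the kit formula; negative results are allowed but warned about."""
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    dna = np.asarray(dna_ng, dtype=float)
    if (dna <= 0).any():
        raise ValueError("dna_ng must be > 0")
    pct = (np.asarray(sample_od, dtype=float) - nc_od) / (slope * dna) * 100.0
    if (np.asarray(pct) < 0).any():
        warnings.warn("negative 5mC% computed (OD below negative control)", stacklevel=2)
    return float(pct) if np.ndim(pct) == 0 else pct


def summarize_by_group(
    values: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str],
) -> GlobalMethylationResult:
    """Group means and SEMs of per-sample 5mC%%.

    SEM uses the n-1 denominator sd; a single-member group gets SEM 0 and a
    ``single_member`` flag.  Samples without a group are dropped with a
    warning (an empty group is simply absent from the summary).
    """
    values = pd.Series(values, dtype=float)
    missing = [s for s in values.index if s not in groups]
    if missing:
        warnings.warn(f"samples without group dropped from summary: {missing}", stacklevel=2)
        values = values.drop(index=missing)
    if values.empty:
        raise ValueError("no grouped values to summarize")
    per_sample = pd.DataFrame(
        {
            "id": values.index,
            "five_mc_percent": values.to_numpy(),
            "group": [groups[s] for s in values.index],
        }
    )
    rows = []
    for g, sub in per_sample.groupby("group", sort=True):
        n = len(sub)
        mean = float(sub["five_mc_percent"].mean())
        if n == 1:
            warnings.warn(f"group {g!r} has a single member; SEM reported as 0", stacklevel=2)
            sem = 0.0
        else:
            sem = float(sub["five_mc_percent"].std(ddof=1) / np.sqrt(n))
        rows.append((g, n, mean, sem, n == 1))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean", "sem", "single_member"])
    return GlobalMethylationResult(per_sample=per_sample, summary=summary)
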