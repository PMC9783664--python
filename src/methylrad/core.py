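"""Core genomic data containers shared across the pipeline.

Coordinate conventions
----------------------
CpG positions are 1-based genomic coordinates of the cytosine (the Bismark
coverage convention, strand-collapsed).  DMR spans are 1-based inclusive over
their member CpGs; conversion to 0-based half-open BED happens only at the
file boundary (:mod:`methylrad.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "MethylationMatrix",
    "SmoothedProfile",
    "TStatTrack",
    "DMR",
    "AnnotatedDMR",
    "GeneAnnotation",
    "validate_sample_sheet",
]

SAMPLE_SHEET_COLUMNS = ("sample", "group", "dose_gy", "time_months", "path")


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single CpG: chromosome name and 1-based cytosine position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    if list(sites.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("sites frame must have columns ('chrom', 'pos')")
    if len(sites) and int(sites["pos"].min()) < 1:
        raise ValueError("CpG positions must be >= 1")
    # strictly increasing within each chromosome, chromosomes contiguous
    for _, sub in sites.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if len(d) and (d <= 0).any():
            raise ValueError("sites must be strictly increasing within a chromosome")
    return sites.reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """Per-CpG read counts for a set of samples.

    Parameters
    ----------
    sites:
        Frame with columns ``chrom`` (str) and ``pos`` (int, 1-based), sorted
        by (chrom, pos) and strictly increasing within each chromosome.
    samples:
        Ordered sample identifiers (columns of the count arrays).
    coverage, methylated:
        ``(n_sites, n_samples)`` non-negative integer arrays with
        ``methylated <= coverage`` elementwise.
    groups:
        Mapping sample id -> group label; every sample must be assigned.
    """

    sites: pd.DataFrame
    samples: list[str]
    coverage: np.ndarray
    methylated: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.coverage.shape != shape or self.methylated.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got "
                f"{self.coverage.shape} / {self.methylated.shape}"
            )
        if (self.coverage < 0).any() or (self.methylated < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.methylated > self.coverage).any():
            raise ValueError("methylated count exceeds coverage")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    # -- convenience ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def sample_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def fractions(self) -> np.ndarray:
        """Raw methylation fractions; 0 where coverage is 0 (weightless)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.methylated / np.maximum(self.coverage, 1)
        return np.where(self.coverage > 0, f, 0.0)

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            coverage=self.coverage[mask],
            methylated=self.methylated[mask],
            groups=dict(self.groups),
        )


@dataclass
class SmoothedProfile:
    """Per-CpG, per-sample smoothed methylation fractions in [0, 1]."""

    sites: pd.DataFrame
    samples: list[str]
    smoothed: np.ndarray
    groups: dict[str, str]
    #: True where the window fit fell back to a (coverage-weighted) mean
    fallback: np.ndarray | None = None
    #: True for sites whose chromosome had fewer CpGs than ``min_cpgs``
    exhausted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        shape = (len(self.sites), len(self.samples))
        if self.smoothed.shape != shape:
            raise ValueError(f"smoothed array must have shape {shape}")
        if not np.isfinite(self.smoothed).all():
            raise ValueError("smoothed values must be finite")
        if (self.smoothed < 0).any() or (self.smoothed > 1).any():
            raise ValueError("smoothed values must lie in [0, 1]")

    def sample_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)


@dataclass
class TStatTrack:
    """Signed per-CpG t statistics (case minus control orientation)."""

    sites: pd.DataFrame
    tstat: np.ndarray
    #: per-site difference of group-mean smoothed fractions (case - control)
    mean_diff: np.ndarray
    cutoff_low: float | None = None
    cutoff_high: float | None = None

    def __post_init__(self) -> None:
        self.tstat = np.asarray(self.tstat, dtype=float)
        self.mean_diff = np.asarray(self.mean_diff, dtype=float)
        if len(self.tstat) != len(self.sites) or len(self.mean_diff) != len(self.sites):
            raise ValueError("track arrays must match the number of sites")
        if not np.isfinite(self.tstat).all():
            raise ValueError("t statistics must be finite")


@dataclass
class DMR:
    """A contiguous run of CpGs differentially methylated between groups.

    ``start``/``end`` are 1-based inclusive positions of the first and last
    member CpG.  ``direction`` is 'hyper' or 'hypo' for the case (irradiated)
    group relative to control (sham).  ``area`` is the sum of |t| over member
    CpGs; ``mean_diff`` the mean case-minus-control smoothed difference.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    direction: str
    mean_diff: float
    area: float
    p: float | None = None
    q: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be 'hyper' or 'hypo', got {self.direction!r}")
        if self.start > self.end:
            raise ValueError("DMR start must be <= end")
        if self.n_cpgs < 1:
            raise ValueError("DMR must contain at least one CpG")
        if abs(self.mean_diff) > 1:
            raise ValueError("|mean_diff| cannot exceed 1 (fraction units)")
        if self.area < 0:
            raise ValueError("area must be non-negative")
        for name in ("p", "q"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    """Gene intervals (BED convention: 0-based half-open), sorted per chrom."""

    intervals: pd.DataFrame  # chrom, start, end, name, strand

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end", "name"]
        if not all(c in df.columns for c in required):
            raise ValueError(f"gene annotation needs columns {required}")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene intervals require start < end")
        if df["name"].isna().any() or (df["name"].astype(str) == "").any():
            raise ValueError("gene names must be non-empty")
        self.intervals = (
            df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        )

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


@dataclass
class AnnotatedDMR:
    """A DMR with its nearest gene under closest-interval semantics."""

    dmr: DMR
    gene: str | None
    distance: int | None
    relative_position: str  # 'upstream' | 'downstream' | 'overlapping' | 'none'
    ties: list[str] = field(default_factory=list)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet frame (sample, group, dose_gy, time_months, path)."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    if (sheet["dose_gy"].astype(float) < 0).any():
        raise ValueError("dose_gy must be >= 0")
    return sheet.reset_index(drop=True)
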