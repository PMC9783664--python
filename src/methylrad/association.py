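"""Pearson correlation of molecular measures with functional outcomes.

Correlations pair subjects by id (strict join: ids present in only one
table are an error, not silently dropped).  p-values come from the t
transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom and are
reported per correlation without multiplicity adjustment (a BH option
exists).  An absolute-value reporting flag mirrors the |r| convention used
for methylation/expression-vs-strain results while the signed r is always
retained.  Subjects can be stratified by mean heart dose (MHD) at the
DEGRO-recommended 2.5 Gy threshold; a dose exactly at the threshold falls
in the low stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .permutation import bh_adjust

__all__ = [
    "CorrelationResult",
    "pearson",
    "correlate_measures",
    "stratify_mhd",
    "MhdStrata",
]


@dataclass
class CorrelationResult:
    """One product-moment correlation with its sample size and p-value."""

    label: str
    r: float
    n: int
    p: float | None
    insufficient: bool = False

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def pearson(x, y, label: str = "") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if n >= 3:
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        p = None
    return CorrelationResult(label=label, r=r, n=n, p=p)


def correlate_measures(
    measures: pd.DataFrame,
    outcomes: pd.DataFrame,
    strata: pd.Series | None = None,
    absolute: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """One correlation per (measure, outcome[, stratum]) combination.

    ``measures`` has columns subject, measure, value; ``outcomes`` has
    subject, outcome, value.  Subjects are paired by id and the subject sets
    of the two tables must agree.  Pairs with fewer than 3 subjects are
    flagged insufficient (no p; r only if 2 subjects with nonzero variance).
    ``strata`` optionally maps subject -> stratum label, adding one row per
    stratum.  ``absolute`` reports |r| alongside the signed r; ``bh`` adds a
    BH-adjusted q column across the reported p-values.
    """
    for frame, cols in ((measures, ["subject", "measure", "value"]),
                        (outcomes, ["subject", "outcome", "value"])):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
    m_subj = set(measures["subject"])
    o_subj = set(outcomes["subject"])
    if m_subj != o_subj:
        raise ValueError(
            f"unmatched subject ids between tables: {sorted(m_subj ^ o_subj)}"
        )
    rows = []
    strata_levels = [None] if strata is None else sorted(strata.dropna().unique())
    for meas_name, msub in measures.groupby("measure", sort=True):
        for out_name, osub in outcomes.groupby("outcome", sort=True):
            merged = msub.merge(
                osub, on="subject", suffixes=("_m", "_o"), how="inner"
            )
            for level in strata_levels:
                sub = merged
                if level is not None:
                    keep = strata.reindex(merged["subject"]).to_numpy() == level
                    sub = merged[keep]
                label = f"{meas_name}~{out_name}" + ("" if level is None else f"|{level}")
                n = len(sub)
                if n < 3:
                    r = np.nan
                    if n == 2 and sub["value_m"].std() > 0 and sub["value_o"].std() > 0:
                        r = pearson(sub["value_m"], sub["value_o"]).r
                    rows.append((meas_name, out_name, level, n, r, np.nan, True))
                    continue
                try:
                    res = pearson(sub["value_m"], sub["value_o"], label=label)
                except ValueError:
                    rows.append((meas_name, out_name, level, n, np.nan, np.nan, True))
                    continue
                rows.append((meas_name, out_name, level, n, res.r, res.p, False))
    out = pd.DataFrame(
        rows,
        columns=["measure", "outcome", "stratum", "n", "r", "p", "insufficient"],
    )
    if absolute:
        out["abs_r"] = out["r"].abs()
    if bh:
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
        out["q"] = q
    return out


class MhdStrata(NamedTuple):
    low: pd.DataFrame  # MHD <= threshold
    high: pd.DataFrame  # MHD > threshold


def stratify_mhd(
    subjects: pd.DataFrame, threshold: float = 2.5, mhd_col: str = "mhd"
) -> MhdStrata:
    """Partition subjects by mean heart dose at ``threshold`` Gy.

    Equality goes to the low stratum.  Subjects with a missing MHD are
    excluded with a warning; the two strata are disjoint and their union is
    the set of subjects with an MHD.
    """
    if mhd_col not in subjects.columns:
        raise ValueError(f"subjects table needs a {mhd_col!r} column")
    missing = subjects[subjects[mhd_col].isna()]
    if len(missing):
        warnings.warn(
            f"{len(missing)} subject(s) without MHD excluded from stratification",
            stacklevel=2,
        )
    present = subjects[subjects[mhd_col].notna()]
    low = present[present[mhd_col] <= threshold].reset_index(drop=True)
    high = present[present[mhd_col] > threshold].reset_index(drop=True)
    return MhdStrata(low=low, high=high)
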