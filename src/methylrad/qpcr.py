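"""Relative expression quantification by the comparative Ct (ddCt) method.

Per sample, dCt = Ct(target) - Ct(reference); per case sample,
ddCt = dCt - (control term), and the log2 fold change is -ddCt (amplification
efficiency fixed at 2.0).  Two normalisation modes are provided:

``group-control``
    The control term is the control group's mean dCt (unpaired designs,
    e.g. irradiated vs sham animals).
``within-subject-baseline``
    The control term is the same subject's baseline-visit dCt (longitudinal
    designs, e.g. patient visits V1/V2 against V0).

A simple variance-based stability ranking of candidate reference genes is
included as plumbing: the score combines within-group and between-group
variability of each candidate's Ct deviation from the candidate-panel mean,
lower being more stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionResult",
    "collapse_replicates",
    "delta_delta_ct",
    "reference_stability",
]


@dataclass
class ExpressionResult:
    """Per-sample dCt/ddCt/log2 fold change plus case-group summary."""

    target: str
    reference: str
    per_sample: pd.DataFrame  # sample, group, dct, ddct, log2fc
    group_mean_log2fc: float
    group_sem_log2fc: float


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = ["sample", "group", "gene", "ct"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns {missing}")
    if (table["ct"] <= 0).any() or not np.isfinite(table["ct"]).all():
        raise ValueError("Ct values must be finite and > 0")
    return table


def collapse_replicates(table: pd.DataFrame, tolerance: float = 0.5) -> pd.DataFrame:
    """Average technical replicates to one Ct per (sample, gene).

    Replicate spread beyond ``tolerance`` cycles is reported with a warning
    (the mean is still used).  Grouping keys other than the replicate index
    are carried through unchanged.
    """
    table = _validate(table)
    keys = [c for c in table.columns if c not in ("ct", "rep")]
    spread = table.groupby(keys, sort=False)["ct"].agg(lambda s: s.max() - s.min())
    wide = spread[spread > tolerance]
    if len(wide):
        warnings.warn(
            f"{len(wide)} (sample, gene) cell(s) with replicate Ct spread > "
            f"{tolerance} cycles",
            stacklevel=2,
        )
    return table.groupby(keys, sort=False, as_index=False)["ct"].mean()


def _pivot_dct(table: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    ct = table.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (target, reference):
        if gene not in ct.columns:
            raise ValueError(f"gene {gene!r} not in table")
        bad = ct.index[ct[gene].isna()].get_level_values("sample").tolist()
        if bad:
            raise ValueError(f"gene {gene!r} missing for samples: {bad}")
    out = ct.reset_index()[["sample", "group"]]
    out["dct"] = (ct[target] - ct[reference]).to_numpy()
    return out


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    case_group: str,
    control_group: str,
    mode: str = "group-control",
    subject_col: str = "subject",
    baseline_group: str | None = None,
) -> ExpressionResult:
    """ddCt relative quantification of ``target`` against ``reference``.

    In ``group-control`` mode the control term is the mean dCt of
    ``control_group``; running case == control therefore yields a mean log2
    fold change of exactly 0.  In ``within-subject-baseline`` mode each
    subject's own dCt at ``baseline_group`` (default: the control group) is
    subtracted instead; ``table`` then needs a ``subject_col`` column.
    """
    table = _validate(table)
    if table.duplicated(subset=["sample", "gene"]).any():
        table = collapse_replicates(table)
    dct = _pivot_dct(table, target, reference)
    case = dct[dct["group"] == case_group].copy()
    control = dct[dct["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    if case.empty:
        raise ValueError(f"case group {case_group!r} is empty")

    if mode == "group-control":
        case["ddct"] = case["dct"] - control["dct"].mean()
    elif mode == "within-subject-baseline":
        if subject_col not in table.columns:
            raise ValueError(f"within-subject mode needs a {subject_col!r} column")
        baseline = baseline_group if baseline_group is not None else control_group
        subj = table[["sample", subject_col]].drop_duplicates().set_index("sample")
        dct = dct.join(subj, on="sample")
        base = (
            dct[dct["group"] == baseline]
            .set_index(subject_col)["dct"]
        )
        case = dct[dct["group"] == case_group].copy()
        unmatched = sorted(set(case[subject_col]) - set(base.index))
        if unmatched:
            raise ValueError(f"no baseline measurement for subjects: {unmatched}")
        case["ddct"] = case["dct"].to_numpy() - base.loc[case[subject_col]].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    case["log2fc"] = -case["ddct"]
    n = len(case)
    mean = float(case["log2fc"].mean())
    sem = float(case["log2fc"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    cols = ["sample", "group", "dct", "ddct", "log2fc"]
    if mode == "within-subject-baseline":
        cols.insert(1, subject_col)
    return ExpressionResult(
        target=target,
        reference=reference,
        per_sample=case[cols].reset_index(drop=True),
        group_mean_log2fc=mean,
        group_sem_log2fc=sem,
    )


def reference_stability(
    table: pd.DataFrame, candidates: list[str], group_col: str = "group"
) -> pd.DataFrame:
    """Rank candidate reference genes by a variance-based stability score.

    For each candidate, d = Ct(candidate) - mean Ct over the candidate panel
    per sample; score = sqrt(pooled within-group variance of d + variance of
    the group means of d).  Ascending score = more stable; ties break
    alphabetically.  Returns a frame (gene, score) sorted by rank.
    """
    table = _validate(table)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate reference genes")
    ct = table.pivot_table(index=["sample", group_col], columns="gene", values="ct")
    for gene in candidates:
        if gene not in ct.columns:
            raise ValueError(f"candidate {gene!r} not in table")
        bad = ct.index[ct[gene].isna()].get_level_values("sample").tolist()
        if bad:
            raise ValueError(f"candidate {gene!r} missing for samples: {bad}")
    panel = ct[candidates]
    dev = panel.sub(panel.mean(axis=1), axis=0)
    grp = dev.groupby(level=group_col)
    sizes = grp.size()
    # pooled within-group variance (groups of 1 contribute nothing)
    ss = (grp.var(ddof=1).mul(sizes - 1, axis=0)).sum(axis=0)
    dof = max(int((sizes - 1).sum()), 1)
    intra = ss / dof
    means = grp.mean()
    between = means.var(ddof=1) if len(means) > 1 else pd.Series(0.0, index=candidates)
    score = np.sqrt(intra + between)
    out = (
        pd.DataFrame({"gene": candidates, "score": score[candidates].to_numpy()})
        .sort_values(["score", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return out
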