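"""Nearest-gene assignment for DMRs (closest-interval semantics).

Each DMR is assigned the gene minimising the gap distance on its chromosome.
Overlapping intervals have distance 0; for disjoint intervals the distance
is the bedtools-style coordinate difference (downstream interval start minus
upstream interval end, both 0-based half-open, plus 1), so bookended
intervals are 1 bp apart.  Ties are broken by the smaller gene start and all
tied genes are reported.  Strand affects only the upstream/downstream label
(the DMR's position relative to the gene in the gene's orientation), never
the choice of nearest gene.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .core import DMR, AnnotatedDMR, GeneAnnotation

__all__ = ["nearest_gene", "annotate_all", "gap_distance"]


def gap_distance(
    a_start0: int, a_end0: int, b_start0: int, b_end0: int
) -> int:
    """Gap between two 0-based half-open intervals; 0 iff they intersect."""
    if a_start0 < b_end0 and b_start0 < a_end0:
        return 0
    if b_start0 >= a_end0:
        return b_start0 - a_end0 + 1
    return a_start0 - b_end0 + 1


def nearest_gene(dmr: DMR, annotation: GeneAnnotation) -> AnnotatedDMR:
    """The gene with the minimum gap distance to the DMR.

    A chromosome absent from the annotation yields a no-annotation marker
    (gene None, relative_position 'none') with a warning rather than an
    error.
    """
    genes = annotation.chrom_table(dmr.chrom)
    if genes.empty:
        warnings.warn(
            f"chromosome {dmr.chrom!r} absent from gene annotation; "
            f"DMR {dmr.id or dmr.start} left unannotated",
            stacklevel=2,
        )
        return AnnotatedDMR(dmr=dmr, gene=None, distance=None, relative_position="none")

    a_start0, a_end0 = dmr.start - 1, dmr.end  # 1-based inclusive -> half-open
    g_start = genes["start"].to_numpy()
    g_end = genes["end"].to_numpy()
    overlap = (a_start0 < g_end) & (g_start < a_end0)
    right = g_start >= a_end0
    dist = np.where(
        overlap,
        0,
        np.where(right, g_start - a_end0 + 1, a_start0 - g_end + 1),
    )
    best = int(dist.min())
    tied = genes.loc[dist == best]
    # deterministic tie-break: leftmost gene start (frame already sorted)
    chosen = tied.iloc[0]
    ties = tied["name"].tolist() if len(tied) > 1 else []

    if best == 0:
        relpos = "overlapping"
    else:
        dmr_is_left = a_end0 <= int(chosen["start"])
        strand = str(chosen.get("strand", "."))
        if strand == "-":
            relpos = "downstream" if dmr_is_left else "upstream"
        else:  # '+' or unstranded: treat as forward
            relpos = "upstream" if dmr_is_left else "downstream"
    return AnnotatedDMR(
        dmr=dmr,
        gene=str(chosen["name"]),
        distance=best,
        relative_position=relpos,
        ties=ties,
    )


def annotate_all(
    dmrs: Sequence[DMR], annotation: GeneAnnotation
) -> list[AnnotatedDMR]:
    """Order-preserving nearest-gene assignment for every DMR."""
    return [nearest_gene(d, annotation) for d in dmrs]
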