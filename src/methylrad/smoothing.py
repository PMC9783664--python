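"""Local-likelihood smoothing of per-sample methylation profiles.

Each sample's raw methylation fractions are smoothed with a weighted local
polynomial (default degree 2) over a genomic window centred on every CpG.
The window radius starts at ``half_width`` bp and, if it holds fewer than
``min_cpgs`` CpGs, grows symmetrically to the next nearest CpG until the
count is met or the chromosome is exhausted.  Weights are a tricube kernel
in scaled bp distance multiplied by read coverage, so deeply covered CpGs
anchor the fit and uncovered CpGs (coverage 0) contribute nothing while
still receiving a fitted value.  Fitted values are clamped to [0, 1].

Windows never cross chromosome boundaries: genomic distance is undefined
across them.  Smoothing ignores group labels entirely, which is what lets
permutation inference reuse one smoothed profile for every relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MethylationMatrix, SmoothedProfile

__all__ = ["SmoothParams", "smoothing_window", "smooth_sample", "smooth_all"]


@dataclass(frozen=True)
class SmoothParams:
    """Tunables for the local fit.

    half_width:
        Minimum window radius in bp (default 500).
    min_cpgs:
        Minimum CpG count a window must contain (default 20); the radius
        expands until this is met.
    kernel:
        Distance weighting scheme; only ``"tricube"`` is implemented.
    degree:
        Local polynomial degree, 0, 1 or 2 (default 2).
    """

    half_width: int = 500
    min_cpgs: int = 20
    kernel: str = "tricube"
    degree: int = 2

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if self.degree not in (0, 1, 2):
            raise ValueError("degree must be 0, 1 or 2")
        if self.kernel != "tricube":
            raise ValueError(f"unknown kernel {self.kernel!r}")


def smoothing_window(
    pos: np.ndarray, index: int, params: SmoothParams
) -> tuple[int, int]:
    """Inclusive index bounds (lo, hi) of the window centred on ``pos[index]``.

    ``pos`` holds the sorted 1-based positions of one chromosome.  The window
    is the set of sites within the smallest radius R >= half_width such that
    it contains >= min_cpgs sites; if the whole chromosome has fewer sites
    the window is the whole chromosome (callers flag this case).
    """
    pos = np.asarray(pos)
    n = len(pos)
    if not 0 <= index < n:
        raise IndexError(f"site index {index} out of range for {n} sites")
    k = min(params.min_cpgs, n)
    # grow outward to the k-th nearest site (two-pointer, ties go left-first
    # but the final radius captures both sides symmetrically)
    left = right = index
    centre = pos[index]
    while right - left + 1 < k:
        d_left = centre - pos[left - 1] if left > 0 else np.inf
        d_right = pos[right + 1] - centre if right + 1 < n else np.inf
        if d_left <= d_right:
            left -= 1
        else:
            right += 1
    radius = max(params.half_width, int(centre - pos[left]), int(pos[right] - centre))
    lo = int(np.searchsorted(pos, centre - radius, side="left"))
    hi = int(np.searchsorted(pos, centre + radius, side="right")) - 1
    return lo, hi


def _window_radius(pos: np.ndarray, index: int, params: SmoothParams) -> int:
    lo, hi = smoothing_window(pos, index, params)
    centre = pos[index]
    return max(params.half_width, int(centre - pos[lo]), int(pos[hi] - centre))


def _smooth_chrom(
    pos: np.ndarray,
    cov: np.ndarray,
    meth: np.ndarray,
    params: SmoothParams,
    global_mean: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth all samples of one chromosome.

    Returns (smoothed (n, S), fallback mask (n, S)).
    """
    n, n_samples = cov.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov > 0, meth / np.maximum(cov, 1), 0.0)
    out = np.empty((n, n_samples), dtype=float)
    fallback = np.zeros((n, n_samples), dtype=bool)
    ncols = params.degree + 1
    for i in range(n):
        lo, hi = smoothing_window(pos, i, params)
        radius = max(
            params.half_width, int(pos[i] - pos[lo]), int(pos[hi] - pos[i])
        )
        sl = slice(lo, hi + 1)
        x = (pos[sl] - pos[i]) / radius
        tri = np.clip(1.0 - np.abs(x) ** 3, 0.0, None) ** 3
        w = tri[:, None] * cov[sl]  # (w, S)
        wsum = w.sum(axis=0)
        covered = wsum > 0
        # normalise weights so the normal equations are O(1)-scaled
        wn = np.divide(w, np.where(covered, wsum, 1.0)[None, :])
        X = np.vander(x, ncols, increasing=True)  # (w, ncols)
        A = np.einsum("wi,ws,wj->sij", X, wn, X)
        b = np.einsum("wi,ws,ws->si", X, wn, frac[sl])
        det = np.linalg.det(A)
        good = covered & np.isfinite(det) & (np.abs(det) > 1e-10)
        if good.any():
            beta = np.linalg.solve(A[good], b[good][..., None])[..., 0]
            vals = beta[:, 0]
            finite = np.isfinite(vals)
            out[i, good] = np.where(finite, vals, 0.0)
            if not finite.all():  # pragma: no cover - numerical safety net
                gidx = np.flatnonzero(good)[~finite]
                out[i, gidx] = (wn[:, gidx] * frac[sl][:, gidx]).sum(axis=0)
                fallback[i, gidx] = True
        bad = ~good
        if bad.any():
            # singular local fit: coverage-weighted window mean; if the
            # window is entirely uncovered, the sample's global mean
            bidx = np.flatnonzero(bad)
            for j in bidx:
                if covered[j]:
                    out[i, j] = float(np.dot(wn[:, j], frac[sl][:, j]))
                else:
                    out[i, j] = global_mean[j]
            fallback[i, bidx] = True
    np.clip(out, 0.0, 1.0, out=out)
    return out, fallback


def smooth_sample(
    matrix: MethylationMatrix, sample: str, params: SmoothParams | None = None
) -> np.ndarray:
    """Smoothed methylation fractions for one sample, per retained site."""
    if sample not in matrix.samples:
        raise KeyError(f"sample {sample!r} not in matrix")
    params = params or SmoothParams()
    j = matrix.samples.index(sample)
    sub = MethylationMatrix(
        sites=matrix.sites,
        samples=[sample],
        coverage=matrix.coverage[:, [j]],
        methylated=matrix.methylated[:, [j]],
        groups={sample: matrix.groups[sample]},
    )
    return smooth_all(sub, params).smoothed[:, 0]


def smooth_all(
    matrix: MethylationMatrix, params: SmoothParams | None = None
) -> SmoothedProfile:
    """Smooth every sample; deterministic and independent of sample order."""
    params = params or SmoothParams()
    n, n_samples = matrix.coverage.shape
    smoothed = np.empty((n, n_samples), dtype=float)
    fallback = np.zeros((n, n_samples), dtype=bool)
    exhausted = np.zeros(n, dtype=bool)

    # sample-level fallback for fully uncovered windows: global coverage-
    # weighted mean fraction (0.5 for a sample with no reads at all)
    total_cov = matrix.coverage.sum(axis=0)
    total_meth = matrix.methylated.sum(axis=0)
    global_mean = np.where(
        total_cov > 0, total_meth / np.maximum(total_cov, 1), 0.5
    )

    chroms = matrix.sites["chrom"].to_numpy()
    pos_all = matrix.sites["pos"].to_numpy()
    start = 0
    while start < n:
        end = start
        while end < n and chroms[end] == chroms[start]:
            end += 1
        pos = pos_all[start:end]
        if len(pos) < params.min_cpgs:
            exhausted[start:end] = True
        sm, fb = _smooth_chrom(
            pos,
            matrix.coverage[start:end],
            matrix.methylated[start:end],
            params,
            global_mean,
        )
        smoothed[start:end] = sm
        fallback[start:end] = fb
        start = end

    return SmoothedProfile(
        sites=matrix.sites,
        samples=list(matrix.samples),
        smoothed=smoothed,
        groups=dict(matrix.groups),
        fallback=fallback,
        exhausted=exhausted,
    )
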