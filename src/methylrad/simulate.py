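"""Synthetic inputs with known ground truth for every pipeline stage.

The bisulfite generator emulates a targeted-capture two-group design: CpG
positions from a renewal process (geometric gaps), a smooth baseline
methylation profile (logistic link over an autocorrelated latent walk, so
island/shore-like structure emerges), sample-level overdispersion via
Beta-distributed per-sample fractions (beta-binomial counts), Poisson
coverage, and planted differentially methylated intervals that shift the
second group's profile by +/- delta_pi.  Companion generators invert the
ELISA formula, plant known log2 fold changes in Ct tables, and draw outcome
values at a chosen population correlation with a measure, so parameter
recovery can be asserted end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DMR, MethylationMatrix
from .elisa import ElisaPlate

__all__ = [
    "SimulationConfig",
    "PlantedDMR",
    "GroundTruth",
    "RecoveryResult",
    "simulate_cpg_landscape",
    "simulate_methylation",
    "simulate_qpcr",
    "simulate_elisa",
    "simulate_outcomes",
    "evaluate_recovery",
    "interval_jaccard",
    "emit_fixture_dir",
]


@dataclass(frozen=True)
class PlantedDMR:
    """A planted differential interval (1-based inclusive CpG span)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    direction: str  # 'hyper' | 'hypo' (group 2 relative to group 1)
    delta_pi: float


@dataclass
class SimulationConfig:
    """Study conditions for the bisulfite generator.

    Defaults mirror the targeted two-group design the pipeline is built for:
    4 sham vs 4 irradiated samples, ~30x Poisson coverage (comfortably above
    the 10x retention filter), mild sample overdispersion (rho = 0.05) and
    planted DMRs of 10-30 CpGs shifting methylation by 0.3 — large enough
    that the >25% effect-size filter is exercised on both sides of its
    threshold once smoothing attenuates region edges.
    """

    n_chrom: int = 1
    chrom_length: int = 500_000
    mean_spacing: float = 100.0
    n_per_group: tuple[int, int] = (4, 4)
    group_labels: tuple[str, str] = ("sham", "irradiated")
    coverage_lambda: float = 30.0
    #: latent baseline process: logistic(mu + OU walk)
    baseline_mu: float = 0.0
    baseline_sd: float = 1.5
    baseline_corr_length: float = 2000.0
    n_dmrs: int = 20
    dmr_n_cpgs: tuple[int, int] = (10, 30)
    delta_pi: float = 0.3
    overdispersion: float = 0.05
    min_gap: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_lambda <= 0:
            raise ValueError("coverage_lambda must be > 0")
        if not 0 <= self.delta_pi <= 1:
            raise ValueError("delta_pi must lie in [0, 1]")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must lie in [0, 1)")
        if self.mean_spacing < self.min_gap:
            raise ValueError("mean CpG spacing must be >= the minimum gap")


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline's output."""

    dmrs: list[PlantedDMR] = field(default_factory=list)
    #: true per-group methylation profiles, keyed by group label
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_r: dict[str, float] = field(default_factory=dict)
    true_percent: dict[str, float] = field(default_factory=dict)
    true_slope: float | None = None


@dataclass
class RecoveryResult:
    sensitivity: float
    fdr: float
    matches: list[tuple[PlantedDMR, DMR, float]]
    no_calls: bool = False


def simulate_cpg_landscape(config: SimulationConfig) -> pd.DataFrame:
    """CpG positions per chromosome: cumulative geometric gaps, min 2 bp."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    frames = []
    # geometric on {0,1,...} shifted by min_gap so the mean matches
    p = 1.0 / (config.mean_spacing - config.min_gap + 1.0)
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        n_guess = int(2.5 * config.chrom_length / config.mean_spacing) + 10
        gaps = rng.geometric(p, size=n_guess) - 1 + config.min_gap
        pos = np.cumsum(gaps)
        pos = pos[pos <= config.chrom_length]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64)}))
    return pd.concat(frames, ignore_index=True)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _plant_intervals(
    sites: pd.DataFrame,
    pi0: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Choose disjoint member-index runs [i0, i1] plus a direction each.

    Runs are separated by at least 5 CpGs so neighbouring planted regions
    stay resolvable, and each is placed where the baseline can absorb the
    full +/- delta_pi shift without hitting the [0.02, 0.98] clamp — the
    recorded ground-truth effect size must be the effect actually planted.
    """
    n = len(sites)
    chosen: list[tuple[int, int, str]] = []
    occupied = np.zeros(n, dtype=bool)
    lo_w, hi_w = config.dmr_n_cpgs
    attempts = 0
    while len(chosen) < config.n_dmrs:
        attempts += 1
        if attempts > 500 * config.n_dmrs:
            raise ValueError("could not place the requested planted DMRs")
        width = int(rng.integers(lo_w, hi_w + 1))
        if width > n:
            raise ValueError("planted interval exceeds the chromosome")
        i0 = int(rng.integers(0, n - width + 1))
        i1 = i0 + width - 1
        pad_lo = max(0, i0 - 5)
        pad_hi = min(n, i1 + 6)
        if occupied[pad_lo:pad_hi].any():
            continue
        if sites["chrom"].iloc[i0] != sites["chrom"].iloc[i1]:
            continue
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        seg = pi0[i0 : i1 + 1]
        if direction == "hyper":
            fits = seg.max() + config.delta_pi <= 0.98
        else:
            fits = seg.min() - config.delta_pi >= 0.02
        if not fits:
            # try the opposite direction before giving up on the location
            direction = "hypo" if direction == "hyper" else "hyper"
            if direction == "hyper":
                fits = seg.max() + config.delta_pi <= 0.98
            else:
                fits = seg.min() - config.delta_pi >= 0.02
        if not fits:
            continue
        occupied[pad_lo:pad_hi] = True
        chosen.append((i0, i1, direction))
    chosen.sort()
    return chosen


def simulate_methylation(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, GroundTruth]:
    """Two-group beta-binomial count matrix with planted DMRs.

    Group profiles are clamped to [0.02, 0.98] so no site is degenerately
    all-methylated or all-unmethylated, which would break variance
    estimation downstream.
    """
    sites = simulate_cpg_landscape(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    n = len(sites)
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()

    # latent Ornstein-Uhlenbeck walk per chromosome -> smooth baseline
    z = np.empty(n)
    start = 0
    while start < n:
        end = start
        while end < n and chroms[end] == chroms[start]:
            end += 1
        z[start] = rng.normal(0.0, config.baseline_sd)
        for i in range(start + 1, end):
            rho = np.exp(-(pos[i] - pos[i - 1]) / config.baseline_corr_length)
            z[i] = rho * z[i - 1] + np.sqrt(1 - rho**2) * rng.normal(
                0.0, config.baseline_sd
            )
        start = end
    pi0 = np.clip(_expit(config.baseline_mu + z), 0.02, 0.98)

    pi1 = pi0.copy()
    planted: list[PlantedDMR] = []
    if config.n_dmrs > 0 and config.delta_pi > 0:
        for i0, i1, direction in _plant_intervals(sites, pi0, config, rng):
            shift = config.delta_pi if direction == "hyper" else -config.delta_pi
            pi1[i0 : i1 + 1] = np.clip(pi0[i0 : i1 + 1] + shift, 0.02, 0.98)
            planted.append(
                PlantedDMR(
                    chrom=str(chroms[i0]),
                    start=int(pos[i0]),
                    end=int(pos[i1]),
                    n_cpgs=i1 - i0 + 1,
                    direction=direction,
                    delta_pi=config.delta_pi,
                )
            )

    g1, g2 = config.group_labels
    n1, n2 = config.n_per_group
    samples = [f"{g1}_{i + 1}" for i in range(n1)] + [f"{g2}_{i + 1}" for i in range(n2)]
    groups = {s: (g1 if i < n1 else g2) for i, s in enumerate(samples)}
    profile = {g1: pi0, g2: pi1}

    coverage = np.empty((n, len(samples)), dtype=np.int64)
    methylated = np.empty_like(coverage)
    rho = config.overdispersion
    for j, s in enumerate(samples):
        mean = profile[groups[s]]
        if rho > 0:
            a = mean * (1 - rho) / rho
            b = (1 - mean) * (1 - rho) / rho
            frac = rng.beta(a, b)
        else:
            frac = mean
        cov = rng.poisson(config.coverage_lambda, size=n)
        coverage[:, j] = cov
        methylated[:, j] = rng.binomial(cov, frac)

    matrix = MethylationMatrix(sites, samples, coverage, methylated, groups)
    truth = GroundTruth(dmrs=planted, profiles={g1: pi0, g2: pi1})
    return matrix, truth


def simulate_qpcr(
    genes: dict[str, float],
    n_per_group: int = 6,
    ct_noise: float = 0.1,
    seed: int = 0,
    reference: str = "PHLPP1",
    case_group: str = "irradiated",
    control_group: str = "sham",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table with known log2 fold changes.

    Control-sample dCt ~ N(mu_g, sigma); case dCt = mu_g - log2fc + noise;
    the reference gene's Ct is constant so target Ct = ref Ct + dCt.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if ct_noise < 0:
        raise ValueError("ct_noise must be >= 0")
    rng = np.random.default_rng(seed)
    ref_ct = 20.0
    rows = []
    samples = [(f"{control_group}_{i + 1}", control_group) for i in range(n_per_group)]
    samples += [(f"{case_group}_{i + 1}", case_group) for i in range(n_per_group)]
    for gene, log2fc in genes.items():
        mu = float(rng.uniform(3.0, 8.0))  # gene-specific baseline dCt
        for sample, grp in samples:
            base = mu if grp == control_group else mu - log2fc
            dct = base + rng.normal(0.0, ct_noise)
            rows.append((sample, grp, gene, ref_ct + dct))
    for sample, grp in samples:
        rows.append((sample, grp, reference, ref_ct))
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    truth = GroundTruth(true_log2fc=dict(genes))
    return table, truth


def simulate_elisa(
    true_percent: Sequence[float] | dict[str, float],
    slope: float = 0.05,
    nc_od: float = 0.05,
    od_noise: float = 0.0,
    dna_ng: float = 100.0,
    seed: int = 0,
    standard_amounts: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0),
) -> tuple[ElisaPlate, GroundTruth]:
    """A plate whose ODs invert the kit formula at the given truth.

    With ``od_noise`` 0 the quantification round-trips exactly:
    od = nc_od + slope * dna_ng * percent / 100.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    if not isinstance(true_percent, dict):
        true_percent = {f"s{i + 1}": float(v) for i, v in enumerate(true_percent)}
    standards = [
        (float(a), nc_od + slope * float(a) + rng.normal(0.0, od_noise))
        for a in standard_amounts
    ]
    samples = [
        (
            sid,
            nc_od + slope * dna_ng * pct / 100.0 + rng.normal(0.0, od_noise),
            float(dna_ng),
        )
        for sid, pct in true_percent.items()
    ]
    plate = ElisaPlate(standards=standards, nc_od=nc_od, samples=samples)
    truth = GroundTruth(true_percent=dict(true_percent), true_slope=float(slope))
    return plate, truth


def simulate_outcomes(
    measures: pd.Series,
    true_r: float,
    seed: int = 0,
    outcome_name: str = "GLS",
    outcome_mean: float = -20.0,
    outcome_sd: float = 3.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Outcome values at population correlation ``true_r`` with a measure.

    Drawn from the conditional normal: y = mu + sd * (r * z_x + sqrt(1-r^2)
    * eps) where z_x is the standardised measure.
    """
    if abs(true_r) > 1:
        raise ValueError("|true_r| must be <= 1")
    x = measures.to_numpy(dtype=float)
    sd_x = x.std()
    if np.isclose(sd_x, 0) and true_r != 0:
        raise ValueError("constant measures cannot carry a nonzero correlation")
    z = (x - x.mean()) / sd_x if sd_x > 0 else np.zeros_like(x)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=len(x))
    y = outcome_mean + outcome_sd * (true_r * z + np.sqrt(1 - true_r**2) * eps)
    out = pd.DataFrame(
        {"subject": measures.index.astype(str), "outcome": outcome_name, "value": y}
    )
    truth = GroundTruth(true_r={outcome_name: float(true_r)})
    return out, truth


def interval_jaccard(
    a: tuple[int, int], b: tuple[int, int]
) -> float:
    """Jaccard of two 1-based inclusive bp intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


def evaluate_recovery(
    called: Sequence[DMR],
    truth: GroundTruth | Sequence[PlantedDMR],
    jaccard_min: float = 0.5,
) -> RecoveryResult:
    """Score called DMRs against planted intervals.

    A planted DMR is recovered when a called DMR reaches interval Jaccard >=
    ``jaccard_min`` with it; matching is one-to-one greedy by descending
    Jaccard.  Sensitivity = recovered / planted; observed FDR = unmatched
    called / called (0 with a flag when there are no calls).
    """
    planted = truth.dmrs if isinstance(truth, GroundTruth) else list(truth)
    if not called:
        return RecoveryResult(
            sensitivity=0.0 if planted else 1.0, fdr=0.0, matches=[], no_calls=True
        )
    pairs = []
    for pi, p in enumerate(planted):
        for ci, c in enumerate(called):
            if c.chrom != p.chrom:
                continue
            j = interval_jaccard((p.start, p.end), (c.start, c.end))
            if j >= jaccard_min:
                pairs.append((j, pi, ci))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_c: set[int] = set()
    matches: list[tuple[PlantedDMR, DMR, float]] = []
    for j, pi, ci in pairs:
        if pi in used_p or ci in used_c:
            continue
        used_p.add(pi)
        used_c.add(ci)
        matches.append((planted[pi], called[ci], j))
    sensitivity = len(used_p) / len(planted) if planted else 1.0
    fdr = (len(called) - len(used_c)) / len(called)
    return RecoveryResult(sensitivity=sensitivity, fdr=fdr, matches=matches)


def emit_fixture_dir(
    config: SimulationConfig,
    out_dir: str | Path,
    genes_log2fc: dict[str, float] | None = None,
    elisa_percent: Sequence[float] | None = None,
    outcome_r: float = 0.9,
) -> Path:
    """Write a complete synthetic input set for the CLI / worked examples.

    Emits per-sample Bismark coverage files, a sample sheet, a random
    non-overlapping gene BED, a qPCR Ct table, an ELISA plate, an outcome
    table and ``ground_truth.json``.
    """
    from .io import (
        write_bismark_coverage,
        write_elisa_csv,
        write_gene_bed,
        write_sample_sheet,
    )
    from .core import GeneAnnotation

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_methylation(config)
    paths = write_bismark_coverage(matrix, out_dir / "coverage")
    sheet = pd.DataFrame(
        {
            "sample": matrix.samples,
            "group": [matrix.groups[s] for s in matrix.samples],
            "dose_gy": [
                0.0 if matrix.groups[s] == config.group_labels[0] else 27.6
                for s in matrix.samples
            ],
            "time_months": 1.5,
            "path": [str(paths[s].relative_to(out_dir)) for s in matrix.samples],
        }
    )
    write_sample_sheet(sheet, out_dir / "samples.csv")

    # random non-overlapping genes tiling each chromosome
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    rows = []
    gid = 0
    for chrom, sub in matrix.sites.groupby("chrom", sort=False):
        cursor = 0
        limit = int(sub["pos"].max())
        while cursor < limit:
            gap = int(rng.integers(500, 5000))
            length = int(rng.integers(1000, 20000))
            start = cursor + gap
            if start >= limit:
                break
            end = min(start + length, limit + 1000)
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, end, f"gene{gid:04d}", strand))
            cursor = end
    genes = GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    )
    write_gene_bed(genes, out_dir / "genes.bed")

    genes_log2fc = genes_log2fc or {"SLMAP": 1.7, "E2F6": 0.8, "ITPR2": 0.0}
    qpcr_table, qpcr_truth = simulate_qpcr(genes_log2fc, seed=config.seed)
    qpcr_table.to_csv(out_dir / "qpcr.csv", index=False)
    truth.true_log2fc = qpcr_truth.true_log2fc

    elisa_percent = list(
        elisa_percent
        if elisa_percent is not None
        else np.round(np.linspace(2.0, 6.0, 8), 3)
    )
    plate, elisa_truth = simulate_elisa(
        elisa_percent, od_noise=0.01, seed=config.seed
    )
    write_elisa_csv(plate, out_dir / "elisa.csv")
    truth.true_percent = elisa_truth.true_percent
    truth.true_slope = elisa_truth.true_slope

    measures = pd.Series(
        elisa_truth.true_percent, name="five_mc_percent", dtype=float
    )
    outcomes, out_truth = simulate_outcomes(measures, outcome_r, seed=config.seed)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    truth.true_r = out_truth.true_r

    payload = {
        "config": asdict(config),
        "planted_dmrs": [asdict(d) for d in truth.dmrs],
        "true_log2fc": truth.true_log2fc,
        "true_percent": truth.true_percent,
        "true_slope": truth.true_slope,
        "true_r": truth.true_r,
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return out_dir
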