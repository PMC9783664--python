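"""Readers and writers for the plain-text formats the pipeline touches.

Bismark coverage files are 6-column TSV with 1-based inclusive coordinates:
``chrom  start  end  methylation%  count_methylated  count_unmethylated``.
DMRs are written as BED6+ (0-based half-open); gene annotations are read from
BED4/BED6.  Sample sheets, qPCR tables and outcome tables are CSV; ELISA
plates use a small sectioned CSV layout (see :func:`read_elisa_csv`).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DMR,
    GeneAnnotation,
    MethylationMatrix,
    SAMPLE_SHEET_COLUMNS,
    validate_sample_sheet,
)
from .elisa import ElisaPlate

__all__ = [
    "ParseError",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_bed",
    "write_gene_bed",
    "write_dmr_bed",
    "read_dmr_bed",
    "read_qpcr_csv",
    "read_elisa_csv",
    "write_elisa_csv",
    "read_outcomes_csv",
]

_BISMARK_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


def _read_one_coverage(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start = int(parts[1])
                pct = float(parts[3])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start < 1 or meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative or zero-based coordinate/count")
            rows.append((chrom, start, pct, meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "pct", "meth", "unmeth"])
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ParseError(f"{path}: duplicate site {first['chrom']}:{first['pos']}")
    cov = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(cov > 0, 100.0 * df["meth"] / np.maximum(cov, 1), 0.0)
    bad = np.abs(implied - df["pct"].to_numpy()) > 0.5
    bad &= cov.to_numpy() > 0
    if bad.any():
        warnings.warn(
            f"{path}: methylation%% inconsistent with counts at {int(bad.sum())} "
            "site(s) by >0.5; counts win",
            stacklevel=3,
        )
    return df[["chrom", "pos", "meth", "unmeth"]]


def read_bismark_coverage(
    paths: Mapping[str, str | Path] | Sequence[str | Path],
    sheet: pd.DataFrame,
) -> MethylationMatrix:
    """Union per-sample Bismark coverage files into a :class:`MethylationMatrix`.

    ``paths`` maps sample id -> file, or is a sequence aligned with the sheet's
    sample order.  Sites absent from a sample get coverage 0 (downstream
    filters decide retention).  Coverage = methylated + unmethylated counts.
    """
    sheet = validate_sample_sheet(sheet)
    samples = sheet["sample"].astype(str).tolist()
    if isinstance(paths, Mapping):
        path_map = {str(k): Path(v) for k, v in paths.items()}
        missing = [s for s in samples if s not in path_map]
        if missing:
            raise ValueError(f"no coverage file given for samples: {missing}")
    else:
        paths = list(paths)
        if len(paths) != len(samples):
            raise ValueError("paths sequence length must match the sample sheet")
        path_map = dict(zip(samples, map(Path, paths)))

    per_sample = {s: _read_one_coverage(path_map[s]) for s in samples}
    all_sites = (
        pd.concat([df[["chrom", "pos"]] for df in per_sample.values()])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(all_sites)
    n = len(all_sites)
    coverage = np.zeros((n, len(samples)), dtype=np.int64)
    methylated = np.zeros_like(coverage)
    for j, s in enumerate(samples):
        df = per_sample[s]
        loc = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        methylated[loc, j] = df["meth"].to_numpy()
        coverage[loc, j] = (df["meth"] + df["unmeth"]).to_numpy()
    groups = dict(zip(samples, sheet["group"].astype(str)))
    return MethylationMatrix(all_sites, samples, coverage, methylated, groups)


def write_bismark_coverage(matrix: MethylationMatrix, directory: str | Path) -> dict[str, Path]:
    """Write one coverage file per sample (sites with coverage 0 omitted)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    chrom = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for j, s in enumerate(matrix.samples):
        cov = matrix.coverage[:, j]
        meth = matrix.methylated[:, j]
        keep = cov > 0
        path = directory / f"{s}.cov"
        with open(path, "w") as fh:
            for c, p, m, u in zip(
                chrom[keep], pos[keep], meth[keep], (cov - meth)[keep]
            ):
                pct = 100.0 * m / (m + u)
                fh.write(f"{c}\t{p}\t{p}\t{pct:.6g}\t{m}\t{u}\n")
        out[s] = path
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample": str, "group": str, "path": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet)[list(SAMPLE_SHEET_COLUMNS)].to_csv(path, index=False)


def read_gene_bed(path: str | Path) -> GeneAnnotation:
    """Read gene intervals from BED4/BED6 (sorted on output, no merging)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns (name required)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = parts[3]
            if not name:
                raise ParseError(f"{path}:{lineno}: empty gene name")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((parts[0], start, end, name, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    )


def write_gene_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in annotation.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


_DMR_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tdirection\tmean_diff\tn_cpgs\tp\tq"


def write_dmr_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """Write DMRs as BED6+ (0-based half-open), sorted by (chrom, start).

    Score column carries the area statistic; extra columns hold direction,
    mean smoothed difference, CpG count and permutation p / BH q ('NA' when
    unset).  An empty DMR list yields a header-only file.
    """
    ordered = sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    with open(path, "w") as fh:
        fh.write(_DMR_HEADER + "\n")
        for i, d in enumerate(ordered):
            name = d.id if d.id is not None else f"dmr_{i + 1:05d}"
            p = "NA" if d.p is None else repr(float(d.p))
            q = "NA" if d.q is None else repr(float(d.q))
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\t{d.area!r}\t.\t"
                f"{d.direction}\t{d.mean_diff!r}\t{d.n_cpgs}\t{p}\t{q}\n"
            )


def read_dmr_bed(path: str | Path) -> list[DMR]:
    dmrs: list[DMR] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 11:
                raise ParseError(f"{path}:{lineno}: expected 11 columns, got {len(parts)}")
            try:
                dmrs.append(
                    DMR(
                        chrom=parts[0],
                        start=int(parts[1]) + 1,
                        end=int(parts[2]),
                        n_cpgs=int(parts[8]),
                        direction=parts[6],
                        mean_diff=float(parts[7]),
                        area=float(parts[4]),
                        p=None if parts[9] == "NA" else float(parts[9]),
                        q=None if parts[10] == "NA" else float(parts[10]),
                        id=parts[3],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return dmrs


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample,group,gene,ct[,rep]."""
    df = pd.read_csv(path, dtype={"sample": str, "group": str, "gene": str})
    required = ["sample", "group", "gene", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: qPCR table missing columns {missing}")
    if (df["ct"] <= 0).any() or not np.isfinite(df["ct"]).all():
        raise ParseError(f"{path}: Ct values must be finite and > 0")
    return df


def write_qpcr_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_elisa_csv(path: str | Path) -> ElisaPlate:
    """Read a sectioned ELISA plate CSV.

    Layout::

        [standards]
        amount_ng,od
        1,0.12
        [controls]
        nc_od
        0.02
        [samples]
        id,od,dna_ng
        s1,0.5,100
    """
    section = None
    header: list[str] | None = None
    standards: list[tuple[float, float]] = []
    nc_od: float | None = None
    samples: list[tuple[str, float, float]] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            first = row[0].strip()
            if first.startswith("["):
                section = first.strip("[]").lower()
                header = None
                continue
            if header is None:
                header = [c.strip() for c in row]
                continue
            try:
                if section == "standards":
                    standards.append((float(row[0]), float(row[1])))
                elif section == "controls":
                    nc_od = float(row[0])
                elif section == "samples":
                    samples.append((row[0].strip(), float(row[1]), float(row[2])))
                else:
                    raise ParseError(f"{path}:{lineno}: row outside a known section")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if nc_od is None:
        raise ParseError(f"{path}: no [controls] nc_od found")
    return ElisaPlate(standards=standards, nc_od=nc_od, samples=samples)


def write_elisa_csv(plate: ElisaPlate, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["[standards]"])
        w.writerow(["amount_ng", "od"])
        for amount, od in plate.standards:
            w.writerow([repr(float(amount)), repr(float(od))])
        w.writerow(["[controls]"])
        w.writerow(["nc_od"])
        w.writerow([repr(float(plate.nc_od))])
        w.writerow(["[samples]"])
        w.writerow(["id", "od", "dna_ng"])
        for sid, od, dna in plate.samples:
            w.writerow([sid, repr(float(od)), repr(float(dna))])


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    """Read an outcome table CSV with columns subject,outcome,value[,...]."""
    df = pd.read_csv(path, dtype={"subject": str, "outcome": str})
    required = ["subject", "outcome", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: outcome table missing columns {missing}")
    if df.duplicated(subset=["subject", "outcome"]).any():
        raise ParseError(f"{path}: duplicate (subject, outcome) rows")
    if not np.isfinite(df["value"]).all():
        raise ParseError(f"{path}: outcome values must be finite")
    return df
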