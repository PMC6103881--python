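"""Readers and writers for the package's text surfaces.

Formats: BED3+ (tab-separated, 0-based half-open) for intervals and summits,
bedGraph-like probe tables (chrom, start, end, log2), two-column chrom-sizes
TSV for the genome layout, and headered TSV transcript tables.  A
``one_based`` flag on the readers shifts 1-based inclusive input back to the
internal convention.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet, PointSet
from .probes import ProbeProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_points",
    "write_points",
    "read_probe_table",
    "write_probe_table",
    "read_transcripts",
    "write_transcripts",
]

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: str | Path):
    """Yield (lineno, fields) skipping comments/track lines with a notice."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                logger.info("%s:%d: skipping header line %r", path, lineno, line[:40])
                continue
            yield lineno, line.split("\t")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            chroms[fields[0]] = int(fields[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed length {fields[1]!r}") from None
    return GenomeLayout(chroms)


def write_chrom_sizes(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


def _parse_bed_rows(path, genome, one_based):
    shift = 1 if one_based else 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start = int(fields[1]) - shift
            end = int(fields[2]) - shift + (1 if one_based else 0)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: malformed coordinates {fields[1]!r}/{fields[2]!r}"
            ) from None
        if genome is not None and chrom not in genome.chromosomes:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        yield chrom, start, end


def read_bed(
    path: str | Path,
    genome: GenomeLayout | None = None,
    one_based: bool = False,
) -> IntervalSet:
    """Read a BED3+ file into a normalized :class:`IntervalSet`.

    With ``one_based=True`` the input is treated as 1-based inclusive and
    shifted onto the 0-based half-open convention.
    """
    ivs = IntervalSet.from_records(_parse_bed_rows(path, genome, one_based))
    if genome is not None:
        ivs.check_within(genome)
    return ivs


def write_bed(
    intervals: IntervalSet,
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        if names is None:
            for chrom, start, end in intervals.to_records():
                fh.write(f"{chrom}\t{start}\t{end}\n")
        else:
            for (chrom, start, end), name in zip(intervals.to_records(), names):
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_points(
    path: str | Path,
    genome: GenomeLayout | None = None,
    one_based: bool = False,
) -> PointSet:
    """Read peak summits from BED.

    1-bp records give the summit directly; wider records contribute their
    (floored) midpoint.
    """
    records = []
    for chrom, start, end in _parse_bed_rows(path, genome, one_based):
        if end <= start:
            raise ValueError(f"{path}: empty interval {chrom}:{start}-{end}")
        records.append((chrom, start + (end - start) // 2))
    return PointSet.from_records(records)


def write_points(points: PointSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in points.items():
            for p in arr:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def read_probe_table(
    path: str | Path, genome: GenomeLayout | None = None
) -> ProbeProfile:
    """Read a bedGraph-like probe table (chrom, start, end, log2 ratio)."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: probe table needs 4 columns")
        chrom = fields[0]
        if genome is not None and chrom not in genome.chromosomes:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            rows.append((chrom, int(fields[1]), float(fields[3])))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed probe record") from None
    df = pd.DataFrame(rows, columns=["chrom", "pos", "log2_raw"])
    return ProbeProfile(df)


def write_probe_table(profile: ProbeProfile, path: str | Path,
                      col: str = "log2_raw") -> None:
    df = profile.df
    with open(path, "w") as fh:
        for chrom, pos, val in zip(df["chrom"], df["pos"], df[col]):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val:.6g}\n")


def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV transcript table.

    Required columns: ``transcript_id``, ``chrom``, ``tss``, ``strand``; every
    further column is a per-tissue FPKM column.  Replicate columns named
    ``<tissue>_rep<k>`` are averaged into a single ``<tissue>`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["transcript_id", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: transcript table missing columns {missing}")
    fpkm_cols = [c for c in df.columns if c not in required]
    rep_groups: dict[str, list[str]] = {}
    for c in fpkm_cols:
        if "_rep" in c:
            tissue = c.rsplit("_rep", 1)[0]
            rep_groups.setdefault(tissue, []).append(c)
    for tissue, cols in rep_groups.items():
        df[tissue] = df[cols].mean(axis=1)
        df = df.drop(columns=cols)
    if (df[[c for c in df.columns if c not in required]] < 0).any().any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def write_transcripts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
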