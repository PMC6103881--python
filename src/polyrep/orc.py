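"""ORC-centric analyses: summit sharing across tissues, density in UR vs
fully replicated regions, the random-placement depletion test, ORC-free
zones around UR midpoints, and low-density ORC domain mapping by sliding
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GInterval, IntervalSet, PointSet, merge_within

__all__ = [
    "ORCFreeZone",
    "PermutationResult",
    "share_classes",
    "orc_density",
    "depletion_test",
    "orc_free_zone",
    "low_density_domains",
    "urs_with_orc",
]


@dataclass
class ORCFreeZone:
    """Nearest ORC summits flanking a UR midpoint.

    The summit strictly left of the midpoint and the first summit at or right
    of it (half-open convention: a summit exactly at the midpoint counts as
    the right site).  A side with no summit on that chromosome is ``None``
    and the zone width undefined.
    """

    ur: GInterval
    left_site: int | None
    right_site: int | None

    @property
    def zone_width(self) -> int | None:
        if self.left_site is None or self.right_site is None:
            return None
        return self.right_site - self.left_site


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    alternative: str


def share_classes(
    peak_sets: list[tuple[str, PointSet]], radius: int = 1_000
) -> pd.DataFrame:
    """Cluster pooled summits across tissues; summits within ``radius`` bp are
    treated as the same site (single linkage, so clusters chain).

    Returns one row per cluster: chrom, span, the sorted tuple of tissues
    present, and ``n_shared`` = number of *other* tissues sharing the site.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets")
    names = [n for n, _ in peak_sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    rows = []
    for name, pts in peak_sets:
        for chrom, arr in pts.items():
            for p in arr:
                rows.append((chrom, int(p), name))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "tissue"])
    clusters = []
    for chrom, sub in df.sort_values(["chrom", "pos"]).groupby("chrom"):
        pos = sub["pos"].to_numpy()
        tissues = sub["tissue"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > radius)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            present = sorted(set(tissues[s:e]))
            clusters.append(
                {
                    "chrom": chrom,
                    "start": int(pos[s]),
                    "end": int(pos[e - 1]) + 1,
                    "tissues": tuple(present),
                    "n_tissues": len(present),
                    "n_shared": len(present) - 1,
                }
            )
    return pd.DataFrame(clusters)


def orc_density(peaks: PointSet, regions: IntervalSet) -> float:
    """Summits falling in ``regions`` per 100 kb of region coverage."""
    cov = regions.coverage_bp
    if cov == 0:
        raise ValueError("regions have zero coverage")
    return peaks.count_in(regions) * 100_000.0 / cov


def _random_placement_counts(
    rng: np.random.Generator,
    peaks: PointSet,
    urs: IntervalSet,
    genome: GenomeLayout,
    n_perm: int,
) -> np.ndarray:
    """Null totals: every UR re-placed uniformly within its own chromosome
    (width preserved, overlaps permitted)."""
    totals = np.zeros(n_perm, dtype=np.int64)
    for chrom, arr in urs.items():
        length = genome.length_of(chrom)
        widths = arr[:, 1] - arr[:, 0]
        if np.any(widths > length):
            raise ValueError(f"UR wider than chromosome {chrom!r}")
        pts = peaks.get(chrom)
        highs = length - widths + 1
        starts = (rng.random((n_perm, len(widths))) * highs).astype(np.int64)
        if len(pts) == 0:
            continue
        counts = np.searchsorted(pts, starts + widths) - np.searchsorted(pts, starts)
        totals += counts.sum(axis=1)
    return totals


def depletion_test(
    peaks: PointSet,
    urs: IntervalSet,
    genome: GenomeLayout,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "depletion",
) -> PermutationResult:
    """Are there fewer summits inside the URs than random placement expects?

    Each permutation re-places every UR uniformly at random within its own
    chromosome (widths preserved, overlaps among placed regions permitted)
    and totals the summits covered.  The empirical p-value uses the add-one
    estimator, so it is never 0 and its floor is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    urs.check_within(genome)
    rng = np.random.default_rng(seed)
    observed = peaks.count_in(urs)
    null = _random_placement_counts(rng, peaks, urs, genome, n_perm)
    if alternative == "depletion":
        extreme = int((null <= observed).sum())
    elif alternative == "enrichment":
        extreme = int((null >= observed).sum())
    else:
        raise ValueError("alternative must be 'depletion' or 'enrichment'")
    return PermutationResult(
        observed=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=(1 + extreme) / (n_perm + 1),
        n_perm=n_perm,
        alternative=alternative,
    )


def orc_free_zone(ur: GInterval, peaks: PointSet) -> ORCFreeZone:
    """Distance between the nearest ORC summits flanking the UR midpoint."""
    mid = ur.midpoint
    pts = peaks.get(ur.chrom)
    i = int(np.searchsorted(pts, mid, side="left"))
    left = int(pts[i - 1]) if i > 0 else None
    right = int(pts[i]) if i < len(pts) else None
    return ORCFreeZone(ur=ur, left_site=left, right_site=right)


def low_density_domains(
    peaks: PointSet,
    genome: GenomeLayout,
    window: int = 150_000,
    step: int = 75_000,
    max_peaks: int = 1,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Low-density ORC domains from overlapping sliding windows.

    Windows of ``window`` bp every ``step`` bp (anchored at 0, trailing
    partial window kept) with at most ``max_peaks`` summits are merged
    (overlapping or adjacent) into domains.  Returns the domains and a table
    with per-domain summit counts.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    kept = []
    for chrom, length in genome.chromosomes.items():
        pts = peaks.get(chrom)
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        counts = np.searchsorted(pts, ends) - np.searchsorted(pts, starts)
        for s, e in zip(starts[counts <= max_peaks], ends[counts <= max_peaks]):
            kept.append((chrom, int(s), int(e)))
    domains = merge_within(IntervalSet.from_records(kept), 0)
    rows = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
         "n_peaks": int(peaks.counts_per_interval(
             IntervalSet.from_intervals([iv]))[0])}
        for iv in domains
    ]
    return domains, pd.DataFrame(rows, columns=["chrom", "start", "end", "n_peaks"])


def urs_with_orc(urs: IntervalSet, peaks: PointSet) -> tuple[float, list[GInterval]]:
    """Fraction of URs containing at least one summit, and which they are."""
    if len(urs) == 0:
        raise ValueError("empty UR set")
    counts = peaks.counts_per_interval(urs)
    occupied = [iv for iv, c in zip(urs, counts) if c > 0]
    return len(occupied) / len(urs), occupied
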