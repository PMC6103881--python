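"""Interval-correlation statistics.

Jaccard index (bp intersection over union), the midpoint projection test
(binomial or permutation form), a width-preserving placement permutation test
for overlap counts (the TAD-style comparison), UR-vs-TAD containment
classification, and summit-per-region summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeLayout, IntervalSet, PointSet
from .orc import PermutationResult

__all__ = [
    "OverlapResult",
    "TADClassification",
    "jaccard",
    "projection_test",
    "placement_permutation_test",
    "classify_vs_tads",
    "peaks_per_region",
]


@dataclass
class OverlapResult:
    jaccard: float | None
    projection_stat: float  # observed fraction of query midpoints in reference
    projection_expected: float  # reference coverage fraction of the genome
    projection_p: float
    mode: str
    n_perm: int | None = None


@dataclass
class PermResultWithNull(PermutationResult):
    null_counts: np.ndarray | None = None


@dataclass
class TADClassification:
    labels: pd.DataFrame  # chrom, start, end, label
    counts: dict[str, int]

    @property
    def fractions(self) -> dict[str, float]:
        n = sum(self.counts.values())
        return {k: v / n for k, v in self.counts.items()} if n else {}


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """coverage(a ∩ b) / coverage(a ∪ b); symmetric; undefined if both empty."""
    union = a.union(b).coverage_bp
    if union == 0:
        raise ValueError("Jaccard undefined: both sets empty")
    return a.intersect(b).coverage_bp / union


def _global_boundaries(reference: IntervalSet, genome: GenomeLayout) -> np.ndarray:
    """Interval boundaries on the concatenated-genome coordinate axis."""
    offsets = {}
    total = 0
    for chrom, length in genome.chromosomes.items():
        offsets[chrom] = total
        total += length
    bounds = []
    for chrom, arr in reference.items():
        off = offsets[chrom]
        bounds.append(arr.astype(np.int64).ravel() + off)
    if not bounds:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(bounds))


def _in_reference(bounds: np.ndarray, global_pos: np.ndarray) -> np.ndarray:
    return np.searchsorted(bounds, global_pos, side="right") % 2 == 1


def _two_sided_empirical(null: np.ndarray, observed: float) -> float:
    n = len(null)
    p_lo = (1 + int((null <= observed).sum())) / (n + 1)
    p_hi = (1 + int((null >= observed).sum())) / (n + 1)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def projection_test(
    query: IntervalSet,
    reference: IntervalSet,
    genome: GenomeLayout,
    mode: str = "analytic",
    n_perm: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Do query midpoints fall inside the reference more (or less) often than
    its genome coverage fraction predicts?

    The statistic is the fraction of query-interval midpoints inside the
    reference; its null is Binomial(n_query, coverage fraction).  Analytic
    mode doubles the smaller binomial tail (capped at 1); permutation mode
    re-places the midpoints uniformly on the genome ``n_perm`` times and uses
    the two-sided add-one empirical p.
    """
    if len(query) == 0:
        raise ValueError("query set is empty")
    cov = reference.coverage_bp
    total = genome.total_length
    if cov == 0 or cov >= total:
        raise ValueError("reference covers none or all of the genome: test degenerate")
    reference.check_within(genome)
    query.check_within(genome)

    mids = query.midpoints()
    n = len(mids)
    k = sum(
        1
        for chrom, m in mids
        if reference.contains_points(chrom, np.array([m]))[0]
    )
    expected = cov / total
    if mode == "analytic":
        p_lo = sps.binom.cdf(k, n, expected)
        p_hi = sps.binom.sf(k - 1, n, expected)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        n_perm_out = None
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        bounds = _global_boundaries(reference, genome)
        draws = (rng.random((n_perm, n)) * total).astype(np.int64)
        null = _in_reference(bounds, draws).sum(axis=1)
        p = _two_sided_empirical(null, k)
        n_perm_out = n_perm
    else:
        raise ValueError("mode must be 'analytic' or 'permutation'")
    return OverlapResult(
        jaccard=None,
        projection_stat=k / n,
        projection_expected=expected,
        projection_p=float(p),
        mode=mode,
        n_perm=n_perm_out,
    )


def placement_permutation_test(
    query: IntervalSet,
    reference: IntervalSet,
    genome: GenomeLayout,
    n_iter: int = 10_000,
    seed: int = 0,
) -> PermResultWithNull:
    """Overlap-count significance by width-preserving random placement.

    The observed statistic is the number of query intervals overlapping at
    least one reference interval.  Each iteration re-places all query
    intervals uniformly within their own chromosomes (widths preserved,
    overlaps permitted); the p-value is the add-one upper-tail (enrichment)
    probability.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    query.check_within(genome)
    reference.check_within(genome)
    rng = np.random.default_rng(seed)

    observed = 0
    null = np.zeros(n_iter, dtype=np.int64)
    for chrom, arr in query.items():
        length = genome.length_of(chrom)
        ref = reference.get(chrom)
        widths = arr[:, 1] - arr[:, 0]
        if np.any(widths > length):
            raise ValueError(f"query interval wider than chromosome {chrom!r}")
        starts_obs = arr[:, 0]
        observed += int(_overlaps_any(ref, starts_obs, widths).sum())
        highs = length - widths + 1
        starts = (rng.random((n_iter, len(widths))) * highs).astype(np.int64)
        null += _overlaps_any(ref, starts, widths).sum(axis=-1)
    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    return PermResultWithNull(
        observed=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_value=float(p),
        n_perm=n_iter,
        alternative="enrichment",
        null_counts=null,
    )


def _overlaps_any(ref: np.ndarray, starts: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Does [start, start+width) overlap any reference interval?"""
    if len(ref) == 0:
        return np.zeros(np.shape(starts), dtype=bool)
    ends = starts + widths
    idx = np.searchsorted(ref[:, 1], starts, side="right")
    ok = idx < len(ref)
    out = np.zeros(np.shape(starts), dtype=bool)
    out[ok] = ref[np.minimum(idx[ok], len(ref) - 1), 0] < ends[ok]
    return out


def classify_vs_tads(urs: IntervalSet, tads: IntervalSet) -> TADClassification:
    """Label each UR: ``within`` one TAD, ``outside`` all TADs, or
    ``crosses_boundary`` (partial overlap or spanning two TADs)."""
    rows = []
    counts = {"within": 0, "crosses_boundary": 0, "outside": 0}
    for iv in urs:
        arr = tads.get(iv.chrom)
        label = "outside"
        if len(arr):
            idx = np.searchsorted(arr[:, 1], iv.start, side="right")
            overlapping = idx < len(arr) and arr[idx, 0] < iv.end
            if overlapping:
                contained = arr[idx, 0] <= iv.start and iv.end <= arr[idx, 1]
                label = "within" if contained else "crosses_boundary"
        rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "label": label})
        counts[label] += 1
    return TADClassification(
        labels=pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
        counts=counts,
    )


def peaks_per_region(
    regions: IntervalSet, peaks: PointSet
) -> tuple[float, float | None, np.ndarray]:
    """(fraction of regions with >= 1 summit, mean count among those regions,
    per-region counts).  The mean is ``None`` when no region has a summit."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    counts = peaks.counts_per_interval(regions)
    nonzero = counts[counts > 0]
    frac = len(nonzero) / len(counts)
    mean_nonzero = float(nonzero.mean()) if len(nonzero) else None
    return frac, mean_nonzero, counts
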