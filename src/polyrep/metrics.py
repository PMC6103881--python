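"""UR geometry and cross-tissue specificity.

Each called UR is re-profiled in a window of twice its width: the probes are
re-smoothed onto a 10-nt grid, the curve minimum gives the maximal fold
underreplication (2^−min log2), and walking outward from the minimum to the
first grid point at half the minimum log2 gives the half-min width — an FWHM
analogue on the copy-number profile.  Specificity accounting clusters URs
across tissues by any-overlap single linkage and tallies base pairs shared
vs. tissue-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, GInterval, IntervalSet
from .probes import ProbeProfile
from .smoothing import local_linear_smooth

__all__ = [
    "URProfile",
    "SpecificityTable",
    "profile_ur",
    "average_replicates",
    "specificity_matrix",
    "width_depth_relation",
]


@dataclass
class URProfile:
    """Geometry of one UR dip measured on the re-smoothed profile."""

    ur: GInterval
    min_log2: float
    min_pos: int
    left_halfmin_pos: int
    right_halfmin_pos: int
    pericentric: bool = False
    edge_truncated: bool = False

    @property
    def halfmin_width(self) -> int:
        return self.right_halfmin_pos - self.left_halfmin_pos

    @property
    def max_fold_ur(self) -> float:
        return float(2.0 ** (-self.min_log2))


def profile_ur(
    ur: GInterval,
    profile: ProbeProfile,
    genome: GenomeLayout | None = None,
    bandwidth: float = 2_000.0,
    grid_step: int = 10,
    value_col: str | None = None,
) -> URProfile:
    """Measure minimum, half-min positions, and fold underreplication.

    The UR is expanded symmetrically to twice its width (clipped at
    chromosome ends), its probes re-smoothed on a ``grid_step``-nt grid, and
    the half-min positions are the first grid points at or above half the
    minimum log2 walking left/right from the minimum.  A side that never
    recovers to half-min within the window falls back to the window edge and
    sets ``edge_truncated``.
    """
    half = ur.width // 2
    win_start = ur.start - half
    win_end = ur.end + half
    if genome is not None:
        length = genome.length_of(ur.chrom)
        win_start = max(0, win_start)
        win_end = min(length, win_end)
    else:
        win_start = max(0, win_start)
    col = value_col or profile.value_column()
    sub = profile.window(ur.chrom, win_start, win_end)
    if len(sub) == 0:
        raise ValueError(f"no probes in window {ur.chrom}:{win_start}-{win_end}")
    pos = sub["pos"].to_numpy()
    vals = sub[col].to_numpy()
    grid = np.arange(win_start, win_end, grid_step, dtype=np.int64)
    sm = local_linear_smooth(pos, vals, grid, bandwidth)

    imin = int(np.argmin(sm))
    min_log2 = float(sm[imin])
    min_pos = int(grid[imin])
    half_level = min_log2 / 2.0

    edge_truncated = False
    left = sm[: imin + 1] >= half_level
    if left.any():
        left_pos = int(grid[np.flatnonzero(left)[-1]])
    else:
        left_pos = int(grid[0])
        edge_truncated = True
    right = sm[imin:] >= half_level
    if right.any():
        right_pos = int(grid[imin + np.flatnonzero(right)[0]])
    else:
        right_pos = int(grid[-1])
        edge_truncated = True

    pericentric = False
    if genome is not None and genome.pericentric is not None:
        overlap = genome.pericentric.intersect(
            IntervalSet.from_intervals([ur])
        )
        pericentric = overlap.coverage_bp > 0

    return URProfile(
        ur=ur,
        min_log2=min_log2,
        min_pos=min_pos,
        left_halfmin_pos=left_pos,
        right_halfmin_pos=right_pos,
        pericentric=pericentric,
        edge_truncated=edge_truncated,
    )


def average_replicates(p1: URProfile, p2: URProfile) -> URProfile:
    """Arithmetic mean of replicate geometry for one UR cluster.

    The replicate profiles must describe the same UR (same chromosome,
    overlapping by at least 1 bp); widths, folds, and positions are averaged.
    """
    a, b = p1.ur, p2.ur
    if a.chrom != b.chrom or min(a.end, b.end) <= max(a.start, b.start):
        raise ValueError(
            f"replicate UR mismatch: {a.chrom}:{a.start}-{a.end} vs "
            f"{b.chrom}:{b.start}-{b.end}"
        )
    # averaged fold maps back to an effective min log2: the mean is taken on
    # the fold scale, matching per-UR averaging of the reported quantity
    mean_fold = (p1.max_fold_ur + p2.max_fold_ur) / 2.0
    return URProfile(
        ur=GInterval(a.chrom, min(a.start, b.start), max(a.end, b.end)),
        min_log2=float(-np.log2(mean_fold)),
        min_pos=(p1.min_pos + p2.min_pos) // 2,
        left_halfmin_pos=(p1.left_halfmin_pos + p2.left_halfmin_pos) // 2,
        right_halfmin_pos=(p1.right_halfmin_pos + p2.right_halfmin_pos) // 2,
        pericentric=p1.pericentric or p2.pericentric,
        edge_truncated=p1.edge_truncated or p2.edge_truncated,
    )


@dataclass
class SpecificityTable:
    """Cross-tissue UR clusters with presence flags and bp accounting."""

    clusters: pd.DataFrame  # chrom, start, end + one bool column per tissue
    counts_by_class: pd.Series  # index: number of tissues, value: n clusters
    shared_bp: int  # bases covered by >= 2 tissues
    specific_bp: int  # bases covered by exactly 1 tissue
    union_bp: int

    @property
    def fraction_specific_clusters(self) -> float:
        n = int(self.counts_by_class.sum())
        return float(self.counts_by_class.get(1, 0)) / n if n else float("nan")

    @property
    def fraction_specific_bp(self) -> float:
        return self.specific_bp / self.union_bp if self.union_bp else float("nan")


def specificity_matrix(per_tissue_urs: list[tuple[str, IntervalSet]]) -> SpecificityTable:
    """Cluster URs across tissues by >= 1 bp overlap (single linkage).

    Every input UR lands in exactly one cluster; clusters are scored by the
    number of tissues present, and base pairs of the union covered by exactly
    one tissue are counted as tissue-specific.
    """
    if len(per_tissue_urs) < 2:
        raise ValueError("need URs from at least 2 tissues")
    tissues = [name for name, _ in per_tissue_urs]
    if len(set(tissues)) != len(tissues):
        raise ValueError("tissue names must be unique")

    rows = []
    for name, ivs in per_tissue_urs:
        for chrom, start, end in ivs.to_records():
            rows.append((chrom, start, end, name))
    clusters: list[dict] = []
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tissue"])
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom"):
        cur_end = None
        cur: dict | None = None
        for _, r in sub.iterrows():
            if cur is None or r["start"] >= cur_end:
                cur = {"chrom": chrom, "start": r["start"], "end": r["end"],
                       "tissues": {r["tissue"]}}
                clusters.append(cur)
                cur_end = r["end"]
            else:
                cur["end"] = max(cur["end"], r["end"])
                cur["tissues"].add(r["tissue"])
                cur_end = cur["end"]

    table = pd.DataFrame(
        [
            {"chrom": c["chrom"], "start": c["start"], "end": c["end"],
             **{t: (t in c["tissues"]) for t in tissues},
             "n_tissues": len(c["tissues"])}
            for c in clusters
        ]
    )
    counts = (
        table["n_tissues"].value_counts().sort_index()
        if len(table)
        else pd.Series(dtype=int)
    )

    # per-base depth accounting over the union
    union_bp = 0
    specific_bp = 0
    all_chroms = {name: ivs for name, ivs in per_tissue_urs}
    chrom_names = sorted({c for ivs in all_chroms.values() for c in ivs.chroms()})
    for chrom in chrom_names:
        events: list[tuple[int, int]] = []
        for _, ivs in per_tissue_urs:
            for s, e in ivs.get(chrom):
                events.append((int(s), 1))
                events.append((int(e), -1))
        events.sort()
        depth = 0
        prev = None
        for pos, delta in events:
            if prev is not None and pos > prev:
                if depth >= 1:
                    union_bp += pos - prev
                if depth == 1:
                    specific_bp += pos - prev
            depth += delta
            prev = pos
    return SpecificityTable(
        clusters=table,
        counts_by_class=counts,
        shared_bp=union_bp - specific_bp,
        specific_bp=specific_bp,
        union_bp=union_bp,
    )


def width_depth_relation(
    urprofiles: list[URProfile],
    exclude_pericentric: bool = True,
) -> dict:
    """Spearman correlation of half-min width vs maximum fold
    underreplication (wider URs are expected to be more deeply
    underreplicated)."""
    kept = [
        p for p in urprofiles if not (exclude_pericentric and p.pericentric)
    ]
    if len(kept) < 3:
        raise ValueError("need at least 3 URs for a rank correlation")
    widths = np.array([p.halfmin_width for p in kept], dtype=float)
    folds = np.array([p.max_fold_ur for p in kept], dtype=float)
    rho, p = stats.spearmanr(widths, folds)
    return {
        "n": len(kept),
        "n_excluded_pericentric": len(urprofiles) - len(kept),
        "spearman_rho": float(rho),
        "p_value": float(p),
        "halfmin_widths": widths,
        "max_folds": folds,
    }
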