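"""Expression calls, TSS–ORC proximity, and percentile-rank comparison
between tissues.

A transcript is *expressed* at FPKM >= 3.  Percentile ranks are computed per
tissue over the full transcript table (ties get the mean rank); the
difference in percentile rank (DPR) between a focal tissue and a comparison
tissue classifies each ORC-proximal transcript as tissue-specific
(DPR > 40), higher-or-equal (1 <= DPR <= 40), lower-or-equal (DPR <= 0), or
not expressed in the focal tissue (which overrides the DPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import IntervalSet, PointSet

__all__ = [
    "EXPRESSED_FPKM",
    "DPRClass",
    "is_expressed",
    "tss_associate",
    "percentile_rank",
    "dpr_classify",
    "fraction_expressed_in_regions",
]

EXPRESSED_FPKM = 3.0


@dataclass(frozen=True)
class DPRClass:
    label: str  # focal_specific | focal_ge_other | focal_le_other | not_expressed
    dpr: float | None


def is_expressed(fpkm: float, threshold: float = EXPRESSED_FPKM) -> bool:
    """FPKM at or above the cutoff (inclusive: 3.0 is expressed)."""
    return float(fpkm) >= threshold


def tss_associate(
    peaks: PointSet,
    transcripts: pd.DataFrame,
    radius: int = 1_000,
) -> pd.DataFrame:
    """All (summit, transcript) pairs with |TSS − summit| <= radius.

    Strand-agnostic distance.  Returns one row per association: chrom,
    summit, transcript_id, tss, distance.  Summits with no transcript in
    range simply contribute no rows.
    """
    rows = []
    for chrom, summits in peaks.items():
        sub = transcripts[transcripts["chrom"] == chrom]
        if len(sub) == 0:
            continue
        order = np.argsort(sub["tss"].to_numpy(), kind="mergesort")
        tss = sub["tss"].to_numpy()[order]
        ids = sub["transcript_id"].to_numpy()[order]
        lo = np.searchsorted(tss, summits - radius, side="left")
        hi = np.searchsorted(tss, summits + radius, side="right")
        for summit, a, b in zip(summits, lo, hi):
            for j in range(a, b):
                rows.append(
                    {
                        "chrom": chrom,
                        "summit": int(summit),
                        "transcript_id": ids[j],
                        "tss": int(tss[j]),
                        "distance": int(abs(int(tss[j]) - int(summit))),
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "summit", "transcript_id", "tss", "distance"]
    )


def percentile_rank(fpkm: np.ndarray) -> np.ndarray:
    """Ranks on a 0–100 scale; ties receive the mean rank.

    The scale is 100·(rank − 1)/n, so a distinct maximum among n transcripts
    ranks 100·(n−1)/n and a distinct minimum ranks 0.
    """
    fpkm = np.asarray(fpkm, dtype=float)
    if fpkm.size < 2:
        raise ValueError("need at least 2 transcripts to rank")
    ranks = sps.rankdata(fpkm, method="average")
    return 100.0 * (ranks - 1.0) / fpkm.size


def dpr_classify(
    focal_rank: float,
    other_rank: float,
    focal_expressed: bool,
) -> DPRClass:
    """Classify one transcript by its difference in percentile rank.

    Not expressed in the focal tissue overrides everything.  Otherwise
    DPR = focal − other: > 40 → focal_specific; in [1, 40] → focal_ge_other;
    <= 0 → focal_le_other.  The legend's gap DPR ∈ (0, 1) is assigned to
    focal_ge_other (higher-or-no-difference), a documented convention.
    """
    for r in (focal_rank, other_rank):
        if not (0.0 <= r <= 100.0):
            raise ValueError(f"percentile rank {r} outside [0, 100]")
    if not focal_expressed:
        return DPRClass("not_expressed", None)
    dpr = focal_rank - other_rank
    if dpr > 40:
        return DPRClass("focal_specific", dpr)
    if dpr <= 0:
        return DPRClass("focal_le_other", dpr)
    return DPRClass("focal_ge_other", dpr)


def fraction_expressed_in_regions(
    transcripts: pd.DataFrame,
    regions: IntervalSet,
    tissue: str,
    threshold: float = EXPRESSED_FPKM,
) -> tuple[float, int, int]:
    """Among transcripts whose TSS lies in the regions, the expressed
    fraction.

    Membership is by TSS position.  Returns (fraction, n_in_regions,
    n_expressed); the fraction is NaN when no TSS falls in the regions.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if tissue not in transcripts.columns:
        raise KeyError(f"tissue {tissue!r} not in transcript table")
    inside = np.zeros(len(transcripts), dtype=bool)
    for chrom, sub in transcripts.groupby("chrom"):
        inside[sub.index] = regions.contains_points(
            str(chrom), sub["tss"].to_numpy()
        )
    n_in = int(inside.sum())
    if n_in == 0:
        return float("nan"), 0, 0
    n_expr = int((transcripts.loc[inside, tissue] >= threshold).sum())
    return n_expr / n_in, n_in, n_expr
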