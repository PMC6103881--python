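"""Underreplicated-region (UR) calling from probe-level log2 ratios.

The caller works per tissue sample in five steps:

1. **Smooth** the raw log2(tissue/diploid) ratios by locally weighted linear
   regression over genomic position (fixed bandwidth, default 5 kb).
2. **Center**: estimate the mode (peak) of the genome-wide smoothed log2
   distribution by kernel density estimation and subtract it, setting the
   bulk of fully replicated probes to 0.
3. **Threshold**: split the centered distribution at 0 and treat the
   over-replication (positive) side as representative of the null; reflect it
   about 0 and take the 5th percentile of this symmetrized null as the copy
   number threshold (a negative log2 value).  By default the null is built
   from the centered *raw* probe values: the raw per-probe distribution is
   the proper measurement-noise null, whereas smoothing both shrinks and
   autocorrelates the noise, which would make spurious below-threshold runs
   frequent if the threshold were taken from the smoothed values themselves.
4. **Run-call**: flag probes whose centered smoothed value falls below the
   threshold; every maximal run of at least ``min_run`` consecutive flagged
   probes (25/11/5 for the 1M/400k/180k array designs) becomes a UR spanning
   first to last flagged probe; URs within 50 kb are merged.
5. **Replicate intersection**: the base-wise intersection of the UR sets from
   two biological replicates is the high-confidence UR set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.kde import KDEUnivariate

from .genome import GenomeLayout, IntervalSet, merge_within
from .probes import ProbeProfile
from .smoothing import local_linear_smooth

__all__ = [
    "DESIGN_MIN_RUN",
    "DESIGN_SPACING",
    "CallerParams",
    "URCallResult",
    "smooth_profile",
    "estimate_mode",
    "center_profile",
    "compute_threshold",
    "call_ur_regions",
    "high_confidence_urs",
    "call_tissue",
]

# array design -> minimum number of consecutive underreplicated probes
DESIGN_MIN_RUN = {"1M": 25, "400k": 11, "180k": 5}
# array design -> mean probe spacing (bp) of the matching tiling design
DESIGN_SPACING = {"1M": 125, "400k": 250, "180k": 1500}


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the UR caller.

    ``design`` selects the run-length requirement (1M: 25, 400k: 11,
    180k: 5 probes in a row).  ``threshold_source`` chooses whether the
    symmetrized null is built from centered raw probe values (default) or
    from the centered smoothed values.
    """

    design: str = "400k"
    smoothing_bandwidth: float = 5_000.0
    null_percentile: float = 5.0
    merge_gap: int = 50_000
    min_run: int | None = None
    threshold_source: str = "raw"

    def __post_init__(self):
        if self.design not in DESIGN_MIN_RUN:
            raise ValueError(f"unknown array design {self.design!r}")
        if not (0 < self.null_percentile < 50):
            raise ValueError("null_percentile must be in (0, 50)")
        if self.min_run is not None and self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.threshold_source not in ("raw", "smooth"):
            raise ValueError("threshold_source must be 'raw' or 'smooth'")

    @property
    def effective_min_run(self) -> int:
        return self.min_run if self.min_run is not None else DESIGN_MIN_RUN[self.design]


@dataclass
class URCallResult:
    """Called URs plus the scalars and per-probe flags that produced them."""

    urs: IntervalSet
    threshold: float
    mode: float
    params: CallerParams
    flags: pd.DataFrame = field(repr=False)  # chrom, pos, flagged

    def to_metadata(self) -> dict:
        return {
            "n_urs": len(self.urs),
            "coverage_bp": self.urs.coverage_bp,
            "threshold_log2": self.threshold,
            "mode_log2": self.mode,
            "design": self.params.design,
            "min_run": self.params.effective_min_run,
            "smoothing_bandwidth_bp": self.params.smoothing_bandwidth,
            "null_percentile": self.params.null_percentile,
            "merge_gap_bp": self.params.merge_gap,
            "threshold_source": self.params.threshold_source,
        }


def smooth_profile(profile: ProbeProfile, bandwidth: float = 5_000.0) -> ProbeProfile:
    """Fill ``log2_smooth`` by local linear regression per chromosome.

    Chromosomes with fewer than 3 probes are passed through unsmoothed.
    """
    import warnings

    smooth = np.empty(profile.n_probes)
    for chrom in profile.chroms():
        sub = profile.chrom_data(chrom)
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        raw = sub["log2_raw"].to_numpy()
        if len(pos) < 3:
            warnings.warn(
                f"chromosome {chrom!r} has {len(pos)} probes; passed through unsmoothed",
                stacklevel=2,
            )
            smooth[idx] = raw
            continue
        smooth[idx] = local_linear_smooth(pos, raw, pos, bandwidth)
    return profile.with_column("log2_smooth", smooth)


def estimate_mode(values: np.ndarray, gridsize: int = 2048) -> float:
    """Location of the maximum of a Gaussian KDE of ``values``.

    Silverman-bandwidth FFT KDE on a ``gridsize``-point grid; ties broken
    leftmost (first argmax).  Deterministic for fixed input.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate mode of empty input")
    if np.ptp(values) == 0:
        return float(values[0])
    kde = KDEUnivariate(values)
    kde.fit(kernel="gau", bw="silverman", fft=True, gridsize=gridsize)
    return float(kde.support[int(np.argmax(kde.density))])


def center_profile(profile: ProbeProfile, mode: float | None = None) -> tuple[ProbeProfile, float]:
    """Subtract the smoothed distribution's mode: ``log2_centered`` column.

    Returns the centered profile and the mode used.
    """
    if not profile.has("log2_smooth"):
        raise ValueError("profile must be smoothed before centering")
    if mode is None:
        mode = estimate_mode(profile.df["log2_smooth"].to_numpy())
    centered = profile.with_column(
        "log2_centered", profile.df["log2_smooth"].to_numpy() - mode
    )
    return centered, float(mode)


def compute_threshold(centered_values: np.ndarray, null_percentile: float = 5.0) -> float:
    """Copy-number threshold from the reflected over-replication null.

    The empirical null is ``{+d, -d}`` for every positive centered deviation
    ``d``; the threshold is that null's ``null_percentile``-th percentile — a
    negative log2 value (−1.645σ for a centered Gaussian at the default 5th
    percentile).
    """
    centered_values = np.asarray(centered_values, dtype=float)
    pos = centered_values[centered_values > 0]
    if pos.size == 0:
        raise ValueError("degenerate null: no positive centered values")
    null = np.concatenate([pos, -pos])
    return float(np.percentile(null, null_percentile))


def _runs_to_intervals(pos: np.ndarray, flagged: np.ndarray, min_run: int):
    """Maximal runs of >= min_run flagged probes -> [first, last+1) intervals."""
    if not flagged.any():
        return []
    padded = np.concatenate([[False], flagged, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive probe index
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            out.append((int(pos[s]), int(pos[e - 1]) + 1))
    return out


def call_ur_regions(
    profile: ProbeProfile,
    params: CallerParams,
    threshold: float | None = None,
) -> URCallResult:
    """Run the full per-sample caller on a raw profile.

    Smooths and centers if those columns are absent, derives the threshold
    (unless one is supplied), flags probes, extracts qualifying runs, and
    merges URs within ``params.merge_gap``.
    """
    if not profile.has("log2_smooth"):
        profile = smooth_profile(profile, params.smoothing_bandwidth)
    if not profile.has("log2_centered"):
        profile, mode = center_profile(profile)
    else:
        mode = float(
            np.median(profile.df["log2_smooth"] - profile.df["log2_centered"])
        )
    if threshold is None:
        if params.threshold_source == "raw":
            null_values = profile.df["log2_raw"].to_numpy() - mode
        else:
            null_values = profile.df["log2_centered"].to_numpy()
        threshold = compute_threshold(null_values, params.null_percentile)
    if threshold >= 0:
        raise ValueError(f"threshold must be negative, got {threshold}")

    records = []
    flag_frames = []
    for chrom in profile.chroms():
        sub = profile.chrom_data(chrom)
        pos = sub["pos"].to_numpy()
        flagged = sub["log2_centered"].to_numpy() < threshold
        flag_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "flagged": flagged})
        )
        for s, e in _runs_to_intervals(pos, flagged, params.effective_min_run):
            records.append((chrom, s, e))
    urs = merge_within(IntervalSet.from_records(records), params.merge_gap)
    return URCallResult(
        urs=urs,
        threshold=float(threshold),
        mode=float(mode),
        params=params,
        flags=pd.concat(flag_frames, ignore_index=True),
    )


def high_confidence_urs(rep1: URCallResult | IntervalSet,
                        rep2: URCallResult | IntervalSet) -> IntervalSet:
    """Base-wise intersection of two replicate UR sets."""
    a = rep1.urs if isinstance(rep1, URCallResult) else rep1
    b = rep2.urs if isinstance(rep2, URCallResult) else rep2
    return a.intersect(b)


def call_tissue(
    replicates: tuple[ProbeProfile, ProbeProfile],
    params: CallerParams,
) -> tuple[IntervalSet, list[URCallResult]]:
    """Call both replicates and return (high-confidence set, per-rep results)."""
    results = [call_ur_regions(rep, params) for rep in replicates]
    return high_confidence_urs(results[0], results[1]), results
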