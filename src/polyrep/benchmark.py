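"""Seeded benchmark studies of the caller and the statistical tests.

These are the package's own validation experiments: null false-positive
control, one-to-one recovery of planted dips with geometry errors,
permutation-test calibration against a uniform p-value law, depletion power
on an ORC-repressed tissue, and recovery of the coupling between ORC-free
zone width and UR geometry.  The test suite asserts on their outputs and the
reproduction script reports them; both therefore exercise exactly the same
code paths as a real analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import CallerParams, call_tissue, call_ur_regions, center_profile, smooth_profile
from .genome import GenomeLayout, GInterval, IntervalSet, PointSet
from .metrics import average_replicates, profile_ur
from .orc import depletion_test, orc_free_zone
from .probes import ProbeProfile
from .simulate import SimConfig, URSpec, simulate_orc_peaks, simulate_probe_profiles, truth_signal
from .smoothing import local_linear_smooth
from .stats import placement_permutation_test, projection_test

__all__ = [
    "null_false_positive_study",
    "make_recovery_config",
    "recovery_study",
    "depletion_calibration_pvalues",
    "projection_calibration_pvalues",
    "placement_calibration_pvalues",
    "depletion_power_study",
    "zone_coupling_study",
]


# ---------------------------------------------------------------------------
# null control
# ---------------------------------------------------------------------------

def null_false_positive_study(
    n_genomes: int = 100,
    n_probes: int = 10_000,
    design: str = "1M",
    base_seed: int = 0,
) -> int:
    """Total URs called across pure-null genomes (no planted dips).

    Each genome has ``n_probes`` probes at the design's mean spacing; a
    single sample is called per genome.  Expected result: 0.
    """
    from .caller import DESIGN_SPACING

    spacing = DESIGN_SPACING[design]
    genome = GenomeLayout({"chrN": n_probes * spacing})
    params = CallerParams(design=design)
    total = 0
    for i in range(n_genomes):
        cfg = SimConfig(genome=genome, seed=base_seed * 100_003 + i,
                        probe_spacing=spacing)
        rep1, _ = simulate_probe_profiles(cfg)
        total += len(call_ur_regions(rep1, params).urs)
    return total


# ---------------------------------------------------------------------------
# recovery of planted dips
# ---------------------------------------------------------------------------

def make_recovery_config(
    seed: int,
    n_urs: int = 5,
    depth_range: tuple[float, float] = (0.5, 3.0),
    width_range: tuple[int, int] = (60_000, 500_000),
    probe_spacing: int = 250,
    chrom_length: int = 6_000_000,
    min_gap: int = 150_000,
) -> SimConfig:
    """One synthetic genome with ``n_urs`` well-separated triangular dips of
    graded depth and width."""
    rng = np.random.default_rng([seed % (2**31), 977])
    widths = rng.integers(width_range[0], width_range[1] + 1, size=n_urs)
    depths = rng.uniform(depth_range[0], depth_range[1], size=n_urs)
    leftover = chrom_length - int(widths.sum()) - (n_urs + 1) * min_gap
    if leftover < 0:
        raise ValueError("chromosome too short for the requested dips")
    frac = rng.random(n_urs + 1)
    gaps = min_gap + (leftover * frac / frac.sum()).astype(np.int64)
    specs = []
    cursor = 0
    for w, d, g in zip(widths, depths, gaps):
        cursor += int(g)
        specs.append(URSpec(GInterval("chrS", cursor, cursor + int(w)), -float(d)))
        cursor += int(w)
    genome = GenomeLayout({"chrS": chrom_length})
    return SimConfig(genome=genome, seed=seed, probe_spacing=probe_spacing,
                     ur_specs=specs)


def _expected_call_extent(
    config: SimConfig, spec: URSpec, positions: np.ndarray,
    bandwidth: float, threshold: float,
) -> tuple[int, int] | None:
    """Where the *noiseless smoothed* planted profile crosses the threshold.

    This is the boundary a perfect noise-free run of the caller would
    produce: the called UR ends where the smoothed dip re-crosses the copy
    number threshold, not at the planted interval edge.
    """
    lo = spec.interval.start - spec.interval.width
    hi = spec.interval.end + spec.interval.width
    sel = (positions >= lo) & (positions < hi)
    pos = positions[sel]
    signal = truth_signal(config, spec.interval.chrom, pos)
    sm = local_linear_smooth(pos, signal, pos, bandwidth)
    below = sm < threshold
    if not below.any():
        return None
    # the contiguous below-threshold run containing this dip's center (the
    # window may graze a neighboring dip)
    center = (spec.interval.start + spec.interval.end) // 2
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if pos[s] <= center < pos[e - 1] + 1:
            return int(pos[s]), int(pos[e - 1]) + 1
    return None


@dataclass
class RecoveryRecord:
    seed: int
    depth: float
    width: int
    recovered: bool
    boundary_err: float  # max of left/right error in bp (inf if unrecovered)
    halfmin_rel_err: float
    fold_rel_err: float


def recovery_study(
    n_genomes: int = 100,
    base_seed: int = 0,
    params: CallerParams | None = None,
    n_urs: int = 5,
) -> pd.DataFrame:
    """Call replicate pairs on seeded genomes with planted triangular dips
    and score each planted dip.

    Scores per planted dip: one-to-one recovery by the high-confidence set,
    boundary error against the noiseless-smoothed threshold crossing,
    half-min width relative error against the triangle's analytic value
    (base width / 2), and maximum-fold relative error against 2^depth.
    """
    params = params or CallerParams(design="400k")
    rows = []
    for i in range(n_genomes):
        seed = base_seed * 100_003 + i
        cfg = make_recovery_config(seed, n_urs=n_urs)
        reps = simulate_probe_profiles(cfg)
        hc, results = call_tissue(reps, params)
        mean_threshold = float(np.mean([r.threshold for r in results]))
        positions = reps[0].positions("chrS")

        smoothed = []
        for rep, res in zip(reps, results):
            prof = smooth_profile(rep, params.smoothing_bandwidth)
            prof, _ = center_profile(prof, mode=res.mode)
            smoothed.append(prof)

        called = list(hc)
        claimed: dict[int, int] = {}  # called index -> planted index
        for j, spec in enumerate(cfg.ur_specs):
            overlapping = [
                k for k, iv in enumerate(called)
                if iv.start < spec.interval.end and spec.interval.start < iv.end
            ]
            rec = RecoveryRecord(
                seed=seed, depth=spec.depth, width=spec.interval.width,
                recovered=False, boundary_err=float("inf"),
                halfmin_rel_err=float("inf"), fold_rel_err=float("inf"),
            )
            if len(overlapping) == 1 and overlapping[0] not in claimed:
                k = overlapping[0]
                claimed[k] = j
                iv = called[k]
                expected = _expected_call_extent(
                    cfg, spec, positions, params.smoothing_bandwidth,
                    mean_threshold,
                )
                if expected is not None:
                    rec.recovered = True
                    rec.boundary_err = max(
                        abs(iv.start - expected[0]), abs(iv.end - expected[1])
                    )
                    pair = [profile_ur(iv, prof, cfg.genome) for prof in smoothed]
                    avg = average_replicates(pair[0], pair[1])
                    true_halfmin = spec.interval.width / 2
                    true_fold = 2.0 ** (-spec.depth)
                    rec.halfmin_rel_err = abs(avg.halfmin_width - true_halfmin) / true_halfmin
                    rec.fold_rel_err = abs(avg.max_fold_ur - true_fold) / true_fold
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation-test calibration
# ---------------------------------------------------------------------------

def _calibration_genome() -> GenomeLayout:
    return GenomeLayout({"cal1": 12_000_000, "cal2": 8_000_000})


def _fixed_intervals(genome: GenomeLayout, n: int, wmin: int, wmax: int,
                     seed: int) -> IntervalSet:
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    recs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        w = int(rng.integers(wmin, wmax))
        s = int(rng.integers(0, genome.chromosomes[chrom] - w))
        recs.append((chrom, s, s + w))
    return IntervalSet.from_records(recs)


def _uniform_points(rng, genome: GenomeLayout, n: int) -> PointSet:
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    return PointSet.from_records(
        (chroms[i], int(rng.integers(0, int(lengths[i])))) for i in idx
    )


def depletion_calibration_pvalues(
    n_runs: int = 200, n_perm: int = 2_000, base_seed: int = 0
) -> np.ndarray:
    """p-values of the depletion test under its null (uniform peaks)."""
    genome = _calibration_genome()
    urs = _fixed_intervals(genome, 40, 20_000, 80_000, seed=1234)
    out = np.empty(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng([base_seed % (2**31), 31, r])
        peaks = _uniform_points(rng, genome, 600)
        out[r] = depletion_test(
            peaks, urs, genome, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        ).p_value
    return out


def projection_calibration_pvalues(
    n_runs: int = 200, n_perm: int = 2_000, base_seed: int = 0
) -> np.ndarray:
    """Two-sided permutation projection-test p-values under a uniform query.

    Calibration is checked with a large query set (2,000 midpoints) on a
    genome-scale space, for two reasons: coarse counts make the doubled-tail
    two-sided p conservative (errs toward 1), and on a small genome dense
    random queries overlap and get union-merged, leaving repulsively spaced
    midpoints whose counts are underdispersed relative to the
    independent-midpoint permutation null.  Neither effect is a calibration
    failure of the test; both vanish when queries are sparse in the genome.
    """
    genome = GenomeLayout({"calA": 120_000_000, "calB": 80_000_000})
    reference = _fixed_intervals(genome, 500, 50_000, 150_000, seed=4321)
    out = np.empty(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng([base_seed % (2**31), 37, r])
        query = _random_query(rng, genome, 2_000, 1_000, 3_000)
        out[r] = projection_test(
            query, reference, genome, mode="permutation",
            n_perm=n_perm, seed=int(rng.integers(2**31)),
        ).projection_p
    return out


def placement_calibration_pvalues(
    n_runs: int = 200, n_perm: int = 2_000, base_seed: int = 0
) -> np.ndarray:
    """Upper-tail placement-test p-values under uniformly placed queries."""
    genome = _calibration_genome()
    reference = _fixed_intervals(genome, 40, 40_000, 100_000, seed=999)
    out = np.empty(n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng([base_seed % (2**31), 41, r])
        query = _random_query(rng, genome, 300, 5_000, 40_000)
        out[r] = placement_permutation_test(
            query, reference, genome, n_iter=n_perm,
            seed=int(rng.integers(2**31)),
        ).p_value
    return out


def _random_query(rng, genome: GenomeLayout, n: int, wmin: int, wmax: int) -> IntervalSet:
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    widths = rng.integers(wmin, wmax, size=n)
    starts = (rng.random(n) * (lengths[idx] - widths)).astype(np.int64)
    return IntervalSet.from_records(
        (chroms[i], int(s), int(s + w)) for i, s, w in zip(idx, starts, widths)
    )


# ---------------------------------------------------------------------------
# depletion power and zone coupling
# ---------------------------------------------------------------------------

def depletion_power_study(
    n_seeds: int = 100,
    n_perm: int = 10_000,
    base_seed: int = 0,
) -> np.ndarray:
    """Depletion p-values on tissues with ORC fully repressed in URs
    (rate 0 inside planted domains, 8 per 100 kb outside)."""
    genome = GenomeLayout({"chrP": 10_000_000})
    urs = IntervalSet.from_records(
        [("chrP", s, s + 100_000) for s in range(500_000, 9_500_000, 450_000)]
    )
    out = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = SimConfig(
            genome=genome, seed=base_seed * 100_003 + i,
            orc_base_rate=8.0, orc_poor_rate=0.0, orc_poor_domains=urs,
        )
        peaks = simulate_orc_peaks(cfg)
        out[i] = depletion_test(
            peaks, urs, genome, n_perm=n_perm, seed=cfg.seed + 1,
        ).p_value
    return out


def zone_coupling_study(
    n_urs: int = 30,
    seed: int = 0,
    params: CallerParams | None = None,
) -> dict:
    """A tissue whose ORC-free zones widen with UR width and depth.

    Dips of increasing width carry proportionally deeper minima and sit in
    ORC-free gaps 1.3× their width; the study calls the URs, measures
    half-min width and maximum fold underreplication, and correlates both
    with the recovered ORC-free zone width (Spearman).
    """
    from scipy import stats as sps

    params = params or CallerParams(design="400k")
    spacing_between = 1_300_000
    length = (n_urs + 1) * spacing_between
    genome = GenomeLayout({"chrZ": length})
    rng = np.random.default_rng([seed % (2**31), 733])
    widths = np.sort(rng.integers(60_000, 400_000, size=n_urs))
    specs, free_zones = [], []
    for i, w in enumerate(widths):
        center = (i + 1) * spacing_between
        depth = 0.5 + 2.3 * (w - 60_000) / 340_000 * float(rng.lognormal(0, 0.08))
        specs.append(
            URSpec(GInterval("chrZ", center - int(w) // 2,
                             center - int(w) // 2 + int(w)), -float(depth))
        )
        z = int(1.3 * w)
        free_zones.append(("chrZ", center - z // 2, center - z // 2 + z))
    cfg = SimConfig(
        genome=genome, seed=seed, ur_specs=specs,
        orc_base_rate=8.0, orc_poor_rate=0.0,
        orc_poor_domains=IntervalSet.from_records(free_zones),
    )
    reps = simulate_probe_profiles(cfg)
    peaks = simulate_orc_peaks(cfg)
    hc, results = call_tissue(reps, params)
    smoothed = []
    for rep, res in zip(reps, results):
        prof = smooth_profile(rep, params.smoothing_bandwidth)
        prof, _ = center_profile(prof, mode=res.mode)
        smoothed.append(prof)
    zone_w, halfmin_w, folds = [], [], []
    for iv in hc:
        z = orc_free_zone(iv, peaks)
        if z.zone_width is None:
            continue
        pair = [profile_ur(iv, prof, genome) for prof in smoothed]
        avg = average_replicates(pair[0], pair[1])
        zone_w.append(z.zone_width)
        halfmin_w.append(avg.halfmin_width)
        folds.append(avg.max_fold_ur)
    rho_w, p_w = sps.spearmanr(zone_w, halfmin_w)
    rho_f, p_f = sps.spearmanr(zone_w, folds)
    return {
        "n": len(zone_w),
        "rho_zone_vs_halfmin": float(rho_w),
        "p_zone_vs_halfmin": float(p_w),
        "rho_zone_vs_fold": float(rho_f),
        "p_zone_vs_fold": float(p_f),
    }
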