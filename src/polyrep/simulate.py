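"""Seeded synthetic data: genomes, replicate array profiles with embedded
underreplication gradients, ORC/γH2Av summit sets, TAD tilings, and
two-tissue transcript tables.

The generator emulates the statistical structure the analysis assumes —
quasi-regular tiling probes, a near-symmetric null log2 distribution centered
at a mode (with optional right skew from an over-replication tail), V-shaped
copy-number dips of graded depth and width, ORC summits as an inhomogeneous
Poisson process depleted inside designated domains, γH2Av enriched inside
URs, TADs tiling each chromosome, and lognormal FPKM values with a forced
not-expressed fraction.  Every generator is a pure function of its config and
seed, and the ground truth is always returned alongside the data.

Default parameter choices (see docs/methods.md for rationale): probe spacing
250 bp; probe noise SD 0.04 log2 units; ORC background 8 summits/100 kb with
0.5/100 kb inside ORC-poor domains; TAD mean width 100 kb; 500 transcripts
with log-normal FPKM (ln-scale mean 1.0, SD 1.5) and 20% forced zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GInterval, IntervalSet, PointSet
from .probes import ProbeProfile

__all__ = [
    "URSpec",
    "FPKMModel",
    "SimConfig",
    "SimulatedTissue",
    "ur_shape",
    "simulate_probe_positions",
    "simulate_probe_profiles",
    "simulate_orc_peaks",
    "simulate_h2av_peaks",
    "simulate_tads",
    "simulate_transcripts",
    "simulate_tissue",
]

# stage identifiers mixed into the master seed so stages draw independently
_STAGE = {"probes": 11, "noise": 13, "orc": 17, "h2av": 19, "tads": 23, "rna": 29}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STAGE[stage], extra])


@dataclass(frozen=True)
class URSpec:
    """A planted underreplication dip.

    ``depth`` is the (negative) log2 ratio reached at the dip center;
    ``shape`` is the gradient form: ``triangular`` (linear walls, the
    default — matches the V-shaped dips real arrays show and makes the
    half-min width analytic at W/2), ``gaussian`` (SD = width/6), or
    ``flat`` (constant depth with sharp walls).
    """

    interval: GInterval
    depth: float
    shape: str = "triangular"

    def __post_init__(self):
        if self.depth >= 0:
            raise ValueError("UR depth must be negative (a copy-number loss)")
        if self.shape not in ("triangular", "gaussian", "flat"):
            raise ValueError(f"unknown UR shape {self.shape!r}")


@dataclass(frozen=True)
class FPKMModel:
    """Per-tissue lognormal FPKM parameters (natural-log scale)."""

    mean_log: float = 1.0
    sd_log: float = 1.5
    zero_fraction: float = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic tissue. ``seed`` is mandatory."""

    genome: GenomeLayout
    seed: int
    probe_spacing: int = 250
    noise_sd: float = 0.04
    noise_skew: float = 0.0
    ur_specs: Sequence[URSpec] = ()
    orc_base_rate: float = 8.0  # summits per 100 kb
    orc_poor_domains: IntervalSet | None = None
    orc_poor_rate: float = 0.5
    h2av_inside_rate: float = 10.0
    h2av_outside_rate: float = 0.5
    tad_mean_width: int = 100_000
    n_transcripts: int = 500
    fpkm_model: Mapping[str, FPKMModel] = field(
        default_factory=lambda: {"FB": FPKMModel(), "Kc": FPKMModel()}
    )

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.noise_skew <= 0.5):
            raise ValueError("noise_skew must be in [0, 0.5]")
        for rate in (self.orc_base_rate, self.orc_poor_rate,
                     self.h2av_inside_rate, self.h2av_outside_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.orc_poor_rate > self.orc_base_rate:
            raise ValueError("orc_poor_rate must not exceed orc_base_rate")
        for spec in self.ur_specs:
            self.genome.check_interval(spec.interval)
            if spec.interval.width > self.genome.length_of(spec.interval.chrom):
                raise ValueError("UR wider than its chromosome")


@dataclass
class SimulatedTissue:
    """All data for one synthetic tissue plus the generating truth."""

    profiles: tuple[ProbeProfile, ProbeProfile]
    orc_peaks: PointSet
    h2av_peaks: PointSet
    tads: IntervalSet
    transcripts: pd.DataFrame
    truth: SimConfig


def ur_shape(spec: URSpec, positions: np.ndarray) -> np.ndarray:
    """Noiseless log2 contribution of a planted dip at ``positions``."""
    s, e = spec.interval.start, spec.interval.end
    center = (s + e) / 2.0
    width = e - s
    x = np.asarray(positions, dtype=float)
    inside = (x >= s) & (x < e)
    out = np.zeros_like(x)
    if spec.shape == "triangular":
        out[inside] = spec.depth * (1.0 - 2.0 * np.abs(x[inside] - center) / width)
    elif spec.shape == "gaussian":
        sd = width / 6.0
        out[inside] = spec.depth * np.exp(-((x[inside] - center) ** 2) / (2 * sd**2))
    else:  # flat
        out[inside] = spec.depth
    return out


def simulate_probe_positions(config: SimConfig) -> dict[str, np.ndarray]:
    """Jittered-grid probe positions, mean spacing ``probe_spacing``.

    Grid centers every ``spacing`` bp with uniform jitter ±spacing/2: the
    quasi-regular layout of real tiling designs, with stable run-length
    semantics.
    """
    rng = _rng(config.seed, "probes")
    spacing = config.probe_spacing
    out = {}
    for chrom, length in config.genome.chromosomes.items():
        centers = np.arange(spacing // 2, length, spacing, dtype=np.int64)
        jitter = rng.integers(-(spacing // 2), spacing - spacing // 2, size=len(centers))
        pos = np.unique(np.clip(centers + jitter, 0, length - 1))
        out[chrom] = pos
    return out


def _noise(rng: np.random.Generator, n: int, sd: float, skew: float) -> np.ndarray:
    base = rng.normal(0.0, sd, size=n)
    if skew > 0:
        # right-skewed null: a minority over-replication tail component
        mask = rng.random(n) < skew
        base[mask] = rng.normal(2.0 * sd, 2.0 * sd, size=int(mask.sum()))
    return base


def truth_signal(config: SimConfig, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Sum of planted dip shapes on one chromosome (noiseless baseline 0)."""
    signal = np.zeros(len(positions))
    for spec in config.ur_specs:
        if spec.interval.chrom == chrom:
            signal += ur_shape(spec, positions)
    return signal


def simulate_probe_profiles(config: SimConfig) -> tuple[ProbeProfile, ProbeProfile]:
    """A biological-replicate pair: shared probe grid and truth, independent
    noise draws."""
    positions = simulate_probe_positions(config)
    reps = []
    for rep in (0, 1):
        rng = _rng(config.seed, "noise", rep)
        data = {}
        for chrom, pos in positions.items():
            signal = truth_signal(config, chrom, pos)
            noise = _noise(rng, len(pos), config.noise_sd, config.noise_skew)
            data[chrom] = (pos, signal + noise)
        reps.append(ProbeProfile.from_arrays(data))
    return reps[0], reps[1]


def _piecewise_poisson(
    rng: np.random.Generator,
    genome: GenomeLayout,
    hot: IntervalSet | None,
    hot_rate: float,
    cold_rate: float,
) -> PointSet:
    """Poisson summits: rate ``hot_rate`` inside ``hot``, ``cold_rate`` elsewhere
    (rates per 100 kb)."""
    out: dict[str, np.ndarray] = {}
    hot = hot if hot is not None else IntervalSet()
    for chrom, length in genome.chromosomes.items():
        segments: list[tuple[int, int, float]] = []
        prev = 0
        for s, e in hot.get(chrom):
            if s > prev:
                segments.append((prev, int(s), cold_rate))
            segments.append((int(s), int(e), hot_rate))
            prev = int(e)
        if prev < length:
            segments.append((prev, length, cold_rate))
        pts = []
        for s, e, rate in segments:
            lam = rate * (e - s) / 100_000.0
            if lam <= 0:
                continue
            n = rng.poisson(lam)
            if n:
                pts.append(rng.integers(s, e, size=n))
        if pts:
            out[chrom] = np.sort(np.concatenate(pts))
    return PointSet(out)


def simulate_orc_peaks(config: SimConfig) -> PointSet:
    """ORC2 summits: background ``orc_base_rate`` per 100 kb, reduced to
    ``orc_poor_rate`` inside ``orc_poor_domains``."""
    rng = _rng(config.seed, "orc")
    return _piecewise_poisson(
        rng, config.genome, config.orc_poor_domains,
        config.orc_poor_rate, config.orc_base_rate,
    )


def simulate_h2av_peaks(
    urs: IntervalSet,
    genome: GenomeLayout,
    inside_rate: float,
    outside_rate: float,
    seed: int,
) -> PointSet:
    """γH2Av summits, enriched inside URs (rates per 100 kb)."""
    rng = _rng(seed, "h2av")
    return _piecewise_poisson(rng, genome, urs, inside_rate, outside_rate)


def simulate_tads(genome: GenomeLayout, mean_width: int, seed: int,
                  boundary_gap: int | None = None) -> IntervalSet:
    """TADs tiling each chromosome with small boundary gaps.

    Widths are lognormal around ``mean_width`` (ln-scale SD 0.4); boundary
    gaps default to 5% of the mean width.
    """
    if mean_width <= 0:
        raise ValueError("mean_width must be > 0")
    rng = _rng(seed, "tads")
    gap = boundary_gap if boundary_gap is not None else max(1, mean_width // 20)
    sigma = 0.4
    mu = np.log(mean_width) - sigma**2 / 2
    records = []
    for chrom, length in genome.chromosomes.items():
        cursor = 0
        while cursor < length:
            width = int(rng.lognormal(mu, sigma))
            width = max(width, mean_width // 10)
            end = min(cursor + width, length)
            if end - cursor >= mean_width // 10:
                records.append((chrom, cursor, end))
            cursor = end + gap
    return IntervalSet.from_records(records)


def simulate_transcripts(config: SimConfig) -> pd.DataFrame:
    """Transcript table: uniform TSS, random strand, lognormal FPKM per
    tissue with a forced not-expressed (FPKM = 0) fraction."""
    rng = _rng(config.seed, "rna")
    chroms = list(config.genome.chromosomes)
    lengths = np.array([config.genome.chromosomes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(chroms), size=config.n_transcripts, p=probs)
    tss = rng.integers(0, lengths[chrom_idx].astype(np.int64))
    strand = rng.choice(["+", "-"], size=config.n_transcripts)
    df = pd.DataFrame(
        {
            "transcript_id": [f"TX{i:05d}" for i in range(config.n_transcripts)],
            "chrom": [chroms[i] for i in chrom_idx],
            "tss": tss,
            "strand": strand,
        }
    )
    for tissue, model in config.fpkm_model.items():
        fpkm = rng.lognormal(model.mean_log, model.sd_log, size=config.n_transcripts)
        zero = rng.random(config.n_transcripts) < model.zero_fraction
        fpkm[zero] = 0.0
        df[tissue] = fpkm
    return df


def simulate_tissue(config: SimConfig) -> SimulatedTissue:
    """Generate every data surface for one tissue from a single config."""
    profiles = simulate_probe_profiles(config)
    ur_intervals = IntervalSet.from_intervals([s.interval for s in config.ur_specs])
    return SimulatedTissue(
        profiles=profiles,
        orc_peaks=simulate_orc_peaks(config),
        h2av_peaks=simulate_h2av_peaks(
            ur_intervals, config.genome,
            config.h2av_inside_rate, config.h2av_outside_rate, config.seed,
        ),
        tads=simulate_tads(config.genome, config.tad_mean_width, config.seed),
        transcripts=simulate_transcripts(config),
        truth=config,
    )
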