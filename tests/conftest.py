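import numpy as np
import pytest

from polyrep.genome import GenomeLayout, GInterval, IntervalSet, PointSet


@pytest.fixture
def toy_genome() -> GenomeLayout:
    return GenomeLayout({"chr2L": 1_000_000, "chr3L": 600_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_interval_set(
    rng: np.random.Generator,
    genome: GenomeLayout,
    n: int,
    max_width: int = 50_000,
) -> IntervalSet:
    records = []
    chroms = list(genome.chromosomes)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = genome.chromosomes[chrom]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, max(1, length - width)))
        records.append((chrom, start, start + width))
    return IntervalSet.from_records(records)


def random_point_set(
    rng: np.random.Generator, genome: GenomeLayout, n: int
) -> PointSet:
    records = []
    chroms = list(genome.chromosomes)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        records.append((chrom, int(rng.integers(0, genome.chromosomes[chrom]))))
    return PointSet.from_records(records)


def bitmap(intervals: IntervalSet, genome: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base boolean oracle representation."""
    out = {}
    for chrom, length in genome.chromosomes.items():
        mask = np.zeros(length, dtype=bool)
        for s, e in intervals.get(chrom):
            mask[s:e] = True
        out[chrom] = mask
    return out


def from_bitmap(masks: dict[str, np.ndarray]) -> IntervalSet:
    records = []
    for chrom, mask in masks.items():
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            records.append((chrom, int(s), int(e)))
    return IntervalSet.from_records(records)
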