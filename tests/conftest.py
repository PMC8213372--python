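import numpy as np
import pytest

from charmod.intervals import GenomicInterval, PeakUniverse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_universe():
    """Three disjoint regions on two chromosomes."""
    return PeakUniverse(
        [
            GenomicInterval("chr1", 100, 300),
            GenomicInterval("chr1", 500, 650),
            GenomicInterval("chr2", 50, 200),
        ]
    )


def random_intervals(rng, n, chrom_length=10_000, chroms=("chr1",)):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_length - 2))
        end = int(rng.integers(start + 1, min(start + 500, chrom_length)))
        out.append(GenomicInterval(chrom, start, end))
    return out


def coverage_mask(intervals, chrom_length=10_000, chroms=("chr1",)):
    """Per-base boolean occupancy, the brute-force merge oracle."""
    masks = {c: np.zeros(chrom_length, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_to_intervals(masks):
    out = []
    for chrom in sorted(masks):
        mask = masks[chrom]
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out
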