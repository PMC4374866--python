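import numpy as np
import pandas as pd
import pytest

from karyosig.genome_model import (
    CopyNumberProfile,
    GenomeBuild,
    Segment,
    SegmentedProfile,
    Thresholds,
    level_from_log2,
    state_from_level,
)


@pytest.fixture
def build5():
    """Five 50-Mb single-armed autosomes."""
    names = tuple(f"chr{i}" for i in range(1, 6))
    return GenomeBuild(names, {n: 50_000_000 for n in names})


@pytest.fixture
def thresholds():
    return Thresholds(loss_cut=-0.3, gain_cut=0.3, amp_cut=1.5)


def make_profile(values_by_chrom, spacing=100_000, sample_id="t",
                 genotype="unknown"):
    """Build a profile from {chrom: log2 array} with tiled probes."""
    frames = []
    for chrom, values in values_by_chrom.items():
        values = np.asarray(values, dtype=float)
        starts = np.arange(len(values), dtype=np.int64) * spacing
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + spacing,
            "log2": values}))
    return CopyNumberProfile(sample_id, pd.concat(frames, ignore_index=True),
                             genotype)


def make_segments(chrom_levels, thresholds, seg_bp=1_000_000,
                  means=None, sample_id="t"):
    """SegmentedProfile from {chrom: [level,...]} with equal-width segments.

    Segment means default to representative values for each level.
    """
    def default_mean(level):
        return {-1: -1.0, 0: 0.0, 1: 0.58}.get(level, 1.5 + 0.5 * (level - 2))

    segs = []
    for chrom, levels in chrom_levels.items():
        for i, level in enumerate(levels):
            mean = (means[chrom][i] if means else default_mean(level))
            assert level_from_log2(mean, thresholds) == level
            segs.append(Segment(chrom, i * seg_bp, (i + 1) * seg_bp, mean,
                                10, state_from_level(level), level))
    return SegmentedProfile(sample_id, tuple(segs), thresholds)
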