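"""Threshold calibration, changepoint segmentation and state assignment.

Gain/loss cutoffs are calibrated from a self-self (control vs control)
hybridization: under the null every probe measures a log2 ratio of zero
plus array noise, so the trimmed moments of that profile give the null
scatter directly and a k-sigma rule yields the cutoffs.

Segmentation minimizes, per chromosome, the within-segment sum of squared
deviations plus a per-breakpoint penalty, by exact dynamic programming.
The optimum is therefore identical to exhaustive enumeration over all
breakpoint subsets (testable at small n) and deterministic in the penalty.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .genome_model import (
    AMP_TIER_STEP,
    CopyNumberProfile,
    Segment,
    SegmentedProfile,
    Thresholds,
    ValidationError,
    level_from_log2,
    state_from_level,
)

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """The null profile cannot support stable threshold calibration."""


def calibrate_thresholds(null_profile: CopyNumberProfile, k: float = 3.0,
                         amp_multiplier: float = 5.0,
                         trim: float = 0.01) -> Thresholds:
    """Derive log2 cutoffs from a self-self control hybridization.

    The extreme ``trim`` fraction of probes on each tail is discarded, then

    * gain cut = trimmed mean + k * trimmed sd
    * loss cut = trimmed mean - k * trimmed sd
    * amplification cut = amp_multiplier * gain cut

    ``k=3`` (three-sigma) with ``amp_multiplier=5`` are conservative
    defaults for a self-self array.
    """
    if k <= 0:
        raise CalibrationError("k must be positive")
    values = null_profile.probes["log2"].to_numpy(dtype=float)
    if len(values) < 100:
        raise CalibrationError(
            f"only {len(values)} probes; need >= 100 for a stable sd")
    trimmed = stats.trimboth(values, trim)
    mean = float(np.mean(trimmed))
    sd = float(np.std(trimmed, ddof=1))
    if sd <= 0:
        raise CalibrationError("null profile has zero variance")
    gain = mean + k * sd
    loss = mean - k * sd
    if not loss < 0 < gain:
        raise CalibrationError(
            f"null profile is not centered: cuts ({loss:.4g}, {gain:.4g})")
    return Thresholds(loss_cut=loss, gain_cut=gain,
                      amp_cut=amp_multiplier * gain)


def _auto_penalty(values: np.ndarray) -> float:
    # BIC-style default: 2 * sigma^2 * log n, sigma from the median absolute
    # first difference (robust to the segment structure itself).
    n = len(values)
    if n < 2:
        return 1e-8
    diffs = np.abs(np.diff(values))
    sigma = np.median(diffs) / (math.sqrt(2.0) * 0.67448975)
    return max(2.0 * sigma * sigma * math.log(max(n, 2)), 1e-8)


def _optimal_breaks(values: np.ndarray, penalty: float,
                    min_probes: int) -> list[int]:
    """Exact penalized least-squares changepoints for one chromosome.

    Returns interior breakpoints as probe indices (segment boundaries),
    minimizing  sum of within-segment SSE + penalty * (#breakpoints),
    every segment holding at least ``min_probes`` probes.  O(n^2) dynamic
    program; ties broken toward the earlier split for determinism.
    """
    n = len(values)
    if n < 2 * min_probes:
        return []
    c1 = np.concatenate(([0.0], np.cumsum(values)))
    c2 = np.concatenate(([0.0], np.cumsum(values * values)))
    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment carries no breakpoint cost
    back = np.zeros(n + 1, dtype=np.intp)
    for j in range(min_probes, n + 1):
        i = np.arange(0, j - min_probes + 1)
        m = j - i
        s = c1[j] - c1[i]
        cost = (c2[j] - c2[i]) - s * s / m
        cand = best[i] + penalty + cost
        b = int(np.argmin(cand))
        best[j] = cand[b]
        back[j] = i[b]
    breaks: list[int] = []
    j = n
    while j > 0:
        i = int(back[j])
        if i > 0:
            breaks.append(i)
        j = i
    breaks.reverse()
    return breaks


def segment_profile(profile: CopyNumberProfile, penalty: float | None = None,
                    min_probes: int = 5) -> SegmentedProfile:
    """Partition each chromosome into constant-copy-number segments.

    ``penalty`` is the cost per breakpoint in squared-log2 units; ``None``
    selects a BIC-style default from a robust per-chromosome noise
    estimate.  ``min_probes`` suppresses segments supported by fewer
    probes.  Chromosomes with fewer than ``min_probes`` probes become a
    single segment (with a warning).  States are not assigned here; see
    :func:`assign_states`.
    """
    if penalty is not None and penalty <= 0:
        raise ValidationError("penalty must be positive")
    if min_probes < 1:
        raise ValidationError("min_probes must be >= 1")
    segments: list[Segment] = []
    for chrom in profile.chromosomes:
        grp = profile.chromosome(chrom)
        values = grp["log2"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n = len(values)
        if n < min_probes:
            logger.warning("chromosome %s has %d < %d probes; "
                           "emitting a single segment", chrom, n, min_probes)
            breaks: list[int] = []
        else:
            pen = _auto_penalty(values) if penalty is None else penalty
            breaks = _optimal_breaks(values, pen, min_probes)
        bounds = [0] + breaks + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(
                chrom=chrom, start=int(starts[a]), end=int(ends[b - 1]),
                mean_log2=float(np.mean(values[a:b])), n_probes=b - a))
    return SegmentedProfile(profile.sample_id, tuple(segments))


def assign_states(seg: SegmentedProfile, thresholds: Thresholds,
                  tier_step: float = AMP_TIER_STEP) -> SegmentedProfile:
    """Assign discrete states and merge same-level adjacent segments.

    State by mean log2: below the loss cut -> LOSS; at/above the
    amplification cut -> AMP (tiered by ``tier_step``); at/above the gain
    cut -> GAIN; otherwise NEUTRAL.  Consecutive segments sharing a level
    are merged; the merged mean is the bp-weighted average and probe counts
    are summed.
    """
    merged: list[Segment] = []
    for s in seg.segments:
        level = level_from_log2(s.mean_log2, thresholds, tier_step)
        cur = Segment(s.chrom, s.start, s.end, s.mean_log2, s.n_probes,
                      state_from_level(level), level)
        if (merged and merged[-1].chrom == cur.chrom
                and merged[-1].level == cur.level):
            prev = merged.pop()
            w_prev = prev.end - prev.start
            w_cur = cur.end - cur.start
            mean = (prev.mean_log2 * w_prev + cur.mean_log2 * w_cur) / (
                w_prev + w_cur)
            cur = Segment(prev.chrom, prev.start, cur.end, mean,
                          prev.n_probes + cur.n_probes, prev.state, prev.level)
        merged.append(cur)
    return SegmentedProfile(seg.sample_id, tuple(merged), thresholds)


def segment_and_call(profile: CopyNumberProfile, thresholds: Thresholds,
                     penalty: float | None = None, min_probes: int = 5,
                     tier_step: float = AMP_TIER_STEP) -> SegmentedProfile:
    """Convenience: segmentation followed by state assignment."""
    return assign_states(segment_profile(profile, penalty, min_probes),
                         thresholds, tier_step)
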