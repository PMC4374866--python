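"""Copy-number rearrangement-signature detectors.

Implements the classification rules applied to segmented aCGH profiles of
the p53-knockout rat tumors:

* **arm-level aneuploidy** — a single alteration or aggregate of same-state
  alterations covering more than 75% of a chromosomal arm;
* **chromothripsis** — at least ten adjacent-segment copy-number switches
  involving two or three distinct copy-number states on one chromosome
  (the Rausch-style count, applied after same-state merging);
* **breakage-fusion-bridge (BFB)** — a stair of at least three strictly
  increasing copy-number states running toward a chromosome terminus,
  bounded on the interior side by a single sharp drop;
* **LOH mechanism** — given that loss of heterozygosity at a locus was
  established independently, classify the copy-number mechanism as
  deletion, chromothripsis, or copy-neutral (gene conversion / SV).

"Changes in segmental copy-number" is operationalized as adjacent-segment
level switches after same-level merging, the only unambiguous reading on
segmented data.  Distinct-state counts are per whole chromosome and include
NEUTRAL, since oscillation patterns include the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .genome_model import (
    GeneAnnotation,
    GenomeBuild,
    Segment,
    SegmentedProfile,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmEventCall:
    """An arm- or chromosome-level gain or loss (aneuploidy)."""

    chrom: str
    arm: str  # "p", "q" or "whole"
    state: str  # "LOSS" or "GAIN" (AMP collapsed into GAIN)
    fraction: float

    def __post_init__(self) -> None:
        if self.state not in ("LOSS", "GAIN"):
            raise ValidationError(f"arm event state {self.state!r}")
        if not 0 < self.fraction <= 1:
            raise ValidationError("arm event fraction outside (0, 1]")


@dataclass(frozen=True)
class ChromothripsisCall:
    chrom: str
    n_switches: int
    distinct_states: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_switches < 10:
            raise ValidationError("chromothripsis call with < 10 switches")
        if self.distinct_states not in (2, 3):
            raise ValidationError("chromothripsis call with state count "
                                  f"{self.distinct_states}")


@dataclass(frozen=True)
class BFBCall:
    chrom: str
    anchor: str  # "start" or "end"
    n_stairs: int
    peak_level: int
    amplified_interval: tuple[int, int]
    stair_segments: tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        if self.n_stairs < 3:
            raise ValidationError("BFB call with < 3 stairs")
        if self.anchor not in ("start", "end"):
            raise ValidationError(f"BFB anchor {self.anchor!r}")


def _state_class(level: int) -> str | None:
    """Collapse a level into the two aneuploidy classes (None = neutral)."""
    if level < 0:
        return "LOSS"
    if level > 0:
        return "GAIN"
    return None


def call_arm_events(seg: SegmentedProfile, build: GenomeBuild,
                    fraction_threshold: float = 0.75) -> list[ArmEventCall]:
    """Call arm-level gains/losses covering > ``fraction_threshold`` of an arm.

    Per arm, the bp of LOSS segments and of GAIN-or-AMP segments are
    aggregated separately; a call is emitted when one class strictly
    exceeds the threshold.  At most one call per arm — the larger fraction
    wins; an exact tie yields no call (logged).
    """
    if not seg.has_states:
        raise ValidationError("states must be assigned before arm calling")
    calls: list[ArmEventCall] = []
    for chrom in seg.chromosomes:
        segs = seg.chromosome(chrom)
        for side, arm_start, arm_end in build.arms(chrom):
            arm_len = arm_end - arm_start
            covered = {"LOSS": 0, "GAIN": 0}
            for s in segs:
                cls = _state_class(s.level)
                if cls is None:
                    continue
                covered[cls] += max(
                    0, min(s.end, arm_end) - max(s.start, arm_start))
            frac = {cls: bp / arm_len for cls, bp in covered.items()}
            qualifying = {cls: f for cls, f in frac.items()
                          if f > fraction_threshold}
            if not qualifying:
                continue
            if len(qualifying) == 2 and frac["LOSS"] == frac["GAIN"]:
                logger.warning("tied LOSS/GAIN arm fractions on %s %s; "
                               "no call emitted", chrom, side)
                continue
            state = max(qualifying, key=qualifying.get)
            calls.append(ArmEventCall(chrom, side, state, frac[state]))
    return calls


def count_altered_bp(seg: SegmentedProfile,
                     arm_events: Sequence[ArmEventCall],
                     build: GenomeBuild | None = None) -> int:
    """Total bp in non-neutral segments, excluding called aneuploidies.

    Base pairs of a segment that fall on an arm carrying an
    :class:`ArmEventCall` of the same state class are excluded, so this
    counts the focal CNV burden only.
    """
    if not seg.has_states:
        raise ValidationError("states must be assigned")
    arm_intervals: dict[tuple[str, str], tuple[int, int]] = {}
    for ev in arm_events:
        if ev.arm == "whole":
            iv = None  # whole chromosome
        else:
            if build is None:
                raise ValidationError(
                    "build required to resolve p/q arm intervals")
            iv = build.arm_interval(ev.chrom, ev.arm)
        arm_intervals[(ev.chrom, ev.arm)] = iv
    total = 0
    for s in seg.segments:
        cls = _state_class(s.level)
        if cls is None:
            continue
        length = s.end - s.start
        for ev in arm_events:
            if ev.chrom != s.chrom or ev.state != cls:
                continue
            iv = arm_intervals[(ev.chrom, ev.arm)]
            if iv is None:
                length -= s.end - s.start
            else:
                length -= max(0, min(s.end, iv[1]) - max(s.start, iv[0]))
        total += max(0, length)
    return total


def detect_chromothripsis(seg: SegmentedProfile, min_switches: int = 10,
                          allowed_distinct_states: Sequence[int] = (2, 3),
                          ) -> list[ChromothripsisCall]:
    """Detect the chromothripsis copy-number signature per chromosome.

    A chromosome is called when the number of adjacent-segment level
    switches is at least ``min_switches`` and the number of distinct
    copy-number levels present is in ``allowed_distinct_states``.
    Assumes same-level merging has been applied (so every adjacent pair
    is a switch candidate exactly once).
    """
    if not seg.has_states:
        raise ValidationError("states must be assigned")
    calls: list[ChromothripsisCall] = []
    for chrom in seg.chromosomes:
        segs = seg.chromosome(chrom)
        levels = [s.level for s in segs]
        n_switches = sum(1 for a, b in zip(levels, levels[1:]) if a != b)
        distinct = len(set(levels))
        if n_switches >= min_switches and distinct in allowed_distinct_states:
            altered = [s for s in segs if s.level != 0] or list(segs)
            span = (min(s.start for s in altered),
                    max(s.end for s in altered))
            calls.append(ChromothripsisCall(chrom, n_switches, distinct, span))
    return calls


def detect_bfb(seg: SegmentedProfile, min_stairs: int = 3,
               drop_levels: int = 2) -> list[BFBCall]:
    """Detect breakage-fusion-bridge stair signatures at chromosome termini.

    From each terminus, the maximal run of above-neutral segments whose
    level strictly decreases moving inward is collected.  A call is emitted
    when the run holds at least ``min_stairs`` segments and the segment
    immediately interior to the run sits at or below NEUTRAL or at least
    ``drop_levels`` levels below the run's minimum (the single sharp drop).
    """
    if not seg.has_states:
        raise ValidationError("states must be assigned")
    calls: list[BFBCall] = []
    for chrom in seg.chromosomes:
        segs = seg.chromosome(chrom)
        for anchor in ("start", "end"):
            ordered = segs if anchor == "start" else segs[::-1]
            run: list[Segment] = []
            for s in ordered:
                if s.level <= 0:
                    break
                if run and s.level >= run[-1].level:
                    break
                run.append(s)
            if len(run) < min_stairs or len(run) == len(ordered):
                continue
            interior = ordered[len(run)]
            run_min = run[-1].level
            if interior.level <= 0 or interior.level <= run_min - drop_levels:
                stair = tuple(sorted(run, key=lambda s: s.start))
                calls.append(BFBCall(
                    chrom=chrom, anchor=anchor, n_stairs=len(run),
                    peak_level=run[0].level,
                    amplified_interval=(stair[0].start, stair[-1].end),
                    stair_segments=stair))
    return calls


def annotate_amplified_genes(calls: Sequence[BFBCall],
                             genes: GeneAnnotation) -> list[list[str]]:
    """Genes overlapping amplified (level >= 2) stair segments, per call.

    Any overlap counts (half-open interval intersection); a call with no
    amplified gene yields an empty list.
    """
    out: list[list[str]] = []
    for call in calls:
        hits: list[str] = []
        for sym, g_start, g_end in genes.on_chromosome(call.chrom):
            for s in call.stair_segments:
                if s.level >= 2 and g_start < s.end and s.start < g_end:
                    hits.append(sym)
                    break
        out.append(hits)
    return out


LOH_DELETION = "deletion"
LOH_CHROMOTHRIPSIS = "affected by chromothripsis"
LOH_COPY_NEUTRAL = "gene conversion or copy-neutral SV"


def classify_loh_mechanism(seg: SegmentedProfile,
                           ct_calls: Sequence[ChromothripsisCall],
                           locus: tuple[str, int, int]) -> str:
    """Classify the copy-number mechanism behind an established LOH event.

    Precedence: a chromothripsis call on the locus chromosome wins (such
    chromosomes contain losses, but the table records them as their own
    category); otherwise an overlap of the locus with a LOSS segment is a
    deletion; otherwise the LOH is copy-neutral (gene conversion or
    copy-neutral structural variant).  The caller is responsible for
    having established LOH independently.
    """
    chrom, start, end = locus
    if chrom not in seg.chromosomes:
        raise ValidationError(
            f"locus chromosome {chrom!r} absent from the segmented profile "
            "(excluded from analysis?)")
    if any(c.chrom == chrom for c in ct_calls):
        return LOH_CHROMOTHRIPSIS
    for s in seg.chromosome(chrom):
        if s.level < 0 and start < s.end and s.start < end:
            return LOH_DELETION
    return LOH_COPY_NEUTRAL


def cooccurrence_summary(records: Sequence) -> tuple[int, int, int]:
    """Co-occurrence of BFB and chromothripsis across tumor records.

    Returns ``(n BFB tumors, n BFB tumors that also have chromothripsis,
    n tumors where the two events share an affected chromosome)``.
    ``records`` need only expose ``bfb``, ``chromothripsis``,
    ``bfb_chroms`` and ``ct_chroms``.
    """
    n_bfb = sum(1 for r in records if r.bfb)
    n_both = sum(1 for r in records if r.bfb and r.chromothripsis)
    n_shared = sum(1 for r in records
                   if set(r.bfb_chroms) & set(r.ct_chroms))
    return n_bfb, n_both, n_shared
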