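"""Coordinate-aware data types for copy-number analysis.

All genomic intervals are 0-based half-open, BED style.  The central
containers are :class:`CopyNumberProfile` (probe-level log2 ratios of tumor
vs matched-control DNA from a two-color aCGH experiment) and
:class:`SegmentedProfile` (its partition into constant-copy-number
segments).  Discrete copy-number states are represented two ways:

* a 4-way class label (``LOSS`` / ``NEUTRAL`` / ``GAIN`` / ``AMP``), and
* an integer *level*: -1 for a loss, 0 for neutral, 1 for a single-copy
  gain, and 2, 3, ... for successive amplification tiers ordered by mean
  log2 ratio.

The level carries strictly more information than the class label: two
adjacent amplified segments at different tiers are genuinely different
copy-number states (the situation a breakage-fusion-bridge stair creates),
so segment merging and switch counting operate on levels throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

LOSS = "LOSS"
NEUTRAL = "NEUTRAL"
GAIN = "GAIN"
AMP = "AMP"

#: default log2-ratio spacing between successive amplification tiers
AMP_TIER_STEP = 0.5


class ProfileParseError(ValueError):
    """A probe or segment file could not be parsed."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


def state_from_level(level: int) -> str:
    """Map an integer copy-number level to its 4-way class label."""
    if level < 0:
        return LOSS
    if level == 0:
        return NEUTRAL
    if level == 1:
        return GAIN
    return AMP


def level_from_log2(mean_log2: float, thresholds: "Thresholds",
                    tier_step: float = AMP_TIER_STEP) -> int:
    """Discretize a segment mean log2 ratio into an integer level.

    Values at or above the amplification cutoff are binned into tiers of
    width ``tier_step`` (nearest tier wins), so stair-step amplifications
    produced by breakage-fusion-bridge cycles remain distinguishable.
    Boundary values classify into the altered state (``>= cut`` is altered).
    """
    if mean_log2 < thresholds.loss_cut:
        return -1
    if mean_log2 >= thresholds.amp_cut:
        tier = int(round((mean_log2 - thresholds.amp_cut) / tier_step))
        return 2 + max(0, tier)
    if mean_log2 >= thresholds.gain_cut:
        return 1
    return 0


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio cutoffs separating copy-number states.

    Calibrated from a self-self (control vs control) hybridization; see
    :func:`karyosig.cnv_segmentation.calibrate_thresholds`.
    """

    loss_cut: float
    gain_cut: float
    amp_cut: float

    def __post_init__(self) -> None:
        if not (self.loss_cut < 0.0 < self.gain_cut < self.amp_cut):
            raise ValidationError(
                f"thresholds must satisfy loss < 0 < gain < amp, got "
                f"({self.loss_cut}, {self.gain_cut}, {self.amp_cut})")

    def to_dict(self) -> dict:
        return {"loss_cut": self.loss_cut, "gain_cut": self.gain_cut,
                "amp_cut": self.amp_cut}

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        return cls(d["loss_cut"], d["gain_cut"], d["amp_cut"])


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome names, lengths and optional centromere positions.

    ``excluded`` chromosomes (by default the sex chromosomes) are dropped on
    load and never reach downstream analysis.  Chromosomes without a
    recorded centromere are treated as single-armed, i.e. the whole
    chromosome is the arm — appropriate for the mostly acrocentric rat
    karyotype.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        for name in self.chromosomes:
            if name not in self.lengths:
                raise ValidationError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValidationError(f"non-positive length for {name!r}")
        for name, pos in self.centromeres.items():
            if name not in self.lengths:
                raise ValidationError(f"centromere for unknown chrom {name!r}")
            if not 0 < pos < self.lengths[name]:
                raise ValidationError(
                    f"centromere of {name!r} not strictly inside chromosome")
        if not self.excluded <= set(self.chromosomes):
            raise ValidationError("excluded set contains unknown chromosomes")

    @property
    def analysis_chromosomes(self) -> tuple[str, ...]:
        """Chromosomes that participate in analysis (excluded set removed)."""
        return tuple(c for c in self.chromosomes if c not in self.excluded)

    def chrom_order(self, chrom: str) -> int:
        return self.chromosomes.index(chrom)

    def arms(self, chrom: str) -> list[tuple[str, int, int]]:
        """Arm intervals of ``chrom`` as ``(side, start, end)`` triples.

        ``side`` is ``"whole"`` for single-armed chromosomes, else
        ``"p"``/``"q"`` split at the centromere.
        """
        length = self.lengths[chrom]
        cen = self.centromeres.get(chrom)
        if cen is None:
            return [("whole", 0, length)]
        return [("p", 0, cen), ("q", cen, length)]

    def arm_interval(self, chrom: str, side: str) -> tuple[int, int]:
        for s, start, end in self.arms(chrom):
            if s == side:
                return start, end
        raise ValidationError(f"arm {side!r} not defined for {chrom!r}")

    @classmethod
    def from_table(cls, path: str | Path,
                   excluded: Iterable[str] = ()) -> "GenomeBuild":
        """Read a 2-3 column tab-delimited table: chrom, length[, centromere]."""
        chroms: list[str] = []
        lengths: dict[str, int] = {}
        centromeres: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ProfileParseError(
                    f"{path}:{lineno}: expected 2-3 columns, got {len(parts)}")
            try:
                chroms.append(parts[0])
                lengths[parts[0]] = int(parts[1])
                if len(parts) == 3 and parts[2] not in ("", "."):
                    centromeres[parts[0]] = int(parts[2])
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
        return cls(tuple(chroms), lengths, centromeres, frozenset(excluded))


@dataclass(frozen=True)
class CopyNumberProfile:
    """One sample's ordered probe-level log2 ratios.

    ``probes`` is a DataFrame with columns ``chrom``, ``start``, ``end``,
    ``log2`` — sorted by build chromosome order then start, non-overlapping
    within each chromosome.
    """

    sample_id: str
    probes: pd.DataFrame
    genotype: str = "unknown"

    _GENOTYPES = ("+/+", "+/-", "-/-", "unknown")

    def __post_init__(self) -> None:
        if self.genotype not in self._GENOTYPES:
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        required = ["chrom", "start", "end", "log2"]
        if list(self.probes.columns[:4]) != required:
            raise ValidationError(
                f"probe table must have columns {required}")
        if len(self.probes) == 0:
            raise ValidationError("profile has no probes")
        starts = self.probes["start"].to_numpy()
        ends = self.probes["end"].to_numpy()
        if (starts >= ends).any():
            raise ValidationError("probe with start >= end")
        for _, grp in self.probes.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValidationError("overlapping or unsorted probes")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.probes[self.probes["chrom"] == chrom]

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.probes["chrom"].unique())


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number run of probes."""

    chrom: str
    start: int
    end: int
    mean_log2: float
    n_probes: int
    state: str | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"segment end <= start on {self.chrom}")
        if self.n_probes < 1:
            raise ValidationError("segment with no probes")
        if (self.state is None) != (self.level is None):
            raise ValidationError("state and level must be set together")
        if self.level is not None and self.state != state_from_level(self.level):
            raise ValidationError(
                f"state {self.state!r} inconsistent with level {self.level}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentedProfile:
    """Partition of a profile into segments, optionally with states assigned.

    After state assignment, adjacent segments within a chromosome always
    carry distinct copy-number levels (same-level runs are merged).
    """

    sample_id: str
    segments: tuple[Segment, ...]
    thresholds: Thresholds | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom:
                if seg.start < prev.end:
                    raise ValidationError(
                        f"overlapping/unsorted segments on {seg.chrom}")
                if (seg.level is not None and prev.level is not None
                        and seg.level == prev.level):
                    raise ValidationError(
                        f"adjacent same-level segments on {seg.chrom}")
            prev = seg

    @property
    def has_states(self) -> bool:
        return all(s.state is not None for s in self.segments)

    def chromosome(self, chrom: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.chrom == chrom)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.segments:
            if s.chrom not in seen:
                seen.append(s.chrom)
        return tuple(seen)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals used to annotate amplified segments."""

    records: tuple[tuple[str, str, int, int], ...]  # (symbol, chrom, start, end)

    def __post_init__(self) -> None:
        for sym, chrom, start, end in self.records:
            if start >= end:
                raise ValidationError(f"gene {sym}: start >= end")

    def on_chromosome(self, chrom: str) -> list[tuple[str, int, int]]:
        return [(sym, s, e) for sym, c, s, e in self.records if c == chrom]

    @classmethod
    def from_bed(cls, path: str | Path,
                 build: GenomeBuild | None = None) -> "GeneAnnotation":
        """Read a 4-column BED: chrom, start, end, name."""
        recs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
            if build is not None and chrom not in build.lengths:
                raise ValidationError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in build")
            recs.append((name, chrom, start, end))
        return cls(tuple(recs))


def load_probe_profile(path: str | Path, build: GenomeBuild,
                       sample_id: str | None = None,
                       genotype: str = "unknown") -> CopyNumberProfile:
    """Load a 4-column tab-delimited probe file (bedGraph dialect).

    Rows are re-sorted into build order; probes on excluded chromosomes are
    dropped; chromosomes absent from the build raise.  ``#``-comment lines
    are allowed.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 4:
            raise ProfileParseError(
                f"{path}:{lineno}: expected 4 tab-delimited columns, "
                f"got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         float(parts[3])))
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValidationError(f"{path}: no probe rows")
    for chrom, *_ in rows:
        if chrom not in build.lengths:
            raise ValidationError(f"{path}: chromosome {chrom!r} not in build")
    rows = [r for r in rows if r[0] not in build.excluded]
    if not rows:
        raise ValidationError(
            f"{path}: all probes fall on excluded chromosomes")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "log2"])
    order = {c: i for i, c in enumerate(build.chromosomes)}
    df = (df.assign(_o=df["chrom"].map(order))
            .sort_values(["_o", "start"], kind="stable")
            .drop(columns="_o")
            .reset_index(drop=True))
    return CopyNumberProfile(sample_id or path.stem, df, genotype)


def write_probe_profile(profile: CopyNumberProfile, path: str | Path) -> None:
    """Write a profile in the 4-column tab-delimited dialect."""
    with open(path, "w") as fh:
        for row in profile.probes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.log2!r}\n")


def write_segments(seg: SegmentedProfile, path: str | Path) -> None:
    """Write segments as BED-like 6 columns.

    Columns: chrom, start, end, state (``.`` if unassigned), mean log2
    (full precision), probe count.  Round-trips losslessly through
    :func:`read_segments` when the same thresholds are supplied.
    """
    with open(path, "w") as fh:
        for s in seg.segments:
            state = s.state if s.state is not None else "."
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{state}\t"
                     f"{s.mean_log2!r}\t{s.n_probes}\n")


def read_segments(path: str | Path, sample_id: str | None = None,
                  thresholds: Thresholds | None = None,
                  tier_step: float = AMP_TIER_STEP) -> SegmentedProfile:
    """Read segments written by :func:`write_segments`.

    If ``thresholds`` are supplied, levels are re-derived from each mean
    log2 (a deterministic mapping, so write→read is the identity).
    """
    path = Path(path)
    segs: list[Segment] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ProfileParseError(
                f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            mean_log2, n_probes = float(parts[4]), int(parts[5])
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
        if thresholds is not None and parts[3] != ".":
            level = level_from_log2(mean_log2, thresholds, tier_step)
            segs.append(Segment(chrom, start, end, mean_log2, n_probes,
                                state_from_level(level), level))
        else:
            segs.append(Segment(chrom, start, end, mean_log2, n_probes))
    return SegmentedProfile(sample_id or path.stem, tuple(segs), thresholds)


def arm_fraction(segments: Sequence[Segment], arm: tuple[str, str],
                 build: GenomeBuild) -> float:
    """Fraction of a chromosomal arm covered by the given segments.

    ``arm`` is ``(chrom, side)`` with side ``"p"``, ``"q"`` or ``"whole"``.
    Additive over disjoint segment lists; never exceeds 1 for
    non-overlapping input.
    """
    chrom, side = arm
    arm_start, arm_end = build.arm_interval(chrom, side)
    covered = 0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        if seg.start < 0 or seg.end > build.lengths[chrom]:
            raise ValidationError(
                f"segment {seg.start}-{seg.end} off chromosome {chrom}")
        covered += max(0, min(seg.end, arm_end) - max(seg.start, arm_start))
    return covered / (arm_end - arm_start)
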