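"""Synthetic profiles, cohorts and read sets with known ground truth.

The generator is the inverse of the detectors: it plants whole-chromosome
gains/losses, focal CNVs, chromothripsis oscillation patterns and
breakage-fusion-bridge amplification stairs into probe-level log2-ratio
profiles, records every breakpoint in a truth manifest, and emits shallow
whole-genome read sets whose telomeric-repeat content corresponds to a
chosen true telomere length.

Probe log2 ratios are the segment's true state mean plus Gaussian noise.
The default state->log2 map places single-copy changes on a diploid
background (log2(1/2) = -1 for a loss, log2(3/2) = 0.58 for a gain) with
amplification tiers at 1.5 + 0.5 per extra tier.  Event breakpoints are
snapped to the probe grid so that noise-free profiles are exactly
recoverable.  All randomness flows from the single supplied seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import CopyNumberProfile, GenomeBuild, ValidationError

ANEUPLOIDY = "ANEUPLOIDY"
FOCAL_CNV = "FOCAL_CNV"
CHROMOTHRIPSIS = "CHROMOTHRIPSIS"
BFB = "BFB"

#: default noise scatter of simulated probes, log2 units
DEFAULT_NOISE_SD = 0.15

#: minimum simulated segment width, in probe spacings
MIN_SEGMENT_SPACINGS = 3


def default_state_log2(level: int) -> float:
    """Default true mean log2 ratio for an integer copy-number level."""
    if level <= -1:
        return -1.0
    if level == 0:
        return 0.0
    if level == 1:
        return 0.58
    return 1.5 + 0.5 * (level - 2)


@dataclass(frozen=True)
class EventSpec:
    """One planted event.

    Kind-specific parameters: ``level`` (aneuploidy), ``interval`` +
    ``level`` (focal CNV), ``n_breakpoints`` + ``alphabet`` of levels
    (chromothripsis), ``n_stairs`` + ``anchor`` + ``max_level`` (BFB).
    """

    kind: str
    chrom: str
    level: int | None = None
    interval: tuple[int, int] | None = None
    n_breakpoints: int | None = None
    alphabet: tuple[int, ...] | None = None
    n_stairs: int | None = None
    anchor: str | None = None
    max_level: int | None = None

    def __post_init__(self) -> None:
        if self.kind == ANEUPLOIDY:
            if self.level is None or self.level == 0:
                raise ValidationError("aneuploidy needs a non-neutral level")
        elif self.kind == FOCAL_CNV:
            if self.interval is None or self.level in (None, 0):
                raise ValidationError("focal CNV needs interval and level")
        elif self.kind == CHROMOTHRIPSIS:
            if self.n_breakpoints is None or self.n_breakpoints < 11:
                raise ValidationError(
                    "chromothripsis needs >= 11 breakpoints")
            if self.alphabet is None or len(set(self.alphabet)) not in (2, 3):
                raise ValidationError(
                    "chromothripsis alphabet must hold 2 or 3 states")
        elif self.kind == BFB:
            if self.n_stairs is None or self.n_stairs < 3:
                raise ValidationError("BFB needs >= 3 stairs")
            if self.anchor not in ("start", "end"):
                raise ValidationError("BFB anchor must be start or end")
            if self.max_level is None or self.max_level < self.n_stairs:
                raise ValidationError(
                    "BFB max_level must be >= n_stairs (stairs stay above "
                    "neutral)")
        else:
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class CohortDesign:
    """Per-genotype sample sizes and event rates for a simulated cohort.

    Defaults emulate the study contrast: 16 heterozygous tumors with
    frequent rearrangement signatures versus 10 homozygous tumors with
    quiet genomes.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"+/-": 16, "-/-": 10})
    p_chromothripsis: dict[str, float] = field(
        default_factory=lambda: {"+/-": 9 / 16, "-/-": 0.0})
    p_bfb: dict[str, float] = field(
        default_factory=lambda: {"+/-": 6 / 16, "-/-": 0.0})
    aneuploidy_rate: dict[str, float] = field(
        default_factory=lambda: {"+/-": 0.25, "-/-": 0.015})
    focal_rate: dict[str, float] = field(
        default_factory=lambda: {"+/-": 3.0, "-/-": 0.5})
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        for rates in (self.p_chromothripsis, self.p_bfb,
                      self.aneuploidy_rate):
            for p in rates.values():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError("probabilities must lie in [0,1]")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be >= 0")


def _grid_cells(length: int, spacing: int) -> int:
    if spacing <= 0:
        raise ValidationError("probe spacing must be positive")
    cells = length // spacing
    if cells < 1:
        raise ValidationError("chromosome shorter than one probe spacing")
    return cells


def inject_chromothripsis(chrom_length: int, n_breakpoints: int,
                          state_alphabet: Sequence[int], seed,
                          probe_spacing: int = 100_000,
                          ) -> list[tuple[int, int, int]]:
    """Plan a chromothripsis oscillation: ``(start, end, level)`` segments.

    ``n_breakpoints`` uniformly random grid-snapped breakpoints partition
    the chromosome (minimum segment width ``MIN_SEGMENT_SPACINGS`` probe
    spacings); adjacent segments always receive different levels from the
    alphabet, so the plan has exactly ``n_breakpoints`` switches.
    """
    alphabet = tuple(dict.fromkeys(state_alphabet))
    if len(alphabet) < 2:
        raise ValidationError("state alphabet must hold >= 2 states")
    if len(alphabet) > 3:
        raise ValidationError("state alphabet must hold <= 3 states")
    if n_breakpoints < 11:
        raise ValidationError("need >= 11 breakpoints")
    rng = np.random.default_rng(seed)
    m = _grid_cells(chrom_length, probe_spacing)
    g = MIN_SEGMENT_SPACINGS
    # uniform sample of breakpoint cell indices b_1<...<b_n with b_1 >= g,
    # b_n <= m-g and gaps >= g, via the standard min-gap bijection
    lo, hi = g, m - g - (g - 1) * (n_breakpoints - 1)
    if hi < lo + n_breakpoints - 1:
        raise ValidationError(
            f"chromosome too short for {n_breakpoints} breakpoints at "
            f"spacing {probe_spacing}")
    e = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_breakpoints,
                           replace=False))
    breaks = e + (g - 1) * np.arange(n_breakpoints)
    bounds = [0] + [int(b) * probe_spacing for b in breaks] + [chrom_length]
    levels: list[int] = []
    for _ in range(n_breakpoints + 1):
        choices = [s for s in alphabet if not levels or s != levels[-1]]
        levels.append(int(choices[rng.integers(len(choices))]))
    return [(bounds[i], bounds[i + 1], levels[i])
            for i in range(len(levels))]


def inject_bfb(chrom_length: int, n_stairs: int, anchor: str,
               max_level: int, seed, probe_spacing: int = 100_000,
               ) -> list[tuple[int, int, int]]:
    """Plan a BFB amplification stair: ``(start, end, level)`` segments.

    ``n_stairs`` segments rise strictly toward the anchored terminus,
    topping out at ``max_level``; the rest of the chromosome is NEUTRAL
    (the single sharp drop on the interior side).  An anchor=start plan is
    the exact coordinate mirror of the anchor=end plan for the same seed.
    """
    if n_stairs < 3:
        raise ValidationError("need >= 3 stairs")
    if anchor not in ("start", "end"):
        raise ValidationError("anchor must be 'start' or 'end'")
    if max_level < n_stairs:
        raise ValidationError("max_level must be >= n_stairs")
    rng = np.random.default_rng(seed)
    m = _grid_cells(chrom_length, probe_spacing)
    g = MIN_SEGMENT_SPACINGS
    widths = rng.integers(g, 3 * g + 1, size=n_stairs)  # cells per stair
    if int(widths.sum()) + g > m:
        raise ValidationError(
            f"chromosome too short for {n_stairs} stairs at spacing "
            f"{probe_spacing}")
    # build anchored at the end, then mirror if anchored at the start
    levels = list(range(max_level - n_stairs + 1, max_level + 1))
    bounds = [m]
    for w in widths:  # widths[0] is the terminal (peak) stair
        bounds.append(bounds[-1] - int(w))
    bounds.reverse()  # interior ... terminal
    plan = [(0, bounds[0] * probe_spacing, 0)]
    for i in range(n_stairs):
        start = bounds[i] * probe_spacing
        end = chrom_length if i == n_stairs - 1 else bounds[i + 1] * probe_spacing
        plan.append((start, end, levels[i]))
    if anchor == "start":
        plan = [(chrom_length - e, chrom_length - s, lev)
                for s, e, lev in reversed(plan)]
    return plan


def _event_plan(event: EventSpec, build: GenomeBuild, probe_spacing: int,
                rng: np.random.Generator) -> list[tuple[int, int, int]]:
    length = build.lengths[event.chrom]
    sub = int(rng.integers(0, 2**31 - 1))
    if event.kind == ANEUPLOIDY:
        return [(0, length, event.level)]
    if event.kind == FOCAL_CNV:
        start, end = event.interval
        if not 0 <= start < end <= length:
            raise ValidationError("focal interval off chromosome")
        return [(start, end, event.level)]
    if event.kind == CHROMOTHRIPSIS:
        return inject_chromothripsis(length, event.n_breakpoints,
                                     event.alphabet, sub, probe_spacing)
    return inject_bfb(length, event.n_stairs, event.anchor,
                      event.max_level, sub, probe_spacing)


def simulate_profile(build: GenomeBuild, events: Sequence[EventSpec],
                     probe_spacing: int, noise_sd: float, seed,
                     sample_id: str = "sim", genotype: str = "unknown",
                     state_log2=default_state_log2,
                     ) -> tuple[CopyNumberProfile, list[dict]]:
    """Simulate a probe profile and its truth manifest.

    Probes tile each analysis chromosome at ``probe_spacing``; each probe's
    log2 ratio is the true mean of its segment's level plus
    Gaussian(0, ``noise_sd``).  The manifest lists every event with exact
    (grid-snapped) breakpoints, sufficient to reconstruct the segment plan.
    """
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    plans: dict[str, list[tuple[int, int, int]]] = {}
    manifest: list[dict] = []
    for event in events:
        if event.chrom not in build.analysis_chromosomes:
            raise ValidationError(
                f"event on unknown/excluded chromosome {event.chrom!r}")
        plan = _event_plan(event, build, probe_spacing, rng)
        existing = plans.setdefault(event.chrom, [])
        for s, e, lev in plan:
            if lev == 0:
                continue
            for s2, e2, lev2 in existing:
                if lev2 != 0 and s < e2 and s2 < e:
                    raise ValidationError(
                        f"overlapping events on {event.chrom}")
        existing.extend(plan)
        manifest.append({
            "kind": event.kind, "chrom": event.chrom,
            "segments": [[int(s), int(e), int(lev)] for s, e, lev in plan
                         if lev != 0],
        })
    frames = []
    for chrom in build.analysis_chromosomes:
        length = build.lengths[chrom]
        cells = _grid_cells(length, probe_spacing)
        starts = np.arange(cells, dtype=np.int64) * probe_spacing
        ends = starts + probe_spacing
        true = np.zeros(cells)
        for s, e, lev in plans.get(chrom, []):
            if lev == 0:
                continue
            mid = (starts + ends) // 2
            true[(mid >= s) & (mid < e)] = state_log2(lev)
        noise = rng.normal(0.0, noise_sd, cells) if noise_sd > 0 else 0.0
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "log2": true + noise}))
    probes = pd.concat(frames, ignore_index=True)
    return CopyNumberProfile(sample_id, probes, genotype), manifest


def write_manifest(manifest: list[dict], path) -> None:
    """Write a truth manifest as JSON-lines, one event per line."""
    with open(path, "w") as fh:
        for event in manifest:
            fh.write(json.dumps(event, sort_keys=True) + "\n")


def simulate_cohort(design: CohortDesign, build: GenomeBuild,
                    probe_spacing: int = 100_000):
    """Simulate a cohort of profiles with truth tumor records.

    Returns a list of ``(profile, manifest, truth_record)`` where
    ``truth_record`` is a :class:`karyosig.cohort_report.TumorRecord`
    carrying the planted chromothripsis/BFB flags and chromosomes, so
    detector output is comparable row by row.
    """
    from .cohort_report import TumorRecord  # local import breaks the cycle

    rng = np.random.default_rng(design.seed)
    out = []
    counter = 0
    for genotype in sorted(design.group_sizes):
        for _ in range(design.group_sizes[genotype]):
            counter += 1
            sample_id = f"SIM{counter:03d}"
            chroms = list(build.analysis_chromosomes)
            free = chroms.copy()
            events: list[EventSpec] = []
            ct_chroms: list[str] = []
            bfb_chroms: list[str] = []
            if rng.random() < design.p_chromothripsis.get(genotype, 0.0):
                chrom = free.pop(int(rng.integers(len(free))))
                events.append(EventSpec(
                    CHROMOTHRIPSIS, chrom,
                    n_breakpoints=int(rng.integers(11, 20)),
                    alphabet=(0, -1, 1)[: int(rng.integers(2, 4))]))
                ct_chroms.append(chrom)
            if rng.random() < design.p_bfb.get(genotype, 0.0) and free:
                chrom = free.pop(int(rng.integers(len(free))))
                events.append(EventSpec(
                    BFB, chrom, n_stairs=int(rng.integers(3, 6)),
                    anchor=("start", "end")[int(rng.integers(2))],
                    max_level=5))
                bfb_chroms.append(chrom)
            aneu_rate = design.aneuploidy_rate.get(genotype, 0.0)
            for chrom in list(free):
                if rng.random() < aneu_rate:
                    free.remove(chrom)
                    events.append(EventSpec(
                        ANEUPLOIDY, chrom,
                        level=(-1, 1)[int(rng.integers(2))]))
            n_focal = rng.poisson(design.focal_rate.get(genotype, 0.0))
            for _ in range(n_focal):
                if not free:
                    break
                chrom = free.pop(int(rng.integers(len(free))))
                length = build.lengths[chrom]
                width = int(rng.integers(5, 20)) * probe_spacing
                if width >= length:
                    continue
                start = int(rng.integers(0, (length - width) //
                                         probe_spacing)) * probe_spacing
                events.append(EventSpec(
                    FOCAL_CNV, chrom, interval=(start, start + width),
                    level=(-1, 1)[int(rng.integers(2))]))
            profile, manifest = simulate_profile(
                build, events, probe_spacing, design.noise_sd,
                rng.integers(0, 2**31 - 1), sample_id, genotype)
            truth = TumorRecord(
                rat_id=sample_id, genotype=genotype, sex="ND",
                age_weeks=None, diagnosis=None, loh=False, loh_type=None,
                chromothripsis=bool(ct_chroms),
                ct_chroms=tuple(ct_chroms),
                bfb=bool(bfb_chroms), bfb_chroms=tuple(bfb_chroms),
                amplified_oncogenes=())
            out.append((profile, manifest, truth))
    return out


# ---------------------------------------------------------------------------
# shallow-WGS read simulation

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
TELOMERE_MOTIF = "TTAGGG"
_MOTIF_F = np.array([_CODE[c] for c in TELOMERE_MOTIF], dtype=np.uint8)
_MOTIF_R = np.array([_CODE[c] for c in "CCCTAA"], dtype=np.uint8)


def simulate_read_arrays(genome_size: int, telomere_length: int,
                         n_ends: int, coverage: float, read_length: int,
                         error_rate: float = 0.01, seed=0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate shallow-WGS reads as a base-code matrix.

    Returns ``(codes, is_telomeric)`` where ``codes`` is a ``(n_reads,
    read_length)`` uint8 matrix (A=0, C=1, G=2, T=3) and ``is_telomeric``
    marks reads drawn from telomeric repeat.  The telomeric read
    proportion is Binomial with success probability ``telomere_length *
    n_ends / (genome_size + telomere_length * n_ends)``; telomeric reads
    are phase-shifted tandem TTAGGG or CCCTAA with per-base substitution
    errors; background reads are uniform random sequence.
    """
    if coverage <= 0:
        raise ValidationError("coverage must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValidationError("error rate must lie in [0, 0.5)")
    if read_length < 6:
        raise ValidationError("read length must be >= 6")
    if telomere_length < 0 or genome_size <= 0 or n_ends <= 0:
        raise ValidationError("sizes must be positive")
    rng = np.random.default_rng(seed)
    tel_bases = telomere_length * n_ends
    total = genome_size + tel_bases
    n_reads = max(1, int(round(coverage * total / read_length)))
    p_tel = tel_bases / total
    n_tel = int(rng.binomial(n_reads, p_tel)) if p_tel > 0 else 0
    n_bg = n_reads - n_tel
    codes = np.empty((n_reads, read_length), dtype=np.uint8)
    if n_tel:
        phases = rng.integers(0, 6, n_tel)
        reverse = rng.integers(0, 2, n_tel).astype(bool)
        idx = (phases[:, None] + np.arange(read_length)) % 6
        tel = np.where(reverse[:, None], _MOTIF_R[idx], _MOTIF_F[idx])
        if error_rate > 0:
            err = rng.random((n_tel, read_length)) < error_rate
            shift = rng.integers(1, 4, (n_tel, read_length)).astype(np.uint8)
            tel = np.where(err, (tel + shift) % 4, tel)
        codes[:n_tel] = tel
    if n_bg:
        codes[n_tel:] = rng.integers(0, 4, (n_bg, read_length),
                                     dtype=np.uint8)
    truth = np.zeros(n_reads, dtype=bool)
    truth[:n_tel] = True
    perm = rng.permutation(n_reads)
    return codes[perm], truth[perm]


def codes_to_sequences(codes: np.ndarray) -> list[str]:
    """Convert a base-code matrix to a list of sequence strings."""
    n, length = codes.shape
    chars = _BASES[codes]
    return [b.decode() for b in chars.view(f"S{length}").ravel()]


def simulate_reads(genome_size: int, telomere_length: int, n_ends: int,
                   coverage: float, read_length: int,
                   error_rate: float = 0.01, seed=0,
                   sample_id: str = "sim") -> list[SeqRecord]:
    """Simulate shallow-WGS reads as FASTQ-ready Biopython records.

    Thin wrapper over :func:`simulate_read_arrays`; constant Phred 30
    qualities.
    """
    codes, truth = simulate_read_arrays(
        genome_size, telomere_length, n_ends, coverage, read_length,
        error_rate, seed)
    records = []
    for i, seq in enumerate(codes_to_sequences(codes)):
        rec = SeqRecord(Seq(seq), id=f"{sample_id}.{i+1}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        records.append(rec)
    return records
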