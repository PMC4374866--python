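"""Telomere length from shallow WGS, plus TRAP / C-circle normalization.

Mean telomere length is estimated from the telomeric-repeat content of
low-coverage (0.1-1.3x) whole-genome reads.  A read is telomeric when it
is essentially a pure tandem array of the vertebrate telomere hexamer
TTAGGG (or its reverse complement CCCTAA): the match fraction against the
periodic repeat, maximized over the 6 phases and 2 orientations, must
reach ``min_repeat_fraction``.  This phase-and-orientation maximum plays
the role of alignment against a tandem TTAGGG reference.

The estimator is

    mean telomere length = telomeric bases / (genome coverage x n ends)

with coverage computed from the non-telomeric reads against the reference
genome size.  With the rat's 2n = 42 karyotype the default number of
telomere ends is 84.  The estimator is scale-free: it is unbiased at any
coverage in the shallow regime and linear in the true length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_model import ValidationError

TELOMERE_MOTIF = "TTAGGG"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MOTIF_F = np.array([_CODE[c] for c in TELOMERE_MOTIF], dtype=np.uint8)
_MOTIF_R = np.array([_CODE[c] for c in "CCCTAA"], dtype=np.uint8)

#: rat diploid karyotype: 2n = 42 chromosomes, two telomeres each
DEFAULT_N_ENDS = 84


class EstimationError(ValueError):
    """The read set cannot support the requested estimate."""


@dataclass(frozen=True)
class TelomereEstimate:
    sample_id: str
    n_reads_total: int
    n_telomeric_reads: int
    telomeric_bases: int
    genome_coverage: float
    n_telomere_ends: int
    mean_telomere_length: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_telomeric_reads <= self.n_reads_total:
            raise ValidationError("telomeric read count out of range")
        if self.mean_telomere_length < 0:
            raise ValidationError("negative telomere length")


@dataclass(frozen=True)
class AssayResult:
    """A TRAP (telomerase) or C-circle (ALT) signal, control-normalized."""

    sample_id: str
    assay: str
    raw_signal: float
    control_signal: float
    relative_activity: float
    activated: bool


def _patterns(read_length: int) -> np.ndarray:
    """The 12 periodic repeat patterns (6 phases x 2 orientations)."""
    idx = (np.arange(6)[:, None] + np.arange(read_length)) % 6
    return np.vstack([_MOTIF_F[idx], _MOTIF_R[idx]])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def repeat_match_fraction(seq: str) -> float:
    """Best match fraction of one sequence against the periodic repeat."""
    codes = _encode(seq)
    pats = _patterns(len(codes))
    return float((pats == codes).mean(axis=1).max())


def _iter_code_blocks(reads) -> Iterable[np.ndarray]:
    """Yield (n, L) uint8 code blocks from the accepted read inputs."""
    if isinstance(reads, np.ndarray):
        if reads.ndim != 2:
            raise ValidationError("read matrix must be 2-D")
        yield reads.astype(np.uint8, copy=False)
        return
    by_length: dict[int, list[np.ndarray]] = {}
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        by_length.setdefault(len(seq), []).append(_encode(seq))
    for length in sorted(by_length):
        yield np.vstack(by_length[length])


def classify_telomeric_reads(reads, min_repeat_fraction: float = 0.9,
                             ) -> tuple[int, int, int]:
    """Count telomeric reads and bases in a read set.

    ``reads`` may be an iterable of sequence strings or Biopython
    ``SeqRecord`` objects (e.g. from ``SeqIO.parse`` of a FASTQ), or a
    pre-encoded ``(n, read_length)`` uint8 base-code matrix.  Returns
    ``(n telomeric reads, telomeric bases, n reads total)``.  An empty
    read set yields zeros.  The classification is invariant under
    reverse-complementing any read.
    """
    n_total = 0
    n_tel = 0
    tel_bases = 0
    for block in _iter_code_blocks(reads):
        n, length = block.shape
        if n == 0:
            continue
        if length < 12:
            raise ValidationError(
                f"reads of {length} bp are too short (need >= 12 bp)")
        pats = _patterns(length)
        best = np.zeros(n)
        for pat in pats:
            np.maximum(best, (block == pat).mean(axis=1), out=best)
        hits = best >= min_repeat_fraction
        n_total += n
        n_tel += int(hits.sum())
        tel_bases += int(hits.sum()) * length
    return n_tel, tel_bases, n_total


def estimate_genome_coverage(n_reads: int, n_telomeric: int,
                             read_length: int, genome_size: int) -> float:
    """Fold coverage of the non-telomeric reference genome."""
    if genome_size <= 0:
        raise ValidationError("genome size must be positive")
    n_bg = n_reads - n_telomeric
    if n_bg <= 0:
        raise EstimationError("no non-telomeric reads; coverage undefined")
    return n_bg * read_length / genome_size


def estimate_telomere_length(telomeric_bases: int, coverage: float,
                             n_ends: int = DEFAULT_N_ENDS) -> float:
    """Mean telomere length in bp: telomeric bases / (coverage x ends)."""
    if coverage <= 0:
        raise EstimationError("coverage must be positive")
    if n_ends <= 0:
        raise ValidationError("n_ends must be positive")
    return telomeric_bases / (coverage * n_ends)


def telomere_estimate(reads, genome_size: int, read_length: int | None = None,
                      n_ends: int = DEFAULT_N_ENDS,
                      min_repeat_fraction: float = 0.9,
                      sample_id: str = "sample") -> TelomereEstimate:
    """End-to-end telomere length estimate from a read set."""
    if isinstance(reads, np.ndarray) and read_length is None:
        read_length = reads.shape[1]
    if read_length is None:
        reads = list(reads)
        if not reads:
            raise EstimationError("empty read set")
        first = reads[0]
        read_length = len(first.seq) if hasattr(first, "seq") else len(first)
    n_tel, tel_bases, n_total = classify_telomeric_reads(
        reads, min_repeat_fraction)
    coverage = estimate_genome_coverage(n_total, n_tel, read_length,
                                        genome_size)
    length = estimate_telomere_length(tel_bases, coverage, n_ends)
    return TelomereEstimate(sample_id, n_total, n_tel, tel_bases, coverage,
                            n_ends, length)


def normalize_assay(raw_signal: float, control_signal: float,
                    activation_threshold: float = 0.1,
                    sample_id: str = "sample",
                    assay: str = "TRAP") -> AssayResult:
    """Normalize an assay signal to its positive control.

    TRAP signals are normalized to the telomerase-positive control line
    supplied with the kit; C-circle signals to the ALT-positive line
    U-2 OS.  ``activated`` is a strict comparison of the relative activity
    against ``activation_threshold``.
    """
    if control_signal <= 0:
        raise ValidationError("control signal must be positive")
    if raw_signal < 0:
        raise ValidationError("raw signal must be >= 0")
    relative = raw_signal / control_signal
    return AssayResult(sample_id, assay, raw_signal, control_signal,
                       relative, relative > activation_threshold)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance) between two groups.

    Returns ``(t statistic, two-sided p)``.  ``welch=True`` switches to the
    unequal-variance form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValidationError("degenerate (zero) pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
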