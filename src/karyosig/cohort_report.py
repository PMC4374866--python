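"""Cohort tables, cross-tabulations and the end-to-end pipeline.

The cohort table dialect mirrors the study's tumor-overview table: one row
per animal with genotype, diagnosis, LOH mechanism, chromothripsis and BFB
flags with their affected chromosomes, and amplified oncogenes.  A verbatim
transcription of the 26-tumor p53-knockout rat cohort ships as the packaged
fixture ``data/table1.tsv``.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence


from . import cnv_segmentation, signature_detection, synthetic_data
from .genome_model import (
    GeneAnnotation,
    GenomeBuild,
    ProfileParseError,
    Thresholds,
    ValidationError,
    load_probe_profile,
    write_segments,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

COHORT_COLUMNS = ["rat_id", "genotype", "sex", "age_weeks", "diagnosis",
                  "loh", "loh_type", "chromothripsis", "ct_chroms", "bfb",
                  "bfb_chroms", "amplified_oncogenes"]

_MISSING = ("", "-", "ND", "nd")


@dataclass(frozen=True)
class TumorRecord:
    """One row of the cohort table."""

    rat_id: str
    genotype: str
    sex: str
    age_weeks: int | None
    diagnosis: str | None
    loh: bool
    loh_type: str | None
    chromothripsis: bool
    ct_chroms: tuple[str, ...]
    bfb: bool
    bfb_chroms: tuple[str, ...]
    amplified_oncogenes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.genotype not in ("+/-", "-/-"):
            raise ValidationError(
                f"rat {self.rat_id}: genotype {self.genotype!r} is not one "
                "of the study arms (+/-, -/-)")
        if self.chromothripsis != bool(self.ct_chroms):
            raise ValidationError(
                f"rat {self.rat_id}: chromothripsis flag inconsistent with "
                "affected-chromosome list")
        if self.bfb != bool(self.bfb_chroms):
            raise ValidationError(
                f"rat {self.rat_id}: BFB flag inconsistent with "
                "affected-chromosome list")


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate counts and distributions over a cohort."""

    n_by_genotype: dict[str, int]
    diagnosis_counts: dict[str, dict[str, int]]
    chromothripsis_counts: dict[str, int]
    bfb_counts: dict[str, int]
    loh_type_counts: dict[str, dict[str, int]]
    cooccurrence: tuple[int, int, int]

    @property
    def n_total(self) -> int:
        return sum(self.n_by_genotype.values())


def _parse_bool(token: str, row_id: str, column: str) -> bool:
    t = token.strip().lower()
    if t in ("yes", "y", "true", "1"):
        return True
    if t in ("no", "n", "false", "0", "-", ""):
        return False
    raise ProfileParseError(
        f"row {row_id}: cannot parse {column}={token!r} as yes/no")


def _parse_list(token: str) -> tuple[str, ...]:
    token = token.strip()
    if token in _MISSING:
        return ()
    return tuple(part.strip() for part in token.split(",") if part.strip())


def load_cohort_table(path: str | Path) -> list[TumorRecord]:
    """Load a tab-delimited cohort table into validated records.

    The header must carry the documented column names; ``ND``/``-`` become
    missing values; chromosome and gene lists are comma-separated.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("%s: empty cohort table", path)
        return []
    header = lines[0].rstrip("\n").split("\t")
    if header != COHORT_COLUMNS:
        raise ProfileParseError(
            f"{path}: header {header} does not match the cohort dialect "
            f"{COHORT_COLUMNS}")
    if len(lines) == 1:
        logger.warning("%s: cohort table has a header but no rows", path)
        return []
    records: list[TumorRecord] = []
    for line in lines[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(COHORT_COLUMNS):
            raise ProfileParseError(
                f"{path}: row {parts[0] if parts else '?'} has "
                f"{len(parts)} columns, expected {len(COHORT_COLUMNS)}")
        row = dict(zip(COHORT_COLUMNS, parts))
        rid = row["rat_id"]
        if row["genotype"] not in ("+/-", "-/-"):
            raise ProfileParseError(
                f"{path}: row {rid}: unknown genotype {row['genotype']!r}")
        records.append(TumorRecord(
            rat_id=rid,
            genotype=row["genotype"],
            sex=row["sex"],
            age_weeks=(None if row["age_weeks"] in _MISSING
                       else int(row["age_weeks"])),
            diagnosis=(None if row["diagnosis"] in _MISSING
                       else row["diagnosis"]),
            loh=_parse_bool(row["loh"], rid, "loh"),
            loh_type=(None if row["loh_type"] in _MISSING
                      else row["loh_type"]),
            chromothripsis=_parse_bool(row["chromothripsis"], rid,
                                       "chromothripsis"),
            ct_chroms=_parse_list(row["ct_chroms"]),
            bfb=_parse_bool(row["bfb"], rid, "bfb"),
            bfb_chroms=_parse_list(row["bfb_chroms"]),
            amplified_oncogenes=_parse_list(row["amplified_oncogenes"]),
        ))
    return records


def write_cohort_table(records: Sequence[TumorRecord],
                       path: str | Path) -> None:
    """Write records in the cohort TSV dialect (round-trips losslessly)."""
    with open(path, "w") as fh:
        fh.write("\t".join(COHORT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.rat_id, r.genotype, r.sex,
                "-" if r.age_weeks is None else str(r.age_weeks),
                "-" if r.diagnosis is None else r.diagnosis,
                "yes" if r.loh else "no",
                "-" if r.loh_type is None else r.loh_type,
                "yes" if r.chromothripsis else "no",
                ",".join(r.ct_chroms) or "-",
                "yes" if r.bfb else "no",
                ",".join(r.bfb_chroms) or "-",
                ",".join(r.amplified_oncogenes) or "-",
            ]) + "\n")


def packaged_cohort_fixture() -> Path:
    """Path of the packaged 26-tumor rat cohort table."""
    return Path(str(resources.files("karyosig").joinpath("data/table1.tsv")))


def summarize_cohort(records: Sequence[TumorRecord]) -> CohortSummary:
    """Exact cross-tabulations of a cohort, by genotype.

    Counts are permutation-invariant and linear (duplicating the record
    list doubles every count).
    """
    n_by_genotype = Counter(r.genotype for r in records)
    diagnosis: dict[str, Counter] = {}
    loh_types: dict[str, Counter] = {}
    ct = Counter()
    bfb = Counter()
    for r in records:
        if r.diagnosis is not None:
            diagnosis.setdefault(r.genotype, Counter())[r.diagnosis] += 1
        if r.loh_type is not None:
            loh_types.setdefault(r.genotype, Counter())[r.loh_type] += 1
        if r.chromothripsis:
            ct[r.genotype] += 1
        if r.bfb:
            bfb[r.genotype] += 1
    return CohortSummary(
        n_by_genotype=dict(n_by_genotype),
        diagnosis_counts={g: dict(c) for g, c in diagnosis.items()},
        chromothripsis_counts=dict(ct),
        bfb_counts=dict(bfb),
        loh_type_counts={g: dict(c) for g, c in loh_types.items()},
        cooccurrence=signature_detection.cooccurrence_summary(records),
    )


def _parse_locus(token: str) -> tuple[str, int, int]:
    chrom, _, span = token.partition(":")
    start, _, end = span.partition("-")
    try:
        return chrom, int(start), int(end)
    except ValueError as exc:
        raise ValidationError(f"cannot parse locus {token!r} "
                              "(expected chrom:start-end)") from exc


def analyze_profile(profile, build: GenomeBuild, thresholds: Thresholds,
                    penalty: float | None = None, min_probes: int = 5,
                    genes: GeneAnnotation | None = None,
                    locus: tuple[str, int, int] | None = None) -> dict:
    """Run segmentation and all signature detectors on one profile.

    Returns a dict with the segmented profile, all calls, the altered-bp
    count, and a :class:`TumorRecord` mirroring the cohort schema.
    """
    seg = cnv_segmentation.segment_and_call(profile, thresholds, penalty,
                                            min_probes)
    arm_events = signature_detection.call_arm_events(seg, build)
    altered_bp = signature_detection.count_altered_bp(seg, arm_events, build)
    ct_calls = signature_detection.detect_chromothripsis(seg)
    bfb_calls = signature_detection.detect_bfb(seg)
    amplified: tuple[str, ...] = ()
    if genes is not None:
        per_call = signature_detection.annotate_amplified_genes(bfb_calls,
                                                                genes)
        amplified = tuple(dict.fromkeys(g for lst in per_call for g in lst))
    loh_type = None
    if locus is not None and locus[0] in seg.chromosomes:
        loh_type = signature_detection.classify_loh_mechanism(
            seg, ct_calls, locus)
    record = TumorRecord(
        rat_id=profile.sample_id, genotype=profile.genotype
        if profile.genotype in ("+/-", "-/-") else "+/-",
        sex="ND", age_weeks=None, diagnosis=None,
        loh=loh_type is not None, loh_type=loh_type,
        chromothripsis=bool(ct_calls),
        ct_chroms=tuple(c.chrom for c in ct_calls),
        bfb=bool(bfb_calls),
        bfb_chroms=tuple(dict.fromkeys(c.chrom for c in bfb_calls)),
        amplified_oncogenes=amplified)
    return {"segmented": seg, "arm_events": arm_events,
            "altered_bp": altered_bp, "chromothripsis": ct_calls,
            "bfb": bfb_calls, "record": record}


def run_pipeline(config: dict) -> dict:
    """End-to-end pipeline: profiles -> segments -> signatures -> summary.

    ``config`` keys:

    * ``build`` — a :class:`GenomeBuild` or ``{"table": path,
      "excluded": [...]}``;
    * input — either ``simulate`` (a :class:`CohortDesign` mapping, plus
      optional ``probe_spacing``) or ``profiles`` (list of
      ``{"path", "sample_id", "genotype"}``);
    * thresholds — ``thresholds`` (mapping with the three cuts) or
      ``null_profile`` (path to a self-self profile, calibrated at
      ``k``/``amp_multiplier``);
    * ``penalty``, ``min_probes`` — segmentation controls;
    * optional ``genes`` (BED path), ``locus`` ("chrom:start-end"),
      ``outdir``, ``seed``.

    Writes (when ``outdir`` is set) ``report.json``, per-sample segment
    BED tracks, and a cohort TSV; returns the report dict.  Reruns with
    the same config and seed are byte-identical.
    """
    seed = int(config.get("seed", 0))
    build = config["build"]
    if not isinstance(build, GenomeBuild):
        build = GenomeBuild.from_table(build["table"],
                                       build.get("excluded", ()))
    genes = config.get("genes")
    if genes is not None and not isinstance(genes, GeneAnnotation):
        genes = GeneAnnotation.from_bed(genes, build)
    locus = config.get("locus")
    if isinstance(locus, str):
        locus = _parse_locus(locus)
    penalty = config.get("penalty")
    min_probes = int(config.get("min_probes", 5))

    if "simulate" in config:
        sim = dict(config["simulate"])
        spacing = int(sim.pop("probe_spacing", 100_000))
        design = synthetic_data.CohortDesign(**sim, seed=seed)
        cohort = synthetic_data.simulate_cohort(design, build, spacing)
        profiles = [p for p, _, _ in cohort]
        truth = [t for _, _, t in cohort]
    else:
        profiles = [load_probe_profile(s["path"], build,
                                       s.get("sample_id"),
                                       s.get("genotype", "unknown"))
                    for s in config["profiles"]]
        truth = None

    if "thresholds" in config:
        thresholds = Thresholds.from_dict(config["thresholds"])
    elif "null_profile" in config:
        null = load_probe_profile(config["null_profile"], build, "null")
        thresholds = cnv_segmentation.calibrate_thresholds(
            null, k=float(config.get("k", 3.0)),
            amp_multiplier=float(config.get("amp_multiplier", 5.0)))
    else:
        raise ValidationError("config needs 'thresholds' or 'null_profile'")

    logger.info("pipeline: %d samples, seed %d, penalty %s, min_probes %d, "
                "thresholds %s", len(profiles), seed, penalty, min_probes,
                thresholds.to_dict())

    records: list[TumorRecord] = []
    sample_reports = []
    analyses = []
    for profile in profiles:
        try:
            res = analyze_profile(profile, build, thresholds, penalty,
                                  min_probes, genes, locus)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at sample {profile.sample_id}: "
                f"{exc}") from exc
        analyses.append(res)
        records.append(res["record"])
        sample_reports.append({
            "sample_id": profile.sample_id,
            "genotype": profile.genotype,
            "n_arm_events": len(res["arm_events"]),
            "arm_events": [{"chrom": e.chrom, "arm": e.arm,
                            "state": e.state,
                            "fraction": round(e.fraction, 6)}
                           for e in res["arm_events"]],
            "altered_bp": res["altered_bp"],
            "chromothripsis": [{"chrom": c.chrom,
                                "n_switches": c.n_switches,
                                "distinct_states": c.distinct_states}
                               for c in res["chromothripsis"]],
            "bfb": [{"chrom": c.chrom, "anchor": c.anchor,
                     "n_stairs": c.n_stairs}
                    for c in res["bfb"]],
            "loh_type": res["record"].loh_type,
            "amplified_oncogenes": list(
                res["record"].amplified_oncogenes),
        })
    summary = summarize_cohort(records)
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "parameters": {"penalty": penalty, "min_probes": min_probes,
                       "thresholds": thresholds.to_dict()},
        "samples": sample_reports,
        "summary": {
            "n_by_genotype": summary.n_by_genotype,
            "chromothripsis_counts": summary.chromothripsis_counts,
            "bfb_counts": summary.bfb_counts,
            "cooccurrence": list(summary.cooccurrence),
        },
    }
    if truth is not None:
        report["truth"] = {
            "chromothripsis_counts": dict(Counter(
                t.genotype for t in truth if t.chromothripsis)),
            "bfb_counts": dict(Counter(
                t.genotype for t in truth if t.bfb)),
        }
    outdir = config.get("outdir")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        write_cohort_table(records, outdir / "cohort.tsv")
        for res in analyses:
            write_segments(res["segmented"],
                           outdir / f"{res['segmented'].sample_id}.bed")
    report["records"] = records
    return report
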