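"""Pipeline orchestration and the JSON QC report.

``run_qc`` executes read filtering -> Tn5 transforms -> peak calling ->
QC metrics and writes a JSON report plus the track/fragment side files.
All randomness derives from one top-level seed through named substreams,
so reruns with the same seed and config are byte-identical (no
timestamps go into the JSON; logging carries them instead).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import qc_metrics as qc
from . import read_processing as rp
from . import signal_and_peaks as sp
from .differential import (CountMatrix, call_dars, count_matrix,
                           differential_test, read_design_table, write_dar_bed)
from .formats_io import (ChromSizes, Interval, ParseError, read_alignments,
                         read_bed, read_chrom_sizes, write_bed, write_bedgraph,
                         write_tsv_matrix)
from .qc_metrics import MetricUndefinedError

SCHEMA_VERSION = "1.0"
logger = logging.getLogger("atacqc")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Every knob of the QC pipeline, with the published defaults."""

    alignments: Optional[str] = None
    chrom_sizes: Optional[str] = None
    peaks: Optional[str] = None          # BED; None => call peaks
    promoters: Optional[str] = None      # TSS BED
    reference: Optional[str] = None      # reference open-chromatin BED
    reference_table: Optional[str] = None
    output_dir: str = "."
    mode: str = rp.MODE_PSEUDO_SE
    mito_name: str = "chrM"
    mapq_min: int = rp.DEFAULT_MAPQ_MIN
    ext: int = rp.DEFAULT_EXT
    plus_shift: int = rp.PLUS_SHIFT
    minus_shift: int = rp.MINUS_SHIFT
    n_background_regions: int = qc.DEFAULT_N_BACKGROUND_REGIONS
    background_width: int = qc.DEFAULT_BACKGROUND_WIDTH
    rpkm_threshold: float = qc.DEFAULT_RPKM_THRESHOLD
    suben_depth: int = qc.DEFAULT_SUBEN_DEPTH
    suben_pseudo: int = qc.DEFAULT_SUBEN_PSEUDO
    saturation_step: float = qc.DEFAULT_SATURATION_STEP
    promoter_half_window: int = qc.DEFAULT_PROMOTER_HALF_WINDOW
    n_quantiles: int = 10
    min_overlap_frac: float = qc.DEFAULT_MIN_OVERLAP_FRAC
    caller_window: int = sp.DEFAULT_CALLER_WINDOW
    caller_q: float = sp.DEFAULT_CALLER_Q
    normalize_to: int = sp.DEFAULT_NORMALIZE_TO
    padj_max: float = 0.01
    min_abs_log2fc: float = 1.0
    include_mito: bool = False
    run_saturation: bool = True
    seed: int = 0


@dataclass
class QCReport:
    """Everything the QC pipeline computed, JSON-serializable."""

    schema_version: str
    parameters: Dict
    alignment: Dict
    metrics: Dict
    grades: Dict[str, str] = field(default_factory=dict)
    validation: Optional[Dict] = None
    notes: Dict = field(default_factory=dict)
    extras: Dict = field(default_factory=dict)

    def to_dict(self) -> Dict:
        out = {
            "schema_version": self.schema_version,
            "parameters": self.parameters,
            "alignment": self.alignment,
            "metrics": self.metrics,
            "grades": self.grades,
            "validation": self.validation,
            "notes": self.notes,
        }
        out.update(self.extras)
        return out


REQUIRED_FIELDS = ("schema_version", "parameters", "alignment", "metrics")


def _check_finite(obj, path="$"):
    if isinstance(obj, float) and not np.isfinite(obj):
        raise ValueError(f"non-finite numeric at {path}")
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}")
    if isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")


def serialize_report(report: QCReport) -> str:
    data = report.to_dict()
    _check_finite(data)
    return json.dumps(data, indent=2, sort_keys=True) + "\n"


def parse_report(text: str) -> QCReport:
    """Parse and validate a JSON QC report; unknown fields are preserved."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid JSON: {exc}") from exc
    for key in REQUIRED_FIELDS:
        if key not in data:
            raise ValueError(f"schema violation at $.{key}: missing required field")
    version = data["schema_version"]
    if version != SCHEMA_VERSION:
        logger.warning("report schema version %s != current %s; parsing with defaults",
                       version, SCHEMA_VERSION)
    known = {"schema_version", "parameters", "alignment", "metrics",
             "grades", "validation", "notes"}
    extras = {k: v for k, v in data.items() if k not in known}
    return QCReport(
        schema_version=version,
        parameters=data["parameters"],
        alignment=data["alignment"],
        metrics=data["metrics"],
        grades=data.get("grades", {}),
        validation=data.get("validation"),
        notes=data.get("notes", {}),
        extras=extras,
    )


def _load_inputs(config: RunConfig) -> Tuple[ChromSizes, List, object]:
    if config.chrom_sizes is None or config.alignments is None:
        raise ParseError("both --alignments and --chrom-sizes are required")
    sizes = read_chrom_sizes(config.chrom_sizes, mito_name=config.mito_name)
    pairs, tally = read_alignments(config.alignments, sizes)
    return sizes, pairs, tally


def run_qc(config: RunConfig) -> QCReport:
    """The one-command QC pipeline; returns the report and writes outputs."""
    os.makedirs(config.output_dir, exist_ok=True)
    sizes, pairs, tally = _load_inputs(config)
    logger.info("stage=read_alignments pairs=%d records=%d",
                tally.yielded_pairs, tally.total_records)

    kept, n_lowq = rp.filter_pairs(pairs, mapq_min=config.mapq_min, tally=tally)
    unique, dup_rate = rp.deduplicate(kept)
    logger.info("stage=filter+dedup kept=%d low_quality=%d unique=%d dup_rate=%.4f",
                len(kept), n_lowq, len(unique), dup_rate)
    align_qc = rp.alignment_qc(unique, sizes, duplication_rate=dup_rate)
    ends = rp.useful_ends(unique, config.mode, sizes,
                          include_mito=config.include_mito, ext=config.ext)
    logger.info("stage=useful_ends mode=%s e_total=%d", config.mode, ends.e_total)

    def caller(endset):
        calls = sp.naive_call_peaks(endset, sizes, window=config.caller_window,
                                    q_cutoff=config.caller_q)
        return sp.calls_to_peakset(calls)

    if config.peaks is not None:
        peaks = qc.merge_peaks(read_bed(config.peaks, sizes), source=config.peaks)
    else:
        peaks = caller(ends)
    logger.info("stage=peaks n=%d total_bp=%d", len(peaks), peaks.total_length)

    promoters: List[Interval] = []
    if config.promoters is not None:
        tss = read_bed(config.promoters, sizes)
        promoters = qc.promoters_from_tss(tss, sizes,
                                          half_window=config.promoter_half_window)

    metrics: Dict = {}
    notes: Dict = {"suben_form": "canonical-form",
                   "e_total_excludes_mito": not config.include_mito,
                   "signal_ranking_quantiles": config.n_quantiles}
    metrics["e_total"] = ends.e_total
    metrics["rupr"] = qc.rupr(ends, peaks, min_frac=config.min_overlap_frac)
    bg = qc.background_metric(
        ends, peaks, sizes, n=config.n_background_regions,
        width=config.background_width, threshold=config.rpkm_threshold,
        seed=stage_seed(config.seed, "background"))
    metrics["background"] = asdict(bg)
    try:
        metrics["proen"] = qc.promoter_enrichment(
            ends, peaks, promoters, sizes, min_frac=config.min_overlap_frac)
    except MetricUndefinedError:
        metrics["proen"] = None
    suben = qc.subsampling_enrichment(
        ends, sizes, caller, depth=config.suben_depth,
        pseudo=config.suben_pseudo, seed=stage_seed(config.seed, "suben"),
        min_frac=config.min_overlap_frac)
    metrics["suben"] = asdict(suben)
    if config.run_saturation:
        try:
            metrics["saturation"] = [
                list(point) for point in qc.saturation_curve(
                    ends, sizes, caller, step_fraction=config.saturation_step,
                    seed=stage_seed(config.seed, "saturation"))]
        except MetricUndefinedError:
            metrics["saturation"] = None
    try:
        metrics["signal_ranking"] = qc.signal_ranking(
            ends, peaks, promoters, n_quantiles=config.n_quantiles)
    except ValueError:
        metrics["signal_ranking"] = None
    try:
        metrics["promoter_peak_fraction"] = qc.promoter_peak_fraction(peaks, promoters)
    except MetricUndefinedError:
        metrics["promoter_peak_fraction"] = None

    validation = None
    if config.reference is not None:
        reference = qc.merge_peaks(read_bed(config.reference, sizes),
                                   source=config.reference)
        validation = asdict(qc.validate_peaks(peaks, reference))

    grades: Dict[str, str] = {}
    if config.reference_table is not None:
        table = qc.ReferenceTable.from_file(config.reference_table)
        gradeable = {
            "rupr": metrics["rupr"],
            "background": bg.background,
            "proen": metrics["proen"],
            "suben": suben.suben,
            "duplication_rate": dup_rate,
            "mito_rate": align_qc.mito_rate,
        }
        grades = qc.grade_metrics(
            {k: v for k, v in gradeable.items() if v is not None}, table)

    report = QCReport(
        schema_version=SCHEMA_VERSION,
        parameters=asdict(config),
        alignment={
            "n_unique_nonredundant": align_qc.n_unique_nonredundant,
            "duplication_rate": align_qc.duplication_rate,
            "per_chrom_counts": align_qc.per_chrom_counts,
            "mito_rate": align_qc.mito_rate,
            "tally": asdict(tally),
        },
        metrics=metrics,
        grades=grades,
        validation=validation,
        notes=notes,
    )

    # side files
    out = config.output_dir
    write_bed([Interval(c, int(s), int(e), strand=str(t))
               for c, s, e, t in zip(ends.chroms, ends.starts, ends.ends,
                                     ends.strands)],
              os.path.join(out, "fragments.bed"))
    cov = sp.coverage_track(ends, sizes, normalize_to=config.normalize_to)
    write_bedgraph(cov.spans(), os.path.join(out, "coverage.bedgraph"))
    sites = [rp.InsertionSite(c, int(m), str(t) if t in "+-" else "+")
             for c, m, t in zip(ends.chroms, ends.centers, ends.strands)] \
        if config.mode == rp.MODE_PSEUDO_SE else []
    if sites:
        ins = sp.insertion_track(sites, sizes)
        write_bedgraph(ins.spans(), os.path.join(out, "insertions.bedgraph"))
    with open(os.path.join(out, "insert_size.tsv"), "w") as fh:
        fh.write("length\tcount\n")
        for length, count in align_qc.insert_size_histogram.items():
            fh.write(f"{length}\t{count}\n")
    write_bed([Interval(p.chrom, p.start, p.end, name=f"peak_{i+1}")
               for i, p in enumerate(peaks.peaks)],
              os.path.join(out, "peaks.bed"))
    with open(os.path.join(out, "report.json"), "w") as fh:
        fh.write(serialize_report(report))
    logger.info("stage=report path=%s", os.path.join(out, "report.json"))
    return report


def run_dar(sample_alignments: Mapping[str, str], design: Mapping[str, str],
            config: RunConfig) -> Dict:
    """Differential-accessibility pipeline over >= 2 samples.

    Peaks come from ``config.peaks`` (BED) or from calling on the pooled
    ends.  Writes the count matrix TSV and per-direction DAR BEDs.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    if config.chrom_sizes is None:
        raise ParseError("--chrom-sizes is required")
    sizes = read_chrom_sizes(config.chrom_sizes, mito_name=config.mito_name)
    missing = [s for s in design if s not in sample_alignments]
    if missing:
        raise ParseError(f"design samples without alignments: {missing}")
    endsets: Dict[str, rp.EndSet] = {}
    for name, path in sample_alignments.items():
        pairs, _ = read_alignments(path, sizes)
        kept, _ = rp.filter_pairs(pairs, mapq_min=config.mapq_min)
        unique, _ = rp.deduplicate(kept)
        endsets[name] = rp.useful_ends(unique, config.mode, sizes,
                                       include_mito=config.include_mito,
                                       ext=config.ext)
        logger.info("stage=sample name=%s e_total=%d", name, endsets[name].e_total)
    if config.peaks is not None:
        peaks = qc.merge_peaks(read_bed(config.peaks, sizes), source=config.peaks)
    else:
        import numpy as _np
        pooled = endsets[next(iter(endsets))]
        for name in list(endsets)[1:]:
            e = endsets[name]
            pooled = rp.EndSet(
                pooled.mode, sizes, pooled.include_mito,
                _np.concatenate([pooled.chroms, e.chroms]),
                _np.concatenate([pooled.starts, e.starts]),
                _np.concatenate([pooled.ends, e.ends]),
                _np.concatenate([pooled.centers, e.centers]),
                _np.concatenate([pooled.strands, e.strands]))
        calls = sp.naive_call_peaks(pooled, sizes, window=config.caller_window,
                                    q_cutoff=config.caller_q)
        peaks = sp.calls_to_peakset(calls)
    matrix = count_matrix(peaks, endsets, config.mode)
    results = differential_test(matrix, design, normalize_to=config.normalize_to)
    dars = call_dars(results, padj_max=config.padj_max,
                     min_abs_log2fc=config.min_abs_log2fc)
    out = config.output_dir
    write_tsv_matrix(matrix.counts, os.path.join(out, "counts.tsv"))
    groups = sorted(set(design.values()))
    write_dar_bed(dars["group1"], os.path.join(out, f"dars_{groups[0]}.bed"))
    write_dar_bed(dars["group2"], os.path.join(out, f"dars_{groups[1]}.bed"))
    summary = {
        "n_peaks": len(peaks),
        "groups": groups,
        "n_dars_group1": len(dars["group1"]),
        "n_dars_group2": len(dars["group2"]),
        "n_ns": len(dars["ns"]),
        "mode": config.mode,
    }
    logger.info("stage=dar %s", summary)
    with open(os.path.join(out, "dar_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
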