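"""Single-sample and tumor/control pipeline orchestration.

One pass per input file: every primary read contributes to the totals and
the GC distribution; telomeric reads are classified into the four
fractions; intratelomeric reads feed the TVR, singleton and context
scans. Results are written as tab-separated tables plus per-category
read files.
"""

from __future__ import annotations

import logging
import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from telomere_profiler.classification import (
    ClassificationConfig,
    ReadCategory,
    classify_read,
    per_chromosome_spectrum,
)
from telomere_profiler.content import (
    GcDistribution,
    TelomereContentEstimate,
    log2_tc_ratio,
    telomere_content,
    uncorrected_content,
)
from telomere_profiler.extraction import ExtractionConfig, RepeatPatternSet, count_repeat_hits, is_telomeric
from telomere_profiler.io_formats import (
    CATEGORIES,
    ReadRecord,
    read_band_file,
    read_header,
    stream_reads,
    write_category_reads,
    write_table,
)
from telomere_profiler.tvr import (
    DEFAULT_MIN_BASE_QUALITY,
    DEFAULT_TVR_CONTEXT_LIST,
    TvrProfile,
    TvrSampleCounts,
    summarize_tvr_profile,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    band_file: str
    out_dir: str
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    mapping_quality_threshold: int = 8
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
    tvr_context_list: Sequence[str] = DEFAULT_TVR_CONTEXT_LIST
    exclude_duplicates: bool = False
    write_reads: bool = True
    read_file_format: str = "bam"
    plot: bool = False


@dataclass
class SampleResult:
    """Everything measured in one pass over one sample."""

    sample: str
    total_reads: int
    gc_distribution: GcDistribution
    category_counts: dict[str, int]
    category_reads: dict[str, list[ReadRecord]]
    estimate: TelomereContentEstimate
    tvr_counts: TvrSampleCounts
    spectrum: pd.DataFrame
    repeats_histogram: Counter
    skipped_duplicates: int = 0

    @property
    def extracted_total(self) -> int:
        return sum(self.category_counts.values())


def repeats_per_read_histogram(
    reads: Iterable[ReadRecord], pattern_set: RepeatPatternSet
) -> Counter:
    """Histogram of repeat-hit counts over intratelomeric reads."""
    hist: Counter = Counter()
    for read in reads:
        hist[count_repeat_hits(read.sequence, pattern_set)] += 1
    return hist


def run_sample(read_file: str, config: RunConfig, sample: str = "sample") -> SampleResult:
    """Process one aligned-read file end to end (no table writing)."""
    band_map = read_band_file(config.band_file)
    cls_config = ClassificationConfig(
        band_map=band_map, mapping_quality_threshold=config.mapping_quality_threshold
    )
    gc_dist = GcDistribution()
    category_reads: dict[str, list[ReadRecord]] = {c: [] for c in CATEGORIES}
    classified: list[tuple[ReadRecord, ReadCategory]] = []
    tvr_counts = TvrSampleCounts()
    skipped_duplicates = 0
    n_reads = 0

    for read in stream_reads(read_file):
        if config.exclude_duplicates and read.is_duplicate:
            skipped_duplicates += 1
            continue
        n_reads += 1
        if not read.sequence:
            continue
        gc_dist.add(read.sequence)
        if is_telomeric(read, config.extraction):
            category = classify_read(read, cls_config)
            category_reads[category.value].append(read)
            classified.append((read, category))
            if category is ReadCategory.INTRATELOMERIC:
                tvr_counts.add_read(
                    read,
                    tvr_list=config.tvr_context_list,
                    min_base_quality=config.min_base_quality,
                )

    gc_dist.total_reads = n_reads
    tvr_counts.total_read_count = n_reads
    category_counts = {c: len(reads) for c, reads in category_reads.items()}
    estimate = telomere_content(category_counts["intratelomeric"], gc_dist)
    spectrum = per_chromosome_spectrum(classified, band_map)
    hist = repeats_per_read_histogram(
        category_reads["intratelomeric"], config.extraction.pattern_set
    )
    if n_reads == 0:
        logger.warning("%s: empty input, emitting all-zero results", read_file)
    logger.info(
        "%s: %d reads, %d extracted (%s), GC-matched denominator %d",
        sample,
        n_reads,
        sum(category_counts.values()),
        ", ".join(f"{c}={n}" for c, n in category_counts.items()),
        estimate.gc_matched_denominator,
    )
    return SampleResult(
        sample=sample,
        total_reads=n_reads,
        gc_distribution=gc_dist,
        category_counts=category_counts,
        category_reads=category_reads,
        estimate=estimate,
        tvr_counts=tvr_counts,
        spectrum=spectrum,
        repeats_histogram=hist,
        skipped_duplicates=skipped_duplicates,
    )


@dataclass
class RunResult:
    tumor: Optional[SampleResult]
    control: Optional[SampleResult]
    profile: TvrProfile
    content_log2_tc: Optional[float]
    summary: pd.DataFrame

    @property
    def paired(self) -> bool:
        return self.tumor is not None and self.control is not None


def _summary_frame(
    results: list[SampleResult], content_log2: Optional[float], paired: bool
) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "sample": res.sample,
            "total_reads": res.total_reads,
            "gc_matched_reads": res.estimate.gc_matched_denominator,
            "intratelomeric": res.category_counts["intratelomeric"],
            "subtelomeric": res.category_counts["subtelomeric"],
            "junction_spanning": res.category_counts["junction_spanning"],
            "intrachromosomal": res.category_counts["intrachromosomal"],
            "trpm": res.estimate.trpm if res.estimate.is_defined else float("nan"),
            "trpm_uncorrected": uncorrected_content(
                res.category_counts["intratelomeric"], res.total_reads
            )
            if res.total_reads
            else float("nan"),
        }
        if paired:
            row["log2_tc"] = content_log2 if content_log2 is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(results: list[SampleResult], run: "RunResult", config: RunConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    write_table(run.summary, os.path.join(config.out_dir, "summary.tsv"))
    write_table(run.profile.hexamer_table, os.path.join(config.out_dir, "tvr_counts.tsv"))
    write_table(run.profile.singleton_table, os.path.join(config.out_dir, "singletons.tsv"))
    write_table(run.profile.context_table, os.path.join(config.out_dir, "contexts.tsv"))
    spectra = []
    for res in results:
        spectrum = res.spectrum.copy()
        spectrum.insert(0, "sample", res.sample)
        spectra.append(spectrum)
    write_table(pd.concat(spectra, ignore_index=True), os.path.join(config.out_dir, "spectrum.tsv"))
    hist_rows = [
        {"sample": res.sample, "repeat_hits": k, "reads": v}
        for res in results
        for k, v in sorted(res.repeats_histogram.items())
    ]
    write_table(
        pd.DataFrame(hist_rows, columns=["sample", "repeat_hits", "reads"]),
        os.path.join(config.out_dir, "repeats_per_read.tsv"),
    )


def _write_category_files(read_file: str, res: SampleResult, config: RunConfig) -> None:
    header = read_header(read_file)
    sample_dir = os.path.join(config.out_dir, res.sample)
    for category in CATEGORIES:
        write_category_reads(
            res.category_reads[category],
            category,
            sample_dir,
            header,
            fmt=config.read_file_format,
        )


def run_single(read_file: str, config: RunConfig, sample: str = "sample") -> RunResult:
    """Tumor-only or control-only run; no log2 columns are emitted."""
    res = run_sample(read_file, config, sample=sample)
    profile = summarize_tvr_profile(res.tvr_counts, None)
    summary = _summary_frame([res], None, paired=False)
    run = RunResult(tumor=res, control=None, profile=profile, content_log2_tc=None, summary=summary)
    _write_outputs([res], run, config)
    if config.write_reads:
        _write_category_files(read_file, res, config)
    if config.plot:
        from telomere_profiler import plots

        plots.plot_all(run, config.out_dir)
    return run


def run_pair(tumor_file: str, control_file: str, config: RunConfig) -> RunResult:
    """Matched tumor/control run with content, TVR and singleton log2 T/C."""
    tumor = run_sample(tumor_file, config, sample="tumor")
    control = run_sample(control_file, config, sample="control")
    profile = summarize_tvr_profile(tumor.tvr_counts, control.tvr_counts)
    content_log2 = log2_tc_ratio(tumor.estimate, control.estimate)
    summary = _summary_frame([tumor, control], content_log2, paired=True)
    run = RunResult(
        tumor=tumor,
        control=control,
        profile=profile,
        content_log2_tc=content_log2,
        summary=summary,
    )
    _write_outputs([tumor, control], run, config)
    if config.write_reads:
        _write_category_files(tumor_file, tumor, config)
        _write_category_files(control_file, control, config)
    if config.plot:
        from telomere_profiler import plots

        plots.plot_all(run, config.out_dir)
    return run
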