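"""Telomere-variant-repeat (TVR) profiling of intratelomeric reads.

Three related scans over intratelomeric reads:

* arbitrary-context hexamers: non-overlapping NNNGGG matches (the
  canonical TTAGGG included, so composition fractions sum to 1), with the
  antisense strand handled by matching CCCNNN and reporting the forward
  hexamer; every matched hexamer must have base quality >= 20 at all six
  positions to be counted;
* singletons: a variant hexamer embedded in exactly-canonical flanks,
  (TTAGGG)x3 - NNNGGG - (TTAGGG)x3, the central hexamer differing from
  TTAGGG; the quality rule applies to the central hexamer;
* 18-bp contexts: for a configurable TVR list, the (left, right) 18-mer
  flank pair of each occurrence far enough from the read ends.

Arbitrary-context counts are normalized per intratelomeric read,
singleton counts per total sample read.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from telomere_profiler.extraction import TTYPE, reverse_complement
from telomere_profiler.io_formats import ReadRecord

DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_FLANK = 18

# Configurable stand-in for the ten most frequently observed TVR types;
# override via --tvr-context / the tvr_list argument.
DEFAULT_TVR_CONTEXT_LIST = (
    "TCAGGG",
    "TGAGGG",
    "TTGGGG",
    "TTCGGG",
    "TTTGGG",
    "ATAGGG",
    "CATGGG",
    "CTAGGG",
    "GTAGGG",
    "TAAGGG",
)

_TTYPE_RC = reverse_complement(TTYPE)  # CCCTAA
_FLANK_FWD = TTYPE * 3
_FLANK_REV = _TTYPE_RC * 3
_ACGT = frozenset("ACGT")


def _is_forward_hexamer(window: str) -> bool:
    return len(window) == 6 and window.endswith("GGG") and set(window) <= _ACGT


def _is_reverse_hexamer(window: str) -> bool:
    return len(window) == 6 and window.startswith("CCC") and set(window) <= _ACGT


def scan_hexamers(
    read: ReadRecord, min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
) -> dict[str, int]:
    """Non-overlapping NNNGGG hexamer counts (antisense reported forward).

    A sequence match always advances the scan by 6; it is counted only if
    all six base qualities reach ``min_base_quality``.
    """
    seq = read.sequence
    quals = read.base_qualities
    counts: Counter[str] = Counter()
    i = 0
    n = len(seq)
    while i + 6 <= n:
        window = seq[i : i + 6]
        if _is_forward_hexamer(window):
            hexamer = window
        elif _is_reverse_hexamer(window):
            hexamer = reverse_complement(window)
        else:
            i += 1
            continue
        if all(q >= min_base_quality for q in quals[i : i + 6]):
            counts[hexamer] += 1
        i += 6
    return dict(counts)


def detect_singletons(
    read: ReadRecord, min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
) -> dict[str, int]:
    """Counts of (TTAGGG)x3-NNNGGG-(TTAGGG)x3 singletons, keyed by forward hexamer.

    Every position whose 42-bp window matches the pattern (sense or
    antisense) contributes one count; the base-quality rule applies to the
    central hexamer only.
    """
    seq = read.sequence
    quals = read.base_qualities
    counts: Counter[str] = Counter()
    n = len(seq)
    for p in range(18, n - 23):
        window = seq[p : p + 6]
        if (
            window != TTYPE
            and _is_forward_hexamer(window)
            and seq[p - 18 : p] == _FLANK_FWD
            and seq[p + 6 : p + 24] == _FLANK_FWD
        ):
            hexamer = window
        elif (
            window != _TTYPE_RC
            and _is_reverse_hexamer(window)
            and seq[p - 18 : p] == _FLANK_REV
            and seq[p + 6 : p + 24] == _FLANK_REV
        ):
            hexamer = reverse_complement(window)
        else:
            continue
        if all(q >= min_base_quality for q in quals[p : p + 6]):
            counts[hexamer] += 1
    return dict(counts)


def extract_contexts(
    read: ReadRecord,
    tvr_list: Sequence[str] = DEFAULT_TVR_CONTEXT_LIST,
    flank: int = DEFAULT_FLANK,
) -> dict[str, Counter]:
    """(left, right) flank pairs around occurrences of the listed TVRs.

    Occurrences closer than ``flank`` bases to a read end are dropped.
    Antisense occurrences are reported in forward orientation (flanks
    reverse-complemented and swapped). Returns {tvr: Counter[(left, right)]}.
    """
    if not tvr_list:
        raise ValueError("tvr_list must be non-empty")
    forward = {t.upper() for t in tvr_list}
    reverse = {reverse_complement(t): t.upper() for t in tvr_list}
    seq = read.sequence
    table: dict[str, Counter] = {}
    i = 0
    n = len(seq)
    while i + 6 <= n:
        window = seq[i : i + 6]
        if window in forward or window in reverse:
            if i >= flank and i + 6 + flank <= n:
                left = seq[i - flank : i]
                right = seq[i + 6 : i + 6 + flank]
                if window in forward:
                    tvr = window
                    pair = (left, right)
                else:
                    tvr = reverse[window]
                    pair = (reverse_complement(right), reverse_complement(left))
                table.setdefault(tvr, Counter())[pair] += 1
            i += 6
        else:
            i += 1
    return table


@dataclass
class TvrSampleCounts:
    """Aggregated TVR scan results for one sample."""

    hexamers: Counter = field(default_factory=Counter)
    singletons: Counter = field(default_factory=Counter)
    contexts: dict[str, Counter] = field(default_factory=dict)
    intratelomeric_read_count: int = 0
    total_read_count: int = 0

    def add_read(
        self,
        read: ReadRecord,
        tvr_list: Sequence[str] = DEFAULT_TVR_CONTEXT_LIST,
        min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    ) -> None:
        """Scan one intratelomeric read into the aggregate."""
        self.intratelomeric_read_count += 1
        self.hexamers.update(scan_hexamers(read, min_base_quality))
        self.singletons.update(detect_singletons(read, min_base_quality))
        for tvr, pairs in extract_contexts(read, tvr_list).items():
            self.contexts.setdefault(tvr, Counter()).update(pairs)


@dataclass
class TvrProfile:
    """Normalized TVR/singleton tables with optional per-hexamer log2 T/C."""

    hexamer_table: pd.DataFrame
    singleton_table: pd.DataFrame
    context_table: pd.DataFrame
    paired: bool


def _log2_or_nan(num: float, den: float) -> float:
    if num > 0 and den > 0:
        return math.log2(num / den)
    return float("nan")


def _count_frame(
    tumor: Counter,
    control: Optional[Counter],
    tumor_norm: Optional[int],
    control_norm: Optional[int],
) -> pd.DataFrame:
    hexamers = sorted(set(tumor) | set(control or ()))
    rows = []
    for h in hexamers:
        row: dict[str, object] = {"hexamer": h, "tumor_raw": tumor.get(h, 0)}
        row["tumor_normalized"] = (
            tumor.get(h, 0) / tumor_norm if tumor_norm else float("nan")
        )
        if control is not None:
            row["control_raw"] = control.get(h, 0)
            row["control_normalized"] = (
                control.get(h, 0) / control_norm if control_norm else float("nan")
            )
            row["log2_tc"] = _log2_or_nan(
                row["tumor_normalized"] if tumor_norm else float("nan"),
                row["control_normalized"] if control_norm else float("nan"),
            )
        rows.append(row)
    columns = ["hexamer", "tumor_raw", "tumor_normalized"]
    if control is not None:
        columns += ["control_raw", "control_normalized", "log2_tc"]
    return pd.DataFrame(rows, columns=columns)


def _context_frame(
    tumor: dict[str, Counter], control: Optional[dict[str, Counter]]
) -> pd.DataFrame:
    rows = []
    samples = [("tumor", tumor)] + ([("control", control)] if control is not None else [])
    for sample, contexts in samples:
        for tvr in sorted(contexts):
            for (left, right), count in sorted(contexts[tvr].items()):
                rows.append(
                    {
                        "sample": sample,
                        "tvr": tvr,
                        "left_flank": left,
                        "right_flank": right,
                        "count": count,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "tvr", "left_flank", "right_flank", "count"])


def summarize_tvr_profile(
    tumor: TvrSampleCounts, control: Optional[TvrSampleCounts] = None
) -> TvrProfile:
    """Build normalized hexamer/singleton/context tables, with log2 T/C if paired.

    Hexamers absent from (or zero in) one side get NaN log2 ratios rather
    than +/- infinity; zero intratelomeric or total reads flag the
    corresponding normalized column as NaN.
    """
    paired = control is not None
    hexamer_table = _count_frame(
        tumor.hexamers,
        control.hexamers if paired else None,
        tumor.intratelomeric_read_count or None,
        (control.intratelomeric_read_count or None) if paired else None,
    )
    singleton_table = _count_frame(
        tumor.singletons,
        control.singletons if paired else None,
        tumor.total_read_count or None,
        (control.total_read_count or None) if paired else None,
    )
    context_table = _context_frame(tumor.contexts, control.contexts if paired else None)
    return TvrProfile(
        hexamer_table=hexamer_table,
        singleton_table=singleton_table,
        context_table=context_table,
        paired=paired,
    )
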