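"""GC-corrected telomere content (TRPM) and tumor/control log2 ratio.

The intratelomeric read count is divided by the number of sample reads
whose GC content falls in the 48-52% window (inclusive) -- close to the
50% GC of the canonical repeat -- and scaled by 1e6 to give TRPM
(telomeric reads per GC-content-matched million reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from telomere_profiler.io_formats import ReadRecord

GC_WINDOW_LOW = 48
GC_WINDOW_HIGH = 52


def gc_percent(sequence: str) -> Optional[int]:
    """Integer GC percent, round-half-up; ambiguous bases excluded.

    Returns None for a sequence with no unambiguous base.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return math.floor(100 * gc / acgt + 0.5)


@dataclass
class GcDistribution:
    """Read counts per integer GC-percent bin (0-100)."""

    bins: list[int] = field(default_factory=lambda: [0] * 101)
    total_reads: int = 0  # includes reads with no countable base

    def add(self, sequence: str) -> None:
        self.total_reads += 1
        pct = gc_percent(sequence)
        if pct is not None:
            self.bins[pct] += 1

    def count_in(self, low: int, high: int) -> int:
        return sum(self.bins[low : high + 1])

    @property
    def binned_reads(self) -> int:
        return sum(self.bins)

    def merge(self, other: "GcDistribution") -> "GcDistribution":
        merged = GcDistribution(
            bins=[a + b for a, b in zip(self.bins, other.bins)],
            total_reads=self.total_reads + other.total_reads,
        )
        return merged


def accumulate_gc_distribution(reads: Iterable[ReadRecord]) -> GcDistribution:
    dist = GcDistribution()
    for read in reads:
        dist.add(read.sequence)
    return dist


@dataclass(frozen=True)
class TelomereContentEstimate:
    intratelomeric_count: int
    gc_matched_denominator: int
    total_read_count: int
    trpm: Optional[float]  # None when denominator is 0 (flagged undefined)

    @property
    def is_defined(self) -> bool:
        return self.trpm is not None


def telomere_content(
    intratelomeric_count: int,
    gc_dist: GcDistribution,
    low: int = GC_WINDOW_LOW,
    high: int = GC_WINDOW_HIGH,
) -> TelomereContentEstimate:
    """TRPM = intratelomeric / (reads with GC in [low, high]) * 1e6."""
    denominator = gc_dist.count_in(low, high)
    trpm = intratelomeric_count / denominator * 1e6 if denominator > 0 else None
    return TelomereContentEstimate(
        intratelomeric_count=intratelomeric_count,
        gc_matched_denominator=denominator,
        total_read_count=gc_dist.total_reads,
        trpm=trpm,
    )


def uncorrected_content(intratelomeric_count: int, total_reads: int) -> Optional[float]:
    """Intratelomeric reads per million total reads (no GC correction)."""
    if total_reads <= 0:
        return None
    return intratelomeric_count / total_reads * 1e6


def log2_tc_ratio(
    tumor: TelomereContentEstimate, control: TelomereContentEstimate
) -> Optional[float]:
    """log2(tumor TRPM / control TRPM); None if either side is undefined or zero."""
    if not tumor.is_defined or not control.is_defined:
        return None
    if tumor.trpm <= 0 or control.trpm <= 0:
        return None
    return math.log2(tumor.trpm / control.trpm)
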