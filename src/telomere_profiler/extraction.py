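"""Telomeric-read extraction by hexamer repeat counting.

A read is telomeric when it carries at least ``n`` occurrences of the
configured repeat patterns (default: t-, c-, g- and j-type hexamers and
their reverse complements), where ``n = floor(read_length * 0.06)`` unless
overridden. Matching is non-overlapping and greedy left-to-right; in
consecutive mode the score is the longest run of adjacent pattern
instances instead of the total count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from telomere_profiler.io_formats import ReadRecord

TTYPE = "TTAGGG"
DEFAULT_PATTERNS = ("TTAGGG", "TCAGGG", "TGAGGG", "TTGGGG")
DEFAULT_THRESHOLD_COEFFICIENT = 0.06

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatPatternSet:
    """Search patterns for extraction, optionally with reverse complements."""

    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    include_reverse_complement: bool = True
    consecutive_mode: bool = False

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("pattern set must not be empty")
        normalized = tuple(p.upper() for p in self.patterns)
        for p in normalized:
            if not p or set(p) - set("ACGT"):
                raise ValueError(f"pattern {p!r} is not a non-empty ACGT string")
        object.__setattr__(self, "patterns", normalized)

    @property
    def search_set(self) -> frozenset[str]:
        pats = set(self.patterns)
        if self.include_reverse_complement:
            pats |= {reverse_complement(p) for p in self.patterns}
        return frozenset(pats)


@dataclass(frozen=True)
class ExtractionConfig:
    pattern_set: RepeatPatternSet = field(default_factory=RepeatPatternSet)
    threshold_override: int | None = None  # the -rt parameter
    threshold_coefficient: float = DEFAULT_THRESHOLD_COEFFICIENT

    def __post_init__(self) -> None:
        if self.threshold_override is not None and self.threshold_override < 1:
            raise ValueError("threshold_override must be >= 1")

    def threshold_for(self, read_length: int) -> int:
        if self.threshold_override is not None:
            return self.threshold_override
        return compute_repeat_threshold(read_length, self.threshold_coefficient)


def compute_repeat_threshold(
    read_length: int, coefficient: float = DEFAULT_THRESHOLD_COEFFICIENT
) -> int:
    """floor(read_length * coefficient), clamped to a minimum of 1.

    Gives the default of 6 repeats for 100-bp reads.
    """
    if read_length < 1:
        raise ValueError(f"read_length must be >= 1, got {read_length}")
    return max(1, math.floor(read_length * coefficient))


def count_repeat_hits(sequence: str, pattern_set: RepeatPatternSet) -> int:
    """Count pattern occurrences in a sequence.

    Non-consecutive mode: total non-overlapping occurrences of any
    search-set pattern, greedy left-to-right (a match advances the scan
    by the pattern length). Consecutive mode: length in pattern units of
    the longest contiguous run of adjacent pattern instances; runs may
    mix patterns of the set.
    """
    seq = sequence.upper()
    patterns = sorted(pattern_set.search_set, key=len)
    n = len(seq)
    if pattern_set.consecutive_mode:
        # longest chain of pattern instances where each begins exactly
        # where the previous one ends; patterns may overlap each other
        # (e.g. CCCTCA / TCAGGG), so a greedy scan would undercount
        best = 0
        run_from = [0] * (n + max(len(p) for p in patterns) + 1)
        for i in range(n - 1, -1, -1):
            for p in patterns:
                if seq.startswith(p, i):
                    run_from[i] = max(run_from[i], 1 + run_from[i + len(p)])
            best = max(best, run_from[i])
        return best
    total = 0
    i = 0
    while i < n:
        hit_len = 0
        for p in patterns:
            if seq.startswith(p, i):
                hit_len = len(p)
                break
        if hit_len:
            total += 1
            i += hit_len
        else:
            i += 1
    return total


def is_telomeric(read: "ReadRecord", config: ExtractionConfig) -> bool:
    """True iff the read's repeat-hit count reaches the (length-scaled) threshold."""
    if not read.sequence:
        raise ValueError(f"read {read.name} has no sequence")
    threshold = config.threshold_for(len(read.sequence))
    return count_repeat_hits(read.sequence, config.pattern_set) >= threshold


def restrict_to_ttype(config: ExtractionConfig) -> ExtractionConfig:
    """Config matching only TTAGGG (plus reverse complement), mirroring ``-r TTAGGG``."""
    return replace(config, pattern_set=replace(config.pattern_set, patterns=(TTYPE,)))
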