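"""Independent brute-force oracles used to cross-check the package.

These deliberately use different mechanics (regex scans, full window
enumeration, right-to-left dynamic programming) from the implementations
they validate.
"""

from __future__ import annotations

import re
from collections import Counter

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def oracle_nonconsecutive_count(sequence: str, patterns: set[str]) -> int:
    """Non-overlapping leftmost-first occurrence count via re.findall."""
    alternation = "|".join(re.escape(p) for p in sorted(patterns))
    return len(re.findall(alternation, sequence.upper()))


def oracle_consecutive_run(sequence: str, patterns: set[str]) -> int:
    """Longest run of adjacent pattern instances via regex repetition.

    ``(?:p1|p2|...){k}`` matches somewhere iff a run of k adjacent
    instances exists (regex backtracking explores all decompositions).
    """
    seq = sequence.upper()
    alternation = "|".join(re.escape(p) for p in sorted(patterns))
    k = 0
    while re.search(f"(?:{alternation}){{{k + 1}}}", seq):
        k += 1
    return k


_HEXAMER_RE = re.compile(r"[ACGT]{3}GGG|CCC[ACGT]{3}")


def oracle_scan_hexamers(sequence: str, qualities: list[int], min_quality: int) -> dict:
    """Regex-based NNNGGG/CCCNNN scan with the per-match quality filter."""
    counts: Counter = Counter()
    for m in _HEXAMER_RE.finditer(sequence.upper()):
        if all(q >= min_quality for q in qualities[m.start() : m.end()]):
            window = m.group(0)
            if window.endswith("GGG"):
                counts[window] += 1
            else:
                counts[revcomp(window)] += 1
    return dict(counts)


def oracle_detect_singletons(sequence: str, qualities: list[int], min_quality: int) -> dict:
    """Enumerate every 42-bp window and test the singleton pattern directly."""
    seq = sequence.upper()
    t3 = "TTAGGG" * 3
    r3 = "CCCTAA" * 3
    counts: Counter = Counter()
    for p in range(0, len(seq) - 41):
        window = seq[p : p + 42]
        central = window[18:24]
        cq = qualities[p + 18 : p + 24]
        if any(q < min_quality for q in cq):
            continue
        if set(central) - set("ACGT"):
            continue
        if window[:18] == t3 and window[24:] == t3:
            if central.endswith("GGG") and central != "TTAGGG":
                counts[central] += 1
        elif window[:18] == r3 and window[24:] == r3:
            if central.startswith("CCC") and central != "CCCTAA":
                counts[revcomp(central)] += 1
    return dict(counts)


def random_telomere_like_sequence(rng, max_length: int = 300) -> str:
    """Random sequence biased toward telomeric motifs (for oracle fuzzing)."""
    motifs = [
        "TTAGGG", "TCAGGG", "TGAGGG", "TTGGGG",
        "CCCTAA", "CCCTGA", "CCCTCA", "CCCCAA",
    ]
    parts: list[str] = []
    length = rng.randrange(1, max_length + 1)
    while sum(len(p) for p in parts) < length:
        if rng.random() < 0.55:
            parts.append(rng.choice(motifs))
        else:
            parts.append("".join(rng.choice("ACGTN") for _ in range(rng.randrange(1, 8))))
    return "".join(parts)[:length]
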