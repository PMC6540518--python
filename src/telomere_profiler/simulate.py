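"""Synthetic aligned-read fixtures with fully known ground truth.

Emits a small cytoBand-style band file (two chromosomes, three bands
each) plus a SAM/BAM file containing reads of each pipeline category:

* intratelomeric: unmapped telomere-repeat reads with configurable TVR
  composition and singleton rate;
* subtelomeric / intrachromosomal: telomere reads mapped at quality 60
  onto a terminal / interior band;
* junction pairs: an unmapped telomere read whose mapped, non-telomeric
  mate sits on a terminal band;
* background: random non-repeat reads (rejection-sampled so they never
  reach the extraction threshold) mapped to interior bands, with an
  exactly controlled GC percent.

Ground truth (intended category per read, planted hexamer/singleton
counts, closed-form TRPM) is returned alongside and is re-derivable from
the emitted file. Telomere sequences are built as tilings of NNNGGG
hexamers; because every tile ends in GGG the scan frame is fixed, so the
tile list *is* the ground truth for hexamer and singleton counts.
"""

from __future__ import annotations

import json
import os
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pysam

from telomere_profiler.extraction import (
    TTYPE,
    RepeatPatternSet,
    compute_repeat_threshold,
    count_repeat_hits,
)
from telomere_profiler.io_formats import ReadRecord

_BAND_LAYOUT = {
    "chr1": [("p1", 0, 1_000_000), ("q1", 1_000_000, 2_000_000), ("q2", 2_000_000, 3_000_000)],
    "chr2": [("p1", 0, 1_000_000), ("q1", 1_000_000, 2_000_000), ("q2", 2_000_000, 3_000_000)],
}
_CHROM_LENGTH = 3_000_000


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic sample."""

    read_length: int = 100
    n_intratelomeric: int = 50
    n_subtelomeric: int = 0
    n_junction_pairs: int = 0
    n_intrachromosomal: int = 0
    n_background: int = 1000
    tvr_freqs: dict[str, float] = field(default_factory=dict)
    singleton_rate: float = 0.0
    background_gc: int = 50
    base_quality: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 6:
            raise ValueError("read_length must be >= 6")
        for hexamer, freq in self.tvr_freqs.items():
            if len(hexamer) != 6 or not hexamer.endswith("GGG"):
                raise ValueError(f"TVR {hexamer!r} must be a 6-mer ending in GGG")
            if freq < 0:
                raise ValueError("TVR frequencies must be >= 0")
        if sum(self.tvr_freqs.values()) > 1:
            raise ValueError("TVR frequencies must sum to <= 1")
        if not 0 <= self.singleton_rate <= 1:
            raise ValueError("singleton_rate must be in [0, 1]")
        if not 0 <= self.background_gc <= 100:
            raise ValueError("background_gc must be a percent")


@dataclass
class FixtureTruth:
    """Intended category per read plus planted counts and closed-form TRPM."""

    categories: dict[str, str]
    planted_hexamers: Counter
    planted_singletons: Counter
    category_counts: dict[str, int]
    total_reads: int
    gc_matched_reads: int
    expected_trpm: Optional[float]

    def to_json(self, path: str | os.PathLike) -> str:
        payload = {
            "categories": self.categories,
            "planted_hexamers": dict(self.planted_hexamers),
            "planted_singletons": dict(self.planted_singletons),
            "category_counts": self.category_counts,
            "total_reads": self.total_reads,
            "gc_matched_reads": self.gc_matched_reads,
            "expected_trpm": self.expected_trpm,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return str(path)


def make_telomere_sequence(
    length: int,
    tvr_freqs: dict[str, float],
    singleton_rate: float,
    rng: random.Random,
) -> tuple[str, Counter, Counter]:
    """Hexamer tiling drawn per frequencies; returns (sequence, hexamers, singletons).

    Planted counts are computed from the tile list: singletons are tiles
    differing from TTAGGG with three canonical tiles on each side (the
    fixed GGG frame makes off-frame matches impossible, see module doc).
    """
    if singleton_rate > 0 and length < 42:
        raise ValueError("singleton planting requires reads of >= 42 bp")
    n_units = length // 6
    variants = sorted(tvr_freqs)
    weights = [tvr_freqs[v] for v in variants]
    t_weight = 1.0 - sum(weights)
    tiles = rng.choices(variants + [TTYPE], weights=weights + [t_weight], k=n_units)
    if singleton_rate > 0 and rng.random() < singleton_rate:
        pos = rng.randrange(3, n_units - 3)
        central = rng.choices(variants, weights=weights, k=1)[0] if variants else "TCAGGG"
        for j in range(pos - 3, pos + 4):
            tiles[j] = central if j == pos else TTYPE
    sequence = "".join(tiles) + TTYPE[: length - 6 * n_units]
    hexamers = Counter(tiles)
    singletons: Counter = Counter()
    for i, tile in enumerate(tiles):
        if (
            tile != TTYPE
            and 3 <= i <= n_units - 4
            and all(tiles[j] == TTYPE for j in range(i - 3, i))
            and all(tiles[j] == TTYPE for j in range(i + 1, i + 4))
        ):
            singletons[tile] += 1
    return sequence, hexamers, singletons


def _gc_percent(sequence: str) -> int:
    gc = sequence.count("G") + sequence.count("C")
    return int(100 * gc / len(sequence) + 0.5)


def make_background_sequence(
    length: int, gc_target: int, rng: random.Random, pattern_set: RepeatPatternSet
) -> str:
    """Random sequence at an exact GC percent with zero telomere-pattern hits."""
    n_gc = round(length * gc_target / 100)
    while True:
        bases = [rng.choice("GC") for _ in range(n_gc)]
        bases += [rng.choice("AT") for _ in range(length - n_gc)]
        rng.shuffle(bases)
        seq = "".join(bases)
        if count_repeat_hits(seq, pattern_set) == 0:
            return seq


def _record(name: str, sequence: str, quality: int, **kwargs) -> ReadRecord:
    return ReadRecord(
        name=name,
        sequence=sequence,
        base_qualities=[quality] * len(sequence),
        **kwargs,
    )


def write_band_file(path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        for chrom, bands in _BAND_LAYOUT.items():
            for name, start, end in bands:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\tgneg\n")
    return str(path)


def build_fixture_reads(spec: FixtureSpec) -> tuple[list[ReadRecord], FixtureTruth]:
    """Generate all fixture reads and their ground truth (no I/O)."""
    rng = random.Random(spec.seed)
    pattern_set = RepeatPatternSet()
    reads: list[ReadRecord] = []
    categories: dict[str, str] = {}
    planted_hexamers: Counter = Counter()
    planted_singletons: Counter = Counter()
    chroms = list(_BAND_LAYOUT)
    q = spec.base_quality

    def telomere_read() -> tuple[str, Counter, Counter]:
        return make_telomere_sequence(
            spec.read_length, spec.tvr_freqs, spec.singleton_rate, rng
        )

    for i in range(spec.n_intratelomeric):
        seq, hexamers, singles = telomere_read()
        name = f"intra_{i}"
        reads.append(_record(name, seq, q, is_mapped=False))
        categories[name] = "intratelomeric"
        planted_hexamers.update(hexamers)
        planted_singletons.update(singles)

    for i in range(spec.n_subtelomeric):
        seq, _, _ = telomere_read()
        name = f"sub_{i}"
        chrom = chroms[i % 2]
        # terminal band: p1 for even reads, q2 for odd
        pos = 5_000 + 10 * i if i % 4 < 2 else 2_500_000 + 10 * i
        reads.append(
            _record(name, seq, q, is_mapped=True, chromosome=chrom, position=pos,
                    mapping_quality=60)
        )
        categories[name] = "subtelomeric"

    for i in range(spec.n_intrachromosomal):
        seq, _, _ = telomere_read()
        name = f"chrom_{i}"
        chrom = chroms[i % 2]
        reads.append(
            _record(name, seq, q, is_mapped=True, chromosome=chrom,
                    position=1_200_000 + 10 * i, mapping_quality=60)
        )
        categories[name] = "intrachromosomal"

    for i in range(spec.n_junction_pairs):
        seq, _, _ = telomere_read()
        name = f"junc_{i}"
        chrom = chroms[i % 2]
        mate_pos = 8_000 + 10 * i
        reads.append(
            _record(name, seq, q, is_mapped=False, is_paired=True, is_read1=True,
                    mate_is_mapped=True, mate_chromosome=chrom, mate_position=mate_pos)
        )
        anchor_seq = make_background_sequence(
            spec.read_length, spec.background_gc, rng, pattern_set
        )
        reads.append(
            _record(name, anchor_seq, q, is_mapped=True, is_paired=True, is_read1=False,
                    chromosome=chrom, position=mate_pos, mapping_quality=60,
                    mate_is_mapped=False)
        )
        categories[name] = "junction_spanning"

    for i in range(spec.n_background):
        seq = make_background_sequence(spec.read_length, spec.background_gc, rng, pattern_set)
        name = f"bg_{i}"
        chrom = chroms[i % 2]
        reads.append(
            _record(name, seq, q, is_mapped=True, chromosome=chrom,
                    position=1_500_000 + 10 * i, mapping_quality=60)
        )
        categories[name] = "background"

    gc_matched = sum(1 for r in reads if 48 <= _gc_percent(r.sequence) <= 52)
    total = len(reads)
    trpm = spec.n_intratelomeric / gc_matched * 1e6 if gc_matched else None
    truth = FixtureTruth(
        categories=categories,
        planted_hexamers=planted_hexamers,
        planted_singletons=planted_singletons,
        category_counts={
            "intratelomeric": spec.n_intratelomeric,
            "subtelomeric": spec.n_subtelomeric,
            "junction_spanning": spec.n_junction_pairs,
            "intrachromosomal": spec.n_intrachromosomal,
            "background": spec.n_background,
        },
        total_reads=total,
        gc_matched_reads=gc_matched,
        expected_trpm=trpm,
    )
    return reads, truth


def fixture_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": _CHROM_LENGTH} for c in _BAND_LAYOUT],
        }
    )


def emit_fixture(
    spec: FixtureSpec, out_dir: str | os.PathLike, *, fmt: str = "sam"
) -> tuple[str, str, FixtureTruth]:
    """Write the read file and band file; returns (read path, band path, truth)."""
    if fmt not in ("sam", "bam"):
        raise ValueError(f"fmt must be 'sam' or 'bam', got {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    band_path = write_band_file(os.path.join(out_dir, "cytoBand.txt"))
    reads, truth = build_fixture_reads(spec)
    header = fixture_header()
    read_path = os.path.join(out_dir, f"fixture.{fmt}")
    mode = "wb" if fmt == "bam" else "wh"
    with pysam.AlignmentFile(read_path, mode, header=header) as out:
        for read in reads:
            out.write(read.to_pysam(header))
    return read_path, band_path, truth
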