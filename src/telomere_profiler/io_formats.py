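"""Aligned-read and chromosome-band I/O.

Reads are streamed from BAM/SAM via :mod:`pysam`; secondary and
supplementary records are dropped so each template contributes once.
Chromosome bands come from a UCSC ``cytoBand.txt``-style file
(tab-separated: chrom, start, end, band name, stain; 0-based half-open
coordinates). Chromosome names are normalized by stripping a leading
``chr`` so band files and read files with differing conventions match.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

CATEGORIES = ("intratelomeric", "junction_spanning", "subtelomeric", "intrachromosomal")


class BandFileError(ValueError):
    """Raised for malformed or empty chromosome-band files."""


def normalize_chromosome(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so 'chr1' and '1' compare equal."""
    if name.lower().startswith("chr"):
        return name[3:]
    return name


@dataclass(frozen=True)
class Band:
    """One cytogenetic band: 0-based half-open interval on a chromosome."""

    chromosome: str
    name: str
    start: int
    end: int
    is_terminal: bool = False

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class BandMap:
    """Ordered, non-overlapping bands per (normalized) chromosome.

    The first and last band of each chromosome are flagged terminal; a
    single-band chromosome has one band that is both first and last.
    """

    bands: dict[str, list[Band]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, rows: Iterable[tuple[str, int, int, str]]) -> "BandMap":
        """Build from (chrom, start, end, band_name) rows; sorts and flags terminals."""
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, name in rows:
            per_chrom.setdefault(normalize_chromosome(chrom), []).append((start, end, name))
        bands: dict[str, list[Band]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda iv: iv[0])
            n = len(ivs)
            bands[chrom] = [
                Band(chrom, name, start, end, is_terminal=(i == 0 or i == n - 1))
                for i, (start, end, name) in enumerate(ivs)
            ]
        return cls(bands=bands)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.bands)

    def lookup(self, chromosome: str, position: int) -> Optional[Band]:
        """Band containing ``position`` or None (unknown contig / outside bands)."""
        chrom_bands = self.bands.get(normalize_chromosome(chromosome))
        if not chrom_bands:
            return None
        for band in chrom_bands:
            if band.contains(position):
                return band
        return None


def read_band_file(path: str | os.PathLike) -> BandMap:
    """Parse a UCSC cytoBand-dialect file into a :class:`BandMap`.

    Raises :class:`BandFileError` naming the offending line on malformed
    input, and on an empty file.
    """
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BandFileError(f"{path}: line {lineno}: expected >=4 tab-separated fields")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BandFileError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise BandFileError(f"{path}: line {lineno}: end < start")
            rows.append((chrom, start, end, name))
    if not rows:
        raise BandFileError(f"{path}: no band records found")
    return BandMap.from_intervals(rows)


@dataclass
class ReadRecord:
    """One sequencing read with the alignment fields the pipeline needs."""

    name: str
    sequence: str
    base_qualities: list[int]
    is_mapped: bool = False
    chromosome: Optional[str] = None
    position: Optional[int] = None  # 0-based leftmost
    mapping_quality: int = 0
    is_paired: bool = False
    is_properly_paired: bool = False
    mate_is_mapped: bool = False
    mate_chromosome: Optional[str] = None
    mate_position: Optional[int] = None
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_read1: bool = True

    def __post_init__(self) -> None:
        if len(self.base_qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.name}: {len(self.base_qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.is_mapped and (self.chromosome is None or self.position is None):
            raise ValueError(f"read {self.name}: mapped but missing coordinates")
        self.sequence = self.sequence.upper()

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "ReadRecord":
        return cls(
            name=aln.query_name or "",
            sequence=(aln.query_sequence or "").upper(),
            base_qualities=list(aln.query_qualities or []),
            is_mapped=not aln.is_unmapped,
            chromosome=aln.reference_name if not aln.is_unmapped else None,
            position=aln.reference_start if not aln.is_unmapped else None,
            mapping_quality=aln.mapping_quality,
            is_paired=aln.is_paired,
            is_properly_paired=aln.is_proper_pair,
            mate_is_mapped=aln.is_paired and not aln.mate_is_unmapped,
            mate_chromosome=(
                aln.next_reference_name
                if aln.is_paired and not aln.mate_is_unmapped
                else None
            ),
            mate_position=(
                aln.next_reference_start
                if aln.is_paired and not aln.mate_is_unmapped
                else None
            ),
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            is_duplicate=aln.is_duplicate,
            is_read1=aln.is_read1 or not aln.is_paired,
        )

    def to_pysam(self, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
        aln = pysam.AlignedSegment(header)
        aln.query_name = self.name
        aln.query_sequence = self.sequence
        aln.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in self.base_qualities)
        )
        flag = 0
        if self.is_paired:
            flag |= 0x1
            flag |= 0x40 if self.is_read1 else 0x80
            if self.is_properly_paired:
                flag |= 0x2
            if not self.mate_is_mapped:
                flag |= 0x8
        if not self.is_mapped:
            flag |= 0x4
        if self.is_secondary:
            flag |= 0x100
        if self.is_supplementary:
            flag |= 0x800
        if self.is_duplicate:
            flag |= 0x400
        aln.flag = flag
        if self.is_mapped:
            aln.reference_id = header.get_tid(self.chromosome)
            aln.reference_start = self.position
            aln.mapping_quality = self.mapping_quality
            aln.cigarstring = f"{len(self.sequence)}M"
        else:
            aln.reference_id = -1
            aln.reference_start = -1
            aln.mapping_quality = 0
        if self.is_paired and self.mate_is_mapped and self.mate_chromosome is not None:
            aln.next_reference_id = header.get_tid(self.mate_chromosome)
            aln.next_reference_start = self.mate_position
        else:
            aln.next_reference_id = -1
            aln.next_reference_start = -1
        return aln


def _open_alignment(path: str | os.PathLike, mode: str, **kwargs) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), mode, **kwargs)


def stream_reads(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Yield every primary, non-supplementary record of a BAM/SAM file.

    Unmapped reads are included (they are candidate intratelomeric reads).
    Counts of skipped secondary/supplementary records are logged.
    """
    skipped = 0
    with _open_alignment(path, "r", check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            yield ReadRecord.from_pysam(aln)
    if skipped:
        logger.info("%s: skipped %d secondary/supplementary records", path, skipped)


def read_header(path: str | os.PathLike) -> pysam.AlignmentHeader:
    with _open_alignment(path, "r", check_sq=False) as fh:
        return fh.header


def write_category_reads(
    reads: Sequence[ReadRecord],
    category: str,
    out_dir: str | os.PathLike,
    header: pysam.AlignmentHeader,
    *,
    fmt: str = "bam",
) -> str:
    """Write one per-category read file (header copied from input); returns its path."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if fmt not in ("bam", "sam"):
        raise ValueError(f"fmt must be 'bam' or 'sam', got {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"{category}.{fmt}")
    mode = "wb" if fmt == "bam" else "wh"
    with _open_alignment(path, mode, header=header) as out:
        for read in reads:
            out.write(read.to_pysam(header))
    return path


def write_table(df, path: str | os.PathLike) -> str:
    """Write a result table as tab-separated text with a header row."""
    df.to_csv(path, sep="\t", index=False)
    return str(path)
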