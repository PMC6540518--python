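"""Four-way classification of extracted telomeric reads.

Each telomeric read is assigned exactly one category from its alignment:

* confidently mapped (mapping quality >= threshold, default 8) to a
  terminal chromosome band -> ``subtelomeric``; to an interior band ->
  ``intrachromosomal``; to a contig absent from the band map ->
  ``intratelomeric``;
* otherwise (unmapped or low quality): a mapped mate on a terminal band
  rescues the read as ``junction_spanning``; else ``intratelomeric``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from telomere_profiler.io_formats import Band, BandMap, ReadRecord

DEFAULT_MAPQ_THRESHOLD = 8


class ReadCategory(str, enum.Enum):
    INTRATELOMERIC = "intratelomeric"
    JUNCTION_SPANNING = "junction_spanning"
    SUBTELOMERIC = "subtelomeric"
    INTRACHROMOSOMAL = "intrachromosomal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassificationConfig:
    band_map: BandMap
    mapping_quality_threshold: int = DEFAULT_MAPQ_THRESHOLD

    def __post_init__(self) -> None:
        if self.mapping_quality_threshold < 0:
            raise ValueError("mapping_quality_threshold must be >= 0")


def locate_band(chromosome: str, position: int, band_map: BandMap) -> Optional[Band]:
    """Band containing the position, or None for unknown contigs / off-band positions."""
    return band_map.lookup(chromosome, position)


def classify_read(read: ReadRecord, config: ClassificationConfig) -> ReadCategory:
    if read.is_mapped and read.mapping_quality >= config.mapping_quality_threshold:
        band = locate_band(read.chromosome, read.position, config.band_map)
        if band is None:
            return ReadCategory.INTRATELOMERIC
        return ReadCategory.SUBTELOMERIC if band.is_terminal else ReadCategory.INTRACHROMOSOMAL
    # unmapped or low-quality: mate on a terminal band rescues as junction spanning
    if read.is_paired and read.mate_is_mapped and read.mate_chromosome is not None:
        mate_band = locate_band(read.mate_chromosome, read.mate_position, config.band_map)
        if mate_band is not None and mate_band.is_terminal:
            return ReadCategory.JUNCTION_SPANNING
    return ReadCategory.INTRATELOMERIC


_SPECTRUM_CATEGORIES = (
    ReadCategory.SUBTELOMERIC,
    ReadCategory.JUNCTION_SPANNING,
    ReadCategory.INTRACHROMOSOMAL,
)


def per_chromosome_spectrum(
    classified: Iterable[tuple[ReadRecord, ReadCategory]], band_map: BandMap
) -> pd.DataFrame:
    """Zero-filled count table (chromosome x non-intratelomeric category).

    Junction-spanning reads are attributed to the mate's chromosome (the
    read itself is unmapped); mapped categories use the read's own.
    """
    index = band_map.chromosomes
    table = pd.DataFrame(
        0, index=pd.Index(index, name="chromosome"),
        columns=[c.value for c in _SPECTRUM_CATEGORIES],
    )
    for read, category in classified:
        if category not in _SPECTRUM_CATEGORIES:
            continue
        if category is ReadCategory.JUNCTION_SPANNING:
            chrom = read.mate_chromosome
        else:
            chrom = read.chromosome
        if chrom is None:
            continue
        from telomere_profiler.io_formats import normalize_chromosome

        chrom = normalize_chromosome(chrom)
        if chrom in table.index:
            table.loc[chrom, category.value] += 1
    return table.reset_index()
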