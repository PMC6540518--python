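from __future__ import annotations

import pytest

from telomere_profiler.io_formats import BandMap, ReadRecord


def make_read(
    sequence: str,
    name: str = "r1",
    quality: int = 35,
    qualities: list[int] | None = None,
    **kwargs,
) -> ReadRecord:
    return ReadRecord(
        name=name,
        sequence=sequence,
        base_qualities=qualities if qualities is not None else [quality] * len(sequence),
        **kwargs,
    )


@pytest.fixture
def band_map() -> BandMap:
    return BandMap.from_intervals(
        [
            ("chr1", 0, 100, "p1"),
            ("chr1", 100, 200, "q1"),
            ("chr1", 200, 300, "q2"),
            ("chr2", 0, 150, "p1"),
        ]
    )


@pytest.fixture
def band_file(tmp_path):
    path = tmp_path / "cytoBand.txt"
    lines = [
        "chr1\t0\t100\tp1\tgneg",
        "chr1\t100\t200\tq1\tgpos50",
        "chr1\t200\t300\tq2\tgneg",
        "chr2\t0\t150\tp1\tgneg",
    ]
    path.write_text("\n".join(lines) + "\n")
    return str(path)
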