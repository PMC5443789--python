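"""Read quality control: Q30 prefix truncation and a length floor.

Each read is truncated at the first base whose Phred score falls below the
threshold; that base and everything after it are removed. "Below" is
strict, so a base at exactly Q30 is retained. Reads left shorter than
``min_length`` are discarded before alignment and never enter any
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np


@dataclass
class Read:
    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.read_id}: bases and qualities differ in length")
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 93):
            raise ValueError(f"{self.read_id}: Phred values must lie in [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QCTally:
    kept: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.discarded


def truncate_at_first_low_quality(read: Read, threshold: int = 30) -> Read:
    """Longest prefix in which every quality is >= threshold."""
    q = np.asarray(read.quals)
    below = q < threshold
    cut = int(np.argmax(below)) if below.any() else len(q)
    return Read(read.read_id, read.bases[:cut], read.quals[:cut])


def filter_short(
    reads: Iterable[Read], min_length: int, tally: QCTally | None = None
) -> Iterator[Read]:
    """Yield reads with length >= min_length, tallying kept/discarded."""
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    if tally is None:
        tally = QCTally()
    for read in reads:
        if len(read) >= min_length:
            tally.kept += 1
            yield read
        else:
            tally.discarded += 1


def qc_reads(
    reads: Iterable[Read], threshold: int = 30, min_length: int = 50
) -> tuple[list[Read], QCTally]:
    """Truncate then length-filter; returns surviving reads and the tally."""
    tally = QCTally()
    kept = list(
        filter_short(
            (truncate_at_first_low_quality(r, threshold) for r in reads),
            min_length,
            tally,
        )
    )
    return kept, tally
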