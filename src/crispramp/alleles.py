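"""Variant haplotypes as ordered indel-event lists applied to a reference.

An ``AlleleSpec`` is the ground-truth representation of an edited allele:
a sorted, non-overlapping list of (position, deleted_length,
inserted_bases) events on the reference amplicon. Applying the events
yields the allele sequence; coordinate lifting maps reference positions
into allele coordinates through the events.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class IndelEvent:
    ref_position: int
    deleted_length: int
    inserted_bases: str = ""

    def __post_init__(self) -> None:
        if self.ref_position < 0:
            raise ValueError("event position must be non-negative")
        if self.deleted_length < 0:
            raise ValueError("deleted_length must be non-negative")
        if self.deleted_length == 0 and not self.inserted_bases:
            raise ValueError("event must delete or insert something")
        if set(self.inserted_bases) - set("ACGT"):
            raise ValueError("inserted bases must be A/C/G/T")

    @property
    def ref_end(self) -> int:
        return self.ref_position + self.deleted_length


@dataclass(frozen=True)
class AlleleSpec:
    events: tuple[IndelEvent, ...] = ()
    label: str = "WT"

    def __post_init__(self) -> None:
        ev = self.events
        if any(a.ref_end > b.ref_position for a, b in zip(ev, ev[1:])):
            raise ValueError(f"{self.label}: events overlap or are unsorted")

    def apply(self, reference: str) -> str:
        return apply_allele(reference, self)

    @property
    def net_length_change(self) -> int:
        return sum(len(e.inserted_bases) - e.deleted_length for e in self.events)

    def has_indel(self) -> bool:
        return bool(self.events)


def apply_allele(reference: str, allele: AlleleSpec) -> str:
    """Apply events left to right; output length obeys the conservation
    arithmetic len(ref) - sum(deleted) + sum(inserted)."""
    parts: list[str] = []
    pos = 0
    for ev in allele.events:
        if ev.ref_end > len(reference):
            raise ValueError(
                f"{allele.label}: event at {ev.ref_position} exceeds reference "
                f"of length {len(reference)}"
            )
        parts.append(reference[pos : ev.ref_position])
        parts.append(ev.inserted_bases)
        pos = ev.ref_end
    parts.append(reference[pos:])
    return "".join(parts)


def lift_coordinate(events: tuple[IndelEvent, ...], ref_coord: int) -> int:
    """Map a reference coordinate to the allele sequence. Positions inside a
    deleted interval collapse onto the event's start (in allele coordinates)."""
    shift = 0
    for ev in events:
        if ev.ref_end <= ref_coord:
            shift += len(ev.inserted_bases) - ev.deleted_length
        elif ev.ref_position <= ref_coord:
            return ev.ref_position + shift
    return ref_coord + shift


def lift_interval(events: tuple[IndelEvent, ...], interval: tuple[int, int]) -> tuple[int, int]:
    a = lift_coordinate(events, interval[0])
    b = lift_coordinate(events, interval[1])
    return (a, max(a, b))
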