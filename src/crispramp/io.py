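"""File formats: FASTQ/FASTA via Biopython, sheets via pandas.

All coordinates written to disk are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantify import GuideSite
from .readqc import Read
from .simulate import DecaySeries, SimulatedLocus


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


LOCUS_SHEET_COLUMNS = [
    "locus_id",
    "amplicon_id",
    "protospacer",
    "pam",
    "strand",
    "protospacer_start",
    "enzyme",
    "mode",
]


def write_locus_sheet(path: str | Path, loci: Iterable[SimulatedLocus]) -> None:
    rows = []
    for locus in loci:
        for g in locus.guides:
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "amplicon_id": locus.locus_id,
                    "protospacer": g.protospacer,
                    "pam": g.pam,
                    "strand": g.strand,
                    "protospacer_start": g.protospacer_start,
                    "enzyme": locus.enzyme.name,
                    "mode": locus.mode,
                }
            )
    pd.DataFrame(rows, columns=LOCUS_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_locus_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protospacer_start": int})
    missing = set(LOCUS_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: locus sheet lacks columns {sorted(missing)}")
    return df


def guides_from_sheet(df: pd.DataFrame) -> dict[str, list[GuideSite]]:
    """Group sheet rows into per-locus guide lists."""
    out: dict[str, list[GuideSite]] = {}
    for _, row in df.iterrows():
        g = GuideSite(
            locus_id=row["locus_id"],
            protospacer=row["protospacer"],
            pam=row["pam"],
            strand=row["strand"],
            protospacer_start=int(row["protospacer_start"]),
        )
        out.setdefault(row["locus_id"], []).append(g)
    return out


def write_series_tsv(path: str | Path, series: DecaySeries) -> None:
    pd.DataFrame(
        {"day": series.timepoints, "relative_copies": series.copy_numbers}
    ).to_csv(path, sep="\t", index=False)


def read_series_tsv(path: str | Path, generation_time_hours: float = 24.0) -> DecaySeries:
    df = pd.read_csv(path, sep="\t")
    for col in ("day", "relative_copies"):
        if col not in df.columns:
            raise ValueError(f"{path}: series table lacks column {col!r}")
    return DecaySeries(
        timepoints=tuple(float(x) for x in df["day"]),
        copy_numbers=tuple(float(x) for x in df["relative_copies"]),
        generation_time_hours=generation_time_hours,
    )
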