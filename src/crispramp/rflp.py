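"""In-silico restriction digest and RFLP genotyping.

Loss of a restriction site that straddles the Cas9 cut site is a cheap
proxy for editing: indels that disrupt the recognition motif leave the PCR
product uncut on a gel. The proxy systematically *underestimates* the true
indel rate, because an indel can sit inside the editing window yet leave
the recognition motif intact — the model makes that direction of bias a
theorem (see ``rflp_rate`` and the dominance tests).

Cut positions are top-strand only (blunt-cut approximation): overhang
geometry does not change fragment lengths at gel resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .align import reverse_complement
from .alleles import AlleleSpec, lift_coordinate

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC, written 5'->3' on the enzyme's top strand
    cut_offset: int  # top-strand cut position within the recognition site

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site must be >= 4 bp")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {sorted(bad)}")

    @property
    def is_palindromic(self) -> bool:
        return _iupac_revcomp(self.recognition) == self.recognition


# enzymes used on the targeted loci, plus EcoRI for examples
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("SacI", "GAGCTC", 5),
        RestrictionEnzyme("AgeI", "ACCGGT", 1),
        RestrictionEnzyme("XbaI", "TCTAGA", 1),
        RestrictionEnzyme("BstXI", "CCANNNNNNTGG", 8),
        RestrictionEnzyme("EcoRI", "GAATTC", 1),
    ]
}

_RC_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def _iupac_revcomp(motif: str) -> str:
    return "".join(_RC_BASE[b] for b in reversed(motif))


def _iupac_regex(motif: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[b]}]" for b in motif))


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """TSV with columns name, recognition, cut_offset (header optional)."""
    table: dict[str, RestrictionEnzyme] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        name, recognition, offset = line.split("\t")[:3]
        table[name] = RestrictionEnzyme(name, recognition.upper(), int(offset))
    return table


def get_enzyme(name: str, extra: dict[str, RestrictionEnzyme] | None = None) -> RestrictionEnzyme:
    table = dict(BUILTIN_ENZYMES)
    if extra:
        table.update(extra)
    if name not in table:
        raise KeyError(f"unknown restriction enzyme {name!r}; known: {sorted(table)}")
    return table[name]


@dataclass
class DigestResult:
    fragment_lengths: list[int]  # multiset, in genomic order
    cut_positions: list[int]


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut coordinates for sites on either strand.

    A site on the reverse strand at top-strand interval [s, s+k) places the
    enzyme's top-strand cut at s + (k - cut_offset). Palindromic matches
    (identical interval on both strands) are reported once, at the forward
    cut position.
    """
    k = len(enzyme.recognition)
    fwd_pat = _iupac_regex(enzyme.recognition)
    rev_pat = _iupac_regex(_iupac_revcomp(enzyme.recognition))
    fwd_starts = {m.start() for m in _overlapping(fwd_pat, sequence)}
    cuts = {s + enzyme.cut_offset for s in fwd_starts}
    for m in _overlapping(rev_pat, sequence):
        s = m.start()
        if s in fwd_starts:
            continue  # palindromic site already counted
        cuts.add(s + k - enzyme.cut_offset)
    return sorted(cuts)


def _overlapping(pattern: re.Pattern, sequence: str):
    pos = 0
    while True:
        m = pattern.search(sequence, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def digest(sequence: str, enzyme: RestrictionEnzyme) -> DigestResult:
    cuts = [c for c in find_sites(sequence, enzyme) if 0 < c < len(sequence)]
    bounds = [0] + cuts + [len(sequence)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return DigestResult(fragment_lengths=fragments, cut_positions=cuts)


def allele_destroys_site(
    reference: str,
    allele: AlleleSpec,
    enzyme: RestrictionEnzyme,
    site_cut_position: int,
) -> bool:
    """True iff the allele sequence has no cut near the (lifted) original
    site — i.e. the indel disrupted the recognition motif."""
    if site_cut_position not in find_sites(reference, enzyme):
        raise ValueError(
            f"no {enzyme.name} cut at reference position {site_cut_position}"
        )
    mutated = allele.apply(reference)
    lifted = lift_coordinate(allele.events, site_cut_position)
    tol = len(enzyme.recognition)
    return not any(abs(c - lifted) <= tol for c in find_sites(mutated, enzyme))


def rflp_rate(
    alleles_with_fractions: list[tuple[AlleleSpec, float]],
    reference: str,
    enzyme: RestrictionEnzyme,
    site_cut_position: int,
) -> float:
    """Uncut-band molecule fraction: summed fractions of alleles whose indel
    destroys the site."""
    total = sum(f for _, f in alleles_with_fractions)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"allele fractions sum to {total}, expected 1")
    return sum(
        f
        for allele, f in alleles_with_fractions
        if allele_destroys_site(reference, allele, enzyme, site_cut_position)
    )


@dataclass
class ClonePattern:
    """Observed band classes of a digested clone PCR product."""

    uncut_present: bool
    cut_present: bool


def pattern_from_fragments(
    fragment_sets: list[list[int]], full_length: int, comigration_tol: int = 5
) -> ClonePattern:
    """Summarize per-allele digest fragments into a gel band pattern.

    A band within ``comigration_tol`` bp of the undigested product length is
    scored as the uncut band (gels cannot resolve small indels); anything
    else is a cut fragment.
    """
    uncut = cut = False
    for frags in fragment_sets:
        for f in frags:
            if abs(f - full_length) <= comigration_tol:
                uncut = True
            else:
                cut = True
    if not (uncut or cut):
        raise ValueError("empty band pattern")
    return ClonePattern(uncut_present=uncut, cut_present=cut)


def genotype_clone(pattern: ClonePattern) -> str:
    """Cut-only -> WT; uncut-only -> biallelic_edited; both -> heterozygous."""
    if not (pattern.uncut_present or pattern.cut_present):
        raise ValueError("empty band pattern")
    if pattern.uncut_present and pattern.cut_present:
        return "heterozygous"
    if pattern.uncut_present:
        return "biallelic_edited"
    return "WT"
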