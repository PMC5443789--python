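"""Paired-gRNA genomic-deletion genotyping.

Two Cas9 cuts excise the intervening fragment; repair joins the cut ends.
Clones are genotyped by two PCR assays: an *internal* primer pair binding
inside the deleted interval (amplifies only non-deleted alleles) and a
*junction* pair flanking it, whose product on the intact template is too
long to amplify and only appears once the deletion shortens it. The band
pattern across both assays separates WT, monoallelic and biallelic clones.

Primer binding is exact full-length matching: the assay is presence/
absence, and exact matching keeps the contract testable. ``max_product``
models PCR dropout of long templates — the property that makes junction
primers deletion-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .align import reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str  # written 5'->3' on the bottom strand, as ordered from a vendor
    label: Literal["internal", "junction"]

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError("primers must be at least 15 nt")


@dataclass(frozen=True)
class DeletionDesign:
    template: str
    deletion_interval: tuple[int, int]  # [cut_left, cut_right)
    internal_pair: PrimerPair
    junction_pair: PrimerPair

    def __post_init__(self) -> None:
        a, b = self.deletion_interval
        if not 0 <= a < b <= len(self.template):
            raise ValueError(f"invalid deletion interval [{a},{b})")


def apply_deletion(template: str, interval: tuple[int, int]) -> str:
    """Join the two cut coordinates: remove template[a:b]."""
    a, b = interval
    if not 0 <= a <= b <= len(template):
        raise ValueError(f"deletion interval [{a},{b}) outside template")
    return template[:a] + template[b:]


def predict_pcr(
    template: str, pair: PrimerPair, max_product: int = 3000
) -> int | None:
    """Product length for exact primer binding, or None.

    The forward primer must match the top strand 5' of the reverse primer's
    binding site (whose top-strand sequence is the reverse complement of
    the reverse primer). None when either site is absent, the orientation
    is wrong, or the product exceeds ``max_product`` (PCR dropout).
    """
    fwd_sites = _find_all(template, pair.forward)
    rev_sites = _find_all(template, reverse_complement(pair.reverse))
    if len(fwd_sites) > 1 or len(rev_sites) > 1:
        raise ValueError(
            f"{pair.label} pair is ambiguous: multiple binding sites on the template"
        )
    if not fwd_sites or not rev_sites:
        return None
    f = fwd_sites[0]
    r_end = rev_sites[0] + len(pair.reverse)
    if f >= rev_sites[0]:
        return None
    product = r_end - f
    return product if product <= max_product else None


def _find_all(template: str, primer: str) -> list[int]:
    out = []
    pos = template.find(primer)
    while pos >= 0:
        out.append(pos)
        pos = template.find(primer, pos + 1)
    return out


@dataclass(frozen=True)
class CloneCall:
    junction_band: bool
    internal_band: bool
    call: Literal["WT", "monoallelic", "biallelic", "assay_failure"]


def classify_clone(junction_band: bool, internal_band: bool) -> CloneCall:
    """Truth table of the two-assay genotype.

    junction + / internal -  -> biallelic (both alleles deleted)
    junction + / internal +  -> monoallelic
    junction - / internal +  -> WT
    junction - / internal -  -> assay_failure
    """
    if junction_band:
        call = "biallelic" if not internal_band else "monoallelic"
    else:
        call = "WT" if internal_band else "assay_failure"
    return CloneCall(junction_band=junction_band, internal_band=internal_band, call=call)


def genotype_clone_templates(
    alleles: list[str], design: DeletionDesign, max_product: int = 3000
) -> CloneCall:
    """Run both assays on a clone's allele templates; a band is present if
    either allele yields a product."""
    junction = any(
        predict_pcr(a, design.junction_pair, max_product) is not None for a in alleles
    )
    internal = any(
        predict_pcr(a, design.internal_pair, max_product) is not None for a in alleles
    )
    return classify_clone(junction, internal)
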