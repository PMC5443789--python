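"""Editing-rate quantification from aligned amplicon reads.

The statistic is the fraction of window-covering reads that carry an indel
inside a window centered on the predicted Cas9 cleavage site (blunt cut
3 nt 5' of the PAM): the editing window spans +/- ``halfwidth`` (15 bp by
default, a 30-bp window). A 30-bp control window displaced 50 bp from the
cut provides the background sequence-variation rate; site-vs-background
significance uses a two-tailed paired Student's t-test across loci.

Substitutions never count as editing; only insertion/deletion variants
(left-normalized) are tested for window intersection. Reads whose
reference span does not fully contain a window are uninformative for that
window and are excluded from its denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .align import (
    AlignmentResult,
    ScoringScheme,
    Variant,
    align_many,
    extract_variants,
    left_normalize,
    reverse_complement,
)
from .readqc import Read, qc_reads


@dataclass(frozen=True)
class GuideSite:
    """A protospacer/PAM placement on an amplicon.

    ``protospacer_start`` is the 0-based start of the 20-mer occupied by the
    protospacer *on the top strand*. On the minus strand, the PAM sits
    immediately 5' of that interval on the top strand (its reverse
    complement reads NGG on the guide strand).
    """

    locus_id: str
    protospacer: str
    pam: str
    strand: Literal["+", "-"]
    protospacer_start: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(f"{self.locus_id}: protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"{self.locus_id}: PAM {self.pam!r} is not NGG")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -")

    @property
    def cut(self) -> int:
        return predicted_cut_site(self)

    def check_against(self, amplicon: str) -> None:
        """Verify the recorded coordinates against the amplicon sequence."""
        s = self.protospacer_start
        seg = amplicon[s : s + 20]
        if self.strand == "+":
            if seg != self.protospacer or amplicon[s + 20 : s + 23] != self.pam:
                raise ValueError(f"{self.locus_id}: protospacer/PAM mismatch on + strand")
        else:
            if seg != reverse_complement(self.protospacer):
                raise ValueError(f"{self.locus_id}: protospacer mismatch on - strand")
            if amplicon[s - 3 : s] != reverse_complement(self.pam):
                raise ValueError(f"{self.locus_id}: PAM mismatch on - strand")


def predicted_cut_site(guide: GuideSite) -> int:
    """Blunt SpCas9 cut between protospacer positions 17 and 18 (3 nt 5' of
    the PAM), as an inter-base top-strand coordinate."""
    if guide.pam[1:] != "GG":
        raise ValueError(f"{guide.locus_id}: PAM {guide.pam!r} is not NGG")
    if guide.strand == "+":
        return guide.protospacer_start + 17
    return guide.protospacer_start + 3


@dataclass(frozen=True)
class WindowSpec:
    start: int
    end: int
    role: Literal["editing", "control"]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def editing_window(cut: int, halfwidth: int = 15, amplicon_length: int | None = None) -> WindowSpec:
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    w = WindowSpec(cut - halfwidth, cut + halfwidth, "editing")
    _check_fits(w, amplicon_length)
    return w


def nickase_window(
    cut_a: int, cut_b: int, halfwidth: int = 15, amplicon_length: int | None = None
) -> WindowSpec:
    """Window spanning both nick sites, widened by halfwidth on each side."""
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    lo, hi = min(cut_a, cut_b), max(cut_a, cut_b)
    w = WindowSpec(lo - halfwidth, hi + halfwidth, "editing")
    _check_fits(w, amplicon_length)
    return w


def control_window(
    cut: int, amplicon_length: int, size: int = 30, gap: int = 50
) -> WindowSpec:
    """A size-bp window gap bp downstream of the cut; falls back to the
    upstream side when the amplicon is too short on the right."""
    right = WindowSpec(cut + gap, cut + gap + size, "control")
    if right.end <= amplicon_length and right.start >= 0:
        return right
    left = WindowSpec(cut - gap - size, cut - gap, "control")
    if left.start >= 0 and left.end <= amplicon_length:
        return left
    raise ValueError(
        f"no room for a {size}-bp control window {gap} bp from cut {cut} "
        f"in a {amplicon_length}-bp amplicon"
    )


def _check_fits(w: WindowSpec, amplicon_length: int | None) -> None:
    if w.start < 0 or (amplicon_length is not None and w.end > amplicon_length):
        raise ValueError(
            f"window [{w.start},{w.end}) exceeds the amplicon; use a longer amplicon"
        )


def classify_read(
    variants: Sequence[Variant], aln: AlignmentResult, window: WindowSpec
) -> str:
    """'uninformative' | 'edited' | 'unedited' for one window.

    A read is informative only if its reference span fully contains the
    window. It is edited if any variant's reference footprint (deletion
    interval, or insertion anchor point) intersects the window.
    """
    if not (aln.ref_start <= window.start and aln.ref_end >= window.end):
        return "uninformative"
    for v in variants:
        a, b = v.ref_interval
        if v.kind == "insertion":
            if window.start < a < window.end:
                return "edited"
        elif a < window.end and b > window.start:
            return "edited"
    return "unedited"


@dataclass
class EditingReport:
    locus_id: str
    n_input: int
    n_qc_pass: int
    n_aligned: int
    n_window_covering: int
    n_indel: int
    rate: float
    control_n_covering: int
    control_n_indel: int
    control_rate: float

    def __post_init__(self) -> None:
        assert self.n_indel <= self.n_window_covering <= self.n_aligned
        assert 0.0 <= self.rate <= 1.0


def editing_rate(
    locus_id: str,
    classified: Sequence[tuple[str, str]],
    *,
    n_input: int | None = None,
    n_qc_pass: int | None = None,
) -> EditingReport:
    """Build a report from per-read (editing_class, control_class) pairs of
    aligned reads."""
    n_aligned = len(classified)
    n_cov = sum(1 for e, _ in classified if e != "uninformative")
    n_ind = sum(1 for e, _ in classified if e == "edited")
    c_cov = sum(1 for _, c in classified if c != "uninformative")
    c_ind = sum(1 for _, c in classified if c == "edited")
    if n_cov == 0:
        raise ValueError(f"{locus_id}: no reads cover the editing window")
    return EditingReport(
        locus_id=locus_id,
        n_input=n_input if n_input is not None else n_aligned,
        n_qc_pass=n_qc_pass if n_qc_pass is not None else n_aligned,
        n_aligned=n_aligned,
        n_window_covering=n_cov,
        n_indel=n_ind,
        rate=n_ind / n_cov,
        control_n_covering=c_cov,
        control_n_indel=c_ind,
        control_rate=c_ind / c_cov if c_cov else float("nan"),
    )


def quantify_locus(
    reads: Sequence[Read],
    amplicon: str,
    edit_window: WindowSpec,
    ctrl_window: WindowSpec | None,
    *,
    locus_id: str = "locus",
    scheme: ScoringScheme | None = None,
    quality_threshold: int = 30,
    min_length: int = 50,
    min_score_fraction: float = 0.6,
) -> EditingReport:
    """QC -> align -> extract+normalize variants -> classify -> report."""
    n_input = len(reads)
    passed, _ = qc_reads(reads, quality_threshold, min_length)
    alns = align_many(
        [r.bases for r in passed],
        amplicon,
        scheme,
        read_ids=[r.read_id for r in passed],
        min_score_fraction=min_score_fraction,
    )
    classified: list[tuple[str, str]] = []
    for aln in alns:
        if not aln.aligned:
            continue
        variants = [left_normalize(v, amplicon) for v in extract_variants(aln)]
        e = classify_read(variants, aln, edit_window)
        c = classify_read(variants, aln, ctrl_window) if ctrl_window else "uninformative"
        classified.append((e, c))
    return editing_rate(
        locus_id, classified, n_input=n_input, n_qc_pass=len(passed)
    )


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    n_pairs: int


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> TTestResult:
    """Two-tailed paired Student's t-test on (site_rate, background_rate)
    pairs; t = mean(d) / (sd(d)/sqrt(n)) with sample sd (n-1 denominator)."""
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    a = np.array([x for x, _ in pairs], dtype=float)
    b = np.array([y for _, y in pairs], dtype=float)
    d = a - b
    if np.all(d == 0):
        raise ValueError("degenerate input: all paired differences are zero")
    res = stats.ttest_rel(a, b)
    return TTestResult(
        t=float(res.statistic),
        df=len(pairs) - 1,
        p_two_sided=float(res.pvalue),
        n_pairs=len(pairs),
    )
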