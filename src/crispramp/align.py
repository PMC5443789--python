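"""Semi-global pairwise alignment with affine gap penalties, plus indel
extraction and left-normalization.

Reads are aligned end-to-end ("global in the read") against a single
amplicon reference with free end gaps on the reference ("local in the
reference"), the natural geometry for amplicon deep sequencing where every
read is a fragment of one known PCR product. Gap costs are affine
(open + extend), so a 30-bp nickase deletion survives as one event instead
of fragmenting into many.

The dynamic program is the Gotoh three-state recurrence. Rows are computed
vectorized over the reference axis; the horizontal (reference-consuming,
i.e. deletion) state is obtained exactly from the unrolled identity

    D[i][j] = max_{k<j} ( H[i][k] + open + extend*(j-k) )
            = extend*j + cummax_{k<j} ( H'[i][k] + open - extend*k )

where H' excludes the D state itself (re-opening a gap inside a gap is
never optimal when open < 0), which turns the in-row dependency into a
prefix-maximum scan. Batches of same-length reads are aligned
simultaneously.

Deterministic tie-breaking during traceback: diagonal (match/mismatch)
over deletion over insertion; within a gap state, closing the gap over
extending it. After extraction, ``left_normalize`` shifts each indel to its
smallest equivalent reference coordinate so window membership is
well-defined inside repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

NEG = -1.0e18

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; gap penalties must be negative, match > mismatch."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


#: kind is one of "match", "mismatch", "insertion", "deletion"
Op = tuple[str, int, str]


@dataclass
class AlignmentResult:
    read_id: str
    ref_start: int
    ref_end: int
    ops: list[Op]
    score: float
    aligned: bool
    strand: Literal["+", "-"] = "+"
    #: read sequence in reference orientation (reverse-complemented if strand == "-")
    query: str = ""

    def cigar(self) -> str:
        sym = {"match": "M", "mismatch": "M", "insertion": "I", "deletion": "D"}
        out = []
        for kind, length, _ in self.ops:
            if out and out[-1][1] == sym[kind]:
                out[-1][0] += length
            else:
                out.append([length, sym[kind]])
        return "".join(f"{n}{s}" for n, s in out)


@dataclass(frozen=True)
class Variant:
    ref_position: int
    kind: Literal["insertion", "deletion"]
    length: int
    inserted_bases: str = ""

    def __post_init__(self) -> None:
        if self.kind == "deletion" and self.length < 1:
            raise ValueError("deletion must remove at least one reference base")
        if self.kind == "insertion" and len(self.inserted_bases) != self.length:
            raise ValueError("insertion length must match inserted bases")

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Reference footprint: [pos, pos+len) for deletions, [pos, pos) anchor
        for insertions."""
        if self.kind == "deletion":
            return (self.ref_position, self.ref_position + self.length)
        return (self.ref_position, self.ref_position)


def _dp_matrices(reads: np.ndarray, ref: np.ndarray, scheme: ScoringScheme):
    """Gotoh DP for a (B, m) batch of encoded reads vs an (n,) encoded ref.

    Returns (H, D, I) of shape (B, m+1, n+1).
    """
    B, m = reads.shape
    n = ref.shape[0]
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.empty((B, m + 1, n + 1))
    D = np.full((B, m + 1, n + 1), NEG)
    I = np.full((B, m + 1, n + 1), NEG)
    H[:, 0, :] = 0.0
    jidx = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        I[:, i, :] = np.maximum(I[:, i - 1, :] + ge, H[:, i - 1, :] + go + ge)
        sub = np.where(reads[:, i - 1, None] == ref[None, :], scheme.match, scheme.mismatch)
        sub[:, ref == 4] = scheme.mismatch  # N never matches
        sub[reads[:, i - 1] == 4, :] = scheme.mismatch
        hne = np.empty((B, n + 1))
        hne[:, 0] = I[:, i, 0]
        hne[:, 1:] = np.maximum(H[:, i - 1, :-1] + sub, I[:, i, 1:])
        # deletion state via prefix-max scan over the gap-free row
        scan = np.maximum.accumulate(hne + go - ge * jidx, axis=1)
        D[:, i, 1:] = scan[:, :-1] + ge * jidx[1:]
        H[:, i, :] = np.maximum(hne, D[:, i, :])
    return H, D, I


def _traceback(
    b: int,
    read: str,
    ref: str,
    H: np.ndarray,
    D: np.ndarray,
    I: np.ndarray,
    scheme: ScoringScheme,
) -> tuple[int, int, list[Op], float]:
    m, n = len(read), len(ref)
    row = H[b, m]
    j = int(np.argmax(row))
    score = float(row[j])
    ops: list[Op] = []
    i = m
    state = "H"
    go, ge = scheme.gap_open, scheme.gap_extend
    ref_end = j
    while i > 0:
        if state == "H":
            # tie-break order: diagonal > deletion > insertion
            if j > 0:
                s = scheme.match if (read[i - 1] == ref[j - 1] and read[i - 1] in "ACGT") else scheme.mismatch
                if H[b, i, j] == H[b, i - 1, j - 1] + s:
                    ops.append(("match" if s == scheme.match else "mismatch", 1, ""))
                    i -= 1
                    j -= 1
                    continue
                if H[b, i, j] == D[b, i, j]:
                    state = "D"
                    continue
            state = "I"
        elif state == "D":
            # consumes a reference base; on ties, close the gap (shortest gap)
            ops.append(("deletion", 1, ""))
            if D[b, i, j] == H[b, i, j - 1] + go + ge:
                state = "H"
            j -= 1
        else:
            # insertion: consumes a read base
            ops.append(("insertion", 1, read[i - 1]))
            if I[b, i, j] == H[b, i - 1, j] + go + ge:
                state = "H"
            i -= 1
    ops.reverse()
    # merge runs, concatenating inserted bases
    merged: list[Op] = []
    for kind, length, ins in ops:
        if merged and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1] + length, merged[-1][2] + ins)
        else:
            merged.append((kind, length, ins))
    return j, ref_end, merged, score


def _all_match_result(read_id: str, read: str, start: int, scheme: ScoringScheme, strand: str) -> AlignmentResult:
    return AlignmentResult(
        read_id=read_id,
        ref_start=start,
        ref_end=start + len(read),
        ops=[("match", len(read), "")],
        score=len(read) * scheme.match,
        aligned=True,
        strand=strand,
        query=read,
    )


def semiglobal_align(
    read: str,
    amplicon: str,
    scheme: ScoringScheme | None = None,
    *,
    read_id: str = "read",
    min_score_fraction: float = 0.6,
    try_reverse_complement: bool = True,
) -> AlignmentResult:
    """Align one read against one amplicon; the reverse complement is also
    tried and the better-scoring orientation wins (forward on ties)."""
    results = align_many(
        [read],
        amplicon,
        scheme,
        read_ids=[read_id],
        min_score_fraction=min_score_fraction,
        try_reverse_complement=try_reverse_complement,
    )
    return results[0]


def align_many(
    reads: Sequence[str],
    amplicon: str,
    scheme: ScoringScheme | None = None,
    *,
    read_ids: Sequence[str] | None = None,
    min_score_fraction: float = 0.6,
    try_reverse_complement: bool = True,
    batch_size: int = 64,
) -> list[AlignmentResult]:
    """Align many reads against one amplicon.

    Identical read sequences are aligned once; exact substrings of the
    amplicon (either orientation) bypass the DP entirely, which is the
    common case for high-accuracy amplicon data.
    """
    scheme = scheme or ScoringScheme()
    if not amplicon:
        raise ValueError("empty amplicon")
    if read_ids is None:
        read_ids = [f"read{k}" for k in range(len(reads))]
    # resolve unique sequences
    cache: dict[str, AlignmentResult] = {}
    pending: list[str] = []
    for seq in reads:
        if not seq:
            raise ValueError("empty read")
        if seq in cache or seq in pending:
            continue
        pos = amplicon.find(seq)
        if pos >= 0:
            cache[seq] = _all_match_result("", seq, pos, scheme, "+")
            continue
        if try_reverse_complement:
            rc = reverse_complement(seq)
            pos = amplicon.find(rc)
            if pos >= 0:
                cache[seq] = _all_match_result("", rc, pos, scheme, "-")
                continue
        pending.append(seq)

    ref_enc = _encode(amplicon)
    by_len: dict[int, list[str]] = {}
    for seq in pending:
        by_len.setdefault(len(seq), []).append(seq)
    for length, group in by_len.items():
        for k0 in range(0, len(group), batch_size):
            chunk = group[k0 : k0 + batch_size]
            fwd = [s for s in chunk]
            rcs = [reverse_complement(s) for s in chunk]
            seqs = fwd + rcs if try_reverse_complement else fwd
            enc = np.stack([_encode(s) for s in seqs])
            H, D, I = _dp_matrices(enc, ref_enc, scheme)
            final = H[:, length, :]
            best = final.max(axis=1)
            for idx, seq in enumerate(chunk):
                if try_reverse_complement and best[idx + len(chunk)] > best[idx]:
                    b, q, strand = idx + len(chunk), rcs[idx], "-"
                else:
                    b, q, strand = idx, fwd[idx], "+"
                rs, re_, ops, score = _traceback(b, q, amplicon, H, D, I, scheme)
                cache[seq] = AlignmentResult(
                    read_id="",
                    ref_start=rs,
                    ref_end=re_,
                    ops=ops,
                    score=score,
                    aligned=True,
                    strand=strand,
                    query=q,
                )
    out: list[AlignmentResult] = []
    for rid, seq in zip(read_ids, reads):
        base = cache[seq]
        aligned = base.score >= min_score_fraction * len(seq) * scheme.match
        out.append(replace(base, read_id=rid, aligned=aligned))
    return out


def semiglobal_scores(
    reads: Sequence[str],
    amplicon: str,
    scheme: ScoringScheme | None = None,
    *,
    batch_size: int = 512,
) -> np.ndarray:
    """Optimal semi-global scores only (no traceback, forward strand only)."""
    scheme = scheme or ScoringScheme()
    ref_enc = _encode(amplicon)
    scores = np.empty(len(reads))
    order: dict[int, list[int]] = {}
    for k, s in enumerate(reads):
        if not s:
            raise ValueError("empty read")
        order.setdefault(len(s), []).append(k)
    for length, idxs in order.items():
        for k0 in range(0, len(idxs), batch_size):
            chunk = idxs[k0 : k0 + batch_size]
            enc = np.stack([_encode(reads[k]) for k in chunk])
            H, _, _ = _dp_matrices(enc, ref_enc, scheme)
            scores[chunk] = H[:, length, :].max(axis=1)
    return scores


def oracle_score(read: str, ref: str, scheme: ScoringScheme | None = None) -> float:
    """Reference scalar implementation of the same semi-global affine-gap
    problem, written as a plain per-cell recurrence over Python lists.

    Deliberately shares no code with the vectorized path; used to validate
    it (and validated in turn, in the test suite, against exhaustive
    alignment enumeration on tiny inputs).
    """
    scheme = scheme or ScoringScheme()
    if not read or not ref:
        raise ValueError("empty input")
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(read), len(ref)
    Hprev = [0.0] * (n + 1)
    Iprev = [NEG] * (n + 1)
    for i in range(1, m + 1):
        Hcur = [0.0] * (n + 1)
        Icur = [0.0] * (n + 1)
        Dcur = NEG
        Icur[0] = max(Iprev[0] + ge, Hprev[0] + go + ge)
        Hcur[0] = Icur[0]
        for j in range(1, n + 1):
            Icur[j] = max(Iprev[j] + ge, Hprev[j] + go + ge)
            s = scheme.match if read[i - 1] == ref[j - 1] else scheme.mismatch
            Dcur = max(Dcur + ge, Hcur[j - 1] + go + ge)
            Hcur[j] = max(Hprev[j - 1] + s, Icur[j], Dcur)
        Hprev, Iprev = Hcur, Icur
    return max(Hprev)


def extract_variants(aln: AlignmentResult) -> list[Variant]:
    """One Variant per indel op, in amplicon coordinates. Mismatches are not
    variants: substitutions never count as editing."""
    if not aln.aligned:
        raise ValueError("cannot extract variants from an unaligned read")
    out: list[Variant] = []
    pos = aln.ref_start
    for kind, length, ins in aln.ops:
        if kind in ("match", "mismatch"):
            pos += length
        elif kind == "deletion":
            out.append(Variant(ref_position=pos, kind="deletion", length=length))
            pos += length
        else:
            out.append(Variant(ref_position=pos, kind="insertion", length=length, inserted_bases=ins))
    return out


def left_normalize(v: Variant, amplicon: str) -> Variant:
    """Shift an indel to the smallest reference position yielding an identical
    alternate sequence (idempotent)."""
    if v.kind == "deletion":
        p = v.ref_position
        while p > 0 and amplicon[p - 1] == amplicon[p + v.length - 1]:
            p -= 1
        return Variant(ref_position=p, kind="deletion", length=v.length)
    p = v.ref_position
    ins = v.inserted_bases
    while p > 0 and ins and amplicon[p - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        p -= 1
    return Variant(ref_position=p, kind="insertion", length=v.length, inserted_bases=ins)


def write_sam(
    path: str,
    alignments: Iterable[AlignmentResult],
    amplicon_name: str,
    amplicon_length: int,
) -> None:
    """Export alignments as SAM for inspection in standard viewers."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": amplicon_name, "LN": amplicon_length}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            a.query_sequence = aln.query or None
            a.flag = 16 if aln.strand == "-" else 0
            if not aln.aligned:
                a.flag |= 4
            a.reference_id = 0
            a.reference_start = aln.ref_start
            a.mapping_quality = 60 if aln.aligned else 0
            a.cigarstring = aln.cigar() if aln.aligned else None
            fh.write(a)
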