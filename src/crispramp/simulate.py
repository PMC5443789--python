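"""Synthetic amplicons, edited alleles, reads, and qPCR decay series.

Everything downstream (QC, alignment, windows, RFLP, genotyping, decay
fitting) is exercised on data from this module, so its defaults encode the
study conditions the analysis assumes:

* 150-bp single reads from an amplicon carrying the protospacer, an NGG
  PAM and a restriction site that straddles the predicted cut site (so the
  RFLP assay is applicable by construction);
* NHEJ alleles with one indel at the cut: deletion sizes from a truncated
  geometric (mean 6 bp, max 30 bp), insertions 1-10 bp; paired-nickase
  alleles with one deletion spanning the nick-to-nick interval, sizes on
  [6, 78] bp with mean 30 bp;
* per-position mean Phred decaying linearly along the read (38 -> 28 by
  default, per-base SD 3, clamped to [2, 40]) so the Q30 truncation rule
  is exercised; uniform substitution sequencing error, no indel errors;
* episomal copy number decaying a few percent per cell generation with
  multiplicative lognormal qPCR noise.

Each read records its true allele label in the read id — a ground-truth
channel for tests, never consulted by the analysis itself.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .alleles import AlleleSpec, IndelEvent, lift_interval
from .align import reverse_complement
from .quantify import GuideSite, WindowSpec, control_window, editing_window, nickase_window
from .readqc import Read
from .rflp import IUPAC, RestrictionEnzyme, find_sites, get_enzyme

BASES = "ACGT"


# ---------------------------------------------------------------------------
# indel-size distributions


@dataclass(frozen=True)
class TruncatedGeometric:
    """Geometric-shaped distribution on the integers [lo, hi], with the decay
    parameter solved so the truncated mean equals ``mean`` exactly."""

    lo: int
    hi: int
    mean: float

    def __post_init__(self) -> None:
        if not self.lo < self.mean < (self.lo + self.hi) / 2:
            raise ValueError(
                f"mean {self.mean} unreachable on [{self.lo},{self.hi}] "
                f"(must lie in ({self.lo}, {(self.lo + self.hi) / 2}))"
            )

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    @property
    def pmf(self) -> np.ndarray:
        return _trunc_geom_pmf(self.lo, self.hi, self.mean)

    @property
    def sd(self) -> float:
        k = self.support
        return float(np.sqrt(np.sum(self.pmf * (k - self.mean) ** 2)))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        out = rng.choice(self.support, size=size, p=self.pmf)
        return out if size is not None else int(out)


@lru_cache(maxsize=None)
def _trunc_geom_pmf(lo: int, hi: int, mean: float) -> np.ndarray:
    k = np.arange(lo, hi + 1, dtype=float)

    def mean_at(q: float) -> float:
        w = (1.0 - q) ** (k - lo)
        return float(np.sum(k * w) / np.sum(w))

    q = brentq(lambda q: mean_at(q) - mean, 1e-12, 1 - 1e-12)
    w = (1.0 - q) ** (k - lo)
    pmf = w / w.sum()
    pmf.setflags(write=False)
    return pmf


DEFAULT_NHEJ_DELETION = TruncatedGeometric(lo=1, hi=30, mean=6.0)
DEFAULT_NICKASE_DELETION = TruncatedGeometric(lo=6, hi=78, mean=30.0)


# ---------------------------------------------------------------------------
# loci


@dataclass(frozen=True)
class SimulatedLocus:
    locus_id: str
    amplicon: str
    guides: tuple[GuideSite, ...]  # one for cas9 mode, two for nickase
    enzyme: RestrictionEnzyme
    enzyme_cut: int
    mode: Literal["cas9", "nickase"]
    seed: int
    read_length: int = 150
    control_gap: int = 50
    control_size: int = 30

    @property
    def guide(self) -> GuideSite:
        if self.mode != "cas9":
            raise ValueError(f"{self.locus_id}: single guide undefined in nickase mode")
        return self.guides[0]

    @property
    def cut_sites(self) -> tuple[int, ...]:
        return tuple(g.cut for g in self.guides)

    @property
    def cut_midpoint(self) -> int:
        cuts = self.cut_sites
        return (min(cuts) + max(cuts)) // 2

    def editing_window(self, halfwidth: int = 15) -> WindowSpec:
        if self.mode == "cas9":
            return editing_window(self.guide.cut, halfwidth, len(self.amplicon))
        a, b = self.cut_sites
        return nickase_window(a, b, halfwidth, len(self.amplicon))

    def control_window(self) -> WindowSpec:
        # for paired nicks the midpoint plays the role of the cleavage site
        return control_window(
            self.cut_midpoint, len(self.amplicon), self.control_size, self.control_gap
        )

    def region_of_interest(self, halfwidth: int = 15) -> tuple[int, int]:
        """Union span of editing and control windows, the region a simulated
        read should cover to be informative for both."""
        w = self.editing_window(halfwidth)
        c = self.control_window()
        return (min(w.start, c.start), max(w.end, c.end))


def generate_locus(
    seed: int,
    length: int = 300,
    enzyme_name: str = "EcoRI",
    mode: Literal["cas9", "nickase"] = "cas9",
    *,
    read_length: int = 150,
    locus_id: str | None = None,
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> SimulatedLocus:
    """Deterministically build an amplicon with protospacer(s), PAM(s) and a
    single restriction site intersecting the editing window.

    The cut site lands early enough in the amplicon that a ``read_length``
    read anchored near position 0 spans both the editing and the control
    window. In nickase mode two guides on opposite strands are placed
    PAM-out with a nick-to-nick offset of 10-60 bp.
    """
    enzyme = get_enzyme(enzyme_name, enzymes)
    if length < 2 * read_length:
        raise ValueError(
            f"amplicon length {length} too small; need >= {2 * read_length}"
        )
    if mode not in ("cas9", "nickase"):
        raise ValueError(f"unknown mode {mode!r}")
    built = None
    for attempt in range(50):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        built = _try_build_locus(rng, length, enzyme, mode, read_length)
        if built is not None:
            break
    if built is None:
        raise RuntimeError(f"could not build a clean locus for seed {seed}")
    amp, rec_start, strand, nick_positions = built
    cut = read_length - 85
    k = len(enzyme.recognition)
    enzyme_cuts = find_sites(amp, enzyme)
    assert len(enzyme_cuts) == 1 and enzyme_cuts[0] == rec_start + enzyme.cut_offset

    lid = locus_id or f"locus{seed}_{mode}"
    if mode == "cas9":
        if strand == "+":
            g = GuideSite(lid, amp[cut - 17 : cut + 3], amp[cut + 3 : cut + 6], "+", cut - 17)
        else:
            g = GuideSite(
                lid,
                reverse_complement(amp[cut - 3 : cut + 17]),
                reverse_complement(amp[cut - 6 : cut - 3]),
                "-",
                cut - 3,
            )
        guides = (g,)
    else:
        nick_a, nick_b = nick_positions
        ga = GuideSite(
            lid,
            reverse_complement(amp[nick_a - 3 : nick_a + 17]),
            reverse_complement(amp[nick_a - 6 : nick_a - 3]),
            "-",
            nick_a - 3,
        )
        gb = GuideSite(lid, amp[nick_b - 17 : nick_b + 3], amp[nick_b + 3 : nick_b + 6], "+", nick_b - 17)
        guides = (ga, gb)
    for g in guides:
        g.check_against(amp)

    locus = SimulatedLocus(
        locus_id=lid,
        amplicon=amp,
        guides=guides,
        enzyme=enzyme,
        enzyme_cut=enzyme_cuts[0],
        mode=mode,
        seed=seed,
        read_length=read_length,
    )
    w = locus.editing_window()
    assert rec_start < w.end and rec_start + k > w.start  # site inside window
    return locus


def _try_build_locus(
    rng: np.random.Generator,
    length: int,
    enzyme: RestrictionEnzyme,
    mode: str,
    read_length: int,
) -> tuple[str, int, str | None, tuple[int, int] | None] | None:
    """One attempt at planting guides, PAM(s) and the recognition site into a
    random amplicon; None when stray motif copies cannot be scrubbed."""
    seq = rng.integers(0, 4, size=length)
    k = len(enzyme.recognition)
    cut = read_length - 85  # ROI [cut-15, cut+80) fits in one read
    if mode == "cas9":
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "+":
            _plant(seq, cut + 4, "GG")  # PAM NGG at [cut+3, cut+6)
            rec_start = cut + 4 - k
        else:
            _plant(seq, cut - 6, "CC")  # top strand shows CCN at [cut-6, cut-3)
            rec_start = cut - 4
        nick_positions = None
    else:
        offset = int(rng.integers(10, 61))
        nick_a = cut - offset // 2
        nick_b = nick_a + offset
        _plant(seq, nick_a - 6, "CC")  # guide A, minus strand, PAM-out left
        _plant(seq, nick_b + 4, "GG")  # guide B, plus strand, PAM-out right
        rec_start = min(max((nick_a + nick_b) // 2 - k // 2, nick_a - 3), nick_b + 3 - k)
        strand = None
        nick_positions = (nick_a, nick_b)
    _plant(seq, rec_start, _resolve_iupac(enzyme.recognition, rng))
    amp = _scrub_extra_sites(seq, enzyme, rec_start, rng)
    if amp is None:
        return None
    return amp, rec_start, strand, nick_positions


def _plant(seq: np.ndarray, start: int, bases: str) -> None:
    for i, b in enumerate(bases):
        seq[start + i] = BASES.index(b)


def _resolve_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(c[int(rng.integers(0, len(c)))] for c in (IUPAC[b] for b in motif))


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[i] for i in seq)


def _motif_matches(amp: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """(start, motif-as-matched) for both-strand occurrences of the motif."""
    from .rflp import _iupac_regex, _iupac_revcomp, _overlapping

    out = []
    for motif in {enzyme.recognition, _iupac_revcomp(enzyme.recognition)}:
        pat = _iupac_regex(motif)
        out.extend((m.start(), motif) for m in _overlapping(pat, amp))
    return out


def _scrub_extra_sites(
    seq: np.ndarray, enzyme: RestrictionEnzyme, rec_start: int, rng: np.random.Generator
) -> str | None:
    """Mutate away chance occurrences of the recognition motif so the planted
    site is the only one; None when a stray match cannot be broken without
    touching the planted site."""
    k = len(enzyme.recognition)
    protected = set(range(rec_start, rec_start + k))
    for _ in range(50):
        amp = _decode(seq)
        extra = [
            (s, motif)
            for s, motif in _motif_matches(amp, enzyme)
            if s != rec_start
        ]
        if not extra:
            return amp
        s, motif = extra[0]
        for off, sym in enumerate(motif):
            pos = s + off
            allowed = IUPAC[sym]
            if pos in protected or len(allowed) == 4:
                continue  # would damage the planted site / cannot break an N
            forbidden = [b for b in BASES if b not in allowed]
            seq[pos] = BASES.index(forbidden[int(rng.integers(0, len(forbidden)))])
            break
        else:
            return None  # every constrained position is protected
    return None


# ---------------------------------------------------------------------------
# alleles


def sample_nhej_allele(
    locus: SimulatedLocus,
    seed: int,
    *,
    deletion_dist: TruncatedGeometric = DEFAULT_NHEJ_DELETION,
    insertion_prob: float = 0.2,
    insertion_max: int = 10,
) -> AlleleSpec:
    """One NHEJ indel whose interval contains or abuts the cut site."""
    if locus.mode != "cas9":
        raise ValueError("sample_nhej_allele requires a cas9-mode locus")
    rng = np.random.default_rng(seed)
    cut = locus.guide.cut
    if rng.random() < insertion_prob:
        n = int(rng.integers(1, insertion_max + 1))
        ins = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
        ev = IndelEvent(cut, 0, ins)
        label = f"ins{n}@{cut}#{seed}"
    else:
        size = deletion_dist.sample(rng)
        start = int(rng.integers(max(0, cut - size), cut + 1))
        ev = IndelEvent(start, size, "")
        label = f"del{size}@{start}#{seed}"
    return AlleleSpec(events=(ev,), label=label)


def sample_nickase_allele(
    locus: SimulatedLocus,
    seed: int,
    *,
    deletion_dist: TruncatedGeometric = DEFAULT_NICKASE_DELETION,
) -> AlleleSpec:
    """One deletion spanning between the two nick sites, sizes on [6,78]."""
    if locus.mode != "nickase":
        raise ValueError("sample_nickase_allele requires a nickase-mode locus")
    rng = np.random.default_rng(seed)
    nick_a, nick_b = sorted(locus.cut_sites)
    size = deletion_dist.sample(rng)
    if size >= nick_b - nick_a:
        start = int(rng.integers(max(0, nick_b - size), nick_a + 1))
    else:
        start = int(rng.integers(nick_a, nick_b - size + 1))
    return AlleleSpec(events=(IndelEvent(start, size, ""),), label=f"ndel{size}@{start}#{seed}")


def sample_background_allele(
    locus: SimulatedLocus, seed: int, *, max_size: int = 3, margin: int = 10
) -> AlleleSpec:
    """A small indel at a uniform random amplicon position — the background
    sequence-variation channel (PCR/sequencing artifacts) used by null
    experiments. Unrelated to the cut site by construction."""
    rng = np.random.default_rng(seed)
    L = len(locus.amplicon)
    size = int(rng.integers(1, max_size + 1))
    pos = int(rng.integers(margin, L - margin - size))
    if rng.random() < 0.5:
        ev = IndelEvent(pos, size, "")
        label = f"bgdel{size}@{pos}#{seed}"
    else:
        ins = "".join(BASES[i] for i in rng.integers(0, 4, size=size))
        ev = IndelEvent(pos, 0, ins)
        label = f"bgins{size}@{pos}#{seed}"
    return AlleleSpec(events=(ev,), label=label)


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class QualityProfile:
    """Linear mean-Phred decay along the read; per-base normal jitter."""

    mean_start: float = 38.0
    mean_end: float = 28.0
    sd: float = 3.0
    q_min: int = 2
    q_max: int = 40

    def means(self, read_length: int) -> np.ndarray:
        return np.linspace(self.mean_start, self.mean_end, read_length)


#: truncation-free profile for experiments that isolate counting from QC
CLEAN_QUALITY = QualityProfile(mean_start=40.0, mean_end=40.0, sd=0.0)


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int
    allele_fractions: Mapping[str, float]
    read_length: int = 150
    substitution_error_rate: float = 0.001
    quality_profile: QualityProfile = QualityProfile()
    #: spread of staggered 5' read starts, emulating offset amplicon primers
    start_stagger: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        fr = list(self.allele_fractions.values())
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("allele fractions must lie in [0,1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {sum(fr)}, expected 1")


def simulate_reads(
    locus: SimulatedLocus, alleles: Sequence[AlleleSpec], config: ReadSimConfig
) -> list[Read]:
    """Sample reads as contiguous windows of allele sequences.

    Reads emulate amplicon sequencing with staggered 5' primers: each read
    starts within ``start_stagger`` bases of the leftmost position whose
    read still contains the locus region of interest (editing + control
    windows, mapped through the allele's events). Anchoring keeps long
    reference context on both sides of any indel, as a primer-defined
    amplicon read would have. When the region does not fit the constraint
    relaxes to the editing window, then to any position. Each read is
    emitted forward or reverse-complemented with probability 1/2.
    """
    by_label = {a.label: a for a in alleles}
    missing = set(config.allele_fractions) - set(by_label)
    if missing:
        raise ValueError(f"fractions reference unknown allele labels: {sorted(missing)}")
    labels = list(config.allele_fractions)
    fractions = np.array([config.allele_fractions[l] for l in labels])
    rng = np.random.default_rng(config.seed)
    rl = config.read_length

    seqs: dict[str, str] = {}
    ranges: dict[str, tuple[int, int]] = {}
    roi = locus.region_of_interest()
    ewin = locus.editing_window().interval
    for label in labels:
        allele = by_label[label]
        seq = allele.apply(locus.amplicon)
        if len(seq) < rl:
            raise ValueError(f"allele {label} shorter than the read length")
        seqs[label] = seq
        start_range = None
        for target in (lift_interval(allele.events, roi), lift_interval(allele.events, ewin)):
            lo = max(0, target[1] - rl)
            hi = min(target[0], len(seq) - rl)
            if lo <= hi:
                start_range = (lo, min(hi, lo + config.start_stagger))
                break
        ranges[label] = start_range or (0, min(len(seq) - rl, config.start_stagger))

    choice = rng.choice(len(labels), size=config.n_reads, p=fractions)
    starts = rng.integers(0, 2**31, size=config.n_reads)
    flips = rng.random(config.n_reads) < 0.5
    err_mask = rng.random((config.n_reads, rl)) < config.substitution_error_rate
    err_shift = rng.integers(1, 4, size=(config.n_reads, rl))
    prof = config.quality_profile
    qmeans = prof.means(rl)
    if prof.sd > 0:
        quals = qmeans[None, :] + rng.normal(0.0, prof.sd, size=(config.n_reads, rl))
    else:
        quals = np.broadcast_to(qmeans, (config.n_reads, rl)).copy()
    quals = np.clip(np.rint(quals), prof.q_min, prof.q_max).astype(int)

    reads: list[Read] = []
    for i in range(config.n_reads):
        label = labels[choice[i]]
        lo, hi = ranges[label]
        start = lo + int(starts[i] % (hi - lo + 1))
        frag = seqs[label][start : start + rl]
        strand = "-" if flips[i] else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        if err_mask[i].any():
            chars = np.array(list(frag))
            idx = np.nonzero(err_mask[i])[0]
            for j in idx:
                chars[j] = BASES[(BASES.index(chars[j]) + err_shift[i, j]) % 4]
            frag = "".join(chars)
        rid = f"{locus.locus_id}|{label}|{start}|{strand}|{i}"
        reads.append(Read(rid, frag, list(quals[i])))
    return reads


def true_label(read: Read) -> str:
    """Recover the ground-truth allele label from a simulated read id."""
    return read.read_id.split("|")[1]


# ---------------------------------------------------------------------------
# qPCR decay series


@dataclass(frozen=True)
class DecaySeries:
    timepoints: tuple[float, ...]  # days since selection withdrawal
    copy_numbers: tuple[float, ...]
    generation_time_hours: float = 24.0

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.copy_numbers):
            raise ValueError("timepoints and copy_numbers differ in length")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(c <= 0 for c in self.copy_numbers):
            raise ValueError("copy numbers must be positive")
        if self.generation_time_hours <= 0:
            raise ValueError("generation time must be positive")


def simulate_qpcr_series(
    initial: float,
    loss_rate_per_generation: float,
    days: Sequence[float],
    generation_time_hours: float = 24.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """Geometric per-generation loss with mean-one lognormal qPCR noise, so
    the expected copy number at day d is initial*(1-rate)^(24 d / g)."""
    if not 0 < loss_rate_per_generation < 1:
        raise ValueError("loss rate must lie in (0,1)")
    if generation_time_hours <= 0:
        raise ValueError("generation time must be positive")
    if initial <= 0:
        raise ValueError("initial copy number must be positive")
    days = tuple(float(d) for d in days)
    gens = np.array(days) * 24.0 / generation_time_hours
    expected = initial * (1.0 - loss_rate_per_generation) ** gens
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        expected = expected * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=len(days)))
    return DecaySeries(
        timepoints=days,
        copy_numbers=tuple(float(c) for c in expected),
        generation_time_hours=generation_time_hours,
    )
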