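# Methods

`crispramp` quantifies CRISPR editing outcomes from amplicon deep
sequencing and models the companion assays of an episomal-vector editing
workflow: in-silico RFLP, paired-gRNA deletion genotyping, and episome
loss kinetics. This note records the models, the parameters that matter,
the numerical choices, and the limitations — in the order the pipeline
runs.

## Read quality control

Each read is truncated at the first base with Phred quality strictly below
the threshold (default Q30); that base and everything after it are
discarded, so the retained read is always a prefix of the input and every
retained base is ≥ Q30. "Below" is strict: a base at exactly Q30 is kept.
Reads shorter than `min_length` (default 50 bp, chosen so a surviving read
can span a 30-bp window plus anchor sequence) are discarded before
alignment and never appear in any denominator. No adapter trimming is
performed; library structure is out of scope.

## Alignment

Reads are aligned to their amplicon with a semi-global affine-gap dynamic
program: global in the read, free end gaps on the reference. Default
scores: match +1, mismatch −2, gap open −5, gap extend −1. Affine gaps
keep a ~30-bp nickase deletion as one event instead of fragmenting it.
Both orientations are tried; the better score wins (forward on ties). An
alignment whose score falls below `min_score_fraction` (default 0.6) of
the perfect score is flagged unaligned and excluded from all denominators.

Implementation: Gotoh three-state recurrence, vectorized one read-row at a
time over the reference axis; the in-row (deletion-state) dependency is
resolved exactly with a prefix-maximum scan of the gap-free row values,
valid because re-opening a gap inside a gap is never optimal when the open
penalty is negative. Same-length reads are aligned in batches; exact
substrings of the amplicon (the common case for accurate amplicon data)
bypass the DP, and duplicate read sequences are aligned once.

Tie-breaking in the traceback is deterministic: diagonal over deletion
over insertion, and gap closure over gap extension. Extracted indels are
then left-normalized (shifted to the smallest reference coordinate that
yields the same alternate sequence), so window membership is well defined
inside repeats. A scalar reference implementation of the same optimum
(`align.oracle_score`, plain per-cell recurrence, no vectorization) ships
with the package for validation; the test suite additionally validates
that scorer against exhaustive enumeration of all alignment paths on tiny
inputs.

## Editing windows and the rate

The predicted SpCas9 cut is blunt, 3 nt 5′ of the PAM: on the + strand at
protospacer_start + 17, on the − strand at protospacer_start + 3 (top
strand, inter-base coordinates). The editing window spans ±`halfwidth`
around the cut (default 15, i.e. a 30-bp window — matching the 30-bp
control fragment; `halfwidth` is a CLI flag so a one-sided reading is also
runnable). For paired nicks the window runs from the leftmost nick −
halfwidth to the rightmost nick + halfwidth, since indels distribute
between the two nick sites. The control window is a 30-bp fragment 50 bp
downstream of the cut (upstream when the amplicon is too short on the
right); for paired nicks the midpoint of the two nicks anchors the control
placement, which keeps it disjoint from the widened window for nick
offsets up to 68 bp.

A read is informative for a window only if its aligned reference span
fully contains the window. It is *edited* if any left-normalized indel
footprint intersects the window — a deletion by its reference interval, an
insertion by its anchor point (strictly inside the window). Substitutions
never count. The editing rate is n_indel / n_window_covering; the same
rule on the control window gives the background rate. Both n_aligned and
n_window_covering are reported, because the covering-read denominator
deviates from a literal "all aligned reads" (partial-coverage reads cannot
be classified). Zero covering reads is an error, not a rate of 0.

Site-vs-background significance across loci uses a two-tailed paired
Student's t-test (t = mean(d)/(sd(d)/√n) on the per-locus rate
differences, sample sd, df = n−1), which errors on fewer than two pairs or
identically-zero differences.

## Synthetic data

The generator builds, per locus, a random amplicon (default 300 bp,
minimum twice the read length) with a planted protospacer + NGG PAM (or a
PAM-out pair of opposite-strand guides with a 10–60 bp nick offset) and
exactly one restriction site whose recognition interval lies inside the
editing window — the geometry the RFLP assay requires; stray motif copies
are mutated away. The cut lands 65 bp into the amplicon so one 150-bp read
spans both the editing and the control window.

Edited alleles carry a single indel: Cas9-mode deletion sizes follow a
truncated geometric on [1, 30] with the decay parameter solved numerically
so the truncated mean is exactly 6 bp; insertions (20% of events; the
observed spectra are deletion-dominated but report no ratio) are 1–10
random bases at the cut. Nickase-mode alleles carry one deletion on
[6, 78] bp, truncated-geometric with mean exactly 30 bp, placed to
intersect the nick-to-nick interval. A separate background channel
(`sample_background_allele`) produces 1–3-bp indels at uniform random
positions, modeling PCR/sequencing indel artifacts for null experiments.

Reads are 150-bp contiguous windows of the allele sequence with staggered
5′ starts (0–10 bp beyond the leftmost position that still covers the
editing + control region, mapped through the allele's events) — the
geometry of primer-anchored amplicon libraries, which also guarantees long
flanks on both sides of any indel. Each read is emitted forward or
reverse-complemented with probability ½; mates of a pair are treated as
independent single reads and mate merging is not modeled. Substitution
errors are uniform per base (default 0.1%, independent of the quality
string); indel sequencing errors are deliberately not modeled. Qualities
follow a linear mean decay along the read (38 → 28 by default, per-base
normal jitter SD 3, clamped to [2, 40]) so the Q30 truncation rule is
exercised; `CLEAN_QUALITY` (constant Q40) is available for experiments
that need truncation-free coverage. Read ids carry the true allele label —
a ground-truth channel for tests and experiments, never read by the
pipeline. Every generator is a pure function of its seed; default
sequencing depth for the CLI simulator is 5000 reads per amplicon (an
arbitrary but typical deep-sequencing figure).

qPCR decay series follow N(d) = N₀(1−r)^(24·d/g) with per-generation loss
rate r, generation time g (default 24 h, a typical hPSC doubling time;
always a flag) and mean-one multiplicative lognormal noise at a given CV.

## RFLP model

Restriction sites are matched IUPAC-aware on both strands (palindromic
sites counted once), with fragment lengths defined by top-strand cut
positions only — a blunt-cut approximation, since overhang geometry does
not move bands at gel resolution. An allele *destroys* its site when the
digested mutant sequence has no cut within one recognition length of the
coordinate-lifted original site. The mixture-level RFLP rate is the summed
fraction of site-destroying alleles — the uncut-band molecule fraction.
Rates are molecule fractions, not densitometry; no band-intensity model is
attempted, and partial digestion, star activity and methylation
sensitivity are out of scope. When interpreting clone band patterns,
fragment classes within ±5 bp co-migrate (configurable); cut-only
patterns are WT, uncut-only biallelic-edited, both heterozygous.

Because an indel can sit inside the editing window without touching the
recognition motif, the RFLP rate is a lower bound on the sequencing rate
when both assays observe the same molecules — the gel's documented
underestimation, exercised as a dominance property over randomized
mixtures.

## Deletion genotyping

A paired-gRNA deletion joins the two cut coordinates. Genotyping uses two
PCR assays: an internal pair (binds inside the deleted interval →
amplifies non-deleted alleles only) and a junction pair (flanks the
interval; its intact-template product exceeds the `max_product` dropout
ceiling and only amplifies once the deletion shortens it). Primer binding
is exact full-length matching — the assay is presence/absence — and a
primer with multiple binding sites is an ambiguous-design error. Band
pattern → call: junction+/internal− biallelic, junction+/internal+
monoallelic, junction−/internal+ WT, neither assay_failure. The bundled
design fixture uses a 319-bp deletion in a 1200-bp template (junction
product 719 bp intact / 400 bp deleted, internal 170 bp, dropout at
600 bp). Inversions and re-integration outcomes of paired cutting are not
modeled.

## Episome decay fit

Copy numbers are fit by least squares on log(copies) versus generations
(log scale because qPCR noise is multiplicative); the loss rate is
1 − exp(slope). Noiseless series invert exactly; constant or growing
series put the rate outside (0,1) and raise rather than returning a
boundary value. At least three timepoints are required.

## Simulation studies (experiments module)

Problem sizes are chosen so the whole suite runs comfortably on a single
CPU while leaving the statistics well-powered:

* **Rate recovery** — one locus, 2000 reads/replicate, 50 replicates per
  true fraction {0, 0.1, 0.5, 0.93}, 0.1% substitution error,
  truncation-free qualities; scored as |rate − truth| ≤ 3√(p(1−p)/n) with
  n the realized covering count.
* **Type-I calibration** — 9 loci × 200 replicates, 600 reads/locus,
   5% background-indel fraction split over three uniform-position
  background alleles, error-free truncation-free reads; rejection
  frequency of the paired t-test at α = 0.05. Depth and fraction are set
  so the expected per-window indel count is a few reads per locus — large
  enough that per-locus rate differences are not dominated by ties at
  zero, the regime in which the paired t-test's size is near nominal and
  insensitive to the exact choice.
* **RFLP dominance** — 100 random Dirichlet mixtures of 1–3 edited alleles,
  400 error-free reads each; the RFLP fraction is computed on the realized
  allele composition of the same reads (one template pool feeds both
  assays), making dominance structural rather than statistical.
* **Deletion truth table** — 100 clones drawn over the four genotype
  classes (assay failure modeled as an off-template sample).
* **Decay recovery** — 50 replicates, true rates uniform in [0.03, 0.06],
  8 timepoints every 2 days, 5% CV.

## Known limitations

* **Coverage-selection bias.** The covering-read denominator interacts
  with aggressive quality truncation: deletion-bearing reads span the
  window with fewer bases, so under the steep default profile they survive
  truncation more often and the reported rate sits above the true edited
  fraction (direction demonstrated by a dedicated test). With realistic
  high-quality data (little truncation) the effect vanishes. Analyses of
  heavily-truncated data should read n_window_covering alongside the rate.
* **Edge-proximal indels.** A deletion a few bases from a read's end can
  be absorbed into end mismatches by the optimal alignment (k mismatches
  cost 3k versus a gap's 5 + length); such reads drop out of the covering
  denominator. Primer-anchored amplicon reads have long flanks, so the
  simulator reproduces that geometry.
* The simulator draws substitution errors independently of the quality
  string, models no PCR bias, chimeras or indel sequencing errors, and
  treats mates as independent reads. Passing tests therefore demonstrate
  the counting, windowing and testing machinery — not robustness to
  error modes the generator does not produce.
* Multi-locus read assignment is best-score-wins with ties dropped;
  genome-scale mapping and chimeric alignments are out of scope.
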