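"""Simulation studies exercising the whole pipeline.

Each function here runs a self-contained experiment — simulate with known
truth, analyze with the ordinary pipeline, compare — and returns plain
numbers. They back both the property-based test suite and the
reproducibility script, so the study conditions (depths, replicate counts,
noise levels) are defined once, here.

All randomness derives from the single ``seed`` argument via spawned
``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import AlleleSpec
from .deletion import DeletionDesign, PrimerPair, apply_deletion, genotype_clone_templates
from .episome import fit_loss_rate
from .quantify import paired_t_test, quantify_locus
from .rflp import rflp_rate
from .simulate import (
    CLEAN_QUALITY,
    ReadSimConfig,
    generate_locus,
    sample_background_allele,
    sample_nhej_allele,
    simulate_qpcr_series,
    simulate_reads,
    true_label,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# editing-rate parameter recovery


@dataclass
class RecoveryResult:
    true_fraction: float
    rates: list[float]
    n_covering: list[int]
    within_3sd: int
    n_replicates: int


def editing_rate_recovery(
    true_fraction: float,
    *,
    n_reads: int = 2000,
    substitution_error_rate: float = 0.001,
    n_replicates: int = 50,
    seed: int = 0,
) -> RecoveryResult:
    """Simulate a locus edited at a known fraction, run the full pipeline
    (QC -> align -> classify), and score how often the reported rate falls
    within 3 binomial standard deviations of truth (evaluated at the
    realized window-covering denominator).

    Qualities are truncation-free: the editing estimator conditions on
    window coverage, and under heavy Q30 truncation coverage probability
    depends on the allele (deletion reads span the window with fewer
    bases), a selection bias documented in the methods note and
    demonstrated by its own test. This experiment measures the counting
    machinery, not that bias."""
    seeds = _child_seeds(seed, 2 * n_replicates + 1)
    locus = generate_locus(seeds[-1], 300, "EcoRI", "cas9")
    rates, ncov = [], []
    within = 0
    for r in range(n_replicates):
        allele = sample_nhej_allele(locus, seeds[2 * r])
        alleles = [AlleleSpec(label="WT"), allele]
        fractions = {"WT": 1.0 - true_fraction, allele.label: true_fraction}
        if true_fraction == 0.0:
            alleles, fractions = [AlleleSpec(label="WT")], {"WT": 1.0}
        elif true_fraction == 1.0:
            alleles, fractions = [allele], {allele.label: 1.0}
        cfg = ReadSimConfig(
            n_reads=n_reads,
            allele_fractions=fractions,
            substitution_error_rate=substitution_error_rate,
            quality_profile=CLEAN_QUALITY,
            seed=seeds[2 * r + 1],
        )
        reads = simulate_reads(locus, alleles, cfg)
        rep = quantify_locus(
            reads,
            locus.amplicon,
            locus.editing_window(),
            locus.control_window(),
            locus_id=locus.locus_id,
        )
        rates.append(rep.rate)
        ncov.append(rep.n_window_covering)
        sd = np.sqrt(true_fraction * (1 - true_fraction) / rep.n_window_covering)
        if abs(rep.rate - true_fraction) <= 3 * sd:
            within += 1
    return RecoveryResult(true_fraction, rates, ncov, within, n_replicates)


# ---------------------------------------------------------------------------
# type-I calibration of the paired site-vs-background t-test


def null_calibration(
    *,
    n_loci: int = 9,
    n_replicates: int = 200,
    n_reads: int = 600,
    background_fraction: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection frequency of the paired two-tailed t-test (site rate vs
    control rate across loci) with zero editing at the cut sites.

    The null world carries background sequence variation — small indels at
    uniform random amplicon positions, the empirical PCR/sequencing
    artifact channel — at ``background_fraction``, split over three
    background alleles per locus. Qualities are truncation-free so the
    experiment isolates counting and testing from QC stochasticity.
    """
    locus_seeds = _child_seeds(seed, n_loci)
    loci = [generate_locus(s, 300, "EcoRI", "cas9") for s in locus_seeds]
    rep_seeds = _child_seeds(seed + 1, n_replicates)
    rejections = 0
    for r in range(n_replicates):
        sub = _child_seeds(rep_seeds[r], 4 * n_loci)
        pairs = []
        for i, locus in enumerate(loci):
            bg = [sample_background_allele(locus, sub[4 * i + j]) for j in range(3)]
            f = background_fraction / 3.0
            alleles = [AlleleSpec(label="WT")] + bg
            fractions = {"WT": 1.0 - background_fraction, **{a.label: f for a in bg}}
            cfg = ReadSimConfig(
                n_reads=n_reads,
                allele_fractions=fractions,
                substitution_error_rate=0.0,
                quality_profile=CLEAN_QUALITY,
                seed=sub[4 * i + 3],
            )
            reads = simulate_reads(locus, alleles, cfg)
            rep = quantify_locus(
                reads,
                locus.amplicon,
                locus.editing_window(),
                locus.control_window(),
                locus_id=locus.locus_id,
            )
            pairs.append((rep.rate, rep.control_rate))
        try:
            res = paired_t_test(pairs)
            if res.p_two_sided < alpha:
                rejections += 1
        except ValueError:
            pass  # degenerate all-zero replicate: cannot reject
    return rejections / n_replicates


# ---------------------------------------------------------------------------
# RFLP dominance


def rflp_dominance(
    *, n_mixtures: int = 100, n_reads: int = 400, seed: int = 0
) -> tuple[int, int]:
    """Randomized allele mixtures with the enzyme site inside the editing
    window: count mixtures where rflp_rate <= sequencing editing rate on
    error-free reads (the RFLP-underestimation direction). Returns
    (holds, total).

    Both assays observe the same molecules: the RFLP fraction is computed
    over the realized allele composition of the window-covering reads (via
    the simulator's ground-truth labels), exactly as a gel lane and a
    sequencing library drawn from one PCR tube share their template
    molecules. Any allele that destroys the site carries an indel
    overlapping the recognition interval inside the window, so each of its
    reads is classified edited — dominance is then structural, not
    statistical."""
    seeds = _child_seeds(seed, 3 * n_mixtures)
    holds = 0
    for m in range(n_mixtures):
        locus = generate_locus(seeds[3 * m], 300, "EcoRI", "cas9")
        rng = np.random.default_rng(seeds[3 * m + 1])
        n_edit = int(rng.integers(1, 4))
        edited = []
        for j in range(n_edit):
            a = sample_nhej_allele(locus, int(rng.integers(0, 2**31)))
            if a.label not in {e.label for e in edited}:
                edited.append(a)
        w = rng.dirichlet(np.ones(len(edited) + 1))
        alleles = [AlleleSpec(label="WT")] + edited
        fractions = {a.label: float(x) for a, x in zip(alleles, w)}
        cfg = ReadSimConfig(
            n_reads=n_reads,
            allele_fractions=fractions,
            substitution_error_rate=0.0,
            quality_profile=CLEAN_QUALITY,
            seed=seeds[3 * m + 2],
        )
        reads = simulate_reads(locus, alleles, cfg)
        rep = quantify_locus(
            reads,
            locus.amplicon,
            locus.editing_window(),
            None,
            locus_id=locus.locus_id,
        )
        # realized composition of the sequenced molecules (truth channel)
        counts = {a.label: 0 for a in alleles}
        for rd in reads:
            counts[true_label(rd)] += 1
        total = sum(counts.values())
        mix = [(a, counts[a.label] / total) for a in alleles]
        r_rflp = rflp_rate(mix, locus.amplicon, locus.enzyme, locus.enzyme_cut)
        if r_rflp <= rep.rate + 1e-12:
            holds += 1
    return holds, n_mixtures


# ---------------------------------------------------------------------------
# deletion genotyping truth table


def make_deletion_design(seed: int = 0) -> DeletionDesign:
    """A 1200-bp template with a 319-bp deletion interval and the two assay
    primer pairs (junction product 719 bp intact / 400 bp deleted; internal
    product 170 bp, inside the deleted interval)."""
    rng = np.random.default_rng(seed)
    template = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1200))
    interval = (400, 719)
    junction = PrimerPair(template[350:370], _rc(template[1049:1069]), "junction")
    internal = PrimerPair(template[450:470], _rc(template[600:620]), "internal")
    return DeletionDesign(template, interval, internal, junction)


def _rc(s: str) -> str:
    from .align import reverse_complement

    return reverse_complement(s)


def deletion_truth_table(*, n_clones: int = 100, seed: int = 0, max_product: int = 600) -> tuple[int, int]:
    """Simulate clones of all four genotype classes and count correct calls.
    Returns (correct, total)."""
    design = make_deletion_design(seed)
    intact = design.template
    deleted = apply_deletion(intact, design.deletion_interval)
    scrambled = "".join(
        "ACGT"[i] for i in np.random.default_rng(seed + 1).integers(0, 4, size=200)
    )
    genotypes = {
        "WT": [intact, intact],
        "monoallelic": [intact, deleted],
        "biallelic": [deleted, deleted],
        "assay_failure": [scrambled, scrambled],
    }
    rng = np.random.default_rng(seed + 2)
    correct = 0
    for _ in range(n_clones):
        truth = list(genotypes)[int(rng.integers(0, 4))]
        call = genotype_clone_templates(genotypes[truth], design, max_product)
        if call.call == truth:
            correct += 1
    return correct, n_clones


# ---------------------------------------------------------------------------
# decay-rate recovery


def decay_recovery(
    *,
    n_replicates: int = 50,
    noise_cv: float = 0.05,
    rate_range: tuple[float, float] = (0.03, 0.06),
    days: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 12, 14),
    seed: int = 0,
) -> dict[str, float]:
    """Fit loss rates on noisy simulated series with per-replicate true rates
    drawn uniformly from ``rate_range``; report the median signed error."""
    rng = np.random.default_rng(seed)
    errors = []
    for r in range(n_replicates):
        true = float(rng.uniform(*rate_range))
        series = simulate_qpcr_series(
            100.0, true, days, 24.0, noise_cv, int(rng.integers(0, 2**31))
        )
        fit = fit_loss_rate(series)
        errors.append(fit.loss_rate_per_generation - true)
    return {
        "median_error": float(np.median(errors)),
        "median_abs_error": float(np.median(np.abs(errors))),
    }
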