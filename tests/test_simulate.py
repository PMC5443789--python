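"""Synthetic-data generators: determinism, invariants, distributions."""

from __future__ import annotations

import numpy as np
import pytest

from crispramp.alleles import AlleleSpec
from crispramp.quantify import predicted_cut_site
from crispramp.rflp import find_sites
from crispramp.simulate import (
    CLEAN_QUALITY,
    DEFAULT_NHEJ_DELETION,
    DEFAULT_NICKASE_DELETION,
    ReadSimConfig,
    TruncatedGeometric,
    generate_locus,
    sample_background_allele,
    sample_nhej_allele,
    sample_nickase_allele,
    simulate_reads,
    true_label,
)


class TestGenerateLocus:
    def test_enzyme_site_intersects_editing_window(self):
        for seed in range(10):
            locus = generate_locus(seed, 300, "EcoRI", "cas9")
            sites = find_sites(locus.amplicon, locus.enzyme)
            assert sites == [locus.enzyme_cut]
            w = locus.editing_window()
            k = len(locus.enzyme.recognition)
            assert locus.enzyme_cut - k < w.end and locus.enzyme_cut + k > w.start

    def test_guide_coordinates_verified_against_amplicon(self):
        # check_against raises unless protospacer+PAM occur where recorded
        for seed in (0, 1, 2):
            locus = generate_locus(seed, 320, "SacI", "cas9")
            for g in locus.guides:
                g.check_against(locus.amplicon)

    def test_deterministic_and_seed_sensitive(self):
        a = generate_locus(1, 300, "EcoRI", "cas9")
        b = generate_locus(1, 300, "EcoRI", "cas9")
        c = generate_locus(2, 300, "EcoRI", "cas9")
        assert a.amplicon == b.amplicon and a.guides == b.guides
        assert c.amplicon != a.amplicon

    def test_nickase_guides_opposite_strands_with_bounded_offset(self):
        for seed in range(8):
            locus = generate_locus(seed, 300, "EcoRI", "nickase")
            (ga, gb) = locus.guides
            assert {ga.strand, gb.strand} == {"-", "+"}
            a, b = locus.cut_sites
            assert 10 <= abs(b - a) <= 60
            for g in locus.guides:
                g.check_against(locus.amplicon)

    def test_unknown_enzyme_named_in_error(self):
        with pytest.raises(KeyError, match="FakeZyme"):
            generate_locus(1, 300, "FakeZyme", "cas9")

    def test_too_short_amplicon_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_locus(1, 200, "EcoRI", "cas9")

    def test_amplicon_at_least_twice_read_length(self):
        locus = generate_locus(3, 340, "XbaI", "cas9")
        assert len(locus.amplicon) >= 2 * locus.read_length


class TestTruncatedGeometric:
    def test_configured_mean_is_exact(self):
        for dist in (DEFAULT_NHEJ_DELETION, DEFAULT_NICKASE_DELETION):
            assert float(np.sum(dist.support * dist.pmf)) == pytest.approx(dist.mean, abs=1e-9)

    def test_unreachable_mean_rejected(self):
        with pytest.raises(ValueError):
            TruncatedGeometric(1, 30, 0.5)
        with pytest.raises(ValueError):
            TruncatedGeometric(1, 30, 20)


class TestNhejAlleles:
    def test_event_contains_or_abuts_cut(self, cas9_locus):
        cut = cas9_locus.guide.cut
        for seed in range(100):
            allele = sample_nhej_allele(cas9_locus, seed)
            (ev,) = allele.events
            if ev.deleted_length:
                assert ev.ref_position <= cut <= ev.ref_end
            else:
                assert ev.ref_position == cut

    def test_requires_cas9_mode(self, nickase_locus):
        with pytest.raises(ValueError):
            sample_nhej_allele(nickase_locus, 1)

    def test_distinct_seeds_give_independent_draws(self, cas9_locus):
        labels = {sample_nhej_allele(cas9_locus, s).label for s in range(30)}
        assert len(labels) > 10

    def test_deletion_size_monte_carlo_mean(self, cas9_locus):
        sizes = []
        for seed in range(10_000):
            allele = sample_nhej_allele(cas9_locus, seed, insertion_prob=0.0)
            sizes.append(allele.events[0].deleted_length)
        sizes = np.array(sizes)
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - DEFAULT_NHEJ_DELETION.mean) <= 3 * se
        assert sizes.max() <= 30 and sizes.min() >= 1


class TestNickaseAlleles:
    def test_size_support_and_mean(self, nickase_locus):
        sizes = np.array(
            [
                sample_nickase_allele(nickase_locus, seed).events[0].deleted_length
                for seed in range(10_000)
            ]
        )
        assert sizes.min() >= 6 and sizes.max() <= 78
        se = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - 30.0) <= 3 * se

    def test_deletion_intersects_nick_interval(self, nickase_locus):
        a, b = sorted(nickase_locus.cut_sites)
        for seed in range(200):
            (ev,) = sample_nickase_allele(nickase_locus, seed).events
            assert ev.ref_position < b and ev.ref_end > a

    def test_requires_nickase_mode(self, cas9_locus):
        with pytest.raises(ValueError):
            sample_nickase_allele(cas9_locus, 1)


class TestSimulateReads:
    def test_pure_wt_no_error_reads_are_exact_substrings(self, cas9_locus):
        cfg = ReadSimConfig(
            n_reads=200, allele_fractions={"WT": 1.0}, substitution_error_rate=0.0, seed=4
        )
        reads = simulate_reads(cas9_locus, [AlleleSpec(label="WT")], cfg)
        from crispramp.align import reverse_complement

        amp = cas9_locus.amplicon
        for r in reads:
            assert r.bases in amp or reverse_complement(r.bases) in amp

    def test_allele_counts_binomial(self, cas9_locus):
        allele = sample_nhej_allele(cas9_locus, 77)
        cfg = ReadSimConfig(
            n_reads=1000,
            allele_fractions={"WT": 0.5, allele.label: 0.5},
            seed=6,
        )
        reads = simulate_reads(cas9_locus, [AlleleSpec(label="WT"), allele], cfg)
        n_wt = sum(1 for r in reads if true_label(r) == "WT")
        assert abs(n_wt - 500) <= 3 * np.sqrt(1000 * 0.25)

    def test_same_seed_same_bytes(self, cas9_locus, tmp_path):
        from crispramp.io import write_fastq

        cfg = ReadSimConfig(n_reads=50, allele_fractions={"WT": 1.0}, seed=9)
        for name in ("a.fastq", "b.fastq"):
            write_fastq(tmp_path / name, simulate_reads(cas9_locus, [AlleleSpec(label="WT")], cfg))
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            ReadSimConfig(n_reads=10, allele_fractions={"WT": 0.6, "x": 0.5})

    def test_unknown_labels_rejected(self, cas9_locus):
        cfg = ReadSimConfig(n_reads=10, allele_fractions={"ghost": 1.0})
        with pytest.raises(ValueError, match="ghost"):
            simulate_reads(cas9_locus, [AlleleSpec(label="WT")], cfg)

    def test_reads_cover_region_of_interest(self, cas9_locus):
        cfg = ReadSimConfig(
            n_reads=100,
            allele_fractions={"WT": 1.0},
            substitution_error_rate=0.0,
            quality_profile=CLEAN_QUALITY,
            seed=2,
        )
        reads = simulate_reads(cas9_locus, [AlleleSpec(label="WT")], cfg)
        lo, hi = cas9_locus.region_of_interest()
        amp = cas9_locus.amplicon
        from crispramp.align import reverse_complement

        for r in reads:
            seq = r.bases if r.bases in amp else reverse_complement(r.bases)
            start = amp.find(seq)
            assert start <= lo and start + len(seq) >= hi

    def test_quality_profile_decays_along_read(self, cas9_locus):
        cfg = ReadSimConfig(n_reads=400, allele_fractions={"WT": 1.0}, seed=3)
        reads = simulate_reads(cas9_locus, [AlleleSpec(label="WT")], cfg)
        q = np.array([r.quals for r in reads], dtype=float)
        assert q[:, :20].mean() > q[:, -20:].mean() + 5
        assert q.min() >= 2 and q.max() <= 40


class TestBackgroundAlleles:
    def test_positions_spread_over_amplicon(self, cas9_locus):
        positions = [
            sample_background_allele(cas9_locus, s).events[0].ref_position
            for s in range(300)
        ]
        # roughly uniform: both halves populated
        L = len(cas9_locus.amplicon)
        frac_left = np.mean([p < L / 2 for p in positions])
        assert 0.35 < frac_left < 0.65
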