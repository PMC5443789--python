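"""Aligner: oracle agreement, variant extraction, left-normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import all_sequences, enumerate_best_score, random_dna
from crispramp.align import (
    ScoringScheme,
    Variant,
    align_many,
    extract_variants,
    left_normalize,
    oracle_score,
    reverse_complement,
    semiglobal_align,
    semiglobal_scores,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


def _align(read, ref, **kw):
    kw.setdefault("min_score_fraction", 0.0)
    kw.setdefault("try_reverse_complement", False)
    return semiglobal_align(read, ref, **kw)


class TestScoring:
    def test_exact_substring_scores_full_match(self, scheme):
        aln = _align("GATTACA", "TTGATTACATT")
        assert aln.score == 7 * scheme.match
        assert aln.ops == [("match", 7, "")]
        assert (aln.ref_start, aln.ref_end) == (2, 9)

    def test_known_single_deletion(self):
        # enumerate_best_score confirms the optimum is one 1-bp deletion
        aln = _align("ACGACGT", "ACGTACGT")
        expected = enumerate_best_score("ACGACGT", "ACGTACGT", ScoringScheme())
        assert aln.score == expected == 1.0
        assert extract_variants(aln) == [Variant(3, "deletion", 1)]

    def test_scalar_oracle_matches_exhaustive_enumeration(self, scheme):
        # validates the reference scorer itself on every tiny 2-letter pair
        for read in all_sequences("AC", 4):
            for ref in all_sequences("AC", 4):
                assert oracle_score(read, ref, scheme) == enumerate_best_score(
                    read, ref, scheme
                ), (read, ref)

    def test_vectorized_matches_oracle_on_random_pairs(self, scheme):
        rng = np.random.default_rng(42)
        for _ in range(200):
            read = random_dna(rng, int(rng.integers(1, 13)))
            ref = random_dna(rng, int(rng.integers(1, 13)))
            assert _align(read, ref).score == oracle_score(read, ref, scheme)

    def test_batch_scores_match_single(self, scheme):
        rng = np.random.default_rng(7)
        ref = random_dna(rng, 40)
        reads = [random_dna(rng, int(rng.integers(3, 15))) for _ in range(30)]
        batch = semiglobal_scores(reads, ref, scheme)
        singles = [_align(r, ref).score for r in reads]
        assert np.array_equal(batch, singles)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            semiglobal_align("", "ACGT")
        with pytest.raises(ValueError):
            semiglobal_align("ACGT", "")

    def test_min_score_fraction_flags_poor_alignments(self):
        aln = semiglobal_align("TTTTTTTTTT", "ACGCAGCGCA", min_score_fraction=0.6)
        assert not aln.aligned
        with pytest.raises(ValueError):
            extract_variants(aln)


class TestTracebackConsistency:
    """The reported ops must re-score to the reported score and reconstruct
    the read from the reference."""

    @staticmethod
    def _check(aln, read, ref, scheme):
        score = 0.0
        for kind, length, ins in aln.ops:
            if kind == "match":
                score += length * scheme.match
            elif kind == "mismatch":
                score += length * scheme.mismatch
            else:
                score += scheme.gap_open + length * scheme.gap_extend
        assert score == aln.score
        ref_len = sum(l for k, l, _ in aln.ops if k in ("match", "mismatch", "deletion"))
        read_len = sum(l for k, l, _ in aln.ops if k in ("match", "mismatch", "insertion"))
        assert ref_len == aln.ref_end - aln.ref_start
        assert read_len == len(read)
        # reconstruct the read by applying indels to the aligned ref slice,
        # ignoring substitutions
        out, pos, rpos = [], aln.ref_start, 0
        for kind, length, ins in aln.ops:
            if kind in ("match", "mismatch"):
                out.append(read[rpos : rpos + length])
                pos += length
                rpos += length
            elif kind == "deletion":
                pos += length
            else:
                out.append(ins)
                rpos += length
        assert "".join(out) == read

    def test_random_pairs(self, scheme):
        rng = np.random.default_rng(3)
        for _ in range(200):
            read = random_dna(rng, int(rng.integers(2, 20)))
            ref = random_dna(rng, int(rng.integers(2, 25)))
            aln = _align(read, ref)
            self._check(aln, read, ref, scheme)

    def test_simulated_indel_reads(self, scheme, cas9_locus):
        # 150-bp reads with real indels: ops must stay self-consistent
        from crispramp.alleles import AlleleSpec
        from crispramp.simulate import ReadSimConfig, sample_nhej_allele, simulate_reads, CLEAN_QUALITY

        allele = sample_nhej_allele(cas9_locus, 99)
        cfg = ReadSimConfig(
            n_reads=40,
            allele_fractions={allele.label: 1.0},
            substitution_error_rate=0.01,
            quality_profile=CLEAN_QUALITY,
            seed=5,
        )
        reads = simulate_reads(cas9_locus, [allele], cfg)
        for aln in align_many([r.bases for r in reads], cas9_locus.amplicon, scheme):
            self._check(aln, aln.query, cas9_locus.amplicon, scheme)


class TestStrandHandling:
    def test_reverse_complement_read_yields_same_variants(self, cas9_locus):
        from crispramp.alleles import AlleleSpec, IndelEvent

        amp = cas9_locus.amplicon
        allele = AlleleSpec(events=(IndelEvent(60, 4, ""),), label="del4")
        read = allele.apply(amp)[10:140]
        fwd = semiglobal_align(read, amp)
        rev = semiglobal_align(reverse_complement(read), amp)
        assert fwd.aligned and rev.aligned
        assert (fwd.strand, rev.strand) == ("+", "-")
        assert extract_variants(fwd) == extract_variants(rev)


class TestSamExport:
    def test_round_trip_through_pysam(self, tmp_path, cas9_locus):
        import pysam

        from crispramp.align import write_sam

        amp = cas9_locus.amplicon
        reads = [amp[10:60], amp[100:160]]
        alns = align_many(reads, amp, read_ids=["r1", "r2"])
        path = tmp_path / "out.sam"
        write_sam(str(path), alns, "amp1", len(amp))
        with pysam.AlignmentFile(str(path)) as fh:
            records = list(fh)
        assert [r.query_name for r in records] == ["r1", "r2"]
        assert records[0].reference_start == 10
        assert records[0].cigarstring == "50M"


class TestLeftNormalize:
    def test_deletion_in_homopolymer_shifts_to_leftmost(self):
        # deleting any single A from the AAAA run is the same haplotype
        v = left_normalize(Variant(5, "deletion", 1), "CCAAAACC")
        assert v.ref_position == 2
        # independent check: enumerate equivalent placements
        ref = "CCAAAACC"
        target = ref[:5] + ref[6:]
        placements = [
            p for p in range(len(ref)) if ref[:p] + ref[p + 1 :] == target
        ]
        assert v.ref_position == min(placements)

    def test_non_repetitive_context_unchanged(self):
        v = Variant(3, "deletion", 2)
        assert left_normalize(v, "ACGTACGTA") == v

    def test_insertion_rotation(self):
        # inserting "TA" after the TA at 2 equals inserting at 0
        v = left_normalize(Variant(2, "insertion", 2, "TA"), "TACG")
        assert v.ref_position == 0
        assert v.inserted_bases == "TA"

    @given(pos=st.integers(1, 7), length=st.integers(1, 3), seq=DNA.filter(lambda s: len(s) >= 10))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_idempotent_and_equivalent(self, pos, length, seq):
        if pos + length > len(seq):
            pos = len(seq) - length
        v = Variant(pos, "deletion", length)
        n1 = left_normalize(v, seq)
        assert left_normalize(n1, seq) == n1
        # same alternate haplotype
        alt = lambda x: seq[: x.ref_position] + seq[x.ref_position + x.length :]
        assert alt(v) == alt(n1)
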