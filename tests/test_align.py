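"""Alignment primitives: global alignment, K2P distance, flank mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import gotoh_score, k2p_closed_form
from tedyn.align import (
    AlignmentInputError,
    GenomeIndex,
    PairwiseAlignment,
    SaturationError,
    global_align,
    global_score,
    identity_coverage,
    k2p_distance,
    k2p_from_counts,
    map_flank,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def _mutate(seq: str, n_subs: int, rng, transversion_only=False) -> str:
    out = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for p in pos:
        out[p] = tv[out[p]] if transversion_only else rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        identity, coverage = identity_coverage(aln)
        assert (identity, coverage) == (1.0, 1.0)
        assert aln.score == 8.0  # 4 matches at +2

    def test_single_mismatch(self):
        aln = global_align("ACGT", "AGGT")
        identity, _ = identity_coverage(aln)
        assert identity == 0.75
        assert aln.score == 3 * 2 - 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentInputError):
            global_align("", "ACGT")
        with pytest.raises(AlignmentInputError):
            global_align("ACGT", "")

    def test_non_dna_rejected(self):
        with pytest.raises(AlignmentInputError):
            global_align("ACGU", "ACGT")

    def test_score_matches_dp_oracle_random_200nt(self, rng):
        """Optimal score equals an independent quadratic-DP implementation
        on random 200-nt pairs at various divergences."""
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), 200))
            b = _mutate(a, int(rng.integers(0, 60)), rng)
            assert global_score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_score_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 50))
            b = "".join(rng.choice(list("ACGT"), 40))
            assert global_score(a, b) == pytest.approx(global_score(b, a))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=dna, b=dna)
    def test_alignment_invariants(self, a, b):
        """Equal row lengths, no gap-in-both column, residue counts match,
        and the reported score is reproducible from the gapped rows."""
        aln = global_align(a, b)
        assert len(aln.aligned_query) == len(aln.aligned_target)
        assert all(not (x == "-" and y == "-") for x, y in aln.columns())
        assert aln.aligned_query.replace("-", "") == a
        assert aln.aligned_target.replace("-", "") == b
        # recompute affine score from the columns
        score, gap_state = 0.0, None
        for x, y in aln.columns():
            if x == "-" or y == "-":
                state = "x" if y == "-" else "y"
                score -= 2.0 if state == gap_state else 7.0
                gap_state = state
            else:
                score += 2.0 if x == y else -3.0
                gap_state = None
        assert score == pytest.approx(aln.score)


class TestK2P:
    def test_identical_gives_zero(self):
        aln = global_align("ACGTACGTACGT", "ACGTACGTACGT")
        res = k2p_distance(aln)
        assert (res.P, res.Q, res.K) == (0.0, 0.0, 0.0)
        assert res.compared_sites == 12

    def test_closed_form_value(self):
        # K = -1/2 ln((1-2*0.1-0.05) * sqrt(1-2*0.05)), evaluated independently
        res = k2p_from_counts(10, 5, 100)
        assert res.K == pytest.approx(k2p_closed_form(0.1, 0.05), abs=1e-12)
        assert res.K == pytest.approx(0.17018116514034714, abs=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_counts(45, 25, 100)  # 1-2P-Q < 0

    def test_transversion_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_counts(0, 50, 100)  # 1-2Q = 0

    def test_no_usable_columns_raises(self):
        aln = PairwiseAlignment("q", "t", "NNN", "NNN", 0.0, (0, 3), (0, 3))
        with pytest.raises(AlignmentInputError):
            k2p_distance(aln)

    def test_gap_and_n_columns_excluded(self):
        # columns: A/A match, C/G transversion, G/G, T/T, gap, N/N
        aln = PairwiseAlignment("q", "t", "ACGT-N", "AGGTCN", 0.0, (0, 5), (0, 6))
        res = k2p_distance(aln)
        assert res.compared_sites == 4
        assert res.P == 0.0
        assert res.Q == pytest.approx(0.25)

    def test_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        other = _mutate(seq, 30, rng)
        f = k2p_distance(global_align(seq, other))
        r = k2p_distance(global_align(other, seq))
        assert f.K == pytest.approx(r.K)
        assert (f.P, f.Q) == (r.P, r.Q)

    def test_k_never_below_raw_divergence(self, rng):
        """K2P correction never shrinks the raw proportion of differences."""
        for p_count, q_count, n in [(1, 1, 100), (10, 5, 200), (30, 10, 150), (0, 0, 50)]:
            res = k2p_from_counts(p_count, q_count, n)
            assert res.K >= res.P + res.Q - 1e-15

    def test_taylor_limit_at_small_divergence(self):
        """K -> P+Q as P,Q -> 0 (within 1% at P,Q <= 1e-3)."""
        res = k2p_from_counts(1, 1, 1000)
        assert res.K == pytest.approx(res.P + res.Q, rel=0.01)


class TestIdentityCoverage:
    def test_truncation_against_column_count_oracle(self, rng):
        """identity/coverage equal a brute-force count over alignment columns."""
        for _ in range(10):
            full = "".join(rng.choice(list("ACGT"), 120))
            cut = int(rng.integers(60, 120))
            aln = global_align(full, full[:cut])
            identity, coverage = identity_coverage(aln)
            cols = [
                (x, y) for x, y in zip(aln.aligned_query, aln.aligned_target)
                if x != "-" and y != "-"
            ]
            matches = sum(1 for x, y in cols if x == y)
            assert identity == pytest.approx(matches / len(cols))
            assert coverage == pytest.approx(len(cols) / 120)

    def test_ten_substitutions_in_100(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = _mutate(a, 10, rng)
        identity, coverage = identity_coverage(global_align(a, b))
        assert identity == pytest.approx(0.90)
        assert coverage == 1.0


class TestMapFlank:
    def test_exact_substring_recovers_coordinates(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 20000))}
        query = genome["chr1"][5000:5400]
        hits = map_flank(query, genome)
        assert hits[0].target_span == (5000, 5400)
        assert hits[0].identity == 1.0
        assert hits[0].coverage == 1.0
        assert hits[0].strand == "+"

    def test_reverse_strand(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 20000))}
        hits = map_flank(revcomp(genome["chr1"][5000:5400]), genome)
        assert hits[0].target_span == (5000, 5400)
        assert hits[0].strand == "-"

    def test_two_planted_loci_give_two_hits(self, rng):
        backbone = "".join(rng.choice(list("ACGT"), 30000))
        insert = "".join(rng.choice(list("ACGT"), 300))
        genome = {"chr1": backbone[:10000] + insert + backbone[10000:20000] + insert + backbone[20000:]}
        hits = map_flank(insert, genome)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 2
        assert {h.target_span[0] for h in plus} == {10000, 20300}

    def test_mutated_query_recovers_locus(self, rng):
        """500-nt query with 5% substitutions maps back within +-5 bp."""
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 50000))}
        query = _mutate(genome["chr1"][30000:30500], 25, rng)
        best = map_flank(query, genome)[0]
        assert abs(best.target_span[0] - 30000) <= 5
        assert abs(best.target_span[1] - 30500) <= 5
        assert best.identity == pytest.approx(0.95, abs=0.02)

    def test_empty_genome_rejected(self):
        with pytest.raises(AlignmentInputError):
            GenomeIndex({})

    def test_query_shorter_than_seed_rejected(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
        with pytest.raises(AlignmentInputError):
            map_flank("ACGTACGT", genome)

    def test_hits_sorted_by_score(self, rng):
        backbone = "".join(rng.choice(list("ACGT"), 30000))
        insert = "".join(rng.choice(list("ACGT"), 300))
        decayed = _mutate(insert, 30, rng)
        genome = {"chr1": backbone[:10000] + insert + backbone[10000:20000] + decayed + backbone[20000:]}
        hits = map_flank(insert, genome)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)
        assert hits[0].target_span[0] == 10000
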