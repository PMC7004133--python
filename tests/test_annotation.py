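"""Structural LTR detection, element filtering and superfamily classification."""

import numpy as np
import pytest

from tedyn.align import GenomeIndex
from tedyn.annotation import (
    DomainHit,
    LTRElement,
    MITECopy,
    classify_superfamily,
    detect_ltr_candidates,
    filter_elements,
    gap_fraction,
    mite_full_length_filter,
    tandem_fraction,
)
from tedyn.simulate import SimConfig, simulate_genome_pair


def _random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), n))


def _plant(backbone, pos, element):
    return backbone[:pos] + element + backbone[pos:]


def _mutate(seq, frac, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)


class TestDetector:
    def test_identical_ltrs_exact_boundaries(self, rng):
        ltr = _random_dna(500, rng)
        internal = _random_dna(2000, rng)
        genome = {"chr1": _plant(_random_dna(30000, rng), 12000, ltr + internal + ltr)}
        cands = detect_ltr_candidates(genome)
        assert len(cands) == 1
        el = cands[0]
        assert abs(el.span[0] - 12000) <= 5
        assert abs(el.span[1] - 15000) <= 5
        assert abs((el.ltr5_span[1] - el.ltr5_span[0]) - 500) <= 10

    def test_no_repeats_gives_empty(self, rng):
        assert detect_ltr_candidates({"chr1": _random_dna(20000, rng)}) == []

    def test_heavily_diverged_ltrs_not_detected(self, rng):
        """LTR pairs at 30% divergence sit far below the 0.85 identity floor."""
        ltr = _random_dna(500, rng)
        element = ltr + _random_dna(2000, rng) + _mutate(ltr, 0.30, rng)
        genome = {"chr1": _plant(_random_dna(30000, rng), 12000, element)}
        assert detect_ltr_candidates(genome) == []

    def test_tsd_recorded(self, rng):
        backbone = _random_dna(30000, rng)
        ltr = _random_dna(500, rng)
        tsd = backbone[12000:12005]
        genome = {"chr1": backbone[:12000] + tsd + ltr + _random_dna(2000, rng) + ltr + backbone[12000:]}
        cands = detect_ltr_candidates(genome)
        assert len(cands) == 1
        assert cands[0].tsd == tsd

    def test_recall_and_precision_on_simulated_genome(self):
        """>= 90% recall and precision for planted elements with LTR
        divergence <= 10% (ages up to ~5 Mya at r = 1e-8)."""
        cfg = SimConfig(
            seed=99, genome_length=400_000, n_conserved=0, n_specific_a=20,
            n_specific_b=0, n_partial_a_in_b=0, n_partial_b_in_a=0,
            min_spacing=16_000,
        )
        sim = simulate_genome_pair(cfg)
        cands = detect_ltr_candidates(sim.genome_a)
        truth_spans = [
            (r.start_a, r.end_a) for r in sim.truth.elements.itertuples() if r.present_a
        ]
        matched = set()
        false_pos = 0
        for c in cands:
            hit = next(
                (
                    i for i, (s, e) in enumerate(truth_spans)
                    if min(e, c.span[1]) - max(s, c.span[0]) > 0.8 * (e - s)
                ),
                None,
            )
            if hit is None:
                false_pos += 1
            else:
                matched.add(hit)
        assert len(matched) / len(truth_spans) >= 0.9
        assert (len(cands) - false_pos) / max(1, len(cands)) >= 0.9


def _element(genome, element_id="e1", span=(1000, 4000), ltr=500):
    s, e = span
    return LTRElement(
        element_id=element_id, sequence_id="chr1", span=span,
        ltr5_span=(s, s + ltr), ltr3_span=(e - ltr, e), internal_span=(s + ltr, e - ltr),
    )


class TestFilterElements:
    def _genome_with_copies(self, rng, n_copies=3):
        backbone = _random_dna(60000, rng)
        elem = _random_dna(3000, rng)
        seq = backbone
        spans = []
        for i in range(n_copies):
            # each insertion lands after all previous ones, so earlier
            # coordinates are final
            pos = 10000 + i * 15000
            seq = seq[:pos] + elem + seq[pos:]
            spans.append((pos, pos + 3000))
        return {"chr1": seq}, spans

    def test_multicopy_coding_element_kept(self, rng):
        genome, spans = self._genome_with_copies(rng)
        el = _element(genome, span=spans[0])
        domains = {"e1": [DomainHit("RT", (600, 900))]}
        kept, rejected = filter_elements([el], genome, domains)
        assert [k.element_id for k in kept] == ["e1"]
        assert rejected == []

    def test_single_copy_element_rejected(self, rng):
        genome = {"chr1": _random_dna(40000, rng)}
        el = _element(genome, span=(10000, 13000))
        domains = {"e1": [DomainHit("RT", (600, 900))]}
        kept, rejected = filter_elements([el], genome, domains)
        assert kept == []
        assert rejected[0][1] == "single_hit"

    def test_non_coding_rejected(self, rng):
        genome, spans = self._genome_with_copies(rng)
        el = _element(genome, span=spans[0])
        kept, rejected = filter_elements([el], genome, {}, check_single_hit=False)
        assert rejected[0][1] == "non_coding"

    def test_gap_rich_rejected(self, rng):
        seq = list(_random_dna(40000, rng))
        seq[10500:11000] = "N" * 500  # ~17% of a 3-kb element
        genome = {"chr1": "".join(seq)}
        el = _element(genome, span=(10000, 13000))
        domains = {"e1": [DomainHit("RT", (600, 900))]}
        kept, rejected = filter_elements([el], genome, domains, check_single_hit=False)
        assert rejected[0][1] == "gap_fraction"

    def test_tandem_body_rejected(self, rng):
        genome = {"chr1": _random_dna(10000, rng) + "AT" * 1500 + _random_dna(10000, rng)}
        el = _element(genome, span=(10000, 13000))
        domains = {"e1": [DomainHit("RT", (600, 900))]}
        kept, rejected = filter_elements([el], genome, domains, check_single_hit=False)
        assert rejected[0][1] == "tandem_fraction"

    def test_unknown_element_in_domain_table_raises(self, rng):
        genome = {"chr1": _random_dna(20000, rng)}
        el = _element(genome, span=(1000, 4000))
        with pytest.raises(ValueError, match="unknown"):
            filter_elements([el], genome, {"ghost": []}, check_single_hit=False)

    def test_partition_and_idempotence(self, rng):
        genome, spans = self._genome_with_copies(rng)
        elements = [_element(genome, f"e{i}", span) for i, span in enumerate(spans)]
        domains = {"e0": [DomainHit("RT", (600, 900))], "e1": []}
        kept, rejected = filter_elements(elements, genome, domains, check_single_hit=False)
        assert len(kept) + len(rejected) == len(elements)
        domains2 = {k: v for k, v in domains.items() if k in {e.element_id for e in kept}}
        kept2, rejected2 = filter_elements(kept, genome, domains2, check_single_hit=False)
        assert [k.element_id for k in kept2] == [k.element_id for k in kept]
        assert rejected2 == []


class TestClassifySuperfamily:
    def _hits(self, order, strand="+"):
        hits = []
        pos = 600
        for d in order:
            hits.append(DomainHit(d, (pos, pos + 200), strand))
            pos += 250
        return hits

    def test_copia_order(self):
        el = _element({}, span=(0, 3000))
        classify_superfamily(el, self._hits(["GAG", "PR", "INT", "RT", "RH"]))
        assert (el.superfamily, el.completeness) == ("Copia", "complete")

    def test_gypsy_order(self):
        el = _element({}, span=(0, 3000))
        classify_superfamily(el, self._hits(["GAG", "PR", "RT", "RH", "INT"]))
        assert (el.superfamily, el.completeness) == ("Gypsy", "complete")

    def test_rt_only_unclassified_incomplete(self):
        el = _element({}, span=(0, 3000))
        classify_superfamily(el, self._hits(["RT"]))
        assert (el.superfamily, el.completeness) == ("unclassified", "incomplete")

    @pytest.mark.parametrize("order,expected", [
        (["GAG", "PR", "INT", "RT", "RH"], "Copia"),
        (["GAG", "PR", "RT", "RH", "INT"], "Gypsy"),
    ])
    def test_strand_invariance(self, order, expected):
        """Hits on the minus strand are mirrored before ordering."""
        el_plus = _element({}, span=(0, 3000))
        classify_superfamily(el_plus, self._hits(order, "+"))
        el_minus = _element({}, span=(0, 3000))
        # on '-' the 5'->3' coding order is the reverse of element coordinates
        classify_superfamily(el_minus, self._hits(list(reversed(order)), "-"))
        assert el_plus.superfamily == el_minus.superfamily == expected


class TestMiteFilter:
    @pytest.mark.parametrize("copy_len,kept", [
        (239, False),  # below 0.8 * 300
        (240, True),   # boundary, closed interval
        (290, True),
        (360, True),   # boundary, 1.2 * 300
        (361, False),
    ])
    def test_consensus_band(self, copy_len, kept):
        copy = MITECopy("fam1", "chr1", (1000, 1000 + copy_len), consensus_length=300)
        assert (mite_full_length_filter([copy]) == [copy]) is kept

    def test_zero_consensus_rejected(self):
        copy = MITECopy("fam1", "chr1", (0, 100), consensus_length=0)
        with pytest.raises(ValueError):
            mite_full_length_filter([copy])


class TestSequenceStats:
    def test_tandem_fraction_of_microsatellite(self):
        assert tandem_fraction("AT" * 100) > 0.9

    def test_tandem_fraction_of_random(self, rng):
        assert tandem_fraction(_random_dna(2000, rng)) < 0.2

    def test_gap_fraction(self):
        assert gap_fraction("ACGTNNNACGT" + "N" * 0) == pytest.approx(3 / 11)
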