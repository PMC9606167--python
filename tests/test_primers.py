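"""Degenerate expansion, binding-site search and in-silico PCR.

The brute-force oracle used throughout enumerates every non-degenerate
expansion and scores each window with match_count; the production scanner
must agree with it exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markerscan import (
    DegeneratePrimer,
    KNOWN_PAIRS,
    PrimerPair,
    SequenceCollection,
    SequenceRecord,
    amplifiability_summary,
    expand_degenerate,
    find_binding_sites,
    in_silico_pcr,
    match_count,
    reverse_complement,
)
from markerscan.primers import PrimerError
from markerscan.seqio import IUPAC_CODES

GYRA3 = KNOWN_PAIRS["gyrA3"]


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestExpandDegenerate:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", {"ACGT"}),
        ("AY", {"AC", "AT"}),
    ])
    def test_small_examples(self, seq, expected):
        assert expand_degenerate(DegeneratePrimer("p", seq)) == expected

    @pytest.mark.parametrize("primer,card", [
        (GYRA3.forward, 72),   # D*H*N*Y = 3*3*4*2
        (GYRA3.reverse, 8),    # M*W*K = 2*2*2
    ])
    def test_cardinality_vs_brute_force(self, primer, card):
        variants = expand_degenerate(primer)
        assert len(variants) == card
        # independent oracle: product of per-position degeneracies
        prod = 1
        for c in primer.seq:
            prod *= len(IUPAC_CODES[c])
        assert len(variants) == prod
        assert all(set(v) <= set("ACGT") for v in variants)
        assert all(
            all(b in IUPAC_CODES[c] for b, c in zip(v, primer.seq))
            for v in variants
        )

    @given(st.text(alphabet=sorted(IUPAC_CODES), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_cardinality_is_product_of_degeneracies(self, seq):
        prod = 1
        for c in seq:
            prod *= len(IUPAC_CODES[c])
        assert len(expand_degenerate(DegeneratePrimer("p", seq))) == prod


class TestMatchCount:
    @pytest.mark.parametrize("v,w,n", [
        ("ACGT", "ACGT", 4),
        ("ACGT", "ACGA", 3),
        ("ACGT", "NNNN", 0),
        ("ACGT", "ACRT", 3),  # ambiguity in the template never matches
    ])
    def test_examples(self, v, w, n):
        assert match_count(v, w) == n

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            match_count("ACG", "ACGT")


def brute_force_sites(primer, target_seq, min_match):
    """Oracle: enumerate every expansion at every window on both strands."""
    k = len(primer)
    fwd = sorted(expand_degenerate(primer))
    rev = [reverse_complement(v) for v in fwd]
    hits = []
    for i in range(len(target_seq) - k + 1):
        window = target_seq[i:i + k]
        if max(match_count(v, window) for v in fwd) >= min_match:
            hits.append((i + 1, "+"))
        if max(match_count(v, window) for v in rev) >= min_match:
            hits.append((i + 1, "-"))
    return sorted(hits)


class TestFindBindingSites:
    PRIMER = DegeneratePrimer("p20", "ACGTACGTACGTACGTACGT")

    def test_exact_hit(self, rng):
        target = SequenceRecord("t", random_dna(rng, 50) + self.PRIMER.seq
                                + random_dna(rng, 50))
        sites = find_binding_sites(self.PRIMER, target, 18)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) >= 1 and plus[0].matched == 20

    def test_three_substitutions_kill_the_site(self):
        core = list(self.PRIMER.seq)
        for i in (2, 9, 16):
            core[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[core[i]]
        target = SequenceRecord("t", "GG" + "".join(core) + "GG")
        assert find_binding_sites(self.PRIMER, target, 18) == []

    def test_degenerate_site_via_variant(self):
        primer = DegeneratePrimer("ay", "AY")
        sites = find_binding_sites(primer, SequenceRecord("t", "GGAT"), 2)
        plus = [s for s in sites if s.strand == "+"]
        assert any(s.start == 3 and s.end == 4 and s.variant == "AT" for s in plus)

    def test_target_shorter_than_primer(self):
        assert find_binding_sites(self.PRIMER, SequenceRecord("t", "ACGT"), 2) == []

    def test_agrees_with_brute_force_oracle(self, rng):
        primer = DegeneratePrimer("deg", "ACGYACRTWC")
        for _ in range(20):
            seq = random_dna(rng, 60)
            got = sorted((s.start, s.strand)
                         for s in find_binding_sites(primer, SequenceRecord("t", seq), 8))
            assert got == brute_force_sites(primer, seq, 8)

    def test_lowering_min_match_never_removes_sites(self, rng):
        seq = random_dna(rng, 300)
        target = SequenceRecord("t", seq)
        strict = {(s.start, s.strand)
                  for s in find_binding_sites(GYRA3.forward, target, 14)}
        loose = {(s.start, s.strand)
                 for s in find_binding_sites(GYRA3.forward, target, 10)}
        assert strict <= loose

    def test_contiguous_and_anchor_options_are_stricter(self, rng):
        seq = random_dna(rng, 400)
        target = SequenceRecord("t", seq)
        base = {(s.start, s.strand)
                for s in find_binding_sites(GYRA3.forward, target, 10)}
        contig = {(s.start, s.strand)
                  for s in find_binding_sites(GYRA3.forward, target, 10,
                                              contiguous=True)}
        anchored = {(s.start, s.strand)
                    for s in find_binding_sites(GYRA3.forward, target, 10,
                                                anchor_3prime=3)}
        assert contig <= base and anchored <= base


def build_template(rng, pair, pad5=100, insert=460, pad3=40):
    """pad + exact forward variant + insert + revcomp(exact reverse variant) + pad."""
    fv = min(expand_degenerate(pair.forward))
    rv = min(expand_degenerate(pair.reverse))
    return (random_dna(rng, pad5) + fv + random_dna(rng, insert)
            + reverse_complement(rv) + random_dna(rng, pad3))


class TestInSilicoPcr:
    def test_constructed_single_amplicon(self, rng):
        seq = build_template(rng, GYRA3)
        amps = in_silico_pcr(GYRA3, SequenceRecord("t", seq))
        assert len(amps) == 1
        amp = amps[0]
        assert amp.start == 101
        assert amp.end == 101 + 20 + 460 + 20 - 1
        assert amp.seq == seq[amp.start - 1:amp.end]
        assert len(amp.insert) == 460

    def test_forward_site_only_is_not_amplifiable(self, rng):
        fv = min(expand_degenerate(GYRA3.forward))
        seq = random_dna(rng, 100) + fv + random_dna(rng, 400)
        assert in_silico_pcr(GYRA3, SequenceRecord("t", seq)) == []

    def test_two_forward_sites_give_two_amplicons(self, rng):
        fv = min(expand_degenerate(GYRA3.forward))
        rv = min(expand_degenerate(GYRA3.reverse))
        seq = (random_dna(rng, 50) + fv + random_dna(rng, 150) + fv
               + random_dna(rng, 200) + reverse_complement(rv) + random_dna(rng, 30))
        amps = in_silico_pcr(GYRA3, SequenceRecord("t", seq))
        assert len(amps) == 2
        assert amps[0].start < amps[1].start and amps[0].end == amps[1].end

    def test_length_bounds_filter(self, rng):
        seq = build_template(rng, GYRA3, insert=460)
        tight = PrimerPair(name="tight", forward=GYRA3.forward,
                           reverse=GYRA3.reverse, min_match=18,
                           min_amplicon_len=100, max_amplicon_len=400)
        assert in_silico_pcr(tight, SequenceRecord("t", seq)) == []

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(30):
            seq = build_template(rng, GYRA3, pad5=int(rng.integers(30, 120)),
                                 insert=int(rng.integers(200, 500)))
            fwd = in_silico_pcr(GYRA3, SequenceRecord("t", seq))
            rev = in_silico_pcr(GYRA3, SequenceRecord("t", reverse_complement(seq)))
            assert sorted(a.seq for a in fwd) == sorted(a.seq for a in rev)
            L = len(seq)
            assert sorted((L - a.end + 1, L - a.start + 1) for a in fwd) == \
                sorted((a.start, a.end) for a in rev)

    def test_raising_max_len_never_removes_amplicons(self, rng):
        seq = build_template(rng, GYRA3)
        small = PrimerPair(name="s", forward=GYRA3.forward, reverse=GYRA3.reverse,
                           min_match=18, max_amplicon_len=600)
        big = PrimerPair(name="b", forward=GYRA3.forward, reverse=GYRA3.reverse,
                         min_match=18, max_amplicon_len=3000)
        got_small = {(a.start, a.end) for a in in_silico_pcr(small, SequenceRecord("t", seq))}
        got_big = {(a.start, a.end) for a in in_silico_pcr(big, SequenceRecord("t", seq))}
        assert got_small <= got_big


class TestAmplifiabilitySummary:
    def test_all_amplifiable(self, rng):
        recs = []
        for i, sp in enumerate(["Species A", "Species A", "Species B"]):
            recs.append(SequenceRecord(id=f"g{i}", seq=build_template(rng, GYRA3),
                                       taxon_label=sp))
        summ = amplifiability_summary(SequenceCollection(recs), GYRA3)
        assert summ.n_species_matched == 2
        assert summ.n_sequences_matched == 3

    def test_nothing_amplifiable(self, rng):
        recs = [SequenceRecord(id=f"g{i}", seq=random_dna(rng, 300),
                               taxon_label=f"Species {i}") for i in range(3)]
        summ = amplifiability_summary(SequenceCollection(recs), GYRA3)
        assert summ.n_species_matched == 0 and summ.n_sequences_matched == 0

    def test_synthetic_truth(self, small_community):
        """Construction plants compatible sites in 4 of 6 species."""
        coll = small_community.collections["gyrA"]
        summ = amplifiability_summary(coll, KNOWN_PAIRS["gyrA3"])
        assert summ.n_species_matched == 4
        assert summ.n_sequences_matched == 12  # 4 species x 3 strains


class TestValidation:
    def test_bad_primer_characters(self):
        with pytest.raises(PrimerError):
            DegeneratePrimer("bad", "ACGX")

    def test_min_match_exceeding_primer_length(self):
        with pytest.raises(PrimerError):
            PrimerPair(name="p", forward=DegeneratePrimer("f", "ACGT"),
                       reverse=DegeneratePrimer("r", "ACGT"), min_match=5)
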