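"""Digest/anneal/ligate simulator and the mock vector."""

import pytest

from mirab.cloning import (
    ENZYMES,
    AnnealingError,
    Fragment,
    StickyEnd,
    anneal,
    assemble_construct,
    canonical_rotation,
    circular_equal,
    digest,
    ligate,
    make_mock_vector,
    screen_sites,
)
from mirab.oligo_design import OligoPair, design_oligos, parse_oligos
from mirab.seqcore import DnaSeq, revcomp_str


class TestEnzymeGeometry:
    def test_bamhi_five_prime_gatc(self):
        enz = ENZYMES["BamHI"]
        assert enz.polarity == "five_prime" and enz.overhang == "GATC"

    def test_apai_three_prime_ggcc(self):
        enz = ENZYMES["ApaI"]
        assert enz.polarity == "three_prime" and enz.overhang == "GGCC"

    def test_offsets_consistent_with_oligo_layout(self, bundled_pairs):
        # designed top oligos begin GATCC (BamHI half-site) and end with an
        # unpaired GGCC tail (ApaI half-site): the duplex ends produced by
        # annealing must match the ends a double digest produces.
        duplex = anneal(bundled_pairs[0].top, bundled_pairs[0].bottom)
        site = DnaSeq("AAAA" + "GGATCC" + "AAAA" + "GGGCCC" + "AAAA")
        frags = digest(site, [ENZYMES["BamHI"], ENZYMES["ApaI"]])
        middle = frags[1]
        assert middle.left_end == duplex.left_end
        assert middle.right_end == duplex.right_end

    def test_blunt_cutter(self):
        assert ENZYMES["PmeI"].polarity == "blunt" and ENZYMES["PmeI"].overhang == ""


class TestDigest:
    def test_circular_k_sites_k_fragments(self, mock_vector):
        vec, _ = mock_vector
        frags = digest(vec, ["BamHI", "ApaI"])
        assert len(frags) == 2
        lengths = sorted(len(f) for f in frags)
        assert lengths[0] == 810  # stuffer fragment: 800 + 5 + 5

    def test_linear_k_sites_k_plus_one(self):
        seq = DnaSeq("AAAA" + "GGATCC" + "AAAA" + "GGATCC" + "AAAA")
        frags = digest(seq, ["BamHI"])
        assert len(frags) == 3
        assert frags[0].left_end.polarity == "blunt"
        assert frags[1].left_end == StickyEnd("five_prime", "GATC")

    def test_zero_sites_returned_uncut(self):
        seq = DnaSeq("AAAATTTT", topology="circular")
        frags = digest(seq, ["BamHI"])
        assert len(frags) == 1 and frags[0].topology == "circular"

    def test_digest_religate_round_trip(self, mock_vector):
        vec, _ = mock_vector
        frags = digest(vec, ["BamHI", "ApaI"])
        products = ligate(frags)
        assert any(circular_equal(p.top, vec.bases) for p in products)

    def test_five_and_three_prime_overhang_bases(self):
        seq = DnaSeq("TTG" + "GATCCAAAGGGCC" + "CTT")
        frags = digest(seq, ["BamHI", "ApaI"])
        assert [len(f) for f in frags] == [3, 13, 3]
        mid = frags[1]
        assert mid.top.startswith("GATC") and mid.top.endswith("GGCC")
        assert mid.core == "CAAAG"  # double-stranded part excludes protrusions


class TestAnneal:
    def test_table_pair_gives_bamhi_apai_overhangs(self, pair_by_name):
        p = pair_by_name["CD4_sh1_Human"]
        duplex = anneal(p.top, p.bottom)
        assert duplex.left_end == StickyEnd("five_prime", "GATC")
        assert duplex.right_end == StickyEnd("three_prime", "GGCC")

    def test_full_complement_is_blunt(self):
        duplex = anneal("ACGTACGT", revcomp_str("ACGTACGT"))
        assert duplex.left_end.polarity == "blunt"
        assert duplex.right_end.polarity == "blunt"

    def test_mismatched_bottom_raises(self, pair_by_name):
        p = pair_by_name["CD4_sh1_Human"]
        bad = "A" * len(p.bottom)
        with pytest.raises(AnnealingError):
            anneal(p.top, bad)

    def test_flip_is_involution(self, pair_by_name):
        p = pair_by_name["CD4_sh1_Human"]
        duplex = anneal(p.top, p.bottom)
        assert duplex.flipped().flipped() == duplex


class TestLigate:
    def test_backbone_plus_duplex_restores_both_junctions(self, mock_vector, bundled_pairs):
        vec, _ = mock_vector
        backbone = max(digest(vec, ["BamHI", "ApaI"]), key=len)
        duplex = anneal(bundled_pairs[0].top, bundled_pairs[0].bottom)
        products = ligate([backbone, duplex])
        with_insert = [p for p in products if duplex.core in p.top + p.top]
        assert len(with_insert) == 1
        construct = with_insert[0].as_dnaseq()
        from mirab.seqcore import find_motif

        assert len(find_motif(construct, "GGATCC")) == 1  # both sites restored
        assert len(find_motif(construct, "GGGCCC")) == 1

    def test_backbone_alone_cannot_self_circularize(self, mock_vector):
        vec, _ = mock_vector
        backbone = max(digest(vec, ["BamHI", "ApaI"]), key=len)
        assert ligate([backbone]) == []

    def test_two_insert_duplexes_form_no_circle(self, bundled_pairs):
        d1 = anneal(bundled_pairs[0].top, bundled_pairs[0].bottom)
        d2 = anneal(bundled_pairs[1].top, bundled_pairs[1].bottom)
        assert ligate([d1, d2]) == []

    def test_compatibility_is_symmetric(self):
        a = StickyEnd("five_prime", "GATC")
        b = StickyEnd("five_prime", "GATC")
        c = StickyEnd("three_prime", "GGCC")
        assert a.compatible(b) and b.compatible(a)
        assert not a.compatible(c) and not c.compatible(a)

    def test_full_cycle_recovers_cassette_for_every_pair(self, mock_vector, bundled_pairs):
        vec, _ = mock_vector
        for p in bundled_pairs:
            construct = assemble_construct(vec, p.top, p.bottom, name=p.name)
            frags = digest(construct.as_dnaseq(), ["BamHI", "ApaI"])
            insert = min(frags, key=len)
            recovered = parse_oligos(OligoPair(top=insert.top, bottom=insert.bottom))
            assert recovered == parse_oligos(p), p.name


class TestScreenAndMockVector:
    def test_table_duplex_cores_free_of_cloning_sites(self, bundled_pairs):
        for p in bundled_pairs:
            core = anneal(p.top, p.bottom).core
            table = screen_sites(DnaSeq(core), ["BamHI", "ApaI"])
            assert table.empty, p.name

    def test_mock_vector_has_one_site_per_enzyme(self, mock_vector):
        vec, ann = mock_vector
        table = screen_sites(vec, ["BamHI", "ApaI"])
        assert sorted(table.enzyme) == ["ApaI", "BamHI"]
        assert set(ann.feature) == {"backbone", "BamHI_site", "stuffer", "ApaI_site"}

    def test_mock_vector_deterministic(self):
        v1, _ = make_mock_vector(seed=5)
        v2, _ = make_mock_vector(seed=5)
        v3, _ = make_mock_vector(seed=6)
        assert v1 == v2 and v1 != v3

    def test_stuffer_length_bookkeeping(self):
        vec, _ = make_mock_vector(seed=5, stuffer_len=120)
        stuffer = min(digest(vec, ["BamHI", "ApaI"]), key=len)
        assert len(stuffer) == 130  # stuffer_len + 5 + 5 (GATCC.. ..GGGCC)

    def test_apai_hit_at_offset_zero(self):
        table = screen_sites(DnaSeq("GGGCCC"), ["ApaI"])
        assert list(table.offset) == [0]

    def test_canonical_rotation(self):
        assert canonical_rotation("BCA") == "ABC"
        assert circular_equal("ACGT", "GTAC")
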