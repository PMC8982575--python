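"""97-nt cassette validation and the two-oligo conversion layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirab.oligo_design import (
    CANONICAL_FLANK3,
    CANONICAL_FLANK5,
    CANONICAL_LOOP,
    LayoutError,
    OligoPair,
    ShRNAmirCassette,
    batch_design,
    design_oligos,
    parse_oligos,
    read_oligo_table,
    reconstruct_97,
    validate_97,
    write_oligo_table,
)
from mirab.seqcore import DnaSeq, revcomp_str

stem22 = st.text(alphabet="ACGT", min_size=22, max_size=22)


def random_cassette(sense, guide):
    return ShRNAmirCassette(
        flank5=CANONICAL_FLANK5,
        sense=sense,
        loop=CANONICAL_LOOP,
        guide=guide,
        flank3=CANONICAL_FLANK3,
    )


class TestLayoutConsensus:
    """The bundled table is the ground truth for the layout constants."""

    def test_single_consensus_across_all_pairs(self, bundled_pairs):
        assert {p.top[:6] for p in bundled_pairs} == {"GATCCG"}
        assert {p.top[69:] for p in bundled_pairs} == {"TGGGCC"}
        assert {p.top[28:47] for p in bundled_pairs} == {CANONICAL_LOOP}

    def test_bottom_is_revcomp_of_top_window(self, bundled_pairs):
        for p in bundled_pairs:
            assert p.bottom == revcomp_str(p.top[4:71])

    def test_length_arithmetic(self, bundled_pairs):
        for p in bundled_pairs:
            assert len(p.top) == 75 and len(p.bottom) == 67
            assert len(p.top) - len(p.bottom) == 8  # two 4-nt overhangs


class TestValidate97:
    def test_length_gate_reports_observed_length(self):
        report, cassette = validate_97("A" * 96)
        assert cassette is None
        assert any("expected 97 nt, got 96" in i.message for i in report.issues)

    def test_fas_sh1_reconstruction_validates_strict(self, pair_by_name):
        seq = reconstruct_97(parse_oligos(pair_by_name["FAS_sh1_Human"]))
        report, cassette = validate_97(seq, mode="strict")
        assert report.ok and cassette is not None
        assert cassette.loop == CANONICAL_LOOP

    def test_mutated_loop_strict_error_lenient_ok(self, pair_by_name):
        seq = reconstruct_97(parse_oligos(pair_by_name["FAS_sh1_Human"])).bases
        base = "A" if seq[45] != "A" else "C"
        mutated = seq[:45] + base + seq[46:]
        strict, _ = validate_97(mutated, mode="strict")
        lenient, cassette = validate_97(mutated, mode="lenient")
        assert not strict.ok and lenient.ok and cassette is not None

    def test_internal_site_warns_but_passes(self):
        sense = "GGATCC" + "A" * 16
        seq = reconstruct_97(random_cassette(sense, "T" * 22))
        report, cassette = validate_97(seq, mode="strict")
        assert report.ok and cassette is not None
        assert any(i.code == "internal_site" for i in report.issues)

    def test_alphabet_error(self):
        report, cassette = validate_97("N" * 97)
        assert cassette is None and not report.ok


class TestDesignOligos:
    def test_human_cd4_sh1_exact_strings(self, pair_by_name):
        pair = design_oligos(parse_oligos(pair_by_name["CD4_sh1_Human"]))
        assert pair.top == (
            "GATCCGACCTGATCATCAAGAATCTTAATAGTGAAGCCACAGATGTATTAAGATTCTTGATGATCAGGGTGGGCC"
        )
        assert pair.bottom == (
            "CACCCTGATCATCAAGAATCTTAATACATCTGTGGCTTCACTATTAAGATTCTTGATGATCAGGTCG"
        )

    def test_all_bundled_rows_regenerated_exactly(self, bundled_pairs):
        for p in bundled_pairs:
            q = design_oligos(parse_oligos(p))
            assert (q.top, q.bottom) == (p.top, p.bottom), p.name

    @settings(max_examples=100, derandomize=True)
    @given(stem22, stem22)
    def test_layout_property_random_cassettes(self, sense, guide):
        pair = design_oligos(random_cassette(sense, guide))
        # independent slicing oracle
        assert len(pair.top) == 75 and len(pair.bottom) == 67
        assert pair.bottom == revcomp_str(pair.top[4:71])
        assert pair.top[6:28] == sense and pair.top[47:69] == guide


class TestParseOligos:
    def test_fas_sh1_regions(self, pair_by_name):
        c = parse_oligos(pair_by_name["FAS_sh1_Human"])
        assert c.sense == "CAGTGTTTGAAAAGATTCTTAA"
        assert c.loop == "TAGTGAAGCCACAGATGTA"
        assert c.guide == "TTAAGAATCTTTTCAAACACTA"

    def test_round_trip_for_every_bundled_cassette(self, bundled_pairs):
        for p in bundled_pairs:
            c = parse_oligos(p)
            assert parse_oligos(design_oligos(c)) == c

    def test_bottom_mismatch_reports_position(self, pair_by_name):
        p = pair_by_name["FAS_sh1_Human"]
        bad = p.bottom[:10] + ("A" if p.bottom[10] != "A" else "C") + p.bottom[11:]
        with pytest.raises(LayoutError, match="position 10"):
            parse_oligos(OligoPair(top=p.top, bottom=bad))

    def test_bad_prefix_is_layout_error(self, pair_by_name):
        p = pair_by_name["FAS_sh1_Human"]
        with pytest.raises(LayoutError, match="start"):
            parse_oligos(OligoPair(top="T" + p.top[1:], bottom=p.bottom))


class TestReconstruct97:
    def test_length_and_strict_validation(self, bundled_cassettes):
        for c in bundled_cassettes:
            seq = reconstruct_97(c)
            assert len(seq) == 97
            report, c2 = validate_97(seq, mode="strict")
            assert report.ok and c2 == c

    def test_bad_field_lengths_rejected(self):
        with pytest.raises(ValueError):
            ShRNAmirCassette("", "A" * 22, CANONICAL_LOOP, "A" * 22, "")


class TestBatchDesign:
    def test_mixed_batch_statuses(self, bundled_cassettes):
        records = [
            (f"ok{i}", reconstruct_97(c)) for i, c in enumerate(bundled_cassettes[:3])
        ] + [("short", DnaSeq("ACGT"))]
        rows = batch_design(records)
        assert [r["status"] for r in rows] == ["ok"] * 3 + ["error"]
        assert "expected 97" in rows[3]["message"]

    def test_thousand_random_inputs_all_convert(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        records = []
        for i in range(1000):
            sense = "".join(rng.choice(bases, 22))
            guide = "".join(rng.choice(bases, 22))
            records.append((f"r{i}", reconstruct_97(random_cassette(sense, guide))))
        rows = batch_design(records, mode="strict")
        assert all(r["status"] == "ok" for r in rows)

    def test_output_tsv_round_trips_through_parse(self, tmp_path, bundled_cassettes):
        records = [(c.name or f"c{i}", reconstruct_97(c))
                   for i, c in enumerate(bundled_cassettes[:5])]
        rows = batch_design(records)
        path = tmp_path / "out.tsv"
        write_oligo_table(path, rows)
        reparsed = [parse_oligos(p) for p in read_oligo_table(path)]
        assert reparsed == bundled_cassettes[:5]
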