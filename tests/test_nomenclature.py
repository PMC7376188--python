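"""Bracket encoding, CE designation and canonical-name round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from strmps.locus_model import (
    FlankVariant,
    Interval,
    LocusConfig,
    TemplateSegment,
)
from strmps.nomenclature import (
    NomenclatureError,
    ParseError,
    SequenceAllele,
    allele_from_sequence,
    bracket_encode,
    ce_designation,
    format_isfg,
    parse_isfg,
    repeat_unit_count,
)


class TestBracketEncode:
    def test_interrupted_run_segments(self, loci):
        seq = "TATC" * 9 + "TGTC" + "TATC"
        structure = bracket_encode(seq, loci["D7S820"])
        assert structure.render() == "[TATC]9 TGTC TATC"

    def test_partial_interruption(self, loci):
        seq = "ATCT" * 5 + "ATGT" + "ATCT" * 2 + "ATC" + "ATCT" * 11
        structure = bracket_encode(seq, loci["D6S1043"])
        assert structure.render() == "[ATCT]5 ATGT [ATCT]2 ATC [ATCT]11"

    def test_single_motif_is_unbracketed_singleton(self, loci):
        structure = bracket_encode("GATA", loci["D16S539"])
        assert structure.render() == "GATA"
        assert structure.segments[0].count == 1

    def test_expansion_identity(self, loci):
        seq = "TATC" * 7 + "TCTC" + "TATC" * 3
        structure = bracket_encode(seq, loci["D7S820"])
        assert structure.expand() == seq

    def test_non_nucleotide_rejected(self, loci):
        with pytest.raises(NomenclatureError, match="non-nucleotide"):
            bracket_encode("TATCX", loci["D7S820"])

    def test_shorter_than_motif_rejected(self, loci):
        with pytest.raises(NomenclatureError, match="shorter"):
            bracket_encode("TAT", loci["D7S820"])

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_random_motif_concatenations_round_trip(self, loci, data):
        """expand(bracket_encode(s)) == s on random motif concatenations."""
        cfg = loci["D21S11"]
        motifs = ["TCTA", "TCTG", "TA", "TCA"]
        parts = data.draw(st.lists(
            st.tuples(st.sampled_from(motifs), st.integers(1, 8)),
            min_size=2, max_size=4))
        seq = "".join(unit * count for unit, count in parts)
        if len(seq) < cfg.motif_len:
            return
        assert bracket_encode(seq, cfg).expand() == seq


class TestRepeatUnitCount:
    def test_compound_interrupted_count(self, loci, novel_rows):
        name = next(r["name"] for r in novel_rows
                    if r["name"].startswith("FGA [CE26]"))
        allele = parse_isfg(name, loci["FGA"])
        assert repeat_unit_count(allele.structure) == 26

    def test_lowercase_segments_not_counted(self, loci, novel_rows):
        name = next(r["name"] for r in novel_rows
                    if r["name"].startswith("D21S11 [CE28]"))
        allele = parse_isfg(name, loci["D21S11"])
        assert repeat_unit_count(allele.structure) == 28

    def test_empty_structure_counts_zero(self):
        from strmps.locus_model import RepeatStructure
        assert repeat_unit_count(RepeatStructure(())) == 0


def _anchor_config(name, unit, count, ce, start=1000):
    end = start + len(unit) * count - 1
    return LocusConfig(
        name=name, chrom_class="autosomal", chrom_label="1",
        repeat_region=Interval(start=start, end=end), motif_len=len(unit),
        reference_structure=(TemplateSegment(unit=unit, count=count,
                                             variable=True),),
        reference_ce=str(ce),
        flank_ranges={"upstream": Interval(start=start - 50, end=start - 1)})


class TestCeDesignation:
    def test_flanking_insertion_shifts_partial(self, loci):
        """One extra flanking nucleotide turns allele 10 into 10.1."""
        cfg = _anchor_config("D7S820", "TATC", 10, 10, start=84160226)
        ins = FlankVariant("insertion", 84160204, alt="A", sub_index=1)
        allele = allele_from_sequence("D7S820", "TATC" * 10, cfg, (ins,))
        assert str(ce_designation(allele, cfg)) == "10.1"

    def test_length_anchored_against_larger_reference(self, loci, novel_rows):
        """The 104-nt allele is CE 26 when anchored to the 108-nt CE-27 allele."""
        ce27 = next(r["name"] for r in novel_rows
                    if r["name"].startswith("FGA [CE27]"))
        anchor = parse_isfg(ce27, loci["FGA"])
        cfg = loci["FGA"].model_copy(update={
            "reference_structure": tuple(
                TemplateSegment(unit=s.unit if not s.lower else s.unit.lower(),
                                count=s.count, variable=s.count > 1)
                for s in anchor.structure.segments),
            "reference_ce": "27"})
        seq = "GGAA" * 2 + "GGAG" + "AAAG" * 16 + "AGAG" + "AAAG" + "AGAA" \
            + "AAAA" + "GAAA" * 3
        assert len(seq) == 104
        allele = allele_from_sequence("FGA", seq, cfg)
        assert str(ce_designation(allele, cfg)) == "26"

    def test_interrupted_microvariant(self):
        """79-nt interrupted allele vs a 64-nt CE-16 anchor gives 19.3."""
        cfg = _anchor_config("D6S1043", "ATCT", 16, 16, start=91740225)
        seq = "ATCT" * 5 + "ATGT" + "ATCT" * 2 + "ATC" + "ATCT" * 11
        assert len(seq) == 79
        allele = allele_from_sequence("D6S1043", seq, cfg)
        assert str(ce_designation(allele, cfg)) == "19.3"

    def test_reference_allele_equals_anchor(self, loci):
        for cfg in loci.values():
            allele = SequenceAllele(cfg.name, cfg.reference_repeat_structure())
            assert ce_designation(allele, cfg) == cfg.ce_anchor

    def test_substitution_does_not_change_ce(self, loci):
        cfg = loci["DXS8378"]
        plain = allele_from_sequence("DXS8378", "ATAG" * 10, cfg)
        sub = FlankVariant("substitution", 9402257, alt="G")
        with_sub = allele_from_sequence("DXS8378", "ATAG" * 10, cfg, (sub,))
        assert ce_designation(plain, cfg) == ce_designation(with_sub, cfg)

    def test_repeat_region_deletion_does_not_double_count(self, loci):
        """A deletion inside the repeat region is already reflected in the
        structure (shorter gap), so it must not shift the CE again."""
        cfg = loci["DYS448"]
        seq = "AGAGAT" * 11 + "N" * 36 + "AGAGAT" * 8
        deletion = FlankVariant.parse("22,218,995–22,219,000 DEL")
        allele = allele_from_sequence("DYS448", seq, cfg, (deletion,))
        assert str(ce_designation(allele, cfg)) == "18"

    def test_allele_shorter_than_representable(self):
        cfg = _anchor_config("LOC", "TATC", 3, 3)
        with pytest.raises(NomenclatureError, match="shorter than representable"):
            ce_designation(allele_from_sequence("LOC", "TATC", cfg),
                           cfg.model_copy(update={"reference_ce": "0"}))

    def test_unit_count_matches_ce_for_plain_reference_alleles(self, loci):
        """Where the structure is reference-patterned with an integer anchor,
        the CE whole equals the counted units (offset loci carry the
        difference entirely in their anchor)."""
        for cfg in loci.values():
            anchor = cfg.ce_anchor
            ref = cfg.reference_repeat_structure()
            if anchor.partial == 0 and not any(
                    s.gap or s.lower for s in ref.segments):
                assert ref.unit_count() == anchor.whole, cfg.name


class TestIsfgNames:
    def test_all_fixture_names_parse_and_reformat(self, loci, novel_rows):
        for row in novel_rows:
            cfg = loci[row["locus"]]
            allele = parse_isfg(row["name"], cfg)
            assert format_isfg(allele, cfg) == row["name"]

    def test_all_fixture_names_reencode_from_sequence(self, loci, novel_rows):
        for row in novel_rows:
            cfg = loci[row["locus"]]
            allele = parse_isfg(row["name"], cfg)
            rebuilt = SequenceAllele(
                row["locus"], bracket_encode(allele.structure.expand(), cfg),
                allele.flank_variants)
            assert format_isfg(rebuilt, cfg) == row["name"]

    def test_gap_and_deletion_name(self, loci):
        allele = parse_isfg(
            "DYS448 [CE17]-ChrY-GRCh38 22,218,923–22,219,078 "
            "[AGAGAT]10 N42 [AGAGAT]7", loci["DYS448"])
        gap = allele.structure.segments[1]
        assert gap.gap and gap.count == 42

    def test_lowercase_segment_parsed_as_uncounted(self, loci):
        allele = parse_isfg(
            "D21S11 [CE28]-Chr21-GRCh38 19,181,973–19,182,099 [TCTA]5 "
            "[TCTG]5 [TCTA]3 ta [TCTA]2 tca [TCTA]2 tccata [TCTA]11",
            loci["D21S11"])
        lowers = [s for s in allele.structure.segments if s.lower]
        assert [s.unit for s in lowers] == ["TA", "TCA", "TCCATA"]
        assert all(not s.counted for s in lowers)

    @pytest.mark.parametrize("bad,match", [
        ("D7S820 [CE10]-Chr7-GRCh38 84,160,226–84,160,277", "too few fields"),
        ("D7S820 [CE10-Chr7-GRCh38 84,160,226–84,160,277 [TATC]10",
         "malformed CE"),
        ("D7S820 [CE10]-Chr7-GRCh38 84,160,226+84,160,277 [TATC]10",
         "malformed coordinate"),
        ("D7S820 [CE11]-Chr7-GRCh38 84,160,226–84,160,277 [TATC]10",
         "inconsistent"),
    ])
    def test_malformed_names_rejected(self, loci, bad, match):
        with pytest.raises(ParseError, match=match):
            parse_isfg(bad, loci["D7S820"])

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_random_alleles_round_trip_through_names(self, loci, data):
        """parse_isfg(format_isfg(a)) == a for synthetic alleles."""
        cfg = loci["D7S820"]
        n_repeats = data.draw(st.integers(4, 13))
        seq = "TATC" * n_repeats
        if data.draw(st.booleans()):
            cut = data.draw(st.integers(4, max(5, len(seq) - 4)))
            seq = seq[:cut] + "TGTC" + seq[cut:]
        variants = []
        if data.draw(st.booleans()):
            variants.append(FlankVariant("substitution", 84160204, alt="A"))
        if data.draw(st.booleans()):
            variants.append(FlankVariant("insertion", 84160204, alt="A",
                                         sub_index=1))
        allele = allele_from_sequence("D7S820", seq, cfg, tuple(variants))
        name = format_isfg(allele, cfg)
        assert parse_isfg(name, cfg) == allele
        assert format_isfg(parse_isfg(name, cfg), cfg) == name
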