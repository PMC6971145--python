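"""Allele names, haplotype strings, registry stability and mosaics."""

import pytest
from hypothesis import given, strategies as st

from bfbl import SynthConfig, curate, generate, standard_fixture
from bfbl.naming import (
    AMBIGUOUS_BLB,
    NULL,
    AlleleName,
    HaplotypeRecord,
    NameConflictError,
    Registry,
    bfbl_name,
    detect_mosaic,
    haplotype_string,
    parse_allele_name,
    parse_haplotype_string,
)


class TestAlleleName:
    def test_canonical_rendering(self):
        assert AlleleName("BF2", 15, 2, 1).render() == "BF2*015:02:01"
        assert AlleleName("BLB1", 2).render() == "BLB1*002:01:01"
        assert AlleleName("BF1", 2, 1, 1, 3).render() == "BF1*002:01:01:03"

    @pytest.mark.parametrize(
        "name,expect",
        [
            (AlleleName("BF1", 2, 1, 1), "2"),
            (AlleleName("BF1", 5, 2, 1), "5:02"),
            (AlleleName("BF2", 30, 1, 1), "30"),
            (AlleleName("BF2", 15, 2, 3), "15:02:03"),
            (AlleleName("BLB2", 8, 1, 2), "8:01:02"),
        ],
    )
    def test_shorthand_drops_trailing_firsts(self, name, expect):
        assert name.shorthand() == expect

    def test_fields_must_be_positive(self):
        with pytest.raises(ValueError):
            AlleleName("BF1", 0)

    names = st.builds(
        AlleleName,
        locus=st.sampled_from(["BLB1", "BLB2", "BF1", "BF2"]),
        f1=st.integers(1, 199),
        f2=st.integers(1, 40),
        f3=st.integers(1, 40),
        f4=st.one_of(st.none(), st.integers(1, 40)),
    )

    @given(names)
    def test_parse_render_round_trip(self, name):
        assert parse_allele_name(name.render()) == name


class TestHaplotypeStrings:
    def test_null_token(self):
        hap = HaplotypeRecord(
            "h",
            slots={
                "BLB1": AlleleName("BLB1", 9),
                "BLB2": AlleleName("BLB2", 34),
                "BF1": NULL,
                "BF2": AlleleName("BF2", 33),
            },
        )
        assert haplotype_string(hap) == "9-34-null-33"

    def test_unknown_token(self):
        hap = HaplotypeRecord(
            "h", slots={"BF1": AlleleName("BF1", 9, 2), "BF2": AlleleName("BF2", 9)}
        )
        assert haplotype_string(hap) == "?-?-9:02-9"

    def test_ambiguous_blb_parentheses(self):
        hap = HaplotypeRecord(
            "h",
            slots={"BF1": AlleleName("BF1", 23, 2), "BF2": AlleleName("BF2", 38)},
            ambiguous_blb=AlleleName(AMBIGUOUS_BLB, 109),
        )
        assert haplotype_string(hap) == "(109-109)-23:02-38"

    @pytest.mark.parametrize("text", ["9-34-null-33", "?-?-9:02-9", "(109-109)-23:02-38"])
    def test_string_round_trip(self, text):
        assert haplotype_string(parse_haplotype_string(text)) == text

    def test_bfbl_name_is_bf2_shorthand(self):
        hap = HaplotypeRecord("h", slots={"BF2": AlleleName("BF2", 15, 2)})
        assert bfbl_name(hap) == "15:02"
        hap.provisional_suffix = "b"
        assert bfbl_name(hap) == "15:02b"


class TestRegistry:
    def test_rerun_on_identical_input_allocates_nothing(self, std_fixture):
        result1 = curate(std_fixture.records, std_fixture.evidence, null_slots=std_fixture.null_slots)
        assert result1.allocations
        result2 = curate(
            std_fixture.records,
            std_fixture.evidence,
            registry=result1.registry,
            null_slots=std_fixture.null_slots,
        )
        assert result2.allocations == []

    def test_superset_preserves_old_names_bit_identical(self, tmp_path):
        fx = standard_fixture()
        subset_haps = {"B2", "B4", "B5"}
        sub_records = [r for r in fx.records if r.haplotype in subset_haps]
        sub_ev = [e for e in fx.evidence if e.seq_id.split("_")[0] in subset_haps]
        r1 = curate(sub_records, sub_ev)
        r1.registry.save(tmp_path / "old")
        old_lines = set((tmp_path / "old" / "registry.tsv").read_text().splitlines())

        r2 = curate(fx.records, fx.evidence, registry=r1.registry, null_slots=fx.null_slots)
        r2.registry.save(tmp_path / "new")
        new_lines = set((tmp_path / "new" / "registry.tsv").read_text().splitlines())
        assert old_lines <= new_lines
        # and the full result still matches the expected catalogue
        for hap, expect in fx.expected_strings.items():
            assert r2.haplotype_string(hap) == expect

    def test_conflicting_allocation_is_hard_error(self):
        reg = Registry()
        reg.allocate("digest1", AlleleName("BF1", 2), "aa1")
        with pytest.raises(NameConflictError, match="BF1\\*002:01:01"):
            reg.allocate("digest1", AlleleName("BF1", 3), "aa1")

    def test_same_name_two_classes_is_hard_error(self):
        reg = Registry()
        reg.allocate("digest1", AlleleName("BF1", 2), "aa1")
        with pytest.raises(NameConflictError):
            reg.allocate("digest2", AlleleName("BF1", 2), "aa2")

    def test_save_load_round_trip(self, tmp_path, std_result):
        std_result.registry.save(tmp_path / "reg")
        back = Registry.load(tmp_path / "reg")
        assert {d: e.name for d, e in back.entries.items()} == {
            d: e.name for d, e in std_result.registry.entries.items()
        }
        assert set(back.haplotypes) == set(std_result.registry.haplotypes)


class TestHaplotypeIndependence:
    def test_identical_sequences_share_one_name(self, std_result):
        # B2, B6 and B8 carry the same BLB1 sequence: one class, one name
        assert (
            std_result.name_of("B2", "BLB1")
            == std_result.name_of("B6", "BLB1")
            == std_result.name_of("B8", "BLB1")
            == "BLB1*002:01:01"
        )

    def test_new_groups_number_from_thirty(self):
        gen = generate(SynthConfig(seed=4, pcr_error_rate=0.0))
        result = curate(gen.records, gen.evidence)
        f1s = sorted(e.name.f1 for e in result.registry.entries.values())
        assert f1s and min(f1s) >= 30 and max(f1s) < 101


class TestProvisionalSuffix:
    def test_shared_bf2_on_distinct_background_gets_letter(self, std_result):
        # B13 carries B4's BF2 allele on a background differing in BLB2
        assert std_result.bfbl_name("B4") == "4"
        assert std_result.bfbl_name("B13") == "4b"


class TestMosaic:
    def test_b19_attributed_to_b12_and_b15(self, std_result):
        report = detect_mosaic(std_result.haplotypes["B19"], std_result.registry)
        assert report.parents == ("B12", "B15")
        assert report.is_mosaic

    def test_registered_haplotype_is_its_own_single_parent(self, std_result):
        clone = HaplotypeRecord("copy-of-B2", slots=dict(std_result.haplotypes["B2"].slots))
        report = detect_mosaic(clone, std_result.registry)
        assert report.parents == ("B2",)
        assert not report.is_mosaic

    def test_planted_recombinant_donors_recovered(self):
        from bfbl.synth import RecombinantSpec

        gen = generate(
            SynthConfig(
                seed=12,
                pcr_error_rate=0.0,
                recombinants=(RecombinantSpec("R1", "H01", "H02", "BF2"),),
            )
        )
        result = curate(gen.records, gen.evidence)
        report = detect_mosaic(result.haplotypes["R1"], result.registry)
        assert report.parents is not None
        # each slot's group is attributed to the donor it came from
        for locus, parents in report.slot_parents.items():
            donor = "H02" if locus == "BF2" else "H01"
            assert donor in parents, f"slot {locus} not attributed to {donor}"
        # the minimal cover is no larger than the donor pair
        assert len(report.parents) <= 2
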