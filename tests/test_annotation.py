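import pytest

from prokit import fixtures
from prokit.annotation import (
    ConsistencyError,
    SiteAnnotation,
    add_custom_column,
    parse_feature_string,
    parse_uniprot_table,
    project_to_residues,
)


class TestFeatureParsing:
    def test_single_position_binding(self):
        anns, skipped = parse_feature_string('BINDING 46..46; /ligand="ATP";')
        assert not skipped
        (ann,) = anns
        assert (ann.feature_type, ann.start, ann.end) == ("binding", 46, 46)
        assert ann.qualifiers["ligand"] == "ATP"

    def test_position_without_range_syntax(self):
        (ann,), _ = parse_feature_string("ACT_SITE 120;")
        assert ann.start == ann.end == 120

    def test_region_span(self):
        (ann,), _ = parse_feature_string('REGION 9..236; /note="Interaction";')
        assert ann.feature_type == "region"
        assert ann.n_residues == 228

    def test_inverted_range_skipped_and_reported(self):
        anns, skipped = parse_feature_string('BINDING 10..5; /ligand="bad";')
        assert anns == []
        assert len(skipped) == 1 and "10..5" in skipped[0][1]

    def test_uncertain_positions_skipped_not_guessed(self):
        anns, skipped = parse_feature_string("REGION <1..29; REGION 30..40;")
        assert len(anns) == 1 and anns[0].start == 30
        assert len(skipped) == 1

    def test_multiple_features_one_cell(self):
        anns, _ = parse_feature_string(
            'BINDING 46; /ligand="ATP"; BINDING 93; /ligand="ATP"; '
            'BINDING 98..102; /ligand="Mg(2+)";'
        )
        assert [(a.start, a.end) for a in anns] == [(46, 46), (93, 93), (98, 102)]
        assert all(a.qualifiers["ligand"] for a in anns)

    def test_ptm_and_secondary_structure_mapping(self):
        anns, _ = parse_feature_string(
            'MOD_RES 641; /note="Phosphoserine"; HELIX 10..25;'
        )
        assert anns[0].feature_type == "ptm"
        assert anns[1].feature_type == "secondary_structure"
        assert anns[1].qualifiers["kind"] == "helix"

    def test_disordered_region_classified_as_disorder(self):
        (ann,), _ = parse_feature_string('REGION 225..278; /note="Disordered";')
        assert ann.feature_type == "disorder"


class TestTableParsing:
    def test_missing_header_rejected(self):
        with pytest.raises(Exception, match="Entry|empty"):
            parse_uniprot_table("P12345\t100\n")

    def test_synthetic_round_trip(self):
        tsv, truth = fixtures.make_synthetic_uniprot_tsv(
            n_proteins=2, features_per_protein=5, seed=11)
        records = parse_uniprot_table(tsv)
        assert set(records) == set(truth)
        for acc, expected in truth.items():
            got = sorted(records[acc].annotations,
                         key=lambda a: (a.start, a.end, a.feature_type))
            exp = sorted(expected,
                         key=lambda a: (a.start, a.end, a.feature_type))
            assert [(a.feature_type, a.start, a.end, a.qualifiers)
                    for a in got] == \
                   [(a.feature_type, a.start, a.end, a.qualifiers)
                    for a in exp]

    def test_malformed_feature_skips_exactly_one(self):
        tsv, truth = fixtures.make_synthetic_uniprot_tsv(
            seed=3, features_per_protein=4, inject_malformed=True)
        with pytest.warns(UserWarning, match="skipped"):
            records = parse_uniprot_table(tsv)
        (record,) = records.values()
        assert len(record.annotations) == 4
        assert len(record.skipped) == 1

    def test_deterministic_generation(self):
        a = fixtures.make_synthetic_uniprot_tsv(seed=7)
        b = fixtures.make_synthetic_uniprot_tsv(seed=7)
        assert a[0] == b[0]


class TestProjection:
    def test_region_covers_exact_residue_range(self):
        table = project_to_residues(
            [SiteAnnotation("region", 9, 236)], sequence_length=732)
        covered = [i for i in range(1, 733) if table.entry("region", i)]
        assert covered == list(range(9, 237))
        assert len(covered) == 228

    def test_empty_annotation_list(self):
        table = project_to_residues([], 50)
        assert table.columns == {}
        assert table.sequence_length == 50

    def test_overlapping_regions_stack(self):
        a = SiteAnnotation("region", 271, 616)
        b = SiteAnnotation("region", 284, 620)
        table = project_to_residues([a, b], 732)
        both = [i for i in range(1, 733) if len(table.entry("region", i)) == 2]
        assert both == list(range(284, 617))

    def test_annotation_past_sequence_rejected(self):
        with pytest.raises(ConsistencyError, match="region"):
            project_to_residues([SiteAnnotation("region", 9, 236)], 100)

    def test_total_entries_equals_sum_of_spans(self):
        tsv, truth = fixtures.make_synthetic_uniprot_tsv(
            features_per_protein=8, seed=5)
        anns = next(iter(truth.values()))
        table = project_to_residues(anns, 200)
        total = sum(len(entry) for col in table.columns.values()
                    for entry in col)
        assert total == sum(a.n_residues for a in anns)

    def test_monotone_under_addition(self):
        base = [SiteAnnotation("binding", 5, 5)]
        extra = base + [SiteAnnotation("binding", 3, 8)]
        t1 = project_to_residues(base, 20)
        t2 = project_to_residues(extra, 20)
        for i in range(1, 21):
            before = {id(a) for a in t1.entry("binding", i)}
            after = {id(a) for a in t2.entry("binding", i)}
            assert len(after) >= len(before)

    def test_annotations_recoverable_from_table(self):
        ann = SiteAnnotation("ptm", 12, 12, {"note": "Phosphoserine"})
        table = project_to_residues([ann], 20)
        assert table.annotations_of("ptm") == [ann]
        assert table.covered_residues(ann) == [12]


class TestCustomColumns:
    def test_correct_length_retrievable(self):
        table = project_to_residues([], 4)
        add_custom_column(table, "intensity", [1.0, 2.0, 3.0, 4.0])
        assert table.entry("intensity", 3) == 3.0

    def test_length_mismatch_rejected(self):
        table = project_to_residues([], 4)
        with pytest.raises(ConsistencyError, match="expected 4"):
            add_custom_column(table, "intensity", [1.0, 2.0, 3.0])

    def test_replacement_warns(self):
        table = project_to_residues([], 2)
        add_custom_column(table, "x", [1, 2])
        with pytest.warns(UserWarning, match="replacing"):
            add_custom_column(table, "x", [3, 4])
        assert table.columns["x"] == [3, 4]
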