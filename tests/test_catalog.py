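"""Somatic-variant filtering, deletion calls and group construction."""

import numpy as np
import pandas as pd
import pytest

from brcalike.catalog import (
    AberrationEvent,
    GroupDefinition,
    VariantAnnotation,
    build_aberration_groups,
    call_homozygous_deletions,
    exclude_overlap,
    filter_somatic_variants,
    load_aberration_events,
    toy_variant_table,
    variants_from_table,
)
from brcalike.errors import ValidationError


def _variant(**kw):
    base = dict(
        patient_id="P1",
        gene="TP53",
        variant_class="missense",
        severity="HIGH",
        sift="deleterious",
        polyphen="damaging",
        population_frequency=0.001,
        classification="unclassified",
    )
    base.update(kw)
    return VariantAnnotation(**base)


class TestSomaticFilter:
    def test_synonymous_excluded_with_reason(self):
        result = filter_somatic_variants(
            [_variant(variant_class="synonymous", severity="MODERATE", population_frequency=0.0001)]
        )
        assert result.n_kept == 0
        assert "synonymous" in result.excluded[0][1]

    def test_damaging_missense_kept(self):
        result = filter_somatic_variants([_variant()])
        assert result.n_kept == 1

    def test_common_variant_excluded(self):
        result = filter_somatic_variants([_variant(population_frequency=0.02)])
        assert result.n_excluded == 1
        assert "common" in result.excluded[0][1]

    def test_brca_gate_excludes_benign_classifications(self):
        kept = filter_somatic_variants([_variant(gene="BRCA1", classification="VUS")])
        assert kept.n_kept == 1
        dropped = filter_somatic_variants([_variant(gene="BRCA1", classification="likely-benign")])
        assert dropped.n_excluded == 1
        assert "brca_not_pathogenic_or_vus" in dropped.excluded[0][1]

    def test_filter_is_monotone_in_frequency_cutoff(self):
        variants = [_variant(patient_id=f"P{i}", population_frequency=f) for i, f in
                    enumerate([0.0001, 0.005, 0.011, 0.02, 0.2])]
        loose = filter_somatic_variants(variants, frequency_cutoff=0.05)
        tight = filter_somatic_variants(variants, frequency_cutoff=0.001)
        kept_loose = {v.patient_id for v in loose.kept}
        kept_tight = {v.patient_id for v in tight.kept}
        assert kept_tight <= kept_loose

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(ValidationError):
            _variant(severity="EXTREME")

    def test_toy_table_partition_matches_hand_derived_fixture(self):
        variants_df, expected = toy_variant_table()
        assert len(variants_df) == 20
        variants = variants_from_table(variants_df)
        result = filter_somatic_variants(variants)
        decisions = {}
        for v in result.kept:
            decisions[v.patient_id] = ("kept", "")
        for v, reasons in result.excluded:
            decisions[v.patient_id] = ("excluded", ";".join(reasons))
        for _, row in expected.iterrows():
            patient = variants_df.loc[variants_df.variant_id == row.variant_id, "patient_id"].iloc[0]
            assert decisions[patient] == (row.decision, row.reasons), row.variant_id


class TestHomozygousDeletions:
    def test_minus_two_yields_event(self):
        cnv = pd.DataFrame({"S1": [-2], "S2": [-1]}, index=["BRCA1"])
        events = call_homozygous_deletions(cnv)
        assert events == [
            AberrationEvent("S1", "BRCA1", "homozygous_deletion")
        ]

    def test_all_zero_table_empty(self):
        cnv = pd.DataFrame(np.zeros((3, 4), dtype=int))
        assert call_homozygous_deletions(cnv) == []

    def test_out_of_range_value_rejected(self):
        cnv = pd.DataFrame({"S1": [3]}, index=["G"])
        with pytest.raises(ValidationError):
            call_homozygous_deletions(cnv)


class TestGroups:
    def _events(self):
        return [
            AberrationEvent("P1", "BRCA1", "germline_mutation"),
            AberrationEvent("P2", "BRCA2", "hypermethylation"),
            AberrationEvent("P3", "BARD1", "germline_mutation"),
            AberrationEvent("P3", "BARD1", "homozygous_deletion"),
        ]

    def test_reference_group_is_union_of_brca_events(self):
        groups = build_aberration_groups(self._events(), ["BARD1"])
        ref = next(g for g in groups if g.label == "BRCA-like")
        assert ref.members == {"P1", "P2"}

    def test_multi_event_patient_counted_once_in_any(self):
        groups = build_aberration_groups(self._events(), ["BARD1"])
        any_group = next(g for g in groups if g.label == "BARD1:any")
        assert any_group.members == {"P3"}
        assert any_group.n == 1

    def test_gene_without_events_has_no_groups(self):
        groups = build_aberration_groups(self._events(), ["PALB2"])
        assert not any(g.gene == "PALB2" for g in groups)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            build_aberration_groups(self._events(), [])

    def test_order_independent(self, rng):
        events = self._events()
        a = build_aberration_groups(events, ["BARD1"])
        b = build_aberration_groups(list(reversed(events)), ["BARD1"])
        assert {(g.label, g.members) for g in a} == {(g.label, g.members) for g in b}

    def test_reference_equals_union_of_per_type_brca_groups(self):
        events = self._events() + [
            AberrationEvent("P4", "BRCA1", "somatic_mutation"),
            AberrationEvent("P5", "BRCA2", "homozygous_deletion"),
        ]
        groups = build_aberration_groups(events, ["BRCA1", "BRCA2"])
        ref = next(g for g in groups if g.label == "BRCA-like")
        union = set()
        for g in groups:
            if g.gene in ("BRCA1", "BRCA2") and ":" in g.label and not g.label.endswith(":any"):
                union |= g.members
        assert ref.members == union


class TestExcludeOverlap:
    def test_shared_members_removed_from_both(self):
        g1 = GroupDefinition("a", "A", ("germline_mutation",), frozenset("ABC"))
        g2 = GroupDefinition("b", "B", ("germline_mutation",), frozenset("CD"))
        e1, e2 = exclude_overlap(g1, g2)
        assert e1.members == {"A", "B"}
        assert e2.members == {"D"}

    def test_disjoint_groups_unchanged(self):
        g1 = GroupDefinition("a", "A", ("germline_mutation",), frozenset("AB"))
        g2 = GroupDefinition("b", "B", ("germline_mutation",), frozenset("CD"))
        e1, e2 = exclude_overlap(g1, g2)
        assert (e1.members, e2.members) == (g1.members, g2.members)

    def test_identical_groups_become_empty(self):
        g = GroupDefinition("a", "A", ("germline_mutation",), frozenset("AB"))
        e1, e2 = exclude_overlap(g, g)
        assert e1.members == frozenset()
        assert e2.members == frozenset()


class TestLoadEvents:
    def test_germline_rows_gated_by_pathogenicity(self):
        table = pd.DataFrame(
            [
                {"patient_id": "P1", "gene": "BRCA1", "event_type": "germline_mutation", "classification": "pathogenic"},
                {"patient_id": "P2", "gene": "BRCA1", "event_type": "germline_mutation", "classification": "VUS"},
                {"patient_id": "P3", "gene": "BRCA1", "event_type": "hypermethylation", "classification": ""},
            ]
        )
        events = load_aberration_events(table)
        assert {(e.patient_id, e.event_type) for e in events} == {
            ("P1", "germline_mutation"),
            ("P3", "hypermethylation"),
        }

    def test_duplicate_rows_collapse(self):
        table = pd.DataFrame(
            [
                {"patient_id": "P1", "gene": "G", "event_type": "somatic_mutation"},
                {"patient_id": "P1", "gene": "G", "event_type": "somatic_mutation"},
            ]
        )
        assert len(load_aberration_events(table)) == 1

    def test_unknown_event_type_rejected(self):
        table = pd.DataFrame([{"patient_id": "P1", "gene": "G", "event_type": "inversion"}])
        with pytest.raises(ValidationError):
            load_aberration_events(table)
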