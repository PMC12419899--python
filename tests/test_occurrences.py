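import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleobridge import occurrences as occ
from paleobridge.occurrences import (
    CladeDataset,
    EmptyCladeError,
    FossilOccurrence,
    HierarchyError,
    RowError,
    SchemaError,
    UnresolvableStageError,
    assemble_clade_dataset,
    bin_species_counts,
    build_analysis_plan,
    deduplicate_occurrences,
    mean_age,
    read_occurrence_table,
)


def make_occ(species, older, younger, **kw):
    return FossilOccurrence(species_name=species, age_older=older,
                            age_younger=younger, **kw)


class TestReadTable:
    CSV = (
        "species,suborder,family,deposit,age_older,age_younger\n"
        "Aus bus,Heteroptera,Fam1,dep1,100,95\n"
        "Cus dus,Heteroptera,Fam1,dep2,150.5,140.5\n"
        "Eus fus,Cicadomorpha,Fam2,dep3,320,315\n"
    )

    def test_well_formed_rows_ingested(self):
        occs = read_occurrence_table(io.StringIO(self.CSV))
        assert len(occs) == 3
        assert occs[0].species_name == "Aus bus"
        assert occs[0].suborder == "Heteroptera"
        assert occs[2].age_older == 320

    def test_reversed_ages_raise_row_error(self):
        bad = "species,age_older,age_younger\nAus bus,315,325\n"
        with pytest.raises(RowError, match=r"rows \[0\]"):
            read_occurrence_table(io.StringIO(bad))

    def test_missing_mandatory_column_raises_schema_error(self):
        with pytest.raises(SchemaError):
            read_occurrence_table(io.StringIO("species,age_older\nA,10\n"))

    def test_header_only_gives_empty_list(self, caplog):
        with caplog.at_level("WARNING"):
            occs = read_occurrence_table(
                io.StringIO("species,age_older,age_younger\n"))
        assert occs == []
        assert "no valid rows" in caplog.text

    def test_rows_with_missing_ages_rejected_with_index(self, caplog):
        csv = ("species,age_older,age_younger\n"
               "A,100,90\nB,,90\nC,50,45\n")
        with caplog.at_level("WARNING"):
            occs = read_occurrence_table(io.StringIO(csv))
        assert [o.species_name for o in occs] == ["A", "C"]
        assert "[1]" in caplog.text


class TestMeanAge:
    @pytest.mark.parametrize(
        "older,younger,expected",
        [(325.0, 315.0, 320.0), (100.0, 100.0, 100.0), (20.44, 13.82, 17.13)],
    )
    def test_midpoint(self, older, younger, expected):
        assert mean_age(make_occ("A sp", older, younger)) == pytest.approx(expected)

    @given(st.floats(0, 400), st.floats(0, 400))
    def test_always_within_interval(self, a, b):
        older, younger = max(a, b), min(a, b)
        m = mean_age(make_occ("A sp", older, younger))
        assert younger <= m <= older


class TestDeduplicate:
    def test_two_deposits_different_stages_both_kept(self, ts):
        occs = [make_occ("A sp", 320, 316, deposit_id="d1"),   # Bashkirian
                make_occ("A sp", 310, 305, deposit_id="d2")]   # Moscovian
        assert len(deduplicate_occurrences(occs, ts)) == 2

    def test_two_deposits_same_stage_first_kept(self, ts):
        occs = [make_occ("A sp", 320, 316, deposit_id="first"),
                make_occ("A sp", 322, 315, deposit_id="second")]
        kept = deduplicate_occurrences(occs, ts)
        assert len(kept) == 1
        assert kept[0].deposit_id == "first"

    def test_single_occurrence_unchanged(self, ts):
        occs = [make_occ("A sp", 100, 95)]
        assert deduplicate_occurrences(occs, ts) == occs

    def test_explicit_stage_label_wins(self, ts):
        # same midpoints, distinct labels: kept apart
        occs = [make_occ("A sp", 100, 95, stage_label="S1"),
                make_occ("A sp", 100, 95, stage_label="S2")]
        assert len(deduplicate_occurrences(occs, ts)) == 2

    def test_unresolvable_stage_raises(self, ts):
        with pytest.raises(UnresolvableStageError):
            deduplicate_occurrences([make_occ("A sp", 500, 490)], ts)

    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.floats(1, 300)),
                    max_size=12))
    def test_idempotent(self, ts, spec):
        occs = [make_occ(f"{s} sp", age + 1.0, age) for s, age in spec]
        once = deduplicate_occurrences(occs, ts)
        assert deduplicate_occurrences(once, ts) == once


class TestBinning:
    def test_direct_binning(self):
        occs = [make_occ("A", 67, 66), make_occ("B", 67.3, 66.5),
                make_occ("C", 70.4, 70.0)]
        counts = bin_species_counts(occs)  # means 66.5, 66.9, 70.2
        assert counts[66] == 2 and counts[70] == 1
        assert counts.sum() == 3 and len(counts) == 72

    def test_empty_input(self):
        counts = bin_species_counts([])
        assert counts.tolist() == [0]

    def test_species_retained_in_two_stages_contributes_twice(self):
        occs = [make_occ("A sp", 101, 100), make_occ("A sp", 96.4, 96.0)]
        counts = bin_species_counts(occs)  # means 100.5 and 96.2
        assert counts[100] == 1 and counts[96] == 1

    @given(st.lists(st.floats(0.25, 200), min_size=1, max_size=20))
    def test_translation_consistency(self, ages):
        occs = [make_occ("A", a + 0.5, a - 0.25) for a in ages]
        shifted = [make_occ("A", a + 1.5, a + 0.75) for a in ages]
        base = bin_species_counts(occs)
        moved = bin_species_counts(shifted)
        for k, c in enumerate(base):
            assert moved[k + 1] == c

    def test_boundary_age_goes_to_bin_of_its_lower_edge(self):
        counts = bin_species_counts([make_occ("A", 12.0, 12.0)])
        assert counts[12] == 1


RICHNESS = pd.DataFrame({
    "clade": ["Peloridiidae", "Heteroptera"],
    "rank": ["family", "suborder"],
    "extant_species": [38, 45000],
})


class TestAssemble:
    def test_extant_clade_anchored_at_richness(self):
        occs = [make_occ("A", 100, 95, family="Peloridiidae"),
                make_occ("B", 50, 45, family="Peloridiidae")]
        data = assemble_clade_dataset(occs, "Peloridiidae", "family", RICHNESS)
        assert data.extant_richness == 38
        assert not data.is_extinct
        assert data.counts.sum() == 2

    def test_clade_absent_from_richness_is_extinct(self):
        occs = [make_occ("A", 100, 95, family="Prosbolidae")]
        data = assemble_clade_dataset(occs, "Prosbolidae", "family", RICHNESS)
        assert data.is_extinct and data.extant_richness == 0

    def test_empty_clade_raises(self):
        occs = [make_occ("A", 100, 95, family="Other")]
        with pytest.raises(EmptyCladeError):
            assemble_clade_dataset(occs, "Nothing", "family", RICHNESS)

    def test_order_level_pools_everything(self):
        occs = [make_occ("A", 100, 95, family="F1"),
                make_occ("B", 50, 45)]  # no family label
        data = assemble_clade_dataset(occs, "all", "order", None)
        assert data.counts.sum() == 2

    def test_family_counts_partition_labeled_occurrences(self):
        occs = [make_occ(f"S{i}", 10 * i + 5, 10 * i, family=f"F{i % 3}")
                for i in range(9)]
        occs.append(make_occ("unlabeled", 50, 40))
        total = 0
        for fam in ("F0", "F1", "F2"):
            total += assemble_clade_dataset(occs, fam, "family").counts.sum()
        assert total == 9

    def test_dataset_invariants_enforced(self):
        with pytest.raises(EmptyCladeError):
            CladeDataset("x", "family", 0, np.zeros(5, int))
        with pytest.raises(ValueError):
            CladeDataset("x", "family", -1, np.array([1]))


def hier_occ(species, age, fam, sup=None, infra=None, sub=None):
    return make_occ(species, age + 1, age, family=fam, superfamily=sup,
                    infraorder=infra, suborder=sub)


class TestAnalysisPlan:
    def test_monotypic_superfamily_aliased_to_family(self):
        occs = [hier_occ("A", 250, "Prosbolidae", sup="Prosboloidea"),
                hier_occ("B", 240, "Prosbolidae", sup="Prosboloidea")]
        plan = {(e.clade, e.rank): e for e in build_analysis_plan(occs)}
        assert plan[("Prosbolidae", "family")].action == "run"
        alias = plan[("Prosboloidea", "superfamily")]
        assert alias.action == "alias"
        assert (alias.target_clade, alias.target_rank) == ("Prosbolidae", "family")

    def test_polytypic_superfamily_gets_own_run(self):
        occs = [hier_occ(f"S{i}", 200 + i, f"F{i}", sup="Sup") for i in range(3)]
        plan = build_analysis_plan(occs)
        runs = [e for e in plan if e.action == "run"]
        assert len(runs) == 4  # 3 families + the superfamily
        assert all(e.action == "run" for e in plan)

    def test_alias_chain_resolves_to_run(self):
        occs = [hier_occ("A", 250, "F1", sup="Sup1", infra="Inf1")]
        plan = {(e.clade, e.rank): e for e in build_analysis_plan(occs)}
        ali = plan[("Inf1", "infraorder")]
        assert ali.action == "alias"
        assert (ali.target_clade, ali.target_rank) == ("F1", "family")

    def test_every_fossil_clade_appears_exactly_once(self):
        occs = [hier_occ("A", 100, "F1", sup="S1", sub="Sub1"),
                hier_occ("B", 110, "F2", sup="S1", sub="Sub1"),
                hier_occ("C", 200, "F3", sup="S2", sub="Sub2"),
                hier_occ("D", 210, None, sub="Sub2")]
        plan = build_analysis_plan(occs)
        keys = [(e.clade, e.rank) for e in plan]
        assert len(keys) == len(set(keys))
        assert set(keys) == {("F1", "family"), ("F2", "family"),
                             ("F3", "family"), ("S1", "superfamily"),
                             ("S2", "superfamily"), ("Sub1", "suborder"),
                             ("Sub2", "suborder")}
        # Sub2 has an occurrence outside F3/S2 -> must be its own run
        by_key = dict(zip(keys, plan))
        assert by_key[("Sub2", "suborder")].action == "run"
        assert by_key[("Sub1", "suborder")].action == "alias"

    def test_inconsistent_hierarchy_raises(self):
        occs = [hier_occ("A", 100, "F1", sup="S1"),
                hier_occ("B", 110, "F1", sup="S2")]
        with pytest.raises(HierarchyError):
            build_analysis_plan(occs)
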