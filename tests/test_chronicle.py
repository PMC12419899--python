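import math

import numpy as np
import pandas as pd
import pytest

from paleobridge import chronicle
from paleobridge.chronicle import (
    RunConfig,
    count_events_by_period,
    derive_seed,
    prior_sensitivity_test,
    read_summary_table,
    run_analysis,
    write_summary_table,
)
from paleobridge.occurrences import FossilOccurrence
from paleobridge.sampler import McmcSettings


def occ(species, age, fam=None, sup=None, sub=None):
    return FossilOccurrence(species_name=species, age_older=age + 2,
                            age_younger=age - 2, family=fam, superfamily=sup,
                            suborder=sub)


@pytest.fixture(scope="module")
def tiny_occs():
    """Two families in one superfamily plus a monotypic lineage."""
    rng = np.random.default_rng(99)
    occs = []
    for i, age in enumerate(rng.uniform(20, 60, 8)):
        occs.append(occ(f"A{i}", age, fam="Alphidae", sup="Alphoidea",
                        sub="Subor1"))
    for i, age in enumerate(rng.uniform(30, 80, 8)):
        occs.append(occ(f"B{i}", age, fam="Betidae", sup="Alphoidea",
                        sub="Subor1"))
    for i, age in enumerate(rng.uniform(100, 150, 6)):
        occs.append(occ(f"C{i}", age, fam="Gammidae", sup="Gammoidea",
                        sub="Subor2"))
    return occs


@pytest.fixture(scope="module")
def tiny_richness():
    return pd.DataFrame({
        "clade": ["Alphidae", "Subor1"],
        "rank": ["family", "suborder"],
        "extant_species": [12, 40],
    })


def tiny_config(tmp_path=None, **kw):
    base = dict(
        occurrences="unused.csv",
        max_ages=(200.0, 220.0),
        mcmc=McmcSettings(iterations=4000, sampling_freq=20, burnin=0.1,
                          n_chains=1),
        seed=7,
        outdir=str(tmp_path) if tmp_path else None,
    )
    base.update(kw)
    return RunConfig(**base)


class TestDeriveSeed:
    def test_stable_and_in_range(self):
        s = derive_seed(7, "Alphidae", "family", 350.0)
        assert s == derive_seed(7, "Alphidae", "family", 350.0)
        assert 0 <= s < 2**31

    def test_distinct_across_inputs(self):
        seeds = {derive_seed(7, c, r, m) for c in ("A", "B")
                 for r in ("family", "order") for m in (325.0, 350.0)}
        assert len(seeds) == 8


@pytest.fixture(scope="module")
def result(tiny_occs, tiny_richness, tmp_path_factory):
    out = tmp_path_factory.mktemp("runout")
    return run_analysis(tiny_config(out), occs=tiny_occs,
                        richness=tiny_richness), out


class TestRunAnalysis:
    def test_one_row_per_clade_and_prior(self, result):
        res, _ = result
        # 3 families + Alphoidea (2 children) + Gammoidea alias + 2 suborders
        # (Subor1 has 2 families -> own run; Subor2 aliases Gammidae) + order
        assert res.ok
        counts = res.summaries.groupby(["clade", "rank"]).size()
        assert (counts == 2).all()  # two max_age settings each
        assert len(res.summaries) == 2 * 8

    def test_propagation_alias_copies_source(self, result):
        res, _ = result
        df = res.summaries.set_index(["clade", "rank", "max_age"])
        for m in (200.0, 220.0):
            alias = df.loc[("Gammoidea", "superfamily", m)]
            src = df.loc[("Gammidae", "family", m)]
            assert alias["root_median"] == src["root_median"]
            assert alias["propagated_from"] == "family:Gammidae"

    def test_medians_bracketed_by_fossil_span(self, result, tiny_occs):
        res, _ = result
        ages = [0.5 * (o.age_older + o.age_younger) for o in tiny_occs]
        for row in res.summaries.itertuples():
            members = [a for a in ages]  # order-level bound applies to all
            assert row.root_median >= min(members) - 100
            if row.rank == "order":
                assert row.root_median >= max(ages)
            if row.extinct and not math.isnan(row.ext_median):
                assert row.ext_median <= min(a for a in ages) + 100

    def test_outputs_written(self, result):
        res, out = result
        assert (out / "summary.tsv").exists()
        assert (out / "manifest.json").exists()
        back = read_summary_table(out / "summary.tsv")
        assert len(back) == len(res.summaries)

    def test_rerun_is_bit_identical(self, result, tiny_occs, tiny_richness):
        res, _ = result
        res2 = run_analysis(tiny_config(), occs=tiny_occs,
                            richness=tiny_richness)
        pd.testing.assert_frame_equal(res.summaries, res2.summaries)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty occurrence"):
            run_analysis(tiny_config(), occs=[])

    def test_failed_runs_recorded_not_dropped(self, tiny_occs, tiny_richness):
        # a max_age below the oldest fossil cannot initialize that clade
        cfg = tiny_config(max_ages=(120.0,))
        res = run_analysis(cfg, occs=tiny_occs, richness=tiny_richness)
        assert not res.ok
        failed = {f["clade"] for f in res.failures}
        assert "Gammidae" in failed
        ok_clades = set(res.summaries["clade"])
        assert "Alphidae" in ok_clades  # unaffected runs still done


from support import wilcoxon_oracle  # noqa: E402


def summaries_frame(medians_by_setting):
    rows = []
    for setting, medians in medians_by_setting.items():
        for i, m in enumerate(medians):
            rows.append({"clade": f"F{i}", "rank": "family",
                         "max_age": setting, "root_median": m})
    return pd.DataFrame(rows)


class TestPriorSensitivity:
    def test_identical_summaries_retain_null(self):
        base = np.linspace(100, 250, 60)
        df = summaries_frame({m: base for m in (325, 350, 386, 407)})
        out = prior_sensitivity_test(df)
        assert len(out) == 6  # all setting pairs
        assert (out["pvalue"] == 1.0).all()

    def test_shift_detected_and_matches_oracle(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(80, 300, 60)
        noise = base + rng.normal(0, 1.0, 60)
        df = summaries_frame({325: base, 350: noise + 20.0})
        out = prior_sensitivity_test(df)
        p = out["pvalue"].iloc[0]
        assert p < 0.01
        p_oracle = wilcoxon_oracle(base, noise + 20.0)
        assert math.isclose(p, p_oracle, rel_tol=0.2, abs_tol=1e-12)

    def test_oracle_agreement_under_null(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(80, 300, 40)
        b = a + rng.normal(0, 5.0, 40)
        out = prior_sensitivity_test(summaries_frame({325: a, 350: b}))
        p_oracle = wilcoxon_oracle(a, b)
        assert out["pvalue"].iloc[0] == pytest.approx(p_oracle, rel=0.15)

    def test_too_few_pairs_power_warning(self):
        df = summaries_frame({325: [100, 110, 120], 350: [105, 115, 125]})
        out = prior_sensitivity_test(df)
        assert math.isnan(out["pvalue"].iloc[0])
        assert "too few" in out["warning"].iloc[0]

    def test_missing_rank_raises(self):
        df = summaries_frame({325: [1.0], 350: [2.0]})
        with pytest.raises(ValueError):
            prior_sensitivity_test(df, rank="suborder")


def summary_row(clade, sub, root, ext=math.nan):
    return {"clade": clade, "rank": "family", "max_age": 350.0,
            "suborder": sub, "root_median": root, "ext_median": ext,
            "extinct": not math.isnan(ext)}


class TestEventCounts:
    def test_cretaceous_origination(self, ts):
        df = pd.DataFrame([summary_row("Cercopidae", "Cicadomorpha", 68.61)])
        counts = count_events_by_period(df, ts)
        hit = counts[(counts["period"] == "Cretaceous")
                     & (counts["suborder"] == "Cicadomorpha")
                     & (counts["event"] == "origination")]
        assert hit["count"].iloc[0] == 1
        assert counts["count"].sum() == 1

    def test_boundary_goes_to_older_period(self, ts):
        df = pd.DataFrame([summary_row("X", "S", 66.0)])
        counts = count_events_by_period(df, ts)
        assert counts.loc[(counts["period"] == "Cretaceous")
                          & (counts["event"] == "origination"),
                          "count"].sum() == 1

    def test_extinct_clade_counts_both_events(self, ts):
        df = pd.DataFrame([summary_row("X", "S", 300.0, ext=252.0)])
        counts = count_events_by_period(df, ts)
        assert counts.loc[(counts["period"] == "Carboniferous")
                          & (counts["event"] == "origination"),
                          "count"].sum() == 1
        assert counts.loc[(counts["period"] == "Permian")
                          & (counts["event"] == "extinction"),
                          "count"].sum() == 1

    def test_totals_invariant_to_row_order(self, ts):
        rows = [summary_row(f"F{i}", "S", age, ext=age - 50)
                for i, age in enumerate([300, 150, 80, 210])]
        a = count_events_by_period(pd.DataFrame(rows), ts)
        b = count_events_by_period(pd.DataFrame(rows[::-1]), ts)
        pd.testing.assert_frame_equal(a, b)

    def test_event_totals_match_clade_counts(self, ts):
        rows = [summary_row(f"F{i}", "S", age) for i, age in
                enumerate([300, 150, 80])]
        rows.append(summary_row("F9", "S", 200, ext=120.0))
        counts = count_events_by_period(pd.DataFrame(rows), ts)
        assert counts[counts["event"] == "origination"]["count"].sum() == 4
        assert counts[counts["event"] == "extinction"]["count"].sum() == 1

    def test_empty_summaries_all_zero(self, ts):
        counts = count_events_by_period(
            pd.DataFrame(columns=["clade", "suborder", "root_median",
                                  "ext_median", "extinct"]), ts)
        assert counts["count"].sum() == 0

    def test_median_outside_span_names_clade(self, ts):
        df = pd.DataFrame([summary_row("Ghostidae", "S", 500.0)])
        with pytest.raises(ValueError, match="Ghostidae"):
            count_events_by_period(df, ts)


class TestSummaryTable:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame([summary_row("A", "S", 100.0)])
        path = tmp_path / "s.tsv"
        write_summary_table(df, path)
        back = read_summary_table(path)
        assert back["root_median"].iloc[0] == 100.0

    def test_empty_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_summary_table(pd.DataFrame(), tmp_path / "s.tsv")
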