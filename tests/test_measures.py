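import datetime as dt

import numpy as np
import pandas as pd
import pytest

from carenet import edges as ce
from carenet import measures as cm
from carenet.types import AggregatedEdge, AnalysisWindow, NetworkSnapshot

from conftest import day, make_appointments, make_providers, make_registry

WINDOW = AnalysisWindow(start=dt.date(2010, 1, 1), end=dt.date(2012, 12, 31))


def edge(a, b, weight, kind="temporal"):
    return AggregatedEdge(provider_a=a, provider_b=b, weight=weight, kind=kind, window=WINDOW)


def snapshot(nodes, edges):
    return NetworkSnapshot(nodes=nodes, edges=tuple(edges), window=WINDOW)


class TestNetworkDensity:
    def test_complete_triangle(self):
        s = snapshot({"a": 1, "b": 1, "c": 1}, [edge("a", "b", 1), edge("a", "c", 1), edge("b", "c", 1)])
        assert cm.network_density(s) == 1.0

    def test_four_nodes_three_edges(self):
        s = snapshot(
            {"a": 1, "b": 1, "c": 1, "d": 1},
            [edge("a", "b", 1), edge("a", "c", 1), edge("a", "d", 1)],
        )
        assert cm.network_density(s) == pytest.approx(0.5)

    def test_degenerate_graphs(self):
        assert cm.network_density(snapshot({}, [])) == 0.0
        assert cm.network_density(snapshot({"a": 1}, [])) == 0.0


class TestCareDensity:
    def test_single_edge(self):
        assert cm.care_density(snapshot({"a": 1, "b": 1}, [edge("a", "b", 5)])) == 5.0

    def test_mean_of_two(self):
        s = snapshot({"a": 1, "b": 1, "c": 1}, [edge("a", "b", 2), edge("a", "c", 4)])
        assert cm.care_density(s) == pytest.approx(3.0)

    def test_all_ones(self):
        s = snapshot({"a": 1, "b": 1, "c": 1}, [edge("a", "b", 1), edge("b", "c", 1)])
        assert cm.care_density(s) == 1.0

    def test_edgeless(self):
        assert cm.care_density(snapshot({"a": 1}, [])) == 0.0


class TestDegreeCentrality:
    def test_star_center(self):
        s = snapshot(
            {"hub": 1, "a": 1, "b": 1, "c": 1},
            [edge("a", "hub", 1), edge("b", "hub", 1), edge("c", "hub", 1)],
        )
        assert cm.degree_centrality(s, "hub") == 3

    def test_isolated(self):
        assert cm.degree_centrality(snapshot({"a": 1}, []), "a") == 0

    def test_unknown_provider(self):
        with pytest.raises(KeyError):
            cm.degree_centrality(snapshot({"a": 1}, []), "zz")

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        providers = [f"d{i}" for i in range(12)]
        for _ in range(20):
            pairs = set()
            for _ in range(rng.integers(0, 25)):
                a, b = rng.choice(providers, size=2, replace=False)
                pairs.add((min(a, b), max(a, b)))
            s = snapshot({p: 1 for p in providers}, [edge(a, b, 1) for a, b in sorted(pairs)])
            for p in providers:
                brute = sum(1 for a, b in pairs if p in (a, b))
                assert cm.degree_centrality(s, p) == brute


class TestEgoNetwork:
    def test_triangle_ego_excludes_far_edge(self):
        edges = [edge("A", "B", 1), edge("A", "C", 2), edge("B", "C", 3)]
        ego = cm.ego_network(edges, "A", WINDOW)
        assert set(ego.nodes) == {"A", "B", "C"}
        assert {e.pair for e in ego.edges} == {("A", "B"), ("A", "C")}

    def test_isolated_provider_single_node(self):
        appts = make_appointments([("p1", "A", "2010-05-01")])
        ego = cm.ego_network([], "A", WINDOW, appointments=appts)
        assert set(ego.nodes) == {"A"} and ego.n_edges == 0
        assert ego.nodes["A"] == 1

    def test_star_care_density(self):
        edges = [edge("A", "B", 2), edge("A", "C", 4)]
        assert cm.care_density(cm.ego_network(edges, "A", WINDOW)) == pytest.approx(3.0)

    def test_unknown_provider(self):
        with pytest.raises(KeyError):
            cm.ego_network([], "nobody", WINDOW)


class TestYearlyInstitutionalStats:
    def test_single_appointment_year(self):
        registry = make_registry([("p1", "2005-03-01", "I")])
        appts = make_appointments([("p1", "A", "2005-03-01")])
        report = cm.yearly_institutional_stats(registry, appts)
        row = report.table.set_index("year").loc[2005]
        assert (row["diagnoses"], row["patients"], row["providers"]) == (1, 1, 1)
        assert row["temporal_edges"] == 0 and row["atemporal_edges"] == 0

    def test_empty_year_all_zero(self):
        registry = make_registry([("p1", "2005-03-01", "I")])
        appts = make_appointments([("p1", "A", "2005-03-01"), ("p1", "A", "2007-03-01")])
        row = cm.yearly_institutional_stats(registry, appts).table.set_index("year").loc[2006]
        assert (row.drop("year", errors="ignore") == 0).all()

    def test_rows_recompute_from_windowed_inputs(self, small_cohort):
        registry, _, appointments = small_cohort
        report = cm.yearly_institutional_stats(registry, appointments)
        rels = ce.patient_relationships(appointments)
        for _, row in report.table.iterrows():
            window = AnalysisWindow.year(int(row["year"]))
            mask = (appointments["date"] >= pd.Timestamp(window.start)) & (
                appointments["date"] <= pd.Timestamp(window.end)
            )
            active = appointments[mask]
            assert row["patients"] == active["patient_id"].nunique()
            assert row["providers"] == active["provider_id"].nunique()
            t_edges = ce.aggregate_edges(rels, "temporal", window)
            a_edges = ce.aggregate_edges(appointments, "atemporal", window)
            assert row["temporal_edges"] == len(t_edges)
            assert row["atemporal_edges"] == len(a_edges)
            assert row["temporal_weight_sum"] == sum(e.weight for e in t_edges)
            assert row["atemporal_weight_sum"] == sum(e.weight for e in a_edges)
            n = active["provider_id"].nunique()
            expected_density = 2 * len(t_edges) / (n * (n - 1)) if n > 1 else 0.0
            assert row["temporal_density"] == pytest.approx(expected_density)


class TestRelativeCareDensity:
    def _appointments_for_enter(self, last_offset):
        # only X's own appointments matter when relationships are supplied
        return make_appointments([("px", "X", 0), ("px", "X", last_offset)])

    def _relationships(self, rows):
        return pd.DataFrame(
            {
                "patient_id": [r[0] for r in rows],
                "provider_a": [min(r[1], "X") for r in rows],
                "provider_b": [max(r[1], "X") for r in rows],
                "start_date": pd.to_datetime([day(r[2]) for r in rows]),
                "end_date": pd.to_datetime([day(r[3]) for r in rows]),
            }
        )

    def test_hand_built_two_years(self):
        rels = self._relationships(
            [
                # year 1: X-Y shared by 2 patients, X-Z shared by 2 -> weights {2,2}
                ("p1", "Y", 10, 20),
                ("p2", "Y", 30, 40),
                ("p1", "Z", 50, 60),
                ("p3", "Z", 70, 80),
                # year 2: X-W shared by 6 patients -> weights {6}
                *[(f"q{i}", "W", 400, 410) for i in range(6)],
            ]
        )
        got = cm.relative_care_density(
            self._appointments_for_enter(700), "X", relationships=rels
        )
        assert got == [(1, pytest.approx(2.0)), (2, pytest.approx(6.0))]

    def test_single_active_year(self):
        got = cm.relative_care_density(
            self._appointments_for_enter(100), "X", relationships=self._relationships([])
        )
        assert got == [(1, 0.0)]

    def test_empty_middle_year_reported_zero(self):
        rels = self._relationships([("p1", "Y", 5, 10), ("p2", "Y", 800, 820)])
        got = cm.relative_care_density(
            self._appointments_for_enter(820), "X", relationships=rels
        )
        assert got == [(1, pytest.approx(1.0)), (2, 0.0), (3, pytest.approx(1.0))]

    def test_unknown_provider(self):
        with pytest.raises(KeyError):
            cm.relative_care_density(self._appointments_for_enter(10), "nobody")


class TestProviderTenure:
    def test_tenure_in_months(self):
        appts = make_appointments([("p1", "A", 0), ("p2", "A", 411)])
        report = cm.provider_tenure_stats(appts)
        assert report.value(
            column="mean_tenure_months", group="all"
        ) == pytest.approx(411 / 30.44)

    def test_single_appointment_provider(self):
        appts = make_appointments([("p1", "A", 0), ("p1", "B", 0), ("p2", "B", 10)])
        report = cm.provider_tenure_stats(appts)
        assert report.value(column="single_appointment_fraction", group="all") == 0.5
        # A has tenure 0 months
        assert report.value(column="median_tenure_months", group="all") == pytest.approx(
            (0 + 10 / 30.44) / 2
        )

    def test_single_visit_and_year_long_sets_disjoint(self):
        appts = make_appointments([("p1", "A", 0), ("p2", "A", 400), ("p3", "B", 5)])
        report = cm.provider_tenure_stats(appts)
        single = report.value(column="single_appointment_fraction", group="all")
        yearlong = report.value(column="fraction_tenure_ge_1y", group="all")
        assert single + yearlong <= 1.0
        assert (single, yearlong) == (0.5, 0.5)

    def test_oncology_subset(self):
        appts = make_appointments([("p1", "A", 0), ("p2", "A", 100), ("p1", "B", 0)])
        providers = make_providers([("A", "medical oncology", True), ("B", "radiology", False)])
        report = cm.provider_tenure_stats(appts, providers=providers)
        assert report.value(
            column="mean_tenure_months", group="oncology_related"
        ) == pytest.approx(100 / 30.44)
        assert report.value(column="n_providers", group="oncology_related") == 1


STUDY_END = dt.date(2016, 12, 31)


class TestPatientRetention:
    def test_span_800_days(self):
        registry = make_registry([("p1", "2010-01-01", "I")])
        appts = make_appointments([("p1", "A", 0), ("p1", "A", 800)])
        got = dict(cm.patient_retention(appts, registry, (2, 5), study_end=STUDY_END))
        assert got[2.0] == 1.0 and got[5.0] == 0.0

    def test_at_risk_denominator_excludes_late_diagnoses(self):
        registry = make_registry(
            [("p1", "2010-01-01", "I"), ("p2", "2016-06-01", "I")]
        )
        appts = make_appointments(
            [
                ("p1", "A", 0),
                ("p1", "A", 400),
                ("p2", "A", "2016-06-01"),
            ]
        )
        # p2 diagnosed < 2 years before study end: not at risk at horizon 2
        got = dict(cm.patient_retention(appts, registry, (2,), study_end=STUDY_END))
        assert got[2.0] == 0.0  # p1 at risk but span 400 < 730.5
        got_all = dict(
            cm.patient_retention(
                appts, registry, (2,), study_end=STUDY_END, denominator="all_patients"
            )
        )
        assert got_all[2.0] == 0.0

    def test_all_single_visit_zero_everywhere(self):
        registry = make_registry([("p1", "2005-01-01", "I"), ("p2", "2006-01-01", "II")])
        appts = make_appointments([("p1", "A", "2005-01-01"), ("p2", "A", "2006-01-01")])
        got = cm.patient_retention(appts, registry, (2, 5, 10), study_end=STUDY_END)
        assert all(fraction == 0.0 for _, fraction in got)

    def test_monotone_on_fixed_at_risk_set(self, small_cohort, small_config):
        registry, _, appointments = small_cohort
        got = cm.patient_retention(
            appointments,
            registry,
            (1, 2, 3),
            study_end=small_config.study_end,
            denominator="all_patients",
        )
        fractions = [f for _, f in got]
        assert fractions == sorted(fractions, reverse=True)


class TestOncologyFractionByMonth:
    providers = make_providers([("ONC", "medical oncology", True), ("GEN", "radiology", False)])

    def test_three_of_four(self):
        registry = make_registry([("p1", "2010-01-01", "I")])
        appts = make_appointments(
            [("p1", "ONC", 1), ("p1", "ONC", 5), ("p1", "ONC", 20), ("p1", "GEN", 25)]
        )
        got = dict(cm.oncology_fraction_by_month(appts, registry, self.providers))
        assert got[0] == pytest.approx(75.0)

    def test_all_oncology_is_100(self):
        registry = make_registry([("p1", "2010-01-01", "I")])
        appts = make_appointments([("p1", "ONC", 40), ("p1", "ONC", 45)])
        got = dict(cm.oncology_fraction_by_month(appts, registry, self.providers))
        assert got == {1: pytest.approx(100.0)}

    def test_empty_months_absent(self):
        registry = make_registry([("p1", "2010-01-01", "I")])
        appts = make_appointments([("p1", "ONC", 1), ("p1", "GEN", 200)])
        months = [m for m, _ in cm.oncology_fraction_by_month(appts, registry, self.providers)]
        assert months == [0, 6]

    def test_stage_filter(self):
        registry = make_registry([("p1", "2010-01-01", "I"), ("p2", "2010-01-01", "III")])
        appts = make_appointments([("p1", "ONC", 1), ("p2", "GEN", 1)])
        got = dict(
            cm.oncology_fraction_by_month(appts, registry, self.providers, stage_filter="III")
        )
        assert got == {0: pytest.approx(0.0)}


class TestCohortSummary:
    def test_providers_per_patient_arithmetic(self):
        registry = make_registry([("p1", "2010-01-01", "I"), ("p2", "2010-01-01", "II")])
        appts = make_appointments(
            [("p1", f"A{i}", i) for i in range(3)] + [("p2", f"B{i}", i) for i in range(5)]
        )
        report = cm.cohort_summary(registry, appts)
        metric = "providers_per_patient"
        assert report.value(stage="all", metric=metric, statistic="mean") == 4.0
        assert report.value(stage="all", metric=metric, statistic="median") == 4.0
        assert report.value(stage="all", metric=metric, statistic="min") == 3.0
        assert report.value(stage="all", metric=metric, statistic="max") == 5.0

    def test_single_patient_degenerate(self):
        registry = make_registry([("p1", "2010-01-01", "I")])
        appts = make_appointments([("p1", "A", 0), ("p1", "B", 1)])
        report = cm.cohort_summary(registry, appts)
        for statistic in ("mean", "median", "min", "max"):
            assert report.value(
                stage="all", metric="providers_per_patient", statistic=statistic
            ) == 2.0

    def test_pooled_providers_at_most_stage_sum(self, small_cohort):
        registry, _, appointments = small_cohort
        report = cm.cohort_summary(registry, appointments, by_stage=True)
        pooled = report.value(stage="all", metric="providers", statistic="count")
        stage_sum = sum(
            report.value(stage=stage, metric="providers", statistic="count")
            for stage in sorted(registry["stage"].unique())
        )
        assert pooled <= stage_sum
        # union oracle: pooled patient count equals the per-stage sum exactly
        pooled_patients = report.value(stage="all", metric="patients", statistic="count")
        assert pooled_patients == sum(
            report.value(stage=stage, metric="patients", statistic="count")
            for stage in sorted(registry["stage"].unique())
        )


class TestMeasureReport:
    def test_tsv_round_trip(self, tmp_path):
        table = pd.DataFrame({"metric": ["x"], "value": [1.5]})
        report = cm.MeasureReport(name="demo", table=table, meta={"policy": "contained"})
        path = report.write_tsv(tmp_path / "demo.tsv")
        text = path.read_text()
        assert text.startswith("# report\tdemo")
        back = pd.read_csv(path, sep="\t", comment="#")
        pd.testing.assert_frame_equal(back, table)

    def test_value_requires_unique_match(self):
        table = pd.DataFrame({"metric": ["x", "x"], "value": [1.0, 2.0]})
        report = cm.MeasureReport(name="demo", table=table)
        with pytest.raises(KeyError):
            report.value(metric="x")
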