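"""Network and cohort measures.

Scalar graph measures (density, care density, degree centrality) operate on
`NetworkSnapshot` objects; cohort-level summaries operate on the validated
frames from :mod:`carenet.io` and return `MeasureReport` tables.

Conventions (documented, configurable where noted):

* month length fixed at 30.44 days and year length at 365.25 days for
  relative-time bucketing and tenure;
* an edgeless graph has care density 0 and a graph with fewer than two nodes
  has network density 0;
* retention denominators default to the "at risk" rule: a patient enters the
  horizon-h denominator only if diagnosed at least h years before study end.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .edges import (
    aggregate_atemporal_frame,
    aggregate_temporal_frame,
    node_patient_counts,
    patient_relationships,
)
from .types import AggregatedEdge, AnalysisWindow, NetworkSnapshot

DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


@dataclass
class MeasureReport:
    """A named table of summary measures with run metadata.

    ``meta`` records the window/policy/parameters the table was computed
    under; ``write_tsv`` emits them as ``#``-prefixed header lines followed
    by the table itself, readable back with ``pandas.read_csv(comment='#')``.
    """

    name: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def write_tsv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            handle.write(f"# report\t{self.name}\n")
            for key in sorted(self.meta):
                handle.write(f"# {key}\t{self.meta[key]}\n")
            self.table.to_csv(handle, sep="\t", index=False)
        return path

    def value(self, column: str = "value", **filters):
        """Return the single table cell matching the filter columns."""
        rows = self.table
        for key, expected in filters.items():
            rows = rows[rows[key] == expected]
        if len(rows) != 1:
            raise KeyError(
                f"filters {filters!r} matched {len(rows)} rows in report "
                f"{self.name!r}"
            )
        return rows.iloc[0][column]


# ---------------------------------------------------------------------------
# scalar graph measures


def network_density(snapshot: NetworkSnapshot) -> float:
    """Fraction of possible pairs that are connected: 2E / (N(N-1)).

    Returns 0.0 for graphs with fewer than two nodes.
    """
    n = snapshot.n_nodes
    if n < 2:
        return 0.0
    return 2.0 * snapshot.n_edges / (n * (n - 1))


def care_density(snapshot: NetworkSnapshot) -> float:
    """Average patients shared per connection: sum of edge weights / edge
    count.  Returns 0.0 for an edgeless snapshot."""
    if snapshot.n_edges == 0:
        return 0.0
    return sum(e.weight for e in snapshot.edges) / snapshot.n_edges


def degree_centrality(snapshot: NetworkSnapshot, provider_id: str) -> int:
    """Number of distinct neighbors of ``provider_id`` in the snapshot."""
    return len(snapshot.neighbors(provider_id))


def ego_network(
    edges: Sequence[AggregatedEdge],
    provider_id: str,
    window: AnalysisWindow,
    appointments: pd.DataFrame | None = None,
) -> NetworkSnapshot:
    """Star subgraph of one central provider.

    Keeps the central node, its neighbors, and only the edges incident to the
    center.  Node patient counts are filled from ``appointments`` when
    given (distinct patients inside the window), otherwise left at 0.  A
    provider with neither incident edges nor in-window appointments is
    unknown and raises ``KeyError``.
    """
    incident = [e for e in edges if provider_id in e.pair]
    counts = (
        node_patient_counts(appointments, window) if appointments is not None else {}
    )
    if not incident and provider_id not in counts:
        raise KeyError(
            f"provider {provider_id!r} has no edges and no appointments in window"
        )
    nodes = {provider_id: counts.get(provider_id, 0)}
    for edge in incident:
        other = edge.provider_b if edge.provider_a == provider_id else edge.provider_a
        nodes[other] = counts.get(other, 0)
    ordered = tuple(sorted(incident, key=lambda e: (e.kind, e.provider_a, e.provider_b)))
    return NetworkSnapshot(nodes=nodes, edges=ordered, window=window)


# ---------------------------------------------------------------------------
# absolute-time institutional statistics


def _full_window(policy: str = "contained") -> AnalysisWindow:
    return AnalysisWindow(
        start=dt.date(1, 1, 1), end=dt.date(9999, 12, 31), containment_policy=policy
    )


def yearly_institutional_stats(
    registry: pd.DataFrame,
    appointments: pd.DataFrame,
    years: Sequence[int] | None = None,
    containment_policy: str = "contained",
) -> MeasureReport:
    """Institutional network statistics per calendar year.

    For each year: new diagnoses, active patients/providers (>=1 appointment
    in the year), temporal and atemporal edge counts and edge-weight sums
    under ``containment_policy``, and both network densities.
    """
    if years is None:
        if appointments.empty:
            years = []
        else:
            years = range(
                int(appointments["date"].dt.year.min()),
                int(appointments["date"].dt.year.max()) + 1,
            )
    relationships = patient_relationships(appointments)
    rows = []
    for year in years:
        window = AnalysisWindow.year(year, containment_policy)
        mask = (appointments["date"] >= pd.Timestamp(window.start)) & (
            appointments["date"] <= pd.Timestamp(window.end)
        )
        active = appointments[mask]
        n_patients = active["patient_id"].nunique()
        n_providers = active["provider_id"].nunique()
        diagnoses = int((registry["diagnosis_date"].dt.year == year).sum())
        t_weights = aggregate_temporal_frame(relationships, window)
        a_weights = aggregate_atemporal_frame(appointments, window)
        denom = n_providers * (n_providers - 1)
        rows.append(
            {
                "year": year,
                "diagnoses": diagnoses,
                "patients": int(n_patients),
                "providers": int(n_providers),
                "temporal_edges": len(t_weights),
                "atemporal_edges": len(a_weights),
                "temporal_weight_sum": int(t_weights["weight"].sum()) if len(t_weights) else 0,
                "atemporal_weight_sum": int(a_weights["weight"].sum()) if len(a_weights) else 0,
                "temporal_density": 2.0 * len(t_weights) / denom if denom else 0.0,
                "atemporal_density": 2.0 * len(a_weights) / denom if denom else 0.0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "year",
            "diagnoses",
            "patients",
            "providers",
            "temporal_edges",
            "atemporal_edges",
            "temporal_weight_sum",
            "atemporal_weight_sum",
            "temporal_density",
            "atemporal_density",
        ],
    )
    return MeasureReport(
        name="yearly_institutional_stats",
        table=table,
        meta={"containment_policy": containment_policy},
    )


# ---------------------------------------------------------------------------
# relative-time analyses


def relative_care_density(
    appointments: pd.DataFrame,
    provider_id: str,
    max_years: int | None = None,
    relationships: pd.DataFrame | None = None,
    containment_policy: str = "contained",
    days_per_year: float = DAYS_PER_YEAR,
) -> list[tuple[int, float]]:
    """Ego care density by year in network, relative to the provider's
    enter date.

    Year k covers day offsets ``[(k-1)*days_per_year, k*days_per_year)``
    from the provider's first appointment across all patients.  Each year's
    value is the care density of the ego edges whose relationship interval is
    admitted by that year's window (offsets compared under
    ``containment_policy``); a year with no admitted edges reports 0.
    """
    mine = appointments[appointments["provider_id"] == provider_id]
    if mine.empty:
        raise KeyError(f"provider {provider_id!r} has no appointments")
    enter = mine["date"].min()
    last = mine["date"].max()
    if max_years is None:
        max_years = int((last - enter).days / days_per_year) + 1
    if relationships is None:
        relationships = patient_relationships(appointments)
    ego = relationships[
        (relationships["provider_a"] == provider_id)
        | (relationships["provider_b"] == provider_id)
    ].copy()
    start_off = (ego["start_date"] - enter).dt.days.to_numpy(dtype=float)
    end_off = (ego["end_date"] - enter).dt.days.to_numpy(dtype=float)
    out: list[tuple[int, float]] = []
    for k in range(1, max_years + 1):
        lo = (k - 1) * days_per_year
        hi = k * days_per_year
        if containment_policy == "contained":
            admitted = (start_off >= lo) & (end_off < hi)
        else:
            admitted = (start_off < hi) & (end_off >= lo)
        sub = ego[admitted]
        if sub.empty:
            out.append((k, 0.0))
            continue
        weights = (
            sub.drop_duplicates(["patient_id", "provider_a", "provider_b"])
            .groupby(["provider_a", "provider_b"])
            .size()
        )
        out.append((k, float(weights.mean())))
    return out


def provider_tenure_stats(
    appointments: pd.DataFrame,
    providers: pd.DataFrame | None = None,
    month_days: float = DAYS_PER_MONTH,
) -> MeasureReport:
    """Provider tenure in the institutional network.

    Tenure is (last - first appointment date across all patients) in days
    divided by ``month_days``.  Reports, for all providers and for the
    oncology-related subset when a provider table is supplied: mean and
    median tenure in months, the fraction of providers with exactly one
    appointment row overall, and the fraction with tenure of at least 12
    months (and at least 5 and 10 years for the oncology rows).
    """
    per = appointments.groupby("provider_id")["date"].agg(["min", "max", "count"])
    per["tenure_months"] = (per["max"] - per["min"]).dt.days / month_days

    def _row(group: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        if n == 0:
            return {
                "group": group,
                "n_providers": 0,
                "mean_tenure_months": 0.0,
                "median_tenure_months": 0.0,
                "single_appointment_fraction": 0.0,
                "fraction_tenure_ge_1y": 0.0,
                "fraction_tenure_ge_5y": 0.0,
                "fraction_tenure_ge_10y": 0.0,
            }
        return {
            "group": group,
            "n_providers": n,
            "mean_tenure_months": float(sub["tenure_months"].mean()),
            "median_tenure_months": float(sub["tenure_months"].median()),
            "single_appointment_fraction": float((sub["count"] == 1).mean()),
            "fraction_tenure_ge_1y": float((sub["tenure_months"] >= 12.0).mean()),
            "fraction_tenure_ge_5y": float((sub["tenure_months"] >= 60.0).mean()),
            "fraction_tenure_ge_10y": float((sub["tenure_months"] >= 120.0).mean()),
        }

    rows = [_row("all", per)]
    if providers is not None:
        onc_ids = set(providers.loc[providers["oncology_related"], "provider_id"])
        rows.append(_row("oncology_related", per[per.index.isin(onc_ids)]))
    return MeasureReport(
        name="provider_tenure_stats",
        table=pd.DataFrame(rows),
        meta={"month_days": month_days},
    )


def patient_retention(
    appointments: pd.DataFrame,
    registry: pd.DataFrame,
    horizons_years: Sequence[float] = (2, 5, 10),
    study_end: dt.date | None = None,
    denominator: str = "at_risk",
    days_per_year: float = DAYS_PER_YEAR,
) -> list[tuple[float, float]]:
    """Fraction of patients still in the network at each horizon.

    A patient's span runs from their first appointment on/after diagnosis to
    their last appointment overall; the patient is retained at horizon h when
    the span is at least ``h * days_per_year`` days.  With the default
    ``denominator="at_risk"`` the horizon-h denominator is restricted to
    patients diagnosed at least h years before ``study_end`` (patients for
    whom retention at h is observable); ``denominator="all_patients"`` uses
    every cohort patient.
    """
    if denominator not in ("at_risk", "all_patients"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if registry.empty:
        return [(float(h), 0.0) for h in horizons_years]
    if study_end is None:
        study_end = appointments["date"].max().date()
    end_ts = pd.Timestamp(study_end)

    merged = appointments.merge(
        registry[["patient_id", "diagnosis_date"]], on="patient_id"
    )
    post = merged[merged["date"] >= merged["diagnosis_date"]]
    first_post = post.groupby("patient_id")["date"].min()
    last_any = merged.groupby("patient_id")["date"].max()
    span_days = (last_any - first_post).dt.days.dropna()

    diag = registry.set_index("patient_id")["diagnosis_date"]
    out: list[tuple[float, float]] = []
    for h in horizons_years:
        need = h * days_per_year
        if denominator == "at_risk":
            at_risk = diag.index[(end_ts - diag).dt.days >= need]
        else:
            at_risk = diag.index
        if len(at_risk) == 0:
            out.append((float(h), 0.0))
            continue
        spans = span_days.reindex(at_risk).fillna(-1.0)
        out.append((float(h), float((spans >= need).mean())))
    return out


def oncology_fraction_by_month(
    appointments: pd.DataFrame,
    registry: pd.DataFrame,
    providers: pd.DataFrame,
    stage_filter: str | None = None,
    month_days: float = DAYS_PER_MONTH,
) -> list[tuple[int, float]]:
    """Percent of appointments with oncology-related providers, by month
    relative to diagnosis.

    Month m buckets appointments with day offset in
    ``[m * month_days, (m+1) * month_days)`` from the patient's diagnosis
    date (negative months hold pre-diagnosis appointments).  Months without
    appointments are absent from the output.
    """
    reg = registry
    if stage_filter is not None:
        reg = reg[reg["stage"] == stage_filter]
    merged = appointments.merge(
        reg[["patient_id", "diagnosis_date"]], on="patient_id"
    )
    if merged.empty:
        return []
    offsets = (merged["date"] - merged["diagnosis_date"]).dt.days
    months = np.floor(offsets / month_days).astype(int)
    onc_ids = set(providers.loc[providers["oncology_related"], "provider_id"])
    is_onc = merged["provider_id"].isin(onc_ids)
    grouped = pd.DataFrame({"month": months, "onc": is_onc}).groupby("month")["onc"]
    return [
        (int(month), float(100.0 * frac))
        for month, frac in grouped.mean().sort_index().items()
    ]


# ---------------------------------------------------------------------------
# cohort summary (per-stage and pooled)


def _dist_rows(stage: str, metric: str, values: pd.Series | np.ndarray) -> list[dict]:
    values = pd.Series(values, dtype=float)
    if values.empty:
        stats = {"mean": 0.0, "median": 0.0, "min": 0.0, "max": 0.0}
    else:
        stats = {
            "mean": float(values.mean()),
            "median": float(values.median()),
            "min": float(values.min()),
            "max": float(values.max()),
        }
    return [
        {"stage": stage, "metric": metric, "statistic": name, "value": value}
        for name, value in stats.items()
    ]


def _summary_rows(
    stage: str, registry: pd.DataFrame, appointments: pd.DataFrame
) -> list[dict]:
    window = _full_window()
    rows: list[dict] = []
    providers_per_patient = appointments.groupby("patient_id")["provider_id"].nunique()
    appts_per_patient = appointments.groupby("patient_id").size()
    node_sizes = appointments.groupby("provider_id")["patient_id"].nunique()
    relationships = patient_relationships(appointments)
    t_weights = aggregate_temporal_frame(relationships, window)
    a_weights = aggregate_atemporal_frame(appointments, window)

    rows += _dist_rows(stage, "providers_per_patient", providers_per_patient)
    rows += _dist_rows(stage, "appointments_per_patient", appts_per_patient)
    rows += _dist_rows(stage, "node_size", node_sizes)
    rows += _dist_rows(stage, "temporal_edge_size", t_weights.get("weight", pd.Series(dtype=float)))
    rows += _dist_rows(stage, "atemporal_edge_size", a_weights.get("weight", pd.Series(dtype=float)))
    for metric, count in (
        ("patients", appointments["patient_id"].nunique()),
        ("providers", appointments["provider_id"].nunique()),
        ("temporal_edges", len(t_weights)),
        ("atemporal_edges", len(a_weights)),
    ):
        rows.append(
            {"stage": stage, "metric": metric, "statistic": "count", "value": float(count)}
        )
    return rows


def cohort_summary(
    registry: pd.DataFrame,
    appointments: pd.DataFrame,
    by_stage: bool = False,
) -> MeasureReport:
    """Distributional summary of the cohort network.

    Reports mean/median/min/max of providers per patient, appointment rows
    per patient, node patient counts, and temporal/atemporal edge weights,
    plus patient/provider/edge counts — pooled, and per stage when
    ``by_stage`` is set.  Providers may repeat across stages, so pooled
    provider counts are at most the per-stage sum.
    """
    rows = _summary_rows("all", registry, appointments)
    if by_stage:
        for stage in sorted(registry["stage"].unique()):
            ids = set(registry.loc[registry["stage"] == stage, "patient_id"])
            sub_reg = registry[registry["patient_id"].isin(ids)]
            sub_app = appointments[appointments["patient_id"].isin(ids)]
            rows += _summary_rows(stage, sub_reg, sub_app)
    table = pd.DataFrame(rows, columns=["stage", "metric", "statistic", "value"])
    return MeasureReport(
        name="cohort_summary", table=table, meta={"by_stage": by_stage}
    )
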