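"""Edge construction: timeline projection versus the atemporal baseline.

Per-patient operations (:func:`build_intervals`, :func:`temporal_pairs`,
:func:`atemporal_pairs`) work on typed records and are the reference
implementation.  The frame-level helpers (:func:`patient_relationships`,
:func:`patient_copairs`) vectorise the same computation over a whole cohort
and are used by the measure suite; tests assert the two routes agree.

Temporal semantics: each provider's membership in a patient's care timeline
is the closed interval from their first to their last appointment with that
patient.  Two providers are related for a patient exactly when those
intervals overlap, overlap-on-one-day included; the relationship carries the
overlap interval as its duration.  The atemporal baseline instead pairs every
two providers who ever saw the same patient, regardless of timing.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence, Union

import pandas as pd

from .types import (
    AggregatedEdge,
    AnalysisWindow,
    Appointment,
    NetworkSnapshot,
    PairRelationship,
    ProviderInterval,
)

AppointmentsLike = Union[pd.DataFrame, Sequence[Appointment]]


def _one_patient_frame(appointments: AppointmentsLike) -> pd.DataFrame:
    if isinstance(appointments, pd.DataFrame):
        df = appointments
    else:
        from .io import appointments_from_records

        df = appointments_from_records(appointments)
    if df.empty:
        return df
    patients = df["patient_id"].unique()
    if len(patients) > 1:
        raise ValueError(
            f"expected appointments of a single patient, got {len(patients)} patients"
        )
    return df


def build_intervals(appointments: AppointmentsLike) -> list[ProviderInterval]:
    """Provider [enter, exit] spans for one patient's appointments.

    One interval per distinct provider: enter is the provider's earliest
    appointment date with this patient, exit the latest.  Duplicate same-day
    rows cannot change the min/max and so change nothing.
    """
    df = _one_patient_frame(appointments)
    if df.empty:
        return []
    patient_id = df["patient_id"].iloc[0]
    agg = df.groupby("provider_id")["date"].agg(["min", "max"]).sort_index()
    return [
        ProviderInterval(
            patient_id=patient_id,
            provider_id=provider,
            enter_date=row["min"].date(),
            exit_date=row["max"].date(),
        )
        for provider, row in agg.iterrows()
    ]


def temporal_pairs(intervals: Sequence[ProviderInterval]) -> list[PairRelationship]:
    """All overlapping interval pairs for one patient, with their overlaps.

    A pair is related iff ``max(enter_a, enter_b) <= min(exit_a, exit_b)``;
    closed-interval semantics, so touching on a single shared day counts.
    """
    if not intervals:
        return []
    patients = {iv.patient_id for iv in intervals}
    if len(patients) > 1:
        raise ValueError(f"intervals span {len(patients)} patients, expected 1")
    providers = [iv.provider_id for iv in intervals]
    if len(set(providers)) != len(providers):
        raise ValueError("expected at most one interval per provider")

    out: list[PairRelationship] = []
    ordered = sorted(intervals, key=lambda iv: iv.provider_id)
    for iv_a, iv_b in combinations(ordered, 2):
        start = max(iv_a.enter_date, iv_b.enter_date)
        end = min(iv_a.exit_date, iv_b.exit_date)
        if start <= end:
            out.append(
                PairRelationship(
                    patient_id=iv_a.patient_id,
                    provider_a=iv_a.provider_id,
                    provider_b=iv_b.provider_id,
                    start_date=start,
                    end_date=end,
                )
            )
    return out


def atemporal_pairs(appointments: AppointmentsLike) -> list[tuple[str, str]]:
    """All C(k, 2) provider pairs over one patient's k distinct providers."""
    df = _one_patient_frame(appointments)
    if df.empty:
        return []
    providers = sorted(df["provider_id"].unique())
    return list(combinations(providers, 2))


# ---------------------------------------------------------------------------
# cohort-scale (vectorised) construction


def provider_intervals_frame(appointments: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, provider) enter/exit dates for a whole cohort.

    Columns: patient_id, provider_id, enter_date, exit_date.
    """
    if appointments.empty:
        return pd.DataFrame(
            columns=["patient_id", "provider_id", "enter_date", "exit_date"]
        )
    agg = (
        appointments.groupby(["patient_id", "provider_id"], sort=True)["date"]
        .agg(enter_date="min", exit_date="max")
        .reset_index()
    )
    return agg


def patient_relationships(appointments: pd.DataFrame) -> pd.DataFrame:
    """Temporal pair relationships for every patient in one pass.

    Returns columns patient_id, provider_a, provider_b, start_date, end_date
    with providers in canonical order; equivalent to mapping
    ``temporal_pairs(build_intervals(...))`` over patients.
    """
    iv = provider_intervals_frame(appointments)
    if iv.empty:
        return pd.DataFrame(
            columns=["patient_id", "provider_a", "provider_b", "start_date", "end_date"]
        )
    merged = iv.merge(iv, on="patient_id", suffixes=("_a", "_b"))
    merged = merged[merged["provider_id_a"] < merged["provider_id_b"]]
    start = merged[["enter_date_a", "enter_date_b"]].max(axis=1)
    end = merged[["exit_date_a", "exit_date_b"]].min(axis=1)
    keep = start <= end
    out = pd.DataFrame(
        {
            "patient_id": merged.loc[keep, "patient_id"],
            "provider_a": merged.loc[keep, "provider_id_a"],
            "provider_b": merged.loc[keep, "provider_id_b"],
            "start_date": start[keep],
            "end_date": end[keep],
        }
    ).reset_index(drop=True)
    return out


def relationships_to_records(frame: pd.DataFrame) -> list[PairRelationship]:
    return [
        PairRelationship(
            patient_id=row.patient_id,
            provider_a=row.provider_a,
            provider_b=row.provider_b,
            start_date=row.start_date.date(),
            end_date=row.end_date.date(),
        )
        for row in frame.itertuples(index=False)
    ]


def patient_copairs(
    appointments: pd.DataFrame, window: AnalysisWindow | None = None
) -> pd.DataFrame:
    """Atemporal per-patient provider pairs, optionally windowed.

    When a window is given, a provider participates for a patient only if it
    has at least one appointment with that patient dated inside the window.
    Columns: patient_id, provider_a, provider_b.
    """
    df = appointments
    if window is not None:
        mask = (df["date"] >= pd.Timestamp(window.start)) & (
            df["date"] <= pd.Timestamp(window.end)
        )
        df = df[mask]
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "provider_a", "provider_b"])
    membership = df[["patient_id", "provider_id"]].drop_duplicates()
    merged = membership.merge(membership, on="patient_id", suffixes=("_a", "_b"))
    merged = merged[merged["provider_id_a"] < merged["provider_id_b"]]
    return pd.DataFrame(
        {
            "patient_id": merged["patient_id"],
            "provider_a": merged["provider_id_a"],
            "provider_b": merged["provider_id_b"],
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregation


def _window_mask(frame: pd.DataFrame, window: AnalysisWindow) -> pd.Series:
    start_ts, end_ts = pd.Timestamp(window.start), pd.Timestamp(window.end)
    if window.containment_policy == "contained":
        return (frame["start_date"] >= start_ts) & (frame["end_date"] <= end_ts)
    return (frame["start_date"] <= end_ts) & (frame["end_date"] >= start_ts)


def aggregate_temporal_frame(
    relationships: pd.DataFrame, window: AnalysisWindow
) -> pd.DataFrame:
    """Distinct-patient weights per pair for relationships admitted by the
    window under its containment policy.  Columns: provider_a, provider_b,
    weight."""
    if relationships.empty:
        return pd.DataFrame(columns=["provider_a", "provider_b", "weight"])
    admitted = relationships[_window_mask(relationships, window)]
    weights = (
        admitted.drop_duplicates(["patient_id", "provider_a", "provider_b"])
        .groupby(["provider_a", "provider_b"], sort=True)
        .size()
        .rename("weight")
        .reset_index()
    )
    return weights


def aggregate_atemporal_frame(
    appointments: pd.DataFrame, window: AnalysisWindow
) -> pd.DataFrame:
    """Distinct-patient weights per pair in the atemporal baseline; a patient
    counts toward a pair iff both providers saw them inside the window."""
    pairs = patient_copairs(appointments, window)
    if pairs.empty:
        return pd.DataFrame(columns=["provider_a", "provider_b", "weight"])
    weights = (
        pairs.drop_duplicates(["patient_id", "provider_a", "provider_b"])
        .groupby(["provider_a", "provider_b"], sort=True)
        .size()
        .rename("weight")
        .reset_index()
    )
    return weights


def _frame_to_edges(
    weights: pd.DataFrame, kind: str, window: AnalysisWindow
) -> list[AggregatedEdge]:
    return [
        AggregatedEdge(
            provider_a=row.provider_a,
            provider_b=row.provider_b,
            weight=int(row.weight),
            kind=kind,
            window=window,
        )
        for row in weights.itertuples(index=False)
    ]


def aggregate_edges(
    data: Union[pd.DataFrame, Iterable[PairRelationship]],
    kind: str,
    window: AnalysisWindow,
) -> list[AggregatedEdge]:
    """Aggregate per-patient pairs into weighted edges for one window.

    ``kind="temporal"`` expects `PairRelationship` records (or the equivalent
    relationship frame); a patient counts toward a pair when the
    relationship's [start, end] is admitted by the window under its
    containment policy.  ``kind="atemporal"`` expects the appointments frame;
    a patient counts toward a pair when both providers saw the patient inside
    the window.  Pairs with weight zero are omitted.

    Passing temporal relationships with ``kind="atemporal"`` (or vice versa)
    is a usage error and raises ``TypeError``.
    """
    if kind == "temporal":
        if isinstance(data, pd.DataFrame):
            required = {"patient_id", "provider_a", "provider_b", "start_date", "end_date"}
            if not required.issubset(data.columns):
                raise TypeError(
                    "temporal aggregation requires a relationship frame with "
                    f"columns {sorted(required)}"
                )
            frame = data
        else:
            records = list(data)
            if any(not isinstance(r, PairRelationship) for r in records):
                raise TypeError(
                    "temporal aggregation requires PairRelationship records"
                )
            frame = pd.DataFrame(
                {
                    "patient_id": [r.patient_id for r in records],
                    "provider_a": [r.provider_a for r in records],
                    "provider_b": [r.provider_b for r in records],
                    "start_date": pd.to_datetime([r.start_date for r in records]),
                    "end_date": pd.to_datetime([r.end_date for r in records]),
                }
            )
        weights = aggregate_temporal_frame(frame, window)
    elif kind == "atemporal":
        if not isinstance(data, pd.DataFrame) or "date" not in getattr(
            data, "columns", ()
        ):
            raise TypeError(
                "atemporal aggregation requires the appointments frame "
                "(patient_id, provider_id, date)"
            )
        weights = aggregate_atemporal_frame(data, window)
    else:
        raise ValueError(f"kind must be 'temporal' or 'atemporal', got {kind!r}")
    return _frame_to_edges(weights, kind, window)


def node_patient_counts(
    appointments: pd.DataFrame, window: AnalysisWindow | None = None
) -> dict[str, int]:
    """Distinct patients seen per provider inside the window."""
    df = appointments
    if window is not None:
        mask = (df["date"] >= pd.Timestamp(window.start)) & (
            df["date"] <= pd.Timestamp(window.end)
        )
        df = df[mask]
    if df.empty:
        return {}
    counts = df.groupby("provider_id")["patient_id"].nunique()
    return {str(k): int(v) for k, v in counts.items()}


def build_snapshot(
    appointments: pd.DataFrame,
    edges: Sequence[AggregatedEdge],
    window: AnalysisWindow,
) -> NetworkSnapshot:
    """Assemble the window's provider graph.

    Nodes are all providers with at least one appointment inside the window
    (isolated providers included), weighted by distinct patients seen.  An
    edge endpoint without any in-window appointment is a consistency error.
    """
    nodes = node_patient_counts(appointments, window)
    for edge in edges:
        for endpoint in edge.pair:
            if endpoint not in nodes:
                raise ValueError(
                    f"edge endpoint {endpoint!r} has no appointments in the window"
                )
    ordered = tuple(
        sorted(edges, key=lambda e: (e.kind, e.provider_a, e.provider_b))
    )
    return NetworkSnapshot(nodes=nodes, edges=ordered, window=window)
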