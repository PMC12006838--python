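"""Input readers with validation, cohort filtering, and graph exporters.

Tabular collections are plain pandas DataFrames with fixed column names:

* appointments: ``patient_id``, ``provider_id``, ``date`` (datetime64)
* registry:     ``patient_id``, ``diagnosis_date`` (datetime64), ``stage``
* providers:    ``provider_id``, ``specialty``, ``oncology_related`` (bool),
                ``fte_status``

Converters to and from the record dataclasses in :mod:`carenet.types` are
provided for callers that prefer typed rows.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from dateutil.relativedelta import relativedelta

from .types import (
    FTE_STATUSES,
    STAGES,
    AggregatedEdge,
    AnalysisWindow,
    Appointment,
    NetworkSnapshot,
    ProviderRecord,
    RegistryRecord,
)

logger = logging.getLogger(__name__)

APPOINTMENT_COLUMNS = ("patient_id", "provider_id", "appointment_date")
REGISTRY_COLUMNS = ("patient_id", "diagnosis_date", "stage")
PROVIDER_COLUMNS = ("provider_id", "specialty", "oncology_related")

EDGE_LIST_COLUMNS = (
    "provider_a",
    "provider_b",
    "weight",
    "kind",
    "window_start",
    "window_end",
    "window_anchor",
    "window_policy",
)


class SchemaError(ValueError):
    """The file's header does not match the declared CSV schema."""


class DataValidationError(ValueError):
    """A row failed validation; the message names the offending line."""


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _parse_dates(raw: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() | (raw.str.len() == 0)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in raw.index[bad][:5]]
        raise DataValidationError(
            f"{path}: unparseable {column} value(s), e.g. "
            f"{raw[bad].iloc[0]!r} at line {lines[0]} (bad lines: {lines})"
        )
    return parsed


def _check_ids(raw: pd.Series, path, column: str) -> None:
    bad = raw.str.len() == 0
    if bad.any():
        line = int(raw.index[bad][0]) + 2
        raise DataValidationError(f"{path}: empty {column} at line {line}")


def read_appointments(path) -> pd.DataFrame:
    """Read an appointments CSV into a validated frame.

    Duplicate rows are preserved: they count toward appointment totals but do
    not change provider intervals.
    """
    df = _read_csv(path, APPOINTMENT_COLUMNS)
    _check_ids(df["patient_id"], path, "patient_id")
    _check_ids(df["provider_id"], path, "provider_id")
    dates = _parse_dates(df["appointment_date"], path, "appointment_date")
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "provider_id": df["provider_id"],
            "date": dates,
        }
    )
    logger.info("read %d appointment rows from %s", len(out), path)
    return out


def read_registry(path) -> pd.DataFrame:
    df = _read_csv(path, REGISTRY_COLUMNS)
    _check_ids(df["patient_id"], path, "patient_id")
    dup = df["patient_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise DataValidationError(
            f"{path}: duplicate registry record for patient "
            f"{df['patient_id'][dup].iloc[0]!r} at line {line}"
        )
    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        line = int(df.index[bad_stage][0]) + 2
        raise DataValidationError(
            f"{path}: stage must be one of {STAGES}, got "
            f"{df['stage'][bad_stage].iloc[0]!r} at line {line}"
        )
    dates = _parse_dates(df["diagnosis_date"], path, "diagnosis_date")
    return pd.DataFrame(
        {"patient_id": df["patient_id"], "diagnosis_date": dates, "stage": df["stage"]}
    )


def read_providers(path) -> pd.DataFrame:
    """Read the provider roster; ``fte_status`` is optional in the file."""
    df = _read_csv(path, PROVIDER_COLUMNS)
    _check_ids(df["provider_id"], path, "provider_id")
    dup = df["provider_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise DataValidationError(
            f"{path}: duplicate provider record at line {line}"
        )
    onc = df["oncology_related"].str.strip()
    bad = ~onc.isin(["0", "1"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise DataValidationError(
            f"{path}: oncology_related must be 0 or 1, got "
            f"{onc[bad].iloc[0]!r} at line {line}"
        )
    if "fte_status" in df.columns:
        fte = df["fte_status"].replace("", "unknown")
        bad_fte = ~fte.isin(FTE_STATUSES)
        if bad_fte.any():
            line = int(df.index[bad_fte][0]) + 2
            raise DataValidationError(
                f"{path}: fte_status must be one of {FTE_STATUSES}, got "
                f"{fte[bad_fte].iloc[0]!r} at line {line}"
            )
    else:
        fte = pd.Series(["unknown"] * len(df), index=df.index)
    return pd.DataFrame(
        {
            "provider_id": df["provider_id"],
            "specialty": df["specialty"].replace("", "unknown"),
            "oncology_related": onc == "1",
            "fte_status": fte,
        }
    )


def write_appointments(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "provider_id": df["provider_id"],
            "appointment_date": pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d"),
        }
    )
    out.to_csv(path, index=False)


def write_registry(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "diagnosis_date": pd.to_datetime(df["diagnosis_date"]).dt.strftime(
                "%Y-%m-%d"
            ),
            "stage": df["stage"],
        }
    )
    out.to_csv(path, index=False)


def write_providers(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "provider_id": df["provider_id"],
            "specialty": df["specialty"],
            "oncology_related": df["oncology_related"].astype(int),
            "fte_status": df["fte_status"],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# record-level converters


def appointments_to_records(df: pd.DataFrame) -> list[Appointment]:
    return [
        Appointment(row.patient_id, row.provider_id, row.date.date())
        for row in df.itertuples(index=False)
    ]


def appointments_from_records(records: Iterable[Appointment]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "provider_id": [r.provider_id for r in records],
            "date": pd.to_datetime([r.date for r in records]),
        }
    )


def registry_to_records(df: pd.DataFrame) -> list[RegistryRecord]:
    return [
        RegistryRecord(row.patient_id, row.diagnosis_date.date(), row.stage)
        for row in df.itertuples(index=False)
    ]


def providers_to_records(df: pd.DataFrame) -> list[ProviderRecord]:
    return [
        ProviderRecord(
            row.provider_id, row.specialty, bool(row.oncology_related), row.fte_status
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# cohort filtering


def filter_cohort(
    registry: pd.DataFrame,
    appointments: pd.DataFrame,
    study_end: dt.date,
    window_months: int = 6,
    lookback_years: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rule and restrict the appointment window.

    A patient is eligible when they have at least one appointment between
    their diagnosis date and ``window_months`` calendar months after it
    (day-clamped, inclusive on both ends).  For eligible patients, only
    appointments dated within ``[diagnosis - lookback_years, study_end]``
    are kept.  Appointments whose patient is absent from the registry are
    dropped with a logged warning.

    Returns ``(eligible_registry, restricted_appointments)``.
    """
    if registry.empty:
        return registry.iloc[0:0].copy(), appointments.iloc[0:0].copy()

    known = appointments["patient_id"].isin(set(registry["patient_id"]))
    if (~known).any():
        logger.warning(
            "dropping %d appointment row(s) for %d patient(s) missing from the "
            "registry",
            int((~known).sum()),
            appointments.loc[~known, "patient_id"].nunique(),
        )
    appts = appointments[known]

    bounds = registry[["patient_id", "diagnosis_date"]].copy()
    diag = [d.date() for d in bounds["diagnosis_date"]]
    bounds["inclusion_end"] = pd.to_datetime(
        [d + relativedelta(months=window_months) for d in diag]
    )
    bounds["lookback_start"] = pd.to_datetime(
        [d - relativedelta(years=lookback_years) for d in diag]
    )

    merged = appts.merge(bounds, on="patient_id", how="left")
    end_ts = pd.Timestamp(study_end)
    # the qualifying visit must itself fall inside the extraction bounds,
    # otherwise filtering would not be idempotent
    qualifies = (
        (merged["date"] >= merged["diagnosis_date"])
        & (merged["date"] <= merged["inclusion_end"])
        & (merged["date"] <= end_ts)
    )
    eligible_ids = set(merged.loc[qualifies, "patient_id"])

    eligible_registry = registry[registry["patient_id"].isin(eligible_ids)].copy()
    keep = (
        merged["patient_id"].isin(eligible_ids)
        & (merged["date"] >= merged["lookback_start"])
        & (merged["date"] <= end_ts)
    )
    restricted = appts[keep.to_numpy()].copy()
    logger.info(
        "cohort filter: %d/%d patients eligible, %d/%d appointment rows retained",
        len(eligible_registry),
        len(registry),
        len(restricted),
        len(appointments),
    )
    return eligible_registry.reset_index(drop=True), restricted.reset_index(drop=True)


# ---------------------------------------------------------------------------
# edge-list and GraphML export


def write_edge_list(edges: Sequence[AggregatedEdge], path) -> None:
    """Write aggregated edges as TSV; round-trips through `read_edge_list`."""
    rows = sorted(edges, key=lambda e: (e.kind, e.provider_a, e.provider_b))
    df = pd.DataFrame(
        {
            "provider_a": [e.provider_a for e in rows],
            "provider_b": [e.provider_b for e in rows],
            "weight": [e.weight for e in rows],
            "kind": [e.kind for e in rows],
            "window_start": [e.window.start.isoformat() for e in rows],
            "window_end": [e.window.end.isoformat() for e in rows],
            "window_anchor": [e.window.anchor for e in rows],
            "window_policy": [e.window.containment_policy for e in rows],
        },
        columns=list(EDGE_LIST_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[AggregatedEdge]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing edge-list column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        window = AnalysisWindow(
            start=dt.date.fromisoformat(row.window_start),
            end=dt.date.fromisoformat(row.window_end),
            anchor=row.window_anchor,
            containment_policy=row.window_policy,
        )
        out.append(
            AggregatedEdge(
                provider_a=row.provider_a,
                provider_b=row.provider_b,
                weight=int(row.weight),
                kind=row.kind,
                window=window,
            )
        )
    return out


def snapshot_to_graph(snapshot: NetworkSnapshot) -> nx.Graph:
    """Undirected weighted graph view of a snapshot."""
    g = nx.Graph()
    for provider, patient_count in snapshot.nodes.items():
        g.add_node(provider, patient_count=int(patient_count))
    for edge in snapshot.edges:
        g.add_edge(edge.provider_a, edge.provider_b, weight=int(edge.weight))
    return g


def write_graphml(snapshot: NetworkSnapshot, path) -> None:
    """Export a snapshot as GraphML with node ``patient_count`` and edge
    ``weight`` attributes.  Snapshot construction already guarantees every
    edge endpoint is a node."""
    nx.write_graphml(snapshot_to_graph(snapshot), path)


def read_graphml(path, window: AnalysisWindow, kind: str = "temporal") -> NetworkSnapshot:
    """Parse a GraphML written by :func:`write_graphml` back to a snapshot."""
    g = nx.read_graphml(path)
    nodes = {n: int(data.get("patient_count", 0)) for n, data in g.nodes(data=True)}
    edges = []
    for a, b, data in g.edges(data=True):
        a, b = (a, b) if a < b else (b, a)
        edges.append(
            AggregatedEdge(
                provider_a=a,
                provider_b=b,
                weight=int(data.get("weight", 1)),
                kind=kind,
                window=window,
            )
        )
    edges.sort(key=lambda e: (e.provider_a, e.provider_b))
    return NetworkSnapshot(nodes=nodes, edges=tuple(edges), window=window)
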