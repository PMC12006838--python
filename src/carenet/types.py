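"""Record types shared across the package.

All records are immutable dataclasses validated at construction time, so a
constructed value is always internally consistent.  Dates are day-granular
``datetime.date`` objects throughout; pandas frames elsewhere in the package
carry them as ``datetime64[ns]`` columns and convert at the boundary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

STAGES = ("I", "II", "III")
FTE_STATUSES = ("full_time", "part_time", "unknown")
ANCHORS = ("absolute", "relative_to_diagnosis", "relative_to_provider_enter")
POLICIES = ("contained", "intersects")
EDGE_KINDS = ("temporal", "atemporal")


def _require_id(value: str, name: str) -> None:
    if not isinstance(value, str) or not value:
        raise ValueError(f"{name} must be a non-empty string, got {value!r}")


def _require_date(value, name: str) -> None:
    # bool/datetime are technically date-like; insist on a plain date
    if not isinstance(value, dt.date) or isinstance(value, dt.datetime):
        raise TypeError(f"{name} must be a datetime.date, got {type(value).__name__}")


@dataclass(frozen=True, slots=True)
class Appointment:
    """One patient-provider encounter on a calendar date."""

    patient_id: str
    provider_id: str
    date: dt.date

    def __post_init__(self) -> None:
        _require_id(self.patient_id, "patient_id")
        _require_id(self.provider_id, "provider_id")
        _require_date(self.date, "date")


@dataclass(frozen=True, slots=True)
class RegistryRecord:
    """Tumor-registry entry: diagnosis date and stage for one patient."""

    patient_id: str
    diagnosis_date: dt.date
    stage: str

    def __post_init__(self) -> None:
        _require_id(self.patient_id, "patient_id")
        _require_date(self.diagnosis_date, "diagnosis_date")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")


@dataclass(frozen=True, slots=True)
class ProviderRecord:
    """Provider roster entry with specialty label and oncology flag."""

    provider_id: str
    specialty: str = "unknown"
    oncology_related: bool = False
    fte_status: str = "unknown"

    def __post_init__(self) -> None:
        _require_id(self.provider_id, "provider_id")
        if self.fte_status not in FTE_STATUSES:
            raise ValueError(
                f"fte_status must be one of {FTE_STATUSES}, got {self.fte_status!r}"
            )


@dataclass(frozen=True, slots=True)
class AnalysisWindow:
    """Closed date window ``[start, end]`` with an anchoring convention.

    ``containment_policy`` controls how date intervals are assigned to the
    window during edge aggregation: ``contained`` requires the whole interval
    to lie inside the window, ``intersects`` requires a non-empty overlap.
    """

    start: dt.date
    end: dt.date
    anchor: str = "absolute"
    containment_policy: str = "contained"

    def __post_init__(self) -> None:
        _require_date(self.start, "start")
        _require_date(self.end, "end")
        if self.start > self.end:
            raise ValueError(f"window start {self.start} is after end {self.end}")
        if self.anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}, got {self.anchor!r}")
        if self.containment_policy not in POLICIES:
            raise ValueError(
                f"containment_policy must be one of {POLICIES}, "
                f"got {self.containment_policy!r}"
            )

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    def contains_interval(self, start: dt.date, end: dt.date) -> bool:
        return self.start <= start and end <= self.end

    def intersects_interval(self, start: dt.date, end: dt.date) -> bool:
        return start <= self.end and end >= self.start

    def admits_interval(self, start: dt.date, end: dt.date) -> bool:
        """Apply the configured containment policy to ``[start, end]``."""
        if self.containment_policy == "contained":
            return self.contains_interval(start, end)
        return self.intersects_interval(start, end)

    @classmethod
    def year(cls, year: int, containment_policy: str = "contained") -> "AnalysisWindow":
        """Calendar-year window, a convenience for yearly institutional stats."""
        return cls(
            start=dt.date(year, 1, 1),
            end=dt.date(year, 12, 31),
            containment_policy=containment_policy,
        )


@dataclass(frozen=True, slots=True)
class ProviderInterval:
    """A provider's membership span in one patient's care timeline.

    ``enter_date``/``exit_date`` are the provider's first/last actual
    appointment dates with this patient, so a single visit yields a
    degenerate interval with enter == exit.
    """

    patient_id: str
    provider_id: str
    enter_date: dt.date
    exit_date: dt.date

    def __post_init__(self) -> None:
        _require_id(self.patient_id, "patient_id")
        _require_id(self.provider_id, "provider_id")
        _require_date(self.enter_date, "enter_date")
        _require_date(self.exit_date, "exit_date")
        if self.enter_date > self.exit_date:
            raise ValueError(
                f"enter_date {self.enter_date} after exit_date {self.exit_date}"
            )


@dataclass(frozen=True, slots=True)
class PairRelationship:
    """Temporal co-care relationship between two providers for one patient.

    ``[start_date, end_date]`` is the closed overlap of the two provider
    intervals; providers are stored in canonical lexicographic order.
    """

    patient_id: str
    provider_a: str
    provider_b: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        _require_id(self.patient_id, "patient_id")
        _require_id(self.provider_a, "provider_a")
        _require_id(self.provider_b, "provider_b")
        if self.provider_a >= self.provider_b:
            raise ValueError(
                "providers must be distinct and in canonical order: "
                f"{self.provider_a!r} !< {self.provider_b!r}"
            )
        _require_date(self.start_date, "start_date")
        _require_date(self.end_date, "end_date")
        if self.start_date > self.end_date:
            raise ValueError(
                f"start_date {self.start_date} after end_date {self.end_date}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.provider_a, self.provider_b)


@dataclass(frozen=True, slots=True)
class AggregatedEdge:
    """Provider pair with its shared-patient count inside one window."""

    provider_a: str
    provider_b: str
    weight: int
    kind: str
    window: AnalysisWindow

    def __post_init__(self) -> None:
        _require_id(self.provider_a, "provider_a")
        _require_id(self.provider_b, "provider_b")
        if self.provider_a >= self.provider_b:
            raise ValueError(
                "providers must be distinct and in canonical order: "
                f"{self.provider_a!r} !< {self.provider_b!r}"
            )
        if not isinstance(self.weight, int) or self.weight < 1:
            raise ValueError(f"weight must be a positive integer, got {self.weight!r}")
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"kind must be one of {EDGE_KINDS}, got {self.kind!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.provider_a, self.provider_b)


@dataclass(frozen=True)
class NetworkSnapshot:
    """One analysis window's provider graph.

    ``nodes`` maps each active provider to the number of distinct patients
    seen inside the window; ``edges`` are the aggregated pair weights.  Every
    edge endpoint must be a node and no (pair, kind) may repeat.
    """

    nodes: Mapping[str, int]
    edges: tuple[AggregatedEdge, ...]
    window: AnalysisWindow

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", dict(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        seen: set[tuple[str, str, str]] = set()
        for edge in self.edges:
            if edge.provider_a not in self.nodes or edge.provider_b not in self.nodes:
                raise ValueError(
                    f"edge endpoint missing from node set: {edge.pair}"
                )
            key = (edge.provider_a, edge.provider_b, edge.kind)
            if key in seen:
                raise ValueError(f"duplicate edge for pair {edge.pair} ({edge.kind})")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, provider_id: str) -> set[str]:
        if provider_id not in self.nodes:
            raise KeyError(f"unknown provider {provider_id!r}")
        out: set[str] = set()
        for edge in self.edges:
            if edge.provider_a == provider_id:
                out.add(edge.provider_b)
            elif edge.provider_b == provider_id:
                out.add(edge.provider_a)
        return out


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a provider pair lexicographically; reject self-pairs."""
    if a == b:
        raise ValueError(f"self-pair for provider {a!r}")
    return (a, b) if a < b else (b, a)
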