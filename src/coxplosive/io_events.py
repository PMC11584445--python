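"""Reading, writing and cleaning acoustic-emission event tables.

An AE event table holds one detected signal per row: the tensile strain at
detection, the signal energy, and the sensor channel that recorded it.
Guard sensors at the specimen ends pick up low-energy friction artifacts;
:func:`filter_friction_events` removes them so downstream fitting sees only
microfailure events.  Event ordering is by strain throughout — the process
model is parametrized by strain, not wall-clock time; any extra columns
(e.g. a time stamp) are carried along as opaque metadata.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Set
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AEEvent",
    "EventSequence",
    "SpecimenMeta",
    "SpecimenRecord",
    "EventTableFormatError",
    "EventTableParseError",
    "read_event_table",
    "write_event_table",
    "filter_friction_events",
    "read_metadata",
    "write_metadata",
    "write_specimen_record",
    "read_specimen_records",
    "write_specimen_records",
]

EVENT_COLUMNS = ("strain", "energy", "channel")
RECORD_COLUMNS = (
    "specimen_id",
    "age",
    "bmi",
    "alpha",
    "lam",
    "beta",
    "nu",
    "e_m",
    "n_ae",
    "eps_max",
    "mu_inf",
    "phi_min",
    "converged",
)


class EventTableFormatError(ValueError):
    """The table is structurally invalid (missing columns, bad values)."""


class EventTableParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"{message} (row {row})")
        self.row = row


@dataclass(frozen=True)
class AEEvent:
    """One detected acoustic-emission signal."""

    strain: float
    energy: float
    channel: str

    def __post_init__(self) -> None:
        if not (self.strain >= 0.0):
            raise ValueError(f"event strain must be >= 0, got {self.strain}")
        if not (self.energy > 0.0):
            raise ValueError(f"event energy must be > 0, got {self.energy}")


@dataclass
class EventSequence:
    """Ordered AE events of one specimen, ascending in strain.

    Stored columnar (numpy arrays) for efficiency; ``events`` materializes
    :class:`AEEvent` objects on demand.  ``extra`` keeps any additional
    input columns, aligned with the event order.
    """

    strains: np.ndarray
    energies: np.ndarray
    channels: np.ndarray
    specimen_id: str = ""
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.channels = np.asarray(self.channels, dtype=object)
        if not (len(self.strains) == len(self.energies) == len(self.channels)):
            raise ValueError("strain/energy/channel arrays differ in length")
        if len(self.strains):
            if np.any(self.strains < 0):
                raise ValueError("event strains must be >= 0")
            if np.any(self.energies <= 0):
                raise ValueError("event energies must be > 0")
            if np.any(np.diff(self.strains) < 0):
                raise ValueError("event strains must be ascending")

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def events(self) -> list[AEEvent]:
        return [
            AEEvent(float(s), float(e), str(c))
            for s, e, c in zip(self.strains, self.energies, self.channels)
        ]

    @property
    def n_ae(self) -> int:
        """Number of events in the sequence."""
        return len(self)

    @property
    def eps_max(self) -> float:
        """Strain of the last event (macroscopic failure strain)."""
        if not len(self):
            raise ValueError("empty sequence has no eps_max")
        return float(self.strains[-1])

    @classmethod
    def from_events(cls, events: Iterable[AEEvent], specimen_id: str = "") -> "EventSequence":
        ev = sorted(events, key=lambda e: (e.strain, -e.energy))
        return cls(
            strains=np.array([e.strain for e in ev], dtype=float),
            energies=np.array([e.energy for e in ev], dtype=float),
            channels=np.array([e.channel for e in ev], dtype=object),
            specimen_id=specimen_id,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"strain": self.strains, "energy": self.energies, "channel": self.channels}
        )
        if self.extra is not None:
            df = pd.concat([df, self.extra.reset_index(drop=True)], axis=1)
        return df


@dataclass(frozen=True)
class SpecimenMeta:
    """Anthropometric metadata of the donor of one rib specimen."""

    specimen_id: str
    age: float  # years
    bmi: float  # kg/m^2

    def __post_init__(self) -> None:
        if not (self.age > 0):
            raise ValueError(f"age must be > 0, got {self.age}")
        if not (self.bmi > 0):
            raise ValueError(f"bmi must be > 0, got {self.bmi}")


@dataclass
class SpecimenRecord:
    """Metadata plus fitted parameters and observables for one specimen.

    Fitted fields are ``None`` until estimation has run; they serialize as
    nulls and round-trip.  ``n_ae`` and ``eps_max`` refer to the friction-
    filtered microfailure sequence.
    """

    specimen_id: str
    age: float | None = None
    bmi: float | None = None
    alpha: float | None = None
    lam: float | None = None
    beta: float | None = None
    nu: float | None = None
    e_m: float | None = None
    n_ae: int | None = None
    eps_max: float | None = None
    mu_inf: float | None = None
    phi_min: float | None = None
    converged: bool | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpecimenRecord":
        def clean(name, value):
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            if name == "n_ae":
                return int(value)
            if name == "converged":
                return bool(value)
            if name == "specimen_id":
                return str(value)
            return float(value)

        return cls(**{k: clean(k, d.get(k)) for k in (f.name for f in fields(cls))})


def read_event_table(
    path: str | Path, delimiter: str = ",", specimen_id: str | None = None
) -> EventSequence:
    """Read a delimited AE event table into an :class:`EventSequence`.

    The file must have a header with at least ``strain,energy,channel``.
    Events are sorted ascending by strain; exact strain ties are ordered by
    energy descending (stable, so equal (strain, energy) pairs keep input
    order).  Extra columns are preserved in ``extra``.

    Raises
    ------
    EventTableFormatError
        A required column is missing or a value violates the event
        invariants (strain < 0, energy <= 0).
    EventTableParseError
        A cell is non-numeric; the exception carries the 0-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for col in ("strain", "energy"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise EventTableParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}", row
            )
        if parsed.isna().any():
            row = int(np.nonzero(parsed.isna().to_numpy())[0][0])
            raise EventTableParseError(f"{path}: empty cell in column {col!r}", row)
        df[col] = parsed
    if (df["strain"] < 0).any() or (df["energy"] <= 0).any():
        raise EventTableFormatError(
            f"{path}: events require strain >= 0 and energy > 0"
        )
    # stable sort: strain ascending, ties broken by energy descending
    df = df.sort_values(["strain", "energy"], ascending=[True, False], kind="mergesort")
    extra_cols = [c for c in df.columns if c not in EVENT_COLUMNS]
    return EventSequence(
        strains=df["strain"].to_numpy(dtype=float),
        energies=df["energy"].to_numpy(dtype=float),
        channels=df["channel"].to_numpy(dtype=object),
        specimen_id=specimen_id if specimen_id is not None else path.stem,
        extra=df[extra_cols].reset_index(drop=True) if extra_cols else None,
    )


def write_event_table(seq: EventSequence, path: str | Path, delimiter: str = ",") -> None:
    """Write an event sequence back to the canonical delimited schema."""
    seq.to_frame().to_csv(path, sep=delimiter, index=False)


def filter_friction_events(
    seq: EventSequence, guard_channels: Set[str] | Iterable[str], e_min: float = 0.0
) -> EventSequence:
    """Drop friction artifacts: guard-channel events and sub-threshold energies.

    Keeps events whose channel is *not* in ``guard_channels`` and whose
    energy is >= ``e_min``; order is preserved.  Friction events are
    energy-distinguishable from microfailures, so ``e_min`` is naturally the
    same knob as the minimum energy of the Pareto energy law.  Idempotent,
    and monotone in ``e_min`` (a larger threshold keeps a subset).
    """
    if e_min < 0:
        raise ValueError("e_min must be >= 0")
    guard = set(guard_channels)
    keep = np.array(
        [(c not in guard) for c in seq.channels], dtype=bool
    ) & (seq.energies >= e_min)
    return EventSequence(
        strains=seq.strains[keep],
        energies=seq.energies[keep],
        channels=seq.channels[keep],
        specimen_id=seq.specimen_id,
        extra=seq.extra[keep].reset_index(drop=True) if seq.extra is not None else None,
    )


def read_metadata(path: str | Path, delimiter: str = ",") -> list[SpecimenMeta]:
    """Read specimen metadata CSV with columns ``specimen_id,age,bmi``."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in ("specimen_id", "age", "bmi") if c not in df.columns]
    if missing:
        raise EventTableFormatError(f"{path}: missing metadata column(s) {missing}")
    return [
        SpecimenMeta(str(r.specimen_id), float(r.age), float(r.bmi))
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: Iterable[SpecimenMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"specimen_id": m.specimen_id, "age": m.age, "bmi": m.bmi} for m in meta]
    ).to_csv(path, index=False)


def _records_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records], columns=list(RECORD_COLUMNS))


def write_specimen_record(
    record: SpecimenRecord, path: str | Path, append: bool = False
) -> None:
    """Write one record as a CSV row (``append=True`` adds to an existing table).

    Floats are written with ``repr`` (shortest round-trip form), so reading
    the file back reproduces every value bit-for-bit.
    """
    path = Path(path)
    header = not (append and path.exists() and path.stat().st_size > 0)
    _records_frame([record]).to_csv(
        path, index=False, mode="a" if append else "w", header=header,
        float_format=lambda x: repr(float(x)),
    )


def write_specimen_records(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = [r.to_dict() for r in records]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        _records_frame(records).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )


def read_specimen_records(path: str | Path) -> list[SpecimenRecord]:
    """Read records written by :func:`write_specimen_record(s)` (CSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        return [SpecimenRecord.from_dict(d) for d in json.loads(path.read_text())]
    df = pd.read_csv(path, float_precision="round_trip")
    return [SpecimenRecord.from_dict(row._asdict()) for row in df.itertuples(index=False)]
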