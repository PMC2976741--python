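"""Hemodynamic trend-record data model and its plain-text on-disk format.

A record is one ICU stay: minute-by-minute heart rate (HR, beats/min) and
systolic / diastolic / mean arterial blood pressure (SBP, DBP, MAP, mmHg) on a
uniform 1-minute grid, plus patient age and timed doses of hemodynamically
active medications. Missing minutes are explicit ``NaN`` in memory and absent
(or blank) cells on disk; the grid itself is never compressed.

On disk a record is a bundle of three files sharing a path prefix::

    <prefix>.vitals.csv   minute,hr,sbp,dbp,map   (one row per present minute)
    <prefix>.meds.csv     minute,drug,dose_mcg_per_kg
    <prefix>.meta.json    {"record_id": ..., "age": ..., "n_minutes": ...}

This mirrors the "numerics" (trend-rate) idea of WFDB archives but stays in
portable CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RAISING_DRUGS",
    "LOWERING_DRUGS",
    "MedicationEvent",
    "HemodynamicRecord",
    "read_record",
    "write_record",
    "validate_record",
    "list_record_prefixes",
]

#: Vasoconstrictors and positive inotropes — tend to raise blood pressure.
RAISING_DRUGS = frozenset(
    {
        "neosynephrine",
        "norepinephrine",
        "vasopressin",
        "dopamine",
        "dobutamine",
        "epinephrine",
        "milrinone",
        "isuprel",
    }
)

#: Vasodilators, diuretics and sedatives — tend to lower blood pressure.
LOWERING_DRUGS = frozenset(
    {
        "nitroglycerine",
        "nitroprusside",
        "diltiazem",
        "esmolol",
        "labetalol",
        "lasix",
    }
)


def drug_group(drug_name: str) -> str:
    """Return ``"raising"`` or ``"lowering"`` for a known drug (case-insensitive).

    Raises
    ------
    ValueError
        If the drug belongs to neither closed list.
    """
    name = drug_name.strip().lower()
    if name in RAISING_DRUGS:
        return "raising"
    if name in LOWERING_DRUGS:
        return "lowering"
    raise ValueError(
        f"unknown medication {drug_name!r}: not in the raising "
        f"(pressor/inotrope) or lowering (dilator/diuretic/sedative) list"
    )


@dataclass(frozen=True)
class MedicationEvent:
    """A timed dose of a hemodynamically active medication.

    ``dose`` is in mcg per kg body weight delivered at ``minute_index``
    (minutes from record start). ``group`` is derived from ``drug_name``.
    """

    minute_index: int
    drug_name: str
    dose: float
    group: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", drug_group(self.drug_name))
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")


@dataclass
class HemodynamicRecord:
    """One ICU stay of minute-by-minute hemodynamic trends.

    All four series share one uniform minute grid (index ``i`` is minute
    ``i`` from ``start_time``); missing minutes are ``NaN``.
    """

    record_id: str
    hr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    age: float
    medications: list[MedicationEvent] = field(default_factory=list)
    start_time: int = 0

    def __post_init__(self) -> None:
        for name in ("hr", "sbp", "dbp", "map"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_minutes(self) -> int:
        return len(self.map)

    def series(self, name: str) -> np.ndarray:
        return getattr(self, name)


def validate_record(record: HemodynamicRecord) -> list[str]:
    """Check every record invariant; return a list of human-readable issues.

    An empty list means the record is valid. Each issue names the offending
    field and, where applicable, the minute index.
    """
    issues: list[str] = []
    lengths = {name: len(record.series(name)) for name in ("hr", "sbp", "dbp", "map")}
    if len(set(lengths.values())) != 1:
        issues.append(
            "series length mismatch: "
            + ", ".join(f"{k}={v}" for k, v in lengths.items())
        )
    if record.age < 18:
        issues.append(f"age {record.age} violates the adult (age >= 18) constraint")
    n = record.n_minutes
    for ev in record.medications:
        if not 0 <= ev.minute_index < n:
            issues.append(
                f"medication {ev.drug_name!r} at minute {ev.minute_index} "
                f"outside record bounds [0, {n})"
            )
        if ev.dose < 0:
            issues.append(
                f"medication {ev.drug_name!r} at minute {ev.minute_index} "
                f"has negative dose {ev.dose}"
            )
    return issues


def _require_valid(record: HemodynamicRecord) -> None:
    issues = validate_record(record)
    if issues:
        raise ValueError("invalid record: " + "; ".join(issues))


def _bundle_path(prefix: Path, part: str) -> Path:
    # plain concatenation: Path.with_suffix mangles dotted record ids
    return prefix.parent / (prefix.name + part)


def write_record(record: HemodynamicRecord, prefix: str | Path) -> None:
    """Write a record bundle to ``<prefix>.vitals.csv/.meds.csv/.meta.json``.

    Fully missing minutes are omitted; minutes with some series present keep
    a row with blank cells for the missing series, so write∘read is identity.
    """
    _require_valid(record)
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    frame = pd.DataFrame(
        {
            "minute": np.arange(record.n_minutes),
            "hr": record.hr,
            "sbp": record.sbp,
            "dbp": record.dbp,
            "map": record.map,
        }
    )
    present = frame[["hr", "sbp", "dbp", "map"]].notna().any(axis=1)
    frame.loc[present].to_csv(_bundle_path(prefix, ".vitals.csv"), index=False)

    meds = pd.DataFrame(
        [
            {
                "minute": ev.minute_index,
                "drug": ev.drug_name,
                "dose_mcg_per_kg": ev.dose,
            }
            for ev in record.medications
        ],
        columns=["minute", "drug", "dose_mcg_per_kg"],
    )
    meds.to_csv(_bundle_path(prefix, ".meds.csv"), index=False)

    meta = {
        "record_id": record.record_id,
        "age": record.age,
        "n_minutes": int(record.n_minutes),
        "start_time": int(record.start_time),
    }
    _bundle_path(prefix, ".meta.json").write_text(json.dumps(meta, indent=1))


def read_record(prefix: str | Path) -> HemodynamicRecord:
    """Read a record bundle written by :func:`write_record`.

    Rows absent from the vitals file become missing (``NaN``) minutes on the
    uniform grid. Raises ``ValueError`` for malformed files, duplicated or
    out-of-range minute indices, or unknown drug names.
    """
    prefix = Path(prefix)
    meta_path = _bundle_path(prefix, ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"no record bundle at prefix {prefix}")
    meta = json.loads(meta_path.read_text())
    n = int(meta["n_minutes"])

    vitals = pd.read_csv(_bundle_path(prefix, ".vitals.csv"), float_precision="round_trip")
    expected_cols = ["minute", "hr", "sbp", "dbp", "map"]
    if list(vitals.columns) != expected_cols:
        raise ValueError(
            f"{prefix}.vitals.csv: expected columns {expected_cols}, "
            f"got {list(vitals.columns)}"
        )
    minutes = vitals["minute"].to_numpy()
    if len(minutes) and (
        not np.issubdtype(minutes.dtype, np.integer)
        and not np.all(minutes == np.floor(minutes))
    ):
        raise ValueError(f"{prefix}.vitals.csv: non-integer minute index")
    minutes = minutes.astype(int)
    if np.any((minutes < 0) | (minutes >= n)):
        bad = minutes[(minutes < 0) | (minutes >= n)][0]
        raise ValueError(f"{prefix}.vitals.csv: minute {bad} outside [0, {n})")
    if len(np.unique(minutes)) != len(minutes):
        raise ValueError(f"{prefix}.vitals.csv: duplicated minute index")

    series = {}
    for name in ("hr", "sbp", "dbp", "map"):
        arr = np.full(n, np.nan)
        arr[minutes] = vitals[name].to_numpy(dtype=float)
        series[name] = arr

    meds_frame = pd.read_csv(_bundle_path(prefix, ".meds.csv"), float_precision="round_trip")
    medications = []
    for i, row in meds_frame.iterrows():
        try:
            medications.append(
                MedicationEvent(
                    minute_index=int(row["minute"]),
                    drug_name=str(row["drug"]),
                    dose=float(row["dose_mcg_per_kg"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{prefix}.meds.csv line {i + 2}: {exc}") from exc

    record = HemodynamicRecord(
        record_id=str(meta["record_id"]),
        hr=series["hr"],
        sbp=series["sbp"],
        dbp=series["dbp"],
        map=series["map"],
        age=float(meta["age"]),
        medications=medications,
        start_time=int(meta.get("start_time", 0)),
    )
    _require_valid(record)
    return record


def list_record_prefixes(directory: str | Path) -> list[Path]:
    """All record-bundle prefixes in a directory, sorted by record id."""
    directory = Path(directory)
    return sorted(
        p.parent / p.name.removesuffix(".meta.json")
        for p in directory.glob("*.meta.json")
    )


def records_equal(a: HemodynamicRecord, b: HemodynamicRecord) -> bool:
    """Field-by-field equality, treating NaN == NaN (round-trip checks)."""
    if (a.record_id, a.start_time, a.age) != (b.record_id, b.start_time, b.age):
        return False
    for name in ("hr", "sbp", "dbp", "map"):
        x, y = a.series(name), b.series(name)
        if len(x) != len(y) or not np.array_equal(x, y, equal_nan=True):
            return False
    if len(a.medications) != len(b.medications):
        return False
    return all(
        (e1.minute_index, e1.drug_name, e1.dose, e1.group)
        == (e2.minute_index, e2.drug_name, e2.dose, e2.group)
        for e1, e2 in zip(a.medications, b.medications)
    )
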