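"""Tabular schemas for aerial-culling encounter and post-mortem logs.

The unit of observation is one animal that was shot at from the helicopter.
An :class:`EncounterRecord` holds the ante-mortem observations (chase time,
time to insensibility with its censoring flag, shots fired, encounter outcome)
and the design structure (sortie, group, ammunition type).  A
:class:`PostMortemRecord` holds the carcase examination for the subset of
animals that could be inspected on the ground: wound-tract count, whole
pellets detected by anatomical zone on radiographs, the number of pellets
expected from the shots fired, and body mass.

Both tables are read and written as plain UTF-8 CSV with a header row,
booleans encoded as ``true``/``false`` and a missing time to insensibility as
an empty field.  All structural invariants are validated before any model
sees the data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Ammo(str, enum.Enum):
    """The four ammunition arms of the trial."""

    RIFLE_308 = "RIFLE_308"
    BUCK_00 = "BUCK_00"
    BUCK_1 = "BUCK_1"
    BUCK_4 = "BUCK_4"


#: Shotgun arms (multi-pellet cartridges); the rifle fires a single bullet.
SHOTGUN_AMMO: tuple[Ammo, ...] = (Ammo.BUCK_00, Ammo.BUCK_1, Ammo.BUCK_4)

#: Lead pellets per cartridge: one bullet for the rifle, 9/16/27 for buckshot.
PELLETS_PER_CARTRIDGE: dict[Ammo, int] = {
    Ammo.RIFLE_308: 1,
    Ammo.BUCK_00: 9,
    Ammo.BUCK_1: 16,
    Ammo.BUCK_4: 27,
}


@dataclass(frozen=True)
class AmmoSpec:
    """An ammunition type together with its fixed pellet count."""

    ammo: Ammo
    pellets_per_cartridge: int

    def __post_init__(self) -> None:
        expected = PELLETS_PER_CARTRIDGE[self.ammo]
        if self.pellets_per_cartridge != expected:
            raise ValidationError(
                f"{self.ammo.value} carries {expected} pellets per cartridge, "
                f"got {self.pellets_per_cartridge}"
            )

    @classmethod
    def for_ammo(cls, ammo: Ammo) -> "AmmoSpec":
        return cls(ammo=ammo, pellets_per_cartridge=PELLETS_PER_CARTRIDGE[ammo])


class Outcome(str, enum.Enum):
    """Four-category encounter outcome."""

    INSENSIBLE_LE_1S = "INSENSIBLE_LE_1S"
    INSENSIBLE_GT_1S = "INSENSIBLE_GT_1S"
    WOUNDED_ESCAPED = "WOUNDED_ESCAPED"
    MISSED_ESCAPED = "MISSED_ESCAPED"


ESCAPE_OUTCOMES = frozenset({Outcome.WOUNDED_ESCAPED, Outcome.MISSED_ESCAPED})


class SexAge(str, enum.Enum):
    ADULT_M = "ADULT_M"
    ADULT_F = "ADULT_F"
    YEARLING = "YEARLING"
    FAWN = "FAWN"


class Zone(str, enum.Enum):
    """Major anatomical zones scored on lateral radiographs."""

    HEAD = "HEAD"
    NECK = "NECK"
    THORAX = "THORAX"
    ABDOMEN = "ABDOMEN"
    LIMBS = "LIMBS"


class Exam(str, enum.Enum):
    IN_SITU_ONLY = "IN_SITU_ONLY"
    EX_SITU = "EX_SITU"


#: Hanging-scale limit; heavier animals are recorded as censored at this mass.
MASS_SCALE_LIMIT_KG = 100.0


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class ValidationError(ValueError):
    """One or more records violate a structural invariant."""


@dataclass
class EncounterRecord:
    """One shot-at animal: times, censoring, outcome, design structure.

    ``tti_s`` is the observed time to insensibility in seconds; for censored
    rows it is the observed minimum (the animal was out of view when it
    became insensible) and ``tti_censored`` is true.  Animals that escaped
    carry no ``tti_s`` at all.
    """

    animal_id: str
    sortie_id: int
    group_id: int
    ammo: Ammo
    ct_s: float
    tti_s: float | None
    tti_censored: bool
    shots_fired: int
    outcome: Outcome
    sex_age: SexAge

    def problems(self) -> list[str]:
        """Invariant violations for this record, empty when valid."""
        errs: list[str] = []
        if not self.animal_id:
            errs.append("empty animal_id")
        if self.sortie_id < 1:
            errs.append(f"sortie_id {self.sortie_id} < 1")
        if self.group_id < 1:
            errs.append(f"group_id {self.group_id} < 1")
        if not self.ct_s > 0:
            errs.append(f"ct_s {self.ct_s} must be > 0")
        if self.shots_fired < 1:
            errs.append(f"shots_fired {self.shots_fired} < 1")
        if self.outcome in ESCAPE_OUTCOMES:
            if self.tti_s is not None:
                errs.append(f"{self.outcome.value} row must not carry tti_s")
        else:
            if self.tti_s is None:
                errs.append(f"{self.outcome.value} row requires tti_s")
            elif self.tti_s < 0:
                errs.append(f"tti_s {self.tti_s} < 0")
        if self.outcome is Outcome.INSENSIBLE_LE_1S:
            if self.tti_s is not None and self.tti_s > 1:
                errs.append(f"INSENSIBLE_LE_1S with tti_s {self.tti_s} > 1")
            if self.tti_censored:
                errs.append("INSENSIBLE_LE_1S row cannot be censored")
        return errs


@dataclass
class PostMortemRecord:
    """Carcase examination for one animal, joined by ``animal_id``."""

    animal_id: str
    wound_tracts: int
    pellets_by_zone: dict[Zone, int]
    pellets_expected: int
    body_mass_kg: float | None
    mass_censored: bool
    exam: Exam

    @property
    def pellets_detected(self) -> int:
        return sum(self.pellets_by_zone.values())

    def problems(self) -> list[str]:
        errs: list[str] = []
        if self.wound_tracts < 0:
            errs.append(f"wound_tracts {self.wound_tracts} < 0")
        if set(self.pellets_by_zone) != set(Zone):
            errs.append("pellets_by_zone must cover all five zones")
        if any(v < 0 for v in self.pellets_by_zone.values()):
            errs.append("negative pellet count")
        if self.pellets_expected < 0:
            errs.append(f"pellets_expected {self.pellets_expected} < 0")
        if self.pellets_detected > self.pellets_expected:
            errs.append(
                f"detected pellets {self.pellets_detected} exceed expected "
                f"{self.pellets_expected}"
            )
        if self.mass_censored:
            if self.body_mass_kg is not None and self.body_mass_kg != MASS_SCALE_LIMIT_KG:
                errs.append("mass-censored record must sit at the scale limit")
        elif self.body_mass_kg is not None and not self.body_mass_kg > 0:
            errs.append(f"body_mass_kg {self.body_mass_kg} must be > 0")
        return errs


ENCOUNTER_COLUMNS = [
    "animal_id", "sortie_id", "group_id", "ammo", "ct_s", "tti_s",
    "tti_censored", "shots_fired", "outcome", "sex_age",
]

_ZONE_COLUMNS = [f"pellets_{z.value.lower()}" for z in Zone]

POSTMORTEM_COLUMNS = [
    "animal_id", "wound_tracts", *_ZONE_COLUMNS, "pellets_expected",
    "body_mass_kg", "mass_censored", "exam",
]


def _check_header(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    got = list(df.columns)
    if got != list(expected):
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        raise SchemaError(
            f"{path}: header mismatch; missing columns {missing}, "
            f"unexpected columns {extra}, order must be {list(expected)}"
        )


def _parse_bool(raw: str, row: int, col: str, path: Path) -> bool:
    if raw == "true":
        return True
    if raw == "false":
        return False
    raise SchemaError(f"{path} row {row}: column {col} must be 'true'/'false', got {raw!r}")


def _parse_enum(cls, raw: str, row: int, col: str, path: Path):
    try:
        return cls(raw)
    except ValueError:
        raise SchemaError(
            f"{path} row {row}: column {col} value {raw!r} not in "
            f"{[m.value for m in cls]}"
        ) from None


def validate_encounters(records: Sequence[EncounterRecord]) -> None:
    """Raise :class:`ValidationError` listing every offending animal."""
    offenders: list[str] = []
    for r in records:
        for p in r.problems():
            offenders.append(f"{r.animal_id}: {p}")
    seen = {}
    dup = set()
    for r in records:
        if r.animal_id in seen:
            dup.add(r.animal_id)
        seen[r.animal_id] = r
    for a in sorted(dup):
        offenders.append(f"{a}: duplicate animal_id")
    # one ammunition type per sortie, across the whole table
    by_sortie: dict[int, set[Ammo]] = {}
    for r in records:
        by_sortie.setdefault(r.sortie_id, set()).add(r.ammo)
    for sid, ammos in sorted(by_sortie.items()):
        if len(ammos) > 1:
            offenders.append(
                f"sortie {sid}: multiple ammo types "
                f"{sorted(a.value for a in ammos)}"
            )
    if offenders:
        raise ValidationError("invalid encounter records:\n  " + "\n  ".join(offenders))


def validate_postmortem(
    records: Sequence[PostMortemRecord],
    encounters: Sequence[EncounterRecord] | None = None,
) -> None:
    offenders = [f"{r.animal_id}: {p}" for r in records for p in r.problems()]
    if encounters is not None:
        known = {e.animal_id for e in encounters}
        for r in records:
            if r.animal_id not in known:
                offenders.append(f"{r.animal_id}: no matching encounter record")
    if offenders:
        raise ValidationError("invalid post-mortem records:\n  " + "\n  ".join(offenders))


def read_encounters(path: str | Path) -> list[EncounterRecord]:
    """Read and validate an encounter table from CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, ENCOUNTER_COLUMNS, path)
    records: list[EncounterRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tti = None if row.tti_s == "" else float(row.tti_s)
            rec = EncounterRecord(
                animal_id=row.animal_id,
                sortie_id=int(row.sortie_id),
                group_id=int(row.group_id),
                ammo=_parse_enum(Ammo, row.ammo, i, "ammo", path),
                ct_s=float(row.ct_s),
                tti_s=tti,
                tti_censored=_parse_bool(row.tti_censored, i, "tti_censored", path),
                shots_fired=int(row.shots_fired),
                outcome=_parse_enum(Outcome, row.outcome, i, "outcome", path),
                sex_age=_parse_enum(SexAge, row.sex_age, i, "sex_age", path),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{path} row {i}: {exc}") from exc
        records.append(rec)
    validate_encounters(records)
    return records


def write_encounters(records: Sequence[EncounterRecord], path: str | Path) -> Path:
    """Write a validated encounter table; read/write round-trips losslessly."""
    validate_encounters(records)
    path = Path(path)
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "sortie_id": [r.sortie_id for r in records],
            "group_id": [r.group_id for r in records],
            "ammo": [r.ammo.value for r in records],
            "ct_s": [repr(float(r.ct_s)) for r in records],
            "tti_s": ["" if r.tti_s is None else repr(float(r.tti_s)) for r in records],
            "tti_censored": ["true" if r.tti_censored else "false" for r in records],
            "shots_fired": [r.shots_fired for r in records],
            "outcome": [r.outcome.value for r in records],
            "sex_age": [r.sex_age.value for r in records],
        },
        columns=ENCOUNTER_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_postmortem(path: str | Path) -> list[PostMortemRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, POSTMORTEM_COLUMNS, path)
    records: list[PostMortemRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            rec = PostMortemRecord(
                animal_id=d["animal_id"],
                wound_tracts=int(d["wound_tracts"]),
                pellets_by_zone={
                    z: int(d[f"pellets_{z.value.lower()}"]) for z in Zone
                },
                pellets_expected=int(d["pellets_expected"]),
                body_mass_kg=None if d["body_mass_kg"] == "" else float(d["body_mass_kg"]),
                mass_censored=_parse_bool(d["mass_censored"], i, "mass_censored", path),
                exam=_parse_enum(Exam, d["exam"], i, "exam", path),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{path} row {i}: {exc}") from exc
        records.append(rec)
    validate_postmortem(records)
    return records


def write_postmortem(records: Sequence[PostMortemRecord], path: str | Path) -> Path:
    validate_postmortem(records)
    path = Path(path)
    data: dict[str, list] = {
        "animal_id": [r.animal_id for r in records],
        "wound_tracts": [r.wound_tracts for r in records],
    }
    for z in Zone:
        data[f"pellets_{z.value.lower()}"] = [r.pellets_by_zone[z] for r in records]
    data["pellets_expected"] = [r.pellets_expected for r in records]
    data["body_mass_kg"] = [
        "" if r.body_mass_kg is None else repr(float(r.body_mass_kg)) for r in records
    ]
    data["mass_censored"] = ["true" if r.mass_censored else "false" for r in records]
    data["exam"] = [r.exam.value for r in records]
    pd.DataFrame(data, columns=POSTMORTEM_COLUMNS).to_csv(path, index=False)
    return path


def ammo_by_animal(records: Sequence[EncounterRecord]) -> dict[str, Ammo]:
    """Map animal_id -> ammunition type, for joining post-mortem data."""
    return {r.animal_id: r.ammo for r in records}


def nfwr(records: Sequence[EncounterRecord]) -> float:
    """Non-fatal wounding rate: hit animals that escaped, over animals hit.

    Clean misses (``MISSED_ESCAPED``) are excluded from the denominator; the
    rate is defined over animals that were shot and hit.
    """
    if not records:
        raise ValidationError("no encounters")
    hit = [r for r in records if r.outcome is not Outcome.MISSED_ESCAPED]
    if not hit:
        raise ValidationError("no hit animals: NFWR undefined")
    wounded = sum(1 for r in hit if r.outcome is Outcome.WOUNDED_ESCAPED)
    return wounded / len(hit)
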