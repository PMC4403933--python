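"""Data model and I/O for blood-pressure survey records.

The central objects are :class:`ParticipantRecord` — one subject's three
sequential systolic/diastolic readings plus the measurement context recorded
on the survey form (arm, posture, cuff, arm circumference, room temperature,
pre-examination and during-measurement behaviour flags) — and
:class:`SurveyProtocol`, a survey's declared measurement procedure and cuff
inventory.  Participant files are plain CSV, protocols are YAML, and the
package ships small CSV fixtures with the published per-survey summary
tables of the twelve-country survey round this package's QC battery targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "PRE_EXAM_FLAGS",
    "DURING_FLAGS",
    "ALL_FLAGS",
    "Reading",
    "ParticipantRecord",
    "CuffSpec",
    "SurveyProtocol",
    "SurveyDataset",
    "LoadLog",
    "ValidationIssue",
    "ValidationReport",
    "TemperatureSummary",
    "SchemaError",
    "ValidationError",
    "load_fixture",
    "load_participants",
    "write_participants",
    "load_protocol",
    "write_protocol",
    "protocols_from_table2",
    "validate_dataset",
    "temperature_summary",
    "arm_circumference_census",
]

#: Behaviour flags recorded before the examination visit.
PRE_EXAM_FLAGS = (
    "smoking",
    "heavy_exercise",
    "heavy_meal",
    "full_bladder",
    "caffeine_alcohol",
)

#: Procedure flags recorded during the measurement itself.
DURING_FLAGS = (
    "talking",
    "legs_crossed",
    "back_unsupported",
    "arm_unsupported",
    "arm_below_heart",
    "cuff_over_clothing",
    "no_rest",
)

ALL_FLAGS = PRE_EXAM_FLAGS + DURING_FLAGS

ARM_VALUES = ("right", "left", "unknown")
POSTURE_VALUES = ("sitting", "supine", "unknown")
DEVICE_TYPES = ("mercury", "oscillometric", "aneroid")
STETHOSCOPE_SIDES = ("bell", "diaphragm", "not_relevant")

#: Cell contents treated as missing in delimited input ("#" and "§" are the
#: markers the published tables use for "not measured / not possible").
MISSING_TOKENS = frozenset({"", "NA", "#", "§"})


class SchemaError(ValueError):
    """A required column is absent from a participant file."""


class ValidationError(ValueError):
    """Input data violate a structural constraint (e.g. duplicate ids)."""


@dataclass(frozen=True)
class Reading:
    """One measurement in a participant's triplicate, in integer mmHg."""

    sequence_index: int
    sbp: Optional[int] = None
    dbp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sequence_index not in (1, 2, 3):
            raise ValidationError(
                f"sequence_index must be 1, 2 or 3, got {self.sequence_index}"
            )


@dataclass
class ParticipantRecord:
    participant_id: str
    survey_id: str
    readings: tuple[Reading, Reading, Reading]
    arm_used: str = "right"
    arm_deviation_reason: Optional[str] = None
    posture: str = "sitting"
    posture_deviation_reason: Optional[str] = None
    arm_circumference_cm: Optional[float] = None
    cuff_label: Optional[str] = None
    room_temp_c: Optional[float] = None
    pre_exam_flags: frozenset[str] = frozenset()
    during_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.readings = tuple(self.readings)  # type: ignore[assignment]
        if len(self.readings) != 3:
            raise ValidationError(
                f"participant {self.participant_id}: expected exactly 3 reading "
                f"slots, got {len(self.readings)}"
            )
        if sorted(r.sequence_index for r in self.readings) != [1, 2, 3]:
            raise ValidationError(
                f"participant {self.participant_id}: reading sequence indices "
                "must be exactly {1, 2, 3}"
            )
        self.pre_exam_flags = frozenset(self.pre_exam_flags)
        self.during_flags = frozenset(self.during_flags)
        bad = (self.pre_exam_flags - set(PRE_EXAM_FLAGS)) | (
            self.during_flags - set(DURING_FLAGS)
        )
        if bad:
            raise ValidationError(
                f"participant {self.participant_id}: unknown flags {sorted(bad)}"
            )

    def reading(self, sequence_index: int) -> Reading:
        for r in self.readings:
            if r.sequence_index == sequence_index:
                return r
        raise KeyError(sequence_index)


@dataclass(frozen=True)
class CuffSpec:
    """A cuff identified by its printed recommended arm-circumference range.

    Open bounds are represented by ``-inf`` / ``+inf``; e.g. the printed
    label "> 42 cm" becomes ``(42, inf)`` with an exclusive lower bound.
    """

    label: str
    min_circ_cm: float = -math.inf
    max_circ_cm: float = math.inf
    lower_inclusive: bool = True
    upper_inclusive: bool = True
    bladder_width_cm: Optional[float] = None
    bladder_length_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.min_circ_cm)
            and math.isfinite(self.max_circ_cm)
            and not self.min_circ_cm < self.max_circ_cm
        ):
            raise ValidationError(
                f"cuff {self.label!r}: lower bound must be below upper bound"
            )

    def covers(self, circumference_cm: float) -> bool:
        lo_ok = (
            circumference_cm >= self.min_circ_cm
            if self.lower_inclusive
            else circumference_cm > self.min_circ_cm
        )
        hi_ok = (
            circumference_cm <= self.max_circ_cm
            if self.upper_inclusive
            else circumference_cm < self.max_circ_cm
        )
        return lo_ok and hi_ok


@dataclass
class SurveyProtocol:
    """A survey's declared blood-pressure measurement procedure."""

    survey_id: str
    n_participants: int = 0
    device_type: str = "oscillometric"
    device_model: str = ""
    cuff_inventory: list[CuffSpec] = field(default_factory=list)
    arm: str = "right"
    posture: str = "sitting"
    n_measurements: int = 3
    rest_minutes: Optional[float] = None
    interval_minutes: Optional[float] = None
    stethoscope_side: str = "not_relevant"
    temp_recorded: bool = False
    mean_temp_c: Optional[float] = None
    min_temp_c: Optional[float] = None
    max_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.device_type not in DEVICE_TYPES:
            raise ValidationError(f"unknown device_type {self.device_type!r}")
        if self.stethoscope_side not in STETHOSCOPE_SIDES:
            raise ValidationError(
                f"unknown stethoscope_side {self.stethoscope_side!r}"
            )
        # Oscillometric devices involve no stethoscope, and conversely an
        # auscultatory device must declare a side.
        if (self.device_type == "oscillometric") != (
            self.stethoscope_side == "not_relevant"
        ):
            raise ValidationError(
                f"survey {self.survey_id}: stethoscope_side must be "
                "'not_relevant' exactly when the device is oscillometric"
            )


@dataclass
class LoadLog:
    warnings: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


@dataclass
class SurveyDataset:
    protocol: SurveyProtocol
    participants: list[ParticipantRecord]
    log: LoadLog = field(default_factory=LoadLog, compare=False, repr=False)

    def __post_init__(self) -> None:
        for p in self.participants:
            if p.survey_id != self.protocol.survey_id:
                raise ValidationError(
                    f"participant {p.participant_id} belongs to survey "
                    f"{p.survey_id!r}, not {self.protocol.survey_id!r}"
                )

    def __len__(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class ValidationIssue:
    participant_id: str
    field: str
    kind: str  # "range" | "ordering" | "enum" | "note"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def n_violations(self) -> int:
        return sum(1 for i in self.issues if i.kind != "note")

    def __len__(self) -> int:
        return len(self.issues)


@dataclass(frozen=True)
class TemperatureSummary:
    n_recorded: int
    min_of_means: Optional[float]
    max_of_means: Optional[float]


# ---------------------------------------------------------------------------
# fixtures


_FIXTURES = {"table2", "table3", "table4", "table5"}


def load_fixture(table_id: str) -> pd.DataFrame:
    """Return one of the bundled published summary tables as a DataFrame.

    ``table2`` — per-survey measurement protocols; ``table3`` — cuff use,
    arm circumference, miss-cuffing and identical-reading proportions;
    ``table4``/``table5`` — terminal-digit percentage distributions for
    systolic/diastolic readings with the printed chi-square p-value.
    """
    if table_id not in _FIXTURES:
        raise ValueError(f"unknown fixture {table_id!r}; expected one of {sorted(_FIXTURES)}")
    with resources.files("bpqc.fixtures").joinpath(f"{table_id}.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if table_id in ("table4", "table5"):
        pct_cols = [f"pct_digit_{d}" for d in range(10)]
        df[pct_cols] = df[pct_cols].astype(int)
        sums = df[pct_cols].sum(axis=1)
        bad = df.loc[(sums - 100).abs() > 2, "survey_id"]
        if not bad.empty:  # guards the transcription, printed rounding is ±2
            raise ValidationError(
                f"{table_id}: digit percentages of survey(s) "
                f"{list(bad)} do not sum to 100±2"
            )
    if table_id == "table2":
        df["n_participants"] = df["n_participants"].astype(int)
    return df


# ---------------------------------------------------------------------------
# participant CSV I/O


#: Canonical participant-file columns, in write order.
PARTICIPANT_COLUMNS = (
    "participant_id",
    "survey_id",
    "sbp1",
    "dbp1",
    "sbp2",
    "dbp2",
    "sbp3",
    "dbp3",
    "arm_used",
    "arm_deviation_reason",
    "posture",
    "posture_deviation_reason",
    "arm_circumference_cm",
    "cuff_label",
    "room_temp_c",
) + ALL_FLAGS

_REQUIRED_COLUMNS = (
    "participant_id",
    "survey_id",
    "sbp1",
    "dbp1",
    "sbp2",
    "dbp2",
    "sbp3",
    "dbp3",
)


def _is_missing(cell: object) -> bool:
    return cell is None or str(cell).strip() in MISSING_TOKENS


def _parse_bp(cell: object, where: str, log: LoadLog) -> Optional[int]:
    """Integer mmHg or None.  Non-integer numerals are rejected (never
    rounded) and unparseable cells become missing; both leave a warning."""
    if _is_missing(cell):
        return None
    text = str(cell).strip()
    try:
        value = float(text)
    except ValueError:
        log.warnings.append(f"{where}: unparseable blood pressure {text!r}; set missing")
        return None
    if value != int(value):
        log.warnings.append(f"{where}: non-integer blood pressure {text!r}; set missing")
        return None
    return int(value)


def _parse_float(cell: object, where: str, log: LoadLog) -> Optional[float]:
    if _is_missing(cell):
        return None
    text = str(cell).strip()
    try:
        return float(text)
    except ValueError:
        log.warnings.append(f"{where}: unparseable number {text!r}; set missing")
        return None


def _parse_flag(cell: object) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "y"}


def load_participants(
    path: str | Path,
    protocol: SurveyProtocol,
    schema: Optional[dict[str, str]] = None,
) -> SurveyDataset:
    """Read a participant CSV into a :class:`SurveyDataset`.

    ``schema`` optionally maps canonical column names to the names used in
    the file.  Unparseable numeric cells become missing values with a logged
    warning; records whose readings invert the systolic/diastolic ordering
    (dbp >= sbp) are excluded from the analysis set and listed in
    ``dataset.log.excluded``.
    """
    schema = schema or {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: schema.get(canon, canon) for canon in PARTICIPANT_COLUMNS}
    for canon in _REQUIRED_COLUMNS:
        if colmap[canon] not in df.columns:
            raise SchemaError(f"required column {colmap[canon]!r} missing from {path}")

    log = LoadLog()
    participants: list[ParticipantRecord] = []
    seen: set[str] = set()

    def cell(row: pd.Series, canon: str) -> object:
        name = colmap[canon]
        return row[name] if name in df.columns else ""

    for idx, row in df.iterrows():
        pid = str(cell(row, "participant_id")).strip()
        if pid in seen:
            raise ValidationError(f"duplicate participant_id {pid!r} in {path}")
        seen.add(pid)
        where = f"row {idx} (participant {pid})"

        readings = []
        ordering_bad = False
        for k in (1, 2, 3):
            sbp = _parse_bp(cell(row, f"sbp{k}"), f"{where} sbp{k}", log)
            dbp = _parse_bp(cell(row, f"dbp{k}"), f"{where} dbp{k}", log)
            if sbp is not None and dbp is not None and dbp >= sbp:
                ordering_bad = True
            readings.append(Reading(k, sbp, dbp))
        if ordering_bad:
            log.excluded.append((pid, "dbp >= sbp"))
            continue

        arm = str(cell(row, "arm_used")).strip().lower() or "unknown"
        posture = str(cell(row, "posture")).strip().lower() or "unknown"
        arm_reason = None if _is_missing(cell(row, "arm_deviation_reason")) else str(
            cell(row, "arm_deviation_reason")
        ).strip()
        posture_reason = None if _is_missing(
            cell(row, "posture_deviation_reason")
        ) else str(cell(row, "posture_deviation_reason")).strip()
        cuff = None if _is_missing(cell(row, "cuff_label")) else str(
            cell(row, "cuff_label")
        ).strip()

        participants.append(
            ParticipantRecord(
                participant_id=pid,
                survey_id=str(cell(row, "survey_id")).strip(),
                readings=tuple(readings),
                arm_used=arm if arm in ARM_VALUES else "unknown",
                arm_deviation_reason=arm_reason,
                posture=posture if posture in POSTURE_VALUES else "unknown",
                posture_deviation_reason=posture_reason,
                arm_circumference_cm=_parse_float(
                    cell(row, "arm_circumference_cm"), f"{where} arm_circumference_cm", log
                ),
                cuff_label=cuff,
                room_temp_c=_parse_float(
                    cell(row, "room_temp_c"), f"{where} room_temp_c", log
                ),
                pre_exam_flags=frozenset(
                    f for f in PRE_EXAM_FLAGS if _parse_flag(cell(row, f))
                ),
                during_flags=frozenset(
                    f for f in DURING_FLAGS if _parse_flag(cell(row, f))
                ),
            )
        )
    return SurveyDataset(protocol=protocol, participants=participants, log=log)


def write_participants(ds: SurveyDataset, path: str | Path) -> None:
    """Write the analysis set back to canonical CSV (round-trips with
    :func:`load_participants`)."""
    rows = []
    for p in ds.participants:
        row: dict[str, object] = {
            "participant_id": p.participant_id,
            "survey_id": p.survey_id,
            "arm_used": p.arm_used,
            "arm_deviation_reason": p.arm_deviation_reason or "",
            "posture": p.posture,
            "posture_deviation_reason": p.posture_deviation_reason or "",
            "arm_circumference_cm": (
                "" if p.arm_circumference_cm is None else p.arm_circumference_cm
            ),
            "cuff_label": p.cuff_label or "",
            "room_temp_c": "" if p.room_temp_c is None else p.room_temp_c,
        }
        for r in p.readings:
            row[f"sbp{r.sequence_index}"] = "" if r.sbp is None else r.sbp
            row[f"dbp{r.sequence_index}"] = "" if r.dbp is None else r.dbp
        for f in ALL_FLAGS:
            row[f] = int(f in p.pre_exam_flags or f in p.during_flags)
        rows.append(row)
    pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# protocol YAML I/O


def load_protocol(path: str | Path) -> SurveyProtocol:
    """Read a survey protocol from a YAML mapping.

    ``cuff_sizes`` may be a list of printed labels ("22–32 cm") or a list of
    mappings with explicit bounds and optional bladder dimensions.
    """
    from . import cuff_matching  # local import: cuff_matching depends on CuffSpec

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cuffs = []
    for item in raw.get("cuff_sizes", []):
        if isinstance(item, str):
            cuffs.append(cuff_matching.parse_cuff_range(item))
        else:
            cuffs.append(CuffSpec(**item))
    kwargs = {
        k: raw[k]
        for k in (
            "survey_id",
            "n_participants",
            "device_type",
            "device_model",
            "arm",
            "posture",
            "n_measurements",
            "rest_minutes",
            "interval_minutes",
            "stethoscope_side",
            "temp_recorded",
            "mean_temp_c",
            "min_temp_c",
            "max_temp_c",
        )
        if k in raw
    }
    return SurveyProtocol(cuff_inventory=cuffs, **kwargs)


def write_protocol(protocol: SurveyProtocol, path: str | Path) -> None:
    data = {
        "survey_id": protocol.survey_id,
        "n_participants": protocol.n_participants,
        "device_type": protocol.device_type,
        "device_model": protocol.device_model,
        "cuff_sizes": [c.label for c in protocol.cuff_inventory],
        "arm": protocol.arm,
        "posture": protocol.posture,
        "n_measurements": protocol.n_measurements,
        "rest_minutes": protocol.rest_minutes,
        "interval_minutes": protocol.interval_minutes,
        "stethoscope_side": protocol.stethoscope_side,
        "temp_recorded": protocol.temp_recorded,
        "mean_temp_c": protocol.mean_temp_c,
        "min_temp_c": protocol.min_temp_c,
        "max_temp_c": protocol.max_temp_c,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, allow_unicode=True, sort_keys=False)


def protocols_from_table2(df: Optional[pd.DataFrame] = None) -> list[SurveyProtocol]:
    """Build :class:`SurveyProtocol` objects from the bundled protocol table.

    All twelve surveys took three seated right-arm measurements; rest and
    interval times are not tabulated per survey and are left unset.
    """
    from . import cuff_matching

    if df is None:
        df = load_fixture("table2")
    protocols = []
    for _, row in df.iterrows():
        cuffs = [
            cuff_matching.parse_cuff_range(label)
            for label in cuff_matching.split_cuff_list(row["cuff_sizes"])
        ]
        temp_recorded = not _is_missing(row["mean_temp_c"])
        protocols.append(
            SurveyProtocol(
                survey_id=row["survey_id"],
                n_participants=int(row["n_participants"]),
                device_type=row["device_type"],
                device_model=row["device_model"],
                cuff_inventory=cuffs,
                arm=row["arm"],
                posture=row["posture"],
                n_measurements=3,
                stethoscope_side=row["stethoscope_side"],
                temp_recorded=temp_recorded,
                mean_temp_c=float(row["mean_temp_c"]) if temp_recorded else None,
                min_temp_c=float(row["min_temp_c"]) if temp_recorded else None,
                max_temp_c=float(row["max_temp_c"]) if temp_recorded else None,
            )
        )
    return protocols


# ---------------------------------------------------------------------------
# validation & summaries


def validate_dataset(ds: SurveyDataset) -> ValidationReport:
    """List per-record constraint violations without mutating the data.

    Checks the physiological range (40 <= dbp < sbp <= 300 mmHg), the
    systolic/diastolic ordering, enum fields, and — as non-violating notes —
    protocol deviations (left arm, supine posture) left unexplained.
    """
    issues: list[ValidationIssue] = []
    for p in ds.participants:
        for r in p.readings:
            for name, value in (("sbp", r.sbp), ("dbp", r.dbp)):
                if value is not None and not 40 <= value <= 300:
                    issues.append(
                        ValidationIssue(
                            p.participant_id,
                            f"{name}{r.sequence_index}",
                            "range",
                            f"{name}{r.sequence_index}={value} outside 40–300 mmHg",
                        )
                    )
            if r.sbp is not None and r.dbp is not None and r.dbp >= r.sbp:
                issues.append(
                    ValidationIssue(
                        p.participant_id,
                        f"reading{r.sequence_index}",
                        "ordering",
                        f"dbp{r.sequence_index}={r.dbp} >= sbp{r.sequence_index}={r.sbp}",
                    )
                )
        if p.arm_used not in ARM_VALUES:
            issues.append(
                ValidationIssue(p.participant_id, "arm_used", "enum", f"unknown arm {p.arm_used!r}")
            )
        if p.posture not in POSTURE_VALUES:
            issues.append(
                ValidationIssue(p.participant_id, "posture", "enum", f"unknown posture {p.posture!r}")
            )
        if p.arm_used == "left" and not p.arm_deviation_reason:
            issues.append(
                ValidationIssue(
                    p.participant_id, "arm_used", "note", "deviation unexplained: left arm without reason"
                )
            )
        if p.posture == "supine" and not p.posture_deviation_reason:
            issues.append(
                ValidationIssue(
                    p.participant_id, "posture", "note", "deviation unexplained: supine posture without reason"
                )
            )
    return ValidationReport(issues=issues)


def temperature_summary(protocols: Sequence[SurveyProtocol]) -> TemperatureSummary:
    """Range of survey-mean room temperatures over protocols that recorded it."""
    if not protocols:
        raise ValueError("temperature_summary requires a non-empty protocol list")
    means = [
        p.mean_temp_c for p in protocols if p.temp_recorded and p.mean_temp_c is not None
    ]
    if not means:
        return TemperatureSummary(n_recorded=0, min_of_means=None, max_of_means=None)
    return TemperatureSummary(
        n_recorded=len(means), min_of_means=min(means), max_of_means=max(means)
    )


def arm_circumference_census(table3: Optional[pd.DataFrame] = None) -> dict[str, int]:
    """Count surveys by arm-circumference recording status.

    ``measured`` counts surveys where the circumference was measured at all
    (recorded or not — codes B and M); ``recorded`` counts code B only.
    """
    if table3 is None:
        table3 = load_fixture("table3")
    codes = table3["arm_circ_code"].str.strip()
    return {
        "measured": int(codes.isin(["B", "M"]).sum()),
        "recorded": int((codes == "B").sum()),
        "not_measured": int((codes == "N").sum()),
    }
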