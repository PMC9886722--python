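"""Plate data model and readers/writers for 96-well PI/OD plate exports.

The pipeline reads two channels per well: propidium-iodide fluorescence
(excitation 535 nm / emission 617 nm, arbitrary units) and absorbance at
600 nm (OD600).  Two file dialects are supported:

* a *grid* CSV — one 8x12 numeric block per channel, each block preceded
  by a header line with the channel name (``PI_535_617`` / ``OD600``);
* a tidy *long table* CSV — one row per well, both channels as columns.

The long table is the canonical internal format; ``picls convert`` turns
grid exports into it.  A YAML layout file maps wells to roles (sample,
unstained negative control, boiled positive control, blank) and
conditions (compound, concentration, age day, replicate).
"""
from __future__ import annotations

import csv
import logging
import math
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import (
    AssayDesignError,
    DataValidationError,
    DuplicateKeyError,
    InvalidPlateError,
    MissingDataError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "WellRecord",
    "WellAssignment",
    "ChannelMeta",
    "PlateLayout",
    "ControlSummary",
    "Condition",
    "normalize_well",
    "well_coords",
    "read_plate_grid",
    "write_plate_grid",
    "read_long_table",
    "write_long_table",
    "records_to_frame",
    "summarize_controls",
]

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9][0-9]?)$")

#: canonical channel names used in grid headers
PI_CHANNEL = "PI_535_617"
OD_CHANNEL = "OD600"


class Role(str, Enum):
    """What a well contributes to the assay."""

    sample = "sample"
    neg_control_unstained = "neg_control_unstained"
    pos_control_boiled = "pos_control_boiled"
    blank = "blank"


def normalize_well(name: str) -> str:
    """Normalize a well name to letter-row/number-column form, e.g. ``a01`` -> ``A1``.

    Rows A-P and columns 1-24 are accepted so the data model also covers
    384-well geometry; the parsers target 96-well plates (A-H, 1-12).
    """
    m = _WELL_RE.match(name.strip())
    if not m:
        raise DataValidationError(f"malformed well name {name!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 24:
        raise DataValidationError(f"well column out of range in {name!r}")
    return f"{row}{col}"


def well_coords(well: str) -> tuple[int, int]:
    """Return zero-based (row, column) indices for a normalized well name."""
    w = normalize_well(well)
    return ord(w[0]) - ord("A"), int(w[1:]) - 1


class WellRecord(BaseModel):
    """One well at one chronological age point.

    ``age_day`` follows the convention that day 1 is the 72 h growth time
    point; ``fluorescence`` is the PI channel (535/617 nm) in arbitrary
    units and ``od600`` the absorbance reading, both required finite and
    non-negative.
    """

    model_config = ConfigDict(frozen=True)

    plate_id: str
    well: str
    role: Role
    compound: Optional[str] = None
    concentration: Optional[float] = None
    concentration_unit: Optional[str] = None
    age_day: int = Field(ge=1)
    replicate: int = Field(default=1, ge=1)
    fluorescence: float = Field(ge=0, allow_inf_nan=False)
    od600: float = Field(ge=0, allow_inf_nan=False)

    @field_validator("well")
    @classmethod
    def _norm_well(cls, v: str) -> str:
        return normalize_well(v)

    @model_validator(mode="after")
    def _blank_has_no_compound(self) -> "WellRecord":
        if self.role is Role.blank and self.compound is not None:
            raise ValueError("blank wells must not carry a compound")
        return self

    @property
    def condition(self) -> "Condition":
        return Condition(self.compound, self.concentration, self.concentration_unit)

    @property
    def norm_fluorescence(self) -> float:
        """OD-normalized fluorescence I/OD (the quantity the survival formula uses)."""
        return self.fluorescence / self.od600


class Condition(tuple):
    """Hashable (compound, concentration, unit) key; compound ``None`` = untreated."""

    __slots__ = ()

    def __new__(cls, compound: Optional[str] = None,
                concentration: Optional[float] = None,
                unit: Optional[str] = None):
        return super().__new__(cls, (compound, concentration, unit))

    @property
    def compound(self) -> Optional[str]:
        return self[0]

    @property
    def concentration(self) -> Optional[float]:
        return self[1]

    @property
    def unit(self) -> Optional[str]:
        return self[2]

    @property
    def is_control(self) -> bool:
        return self[0] is None

    def label(self) -> str:
        if self.is_control:
            return "untreated"
        conc = "" if self.concentration is None else f" {self.concentration:g}"
        unit = self.unit or ""
        return f"{self.compound}{conc}{unit and ' ' + unit}"


class WellAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    role: Role
    compound: Optional[str] = None
    concentration: Optional[float] = None
    concentration_unit: Optional[str] = None
    replicate: int = Field(default=1, ge=1)


class ChannelMeta(BaseModel):
    model_config = ConfigDict(frozen=True)

    excitation_nm: float = 535.0
    emission_nm: float = 617.0
    od_wavelength_nm: float = 600.0


class PlateLayout(BaseModel):
    """Role/condition map for one plate plus channel metadata.

    ``min_controls`` (default 3 per control role) is enforced when
    ``require_controls`` is true; layouts for calibration plates that carry
    no biological controls may set it to 0 or disable the check.
    """

    plate_id: str
    assignments: dict[str, WellAssignment]
    channel_meta: ChannelMeta = ChannelMeta()
    min_controls: int = 3
    require_controls: bool = True

    @field_validator("assignments")
    @classmethod
    def _norm_keys(cls, v: dict[str, WellAssignment]) -> dict[str, WellAssignment]:
        out: dict[str, WellAssignment] = {}
        for k, a in v.items():
            nk = normalize_well(k)
            if nk in out:
                raise ValueError(f"well {nk} assigned twice in layout")
            out[nk] = a
        return out

    @model_validator(mode="after")
    def _check_controls(self) -> "PlateLayout":
        if not self.require_controls:
            return self
        for role in (Role.neg_control_unstained, Role.pos_control_boiled):
            n = sum(1 for a in self.assignments.values() if a.role is role)
            if n < self.min_controls:
                raise ValueError(
                    f"layout {self.plate_id}: {n} wells of role {role.value}, "
                    f"minimum {self.min_controls} required"
                )
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        wells = doc.pop("wells")
        return cls(assignments=wells, **doc)

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "plate_id": self.plate_id,
            "channel_meta": self.channel_meta.model_dump(),
            "min_controls": self.min_controls,
            "require_controls": self.require_controls,
            "wells": {
                w: {k: v for k, v in a.model_dump(mode="json").items()
                    if v is not None}
                for w, a in self.assignments.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


class ControlSummary(BaseModel):
    """Per-plate, per-age-day control aggregates.

    ``i_c``/``od_c`` are the mean fluorescence and OD of the unstained
    negative controls (live cells without PI); ``i_d``/``od_d`` those of
    the boiled positive controls (100% dead, PI-stained).  A valid plate
    must have the dead control brighter after OD normalization:
    ``i_d/od_d > i_c/od_c``.
    """

    model_config = ConfigDict(frozen=True)

    i_c: float
    od_c: float
    i_d: float
    od_d: float
    n_neg: int = Field(ge=1)
    n_pos: int = Field(ge=1)

    @property
    def neg_ratio(self) -> float:
        return self.i_c / self.od_c

    @property
    def pos_ratio(self) -> float:
        return self.i_d / self.od_d

    @property
    def separation_ok(self) -> bool:
        return self.pos_ratio > self.neg_ratio


# ---------------------------------------------------------------------------
# grid dialect

def _parse_grid_blocks(path: Union[str, Path]) -> dict[str, dict[str, float]]:
    """Parse stacked 8x12 channel blocks into {channel: {well: value}}."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]

    channels: dict[str, dict[str, float]] = {}
    i = 0
    known = {PI_CHANNEL.lower(): PI_CHANNEL, OD_CHANNEL.lower(): OD_CHANNEL}
    while i < len(rows):
        first = rows[i][0].strip().lower() if rows[i] else ""
        if first not in known:
            if any(c.strip() for c in rows[i]):
                raise ParseError(
                    f"{path}: unexpected line {i + 1}; expected a channel "
                    f"header ({PI_CHANNEL} or {OD_CHANNEL})"
                )
            i += 1
            continue
        channel = known[first]
        i += 1
        # optional column-index header line (first cell empty)
        if i < len(rows) and rows[i] and rows[i][0].strip() == "":
            i += 1
        block: dict[str, float] = {}
        n_rows = 0
        while i < len(rows) and n_rows < 8:
            cells = rows[i]
            if not any(c.strip() for c in cells):
                break
            if cells[0].strip().lower() in known:
                break
            if re.match(r"^[A-Ha-h]$", cells[0].strip()):
                row_letter = cells[0].strip().upper()
                values = cells[1:]
            else:
                row_letter = chr(ord("A") + n_rows)
                values = cells
            if len(values) != 12:
                raise ParseError(
                    f"{path}: channel block {channel!r}, row {row_letter}: "
                    f"expected 12 columns, found {len(values)}"
                )
            for col, cell in enumerate(values, start=1):
                cell = cell.strip()
                if cell == "":
                    continue
                try:
                    val = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: channel block {channel!r}, well "
                        f"{row_letter}{col}: non-numeric value {cell!r}"
                    ) from exc
                block[f"{row_letter}{col}"] = val
            n_rows += 1
            i += 1
        if n_rows != 8:
            raise ParseError(
                f"{path}: channel block {channel!r} has {n_rows} rows, expected 8"
            )
        channels[channel] = block
    for ch in (PI_CHANNEL, OD_CHANNEL):
        if ch not in channels:
            raise ParseError(f"{path}: missing channel block {ch!r}")
    return channels


def read_plate_grid(path: Union[str, Path], layout: PlateLayout,
                    age_day: int) -> list[WellRecord]:
    """Read a stacked-block grid CSV into well records using *layout*.

    One record is produced per assigned well with both channels populated;
    grid wells not covered by the layout are skipped with a warning.
    """
    channels = _parse_grid_blocks(path)
    pi, od = channels[PI_CHANNEL], channels[OD_CHANNEL]

    extra = (set(pi) | set(od)) - set(layout.assignments)
    if extra:
        logger.warning(
            "plate %s: %d wells with readings are not in the layout and "
            "were skipped: %s", layout.plate_id, len(extra),
            ", ".join(sorted(extra)[:8]),
        )
    records = []
    for well, assign in layout.assignments.items():
        if well not in pi or well not in od:
            missing = [c for c, blk in ((PI_CHANNEL, pi), (OD_CHANNEL, od))
                       if well not in blk]
            raise MissingDataError(
                f"plate {layout.plate_id}: well {well} assigned in layout but "
                f"missing from channel(s) {', '.join(missing)}"
            )
        try:
            records.append(WellRecord(
                plate_id=layout.plate_id,
                well=well,
                role=assign.role,
                compound=assign.compound,
                concentration=assign.concentration,
                concentration_unit=assign.concentration_unit,
                age_day=age_day,
                replicate=assign.replicate,
                fluorescence=pi[well],
                od600=od[well],
            ))
        except ValueError as exc:
            raise DataValidationError(
                f"plate {layout.plate_id}, well {well}: {exc}"
            ) from exc
    return records


def write_plate_grid(records: Sequence[WellRecord], path: Union[str, Path]) -> None:
    """Write records from a single plate/age-day as a stacked-block grid CSV."""
    if not records:
        raise DataValidationError("cannot write an empty plate grid")
    keys = {(r.plate_id, r.age_day) for r in records}
    if len(keys) > 1:
        raise DataValidationError(
            f"grid files hold one plate at one age day; got {sorted(keys)}"
        )
    by_well = {r.well: r for r in records}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for channel, attr in ((PI_CHANNEL, "fluorescence"), (OD_CHANNEL, "od600")):
            writer.writerow([channel])
            writer.writerow([""] + [str(c) for c in range(1, 13)])
            for row in "ABCDEFGH":
                cells = [row]
                for col in range(1, 13):
                    rec = by_well.get(f"{row}{col}")
                    cells.append("" if rec is None else repr(getattr(rec, attr)))
                writer.writerow(cells)


# ---------------------------------------------------------------------------
# long-table dialect

_LONG_COLUMNS = [
    "plate_id", "well", "role", "compound", "concentration",
    "concentration_unit", "age_day", "replicate", "fluorescence", "od600",
]
_REQUIRED_COLUMNS = [c for c in _LONG_COLUMNS if c != "concentration_unit"]


def read_long_table(path: Union[str, Path]) -> list[WellRecord]:
    """Read the canonical tidy long-table CSV into typed well records."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                  "compound": str, "concentration_unit": str},
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "concentration_unit" not in df.columns:
        df["concentration_unit"] = None

    records: list[WellRecord] = []
    seen: set[tuple] = set()
    for idx, row in df.iterrows():
        def text(col):
            v = row[col]
            if pd.isna(v):
                return None
            v = str(v).strip()
            return v or None

        for col in ("fluorescence", "od600"):
            v = row[col]
            if pd.isna(v) or not math.isfinite(float(v)):
                raise DataValidationError(
                    f"{path}, row {idx + 2}: non-finite {col} value"
                )
            if float(v) < 0:
                raise DataValidationError(
                    f"{path}, row {idx + 2}: negative {col} reading"
                )
        conc = row["concentration"]
        try:
            rec = WellRecord(
                plate_id=text("plate_id") or "",
                well=text("well") or "",
                role=Role(text("role")),
                compound=text("compound"),
                concentration=None if pd.isna(conc) else float(conc),
                concentration_unit=text("concentration_unit"),
                age_day=int(row["age_day"]),
                replicate=int(row["replicate"]),
                fluorescence=float(row["fluorescence"]),
                od600=float(row["od600"]),
            )
        except ValueError as exc:
            raise DataValidationError(f"{path}, row {idx + 2}: {exc}") from exc
        key = (rec.plate_id, rec.well, rec.age_day)
        if key in seen:
            raise DuplicateKeyError(
                f"{path}: duplicate reading for plate {rec.plate_id}, well "
                f"{rec.well}, day {rec.age_day}"
            )
        seen.add(key)
        records.append(rec)
    return records


def records_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Well records as a tidy DataFrame (column order of the long table)."""
    rows = [{
        "plate_id": r.plate_id, "well": r.well, "role": r.role.value,
        "compound": r.compound, "concentration": r.concentration,
        "concentration_unit": r.concentration_unit, "age_day": r.age_day,
        "replicate": r.replicate, "fluorescence": r.fluorescence,
        "od600": r.od600,
    } for r in records]
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


def write_long_table(records: Sequence[WellRecord], path: Union[str, Path]) -> None:
    """Write records as the canonical long-table CSV (round-trip safe)."""
    if not records:
        raise DataValidationError("refusing to write an empty long table")
    records_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# control aggregation

def summarize_controls(records: Iterable[WellRecord], min_controls: int = 3,
                       strict: bool = True) -> ControlSummary:
    """Aggregate unstained-negative and boiled-positive controls of one
    plate at one age day into per-role mean fluorescence and OD.

    With ``strict`` (default) an inverted plate — dead control not brighter
    than unstained after OD normalization — raises
    :class:`~picls.errors.InvalidPlateError`; ``strict=False`` returns the
    summary anyway so QC reporting can flag it.
    """
    recs = list(records)
    keys = {(r.plate_id, r.age_day) for r in recs}
    if len(keys) != 1:
        raise AssayDesignError(
            f"controls are summarized per plate per age day; got {sorted(keys)}"
        )
    neg = [r for r in recs if r.role is Role.neg_control_unstained]
    pos = [r for r in recs if r.role is Role.pos_control_boiled]
    for role, group in (("neg_control_unstained", neg), ("pos_control_boiled", pos)):
        if len(group) < min_controls:
            raise AssayDesignError(
                f"plate {recs[0].plate_id} day {recs[0].age_day}: "
                f"{len(group)} wells of role {role}, minimum {min_controls}"
            )
    # fsum: exact summation, so the result is independent of record order
    mean = lambda vals: math.fsum(vals) / len(vals)
    summary = ControlSummary(
        i_c=mean([r.fluorescence for r in neg]),
        od_c=mean([r.od600 for r in neg]),
        i_d=mean([r.fluorescence for r in pos]),
        od_d=mean([r.od600 for r in pos]),
        n_neg=len(neg),
        n_pos=len(pos),
    )
    if strict and not summary.separation_ok:
        raise InvalidPlateError(
            f"plate {recs[0].plate_id} day {recs[0].age_day}: boiled positive "
            f"control (I/OD = {summary.pos_ratio:.3g}) is not brighter than "
            f"the unstained negative control (I/OD = {summary.neg_ratio:.3g})"
        )
    return summary
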