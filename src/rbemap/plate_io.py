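"""Plate-format I/O and the structural data model of a high-throughput
clonogenic experiment.

A 96-well plate sits in a stepped holder so that each of its 12 columns
samples a different depth along a particle beam path and therefore receives
its own combination of dose and beam quality (LET_d, y_d).  Rows A-H within
a column are replicate wells.  Two plates are irradiated per exposure level,
giving 16 replicate wells per dose/beam-quality combination; sham-irradiated
control plates provide the plating efficiency.

Counts travel as long-format CSV (one row per well); the column -> condition
mapping travels as JSON or YAML validated against the schema shipped in
``rbemap/data/conditions.schema.json``.  Reference tables of published RBE
values for the H460 and H1437 cell lines are packaged as CSV fixtures.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

ROW_LABELS = "ABCDEFGH"
N_COLUMNS = 12
IONS = ("photon", "proton", "helium", "carbon")
CHARGED_IONS = ("proton", "helium", "carbon")
CELL_LINES = ("H460", "H1437")

COUNTS_HEADER = ["plate_id", "role", "dose_level_id", "row", "column", "count"]


class PlateFormatError(ValueError):
    """Raised for malformed plate-count files or inconsistent experiments."""


class ConditionConfigError(ValueError):
    """Raised for invalid beam-condition configuration files."""


@dataclass(frozen=True)
class BeamColumnCondition:
    """Beam condition at one plate column: ion, dose ladder and beam quality.

    Parameters
    ----------
    column_index : int
        Plate column, 1-12 (plate convention A1..H12).
    ion : str
        One of ``photon``, ``proton``, ``helium``, ``carbon``.
    doses : tuple of float
        Delivered dose in Gy per exposure level, strictly increasing.
    let_d : float, optional
        Dose-averaged LET at this column's depth, keV/um.
    y_d : float, optional
        Dose-mean lineal energy at this column's depth, keV/um.  Charged
        particle conditions must carry at least one of ``let_d``/``y_d``.
    depth_label : str, optional
        Free-text depth annotation (e.g. "entrance", "distal edge").
    """

    column_index: int
    ion: str
    doses: tuple[float, ...]
    let_d: Optional[float] = None
    y_d: Optional[float] = None
    depth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.column_index <= N_COLUMNS:
            raise ConditionConfigError(
                f"column_index {self.column_index} outside 1..{N_COLUMNS}"
            )
        if self.ion not in IONS:
            raise ConditionConfigError(
                f"unknown ion {self.ion!r}; expected one of {IONS}"
            )
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        if not doses:
            raise ConditionConfigError(
                f"column {self.column_index}: empty dose list"
            )
        if any(d < 0 for d in doses):
            raise ConditionConfigError(
                f"column {self.column_index}: negative dose in {doses}"
            )
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ConditionConfigError(
                f"column {self.column_index}: dose list {doses} not strictly increasing"
            )
        if self.ion in CHARGED_IONS and self.let_d is None and self.y_d is None:
            raise ConditionConfigError(
                f"column {self.column_index}: charged-particle condition "
                f"({self.ion}) needs at least one of let_d / y_d"
            )
        for name in ("let_d", "y_d"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConditionConfigError(
                    f"column {self.column_index}: {name} must be positive, got {v}"
                )

    def dose_for_level(self, dose_level_id: int) -> float:
        """Dose in Gy delivered to this column at a 1-based exposure level."""
        if not 1 <= dose_level_id <= len(self.doses):
            raise PlateFormatError(
                f"dose_level_id {dose_level_id} does not resolve to a dose "
                f"for column {self.column_index} ({len(self.doses)} levels)"
            )
        return self.doses[dose_level_id - 1]


@dataclass(frozen=True)
class Plate:
    """One physical 96-well plate: identity, role and exposure level."""

    plate_id: str
    role: str  # "control" | "irradiated"
    dose_level_id: Optional[int] = None  # 1-based, None for controls

    def __post_init__(self) -> None:
        if self.role not in ("control", "irradiated"):
            raise PlateFormatError(
                f"plate {self.plate_id}: role must be control|irradiated, "
                f"got {self.role!r}"
            )
        if self.role == "irradiated" and self.dose_level_id is None:
            raise PlateFormatError(
                f"irradiated plate {self.plate_id} needs a dose_level_id"
            )


WellKey = tuple[str, str, int]  # (plate_id, row letter, column)


@dataclass
class PlateExperiment:
    """A complete plate experiment: plates, well counts and beam conditions.

    ``wells`` maps (plate_id, row, column) to a colony count; ``None`` marks
    a well that was recorded but not scoreable (missing), which is distinct
    from a zero count -- zero colonies is a datum carrying Poisson
    information, absence is not.
    """

    plates: list[Plate] = field(default_factory=list)
    wells: dict[WellKey, Optional[int]] = field(default_factory=dict)
    cells_seeded_per_well: int = 100
    conditions: list[BeamColumnCondition] = field(default_factory=list)
    replicates_per_column_per_plate: int = 8

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.cells_seeded_per_well <= 0:
            raise PlateFormatError("cells_seeded_per_well must be positive")
        seen_cols = [c.column_index for c in self.conditions]
        if len(seen_cols) != len(set(seen_cols)):
            raise ConditionConfigError("duplicate column_index among conditions")
        ids = [p.plate_id for p in self.plates]
        if len(ids) != len(set(ids)):
            raise PlateFormatError("duplicate plate_id")
        plate_map = {p.plate_id: p for p in self.plates}
        cond_map = self.condition_map()
        for (plate_id, row, col), count in self.wells.items():
            if plate_id not in plate_map:
                raise PlateFormatError(f"well references unknown plate {plate_id!r}")
            if row not in ROW_LABELS:
                raise PlateFormatError(f"bad row label {row!r} (expected A-H)")
            if not 1 <= col <= N_COLUMNS:
                raise PlateFormatError(f"column {col} out of range 1..{N_COLUMNS}")
            if count is not None:
                if count < 0:
                    raise PlateFormatError(
                        f"negative colony count {count} in {plate_id} {row}{col}"
                    )
                if count > self.cells_seeded_per_well:
                    raise PlateFormatError(
                        f"colony count {count} in {plate_id} {row}{col} exceeds "
                        f"cells seeded ({self.cells_seeded_per_well})"
                    )
        # every irradiated plate's level must resolve in every configured column
        for p in self.plates:
            if p.role == "irradiated" and cond_map:
                for cond in self.conditions:
                    cond.dose_for_level(p.dose_level_id)

    # -- accessors ----------------------------------------------------------

    def condition_map(self) -> dict[int, BeamColumnCondition]:
        return {c.column_index: c for c in self.conditions}

    def plate(self, plate_id: str) -> Plate:
        for p in self.plates:
            if p.plate_id == plate_id:
                return p
        raise KeyError(plate_id)

    def control_counts(self) -> list[int]:
        """Non-missing counts from all wells of control plates."""
        controls = {p.plate_id for p in self.plates if p.role == "control"}
        return [
            c
            for (pid, _r, _col), c in self.wells.items()
            if pid in controls and c is not None
        ]

    def column_wells(
        self, column_index: int, include_controls: bool = False
    ) -> list[tuple[float, int]]:
        """(dose Gy, count) pairs for one column across irradiated plates.

        Controls contribute dose-0 pairs when ``include_controls`` is set.
        Missing wells are skipped.
        """
        cond = self.condition_map().get(column_index)
        plate_map = {p.plate_id: p for p in self.plates}
        out: list[tuple[float, int]] = []
        for (pid, _row, col), count in self.wells.items():
            if col != column_index or count is None:
                continue
            plate = plate_map[pid]
            if plate.role == "control":
                if include_controls:
                    out.append((0.0, count))
                continue
            if cond is None:
                raise ConditionConfigError(
                    f"no beam condition configured for column {column_index}"
                )
            out.append((cond.dose_for_level(plate.dose_level_id), count))
        return out

    def n_wells(self) -> int:
        return len(self.wells)


# ---------------------------------------------------------------------------
# counts CSV
# ---------------------------------------------------------------------------


def _parse_well_label(row_label: str, column_field: str, lineno: int) -> tuple[str, int]:
    row = row_label.strip().upper()
    if row not in ROW_LABELS:
        raise PlateFormatError(
            f"line {lineno}: bad row label {row_label!r} (expected A-H)"
        )
    try:
        col = int(column_field)
    except ValueError:
        raise PlateFormatError(
            f"line {lineno}: column {column_field!r} is not an integer"
        ) from None
    if not 1 <= col <= N_COLUMNS:
        raise PlateFormatError(
            f"line {lineno}: column {col} out of range 1..{N_COLUMNS}"
        )
    return row, col


def read_counts(
    path: Union[str, Path],
    delimiter: str = ",",
    cells_seeded_per_well: int = 100,
    conditions: Optional[Sequence[BeamColumnCondition]] = None,
) -> PlateExperiment:
    """Read long-format per-well colony counts into a :class:`PlateExperiment`.

    Expects a header row with columns ``plate_id, role, dose_level_id, row,
    column, count``.  An empty count field marks a missing well (recorded but
    unscoreable); it is never coerced to zero.
    """
    path = Path(path)
    plates: dict[str, Plate] = {}
    wells: dict[WellKey, Optional[int]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise PlateFormatError(f"{path}: empty file, header row required")
        missing = [h for h in COUNTS_HEADER if h not in reader.fieldnames]
        if missing:
            raise PlateFormatError(
                f"{path}: header is missing required columns {missing}"
            )
        for rec in reader:
            lineno = reader.line_num
            plate_id = (rec["plate_id"] or "").strip()
            if not plate_id:
                raise PlateFormatError(f"line {lineno}: empty plate_id")
            role = (rec["role"] or "").strip().lower()
            level_field = (rec["dose_level_id"] or "").strip()
            level = int(level_field) if level_field else None
            plate = Plate(plate_id=plate_id, role=role, dose_level_id=level)
            prev = plates.setdefault(plate_id, plate)
            if prev != plate:
                raise PlateFormatError(
                    f"line {lineno}: plate {plate_id!r} redefined with "
                    f"conflicting role/dose_level_id"
                )
            row, col = _parse_well_label(rec["row"], rec["column"], lineno)
            key = (plate_id, row, col)
            if key in wells:
                raise PlateFormatError(
                    f"line {lineno}: duplicate well {plate_id} {row}{col}"
                )
            count_field = (rec["count"] or "").strip()
            if count_field == "":
                wells[key] = None
            else:
                try:
                    count = int(count_field)
                except ValueError:
                    raise PlateFormatError(
                        f"line {lineno}: count {count_field!r} is not an integer"
                    ) from None
                wells[key] = count
    return PlateExperiment(
        plates=list(plates.values()),
        wells=wells,
        cells_seeded_per_well=cells_seeded_per_well,
        conditions=list(conditions) if conditions else [],
    )


def write_counts(
    experiment: PlateExperiment, path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write an experiment's well counts in the long CSV format read back by
    :func:`read_counts` (round trip preserves all well data)."""
    path = Path(path)
    plate_map = {p.plate_id: p for p in experiment.plates}
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COUNTS_HEADER)
        for (pid, row, col) in sorted(experiment.wells):
            plate = plate_map[pid]
            count = experiment.wells[(pid, row, col)]
            writer.writerow(
                [
                    pid,
                    plate.role,
                    plate.dose_level_id if plate.dose_level_id is not None else "",
                    row,
                    col,
                    count if count is not None else "",
                ]
            )


# ---------------------------------------------------------------------------
# conditions configuration (JSON / YAML)
# ---------------------------------------------------------------------------


def read_conditions(path: Union[str, Path]) -> list[BeamColumnCondition]:
    """Read the column -> beam condition mapping from a JSON or YAML file.

    The file holds ``{"conditions": [...]}`` (or a bare list); each entry
    needs ``column``, ``ion`` and a strictly increasing ``doses`` ladder,
    with ``let_d``/``y_d``/``depth_label`` optional (but charged-particle
    entries need at least one beam-quality value).  A configuration covering
    fewer than 12 columns is accepted with a warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if isinstance(payload, dict):
        entries = payload.get("conditions")
        if entries is None:
            raise ConditionConfigError(f"{path}: missing top-level 'conditions' key")
    elif isinstance(payload, list):
        entries = payload
    else:
        raise ConditionConfigError(f"{path}: expected a mapping or list")
    conditions = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ConditionConfigError(f"{path}: condition #{i + 1} is not a mapping")
        for req in ("column", "ion", "doses"):
            if req not in entry:
                raise ConditionConfigError(
                    f"{path}: condition #{i + 1} missing required field {req!r}"
                )
        conditions.append(
            BeamColumnCondition(
                column_index=int(entry["column"]),
                ion=str(entry["ion"]),
                doses=tuple(entry["doses"]),
                let_d=entry.get("let_d"),
                y_d=entry.get("y_d"),
                depth_label=entry.get("depth_label"),
            )
        )
    cols = [c.column_index for c in conditions]
    if len(cols) != len(set(cols)):
        raise ConditionConfigError(f"{path}: duplicate column indices")
    if len(conditions) < N_COLUMNS:
        warnings.warn(
            f"{path}: partial configuration with {len(conditions)} of "
            f"{N_COLUMNS} columns",
            stacklevel=2,
        )
    return conditions


def write_conditions(
    conditions: Sequence[BeamColumnCondition], path: Union[str, Path]
) -> None:
    """Write conditions as JSON (or YAML when the path ends in .yaml/.yml)."""
    path = Path(path)
    payload = {
        "conditions": [
            {
                k: v
                for k, v in {
                    "column": c.column_index,
                    "ion": c.ion,
                    "doses": list(c.doses),
                    "let_d": c.let_d,
                    "y_d": c.y_d,
                    "depth_label": c.depth_label,
                }.items()
                if v is not None
            }
            for c in conditions
        ]
    }
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged published-RBE table fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableRBERow:
    """One column's published RBE entry; ``None`` marks a value excluded in
    the source table for lack of data coverage (never silently zero)."""

    column_index: int
    y_d: float
    rbe_05: Optional[float]
    rbe_01: Optional[float]


@dataclass(frozen=True)
class TableFixture:
    """Published RBE-vs-y_d table for one cell line and ion (12 columns)."""

    cell_line: str
    ion: str
    rows: tuple[TableRBERow, ...]

    def row(self, column_index: int) -> TableRBERow:
        for r in self.rows:
            if r.column_index == column_index:
                return r
        raise KeyError(column_index)


_FIXTURE_FILES = {"H460": "rbe_h460.csv", "H1437": "rbe_h1437.csv"}


def load_fixture(cell_line: str, ion: str) -> TableFixture:
    """Load the packaged published RBE table for ``cell_line`` x ``ion``.

    Available: cell lines H460 and H1437, ions helium and carbon.  Entries
    excluded in the source for lack of data coverage come back as ``None``
    with their position preserved.
    """
    if cell_line not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown cell line {cell_line!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    if ion not in ("helium", "carbon"):
        raise KeyError(f"no packaged RBE table for ion {ion!r}")
    ref = resources.files("rbemap.data") / _FIXTURE_FILES[cell_line]
    rows = []
    with ref.open("r", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            if rec["ion"] != ion:
                continue
            rows.append(
                TableRBERow(
                    column_index=int(rec["column"]),
                    y_d=float(rec["y_d_kev_um"]),
                    rbe_05=float(rec["rbe_sf05"]) if rec["rbe_sf05"] else None,
                    rbe_01=float(rec["rbe_sf01"]) if rec["rbe_sf01"] else None,
                )
            )
    if len(rows) != N_COLUMNS:
        raise PlateFormatError(
            f"fixture {cell_line}/{ion}: expected {N_COLUMNS} rows, got {len(rows)}"
        )
    return TableFixture(cell_line=cell_line, ion=ion, rows=tuple(rows))
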