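"""Reading and writing Slicer markups fiducial files (.fcsv).

All coordinates are held internally in RAS+ world millimeters; LPS files
have x and y negated at the file boundary, on both read and write. Labels
are mapped to protocol ids through the bundled 32-landmark registry;
unmatched labels are kept with ``afid_id == 0`` so ad-hoc points (e.g.
electrode tips) can travel in the same containers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FcsvParseError, InputError

__all__ = [
    "FiducialRecord",
    "FiducialSet",
    "read_fcsv",
    "write_fcsv",
    "afid_registry",
    "load_template_consensus",
    "SPACES",
]

SPACES = ("subject", "template")

_FCSV_COLUMNS = (
    "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"
)


@dataclass(frozen=True)
class FiducialRecord:
    """A single labeled 3D point in RAS+ world millimeters."""

    afid_id: int
    label: str
    coordinate: np.ndarray
    rater_id: str = "unknown"
    subject_id: str = "unknown"
    space: str = "subject"
    description: str = ""

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        if coord.shape != (3,):
            raise InputError(f"coordinate must be a 3-vector, got shape {coord.shape}")
        if not np.all(np.isfinite(coord)):
            raise InputError(f"non-finite coordinate for label {self.label!r}: {coord}")
        if not (0 <= int(self.afid_id) <= 32):
            raise InputError(f"afid_id must be in 0..32, got {self.afid_id}")
        if self.space not in SPACES:
            raise InputError(f"space must be one of {SPACES}, got {self.space!r}")
        object.__setattr__(self, "coordinate", coord)
        object.__setattr__(self, "afid_id", int(self.afid_id))


@dataclass(frozen=True)
class FiducialSet:
    """An ordered collection of fiducial records for one subject/rater/space."""

    records: tuple[FiducialRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise InputError("FiducialSet must contain at least one record")
        subjects = {r.subject_id for r in records}
        raters = {r.rater_id for r in records}
        spaces = {r.space for r in records}
        if len(subjects) > 1 or len(raters) > 1 or len(spaces) > 1:
            raise InputError(
                "all records in a FiducialSet must share subject_id, rater_id and "
                f"space; got subjects={sorted(subjects)}, raters={sorted(raters)}, "
                f"spaces={sorted(spaces)}"
            )
        nonzero = [r.afid_id for r in records if r.afid_id != 0]
        if len(nonzero) != len(set(nonzero)):
            dupes = sorted({i for i in nonzero if nonzero.count(i) > 1})
            raise InputError(f"duplicate afid_id values in FiducialSet: {dupes}")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FiducialRecord]:
        return iter(self.records)

    @property
    def subject_id(self) -> str:
        return self.records[0].subject_id

    @property
    def rater_id(self) -> str:
        return self.records[0].rater_id

    @property
    def space(self) -> str:
        return self.records[0].space

    @property
    def afid_ids(self) -> tuple[int, ...]:
        return tuple(r.afid_id for r in self.records)

    def get(self, afid_id: int) -> FiducialRecord:
        for rec in self.records:
            if rec.afid_id == afid_id:
                return rec
        raise KeyError(f"afid_id {afid_id} not present in set")

    def coordinates(self, afid_ids: Sequence[int] | None = None) -> np.ndarray:
        """Stack coordinates as an (n, 3) array, optionally for selected ids."""
        if afid_ids is None:
            return np.stack([r.coordinate for r in self.records])
        return np.stack([self.get(i).coordinate for i in afid_ids])

    def with_coordinates(self, coords: np.ndarray, **overrides) -> "FiducialSet":
        """Copy of this set with replaced coordinates (same record order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.records), 3):
            raise InputError(
                f"expected coordinates of shape {(len(self.records), 3)}, "
                f"got {coords.shape}"
            )
        new = tuple(
            replace(rec, coordinate=coords[i], **overrides)
            for i, rec in enumerate(self.records)
        )
        return FiducialSet(records=new, provenance=self.provenance)


def _registry_lookup() -> dict[str, int]:
    """Map label spellings to afid ids: label, numeric string, AFIDnn."""
    table = afid_registry()
    lookup: dict[str, int] = {}
    for afid_id, label in zip(table["afid_id"], table["label"]):
        lookup[str(label).upper()] = int(afid_id)
        lookup[str(int(afid_id))] = int(afid_id)
        lookup[f"AFID{int(afid_id):02d}"] = int(afid_id)
    return lookup


def afid_registry() -> pd.DataFrame:
    """Return the 32-landmark protocol registry as a DataFrame.

    Columns: ``afid_id`` (1..32), ``label`` (unique short name),
    ``description`` (free display text, editable in the bundled JSON).
    """
    raw = resources.files("afidreg.data").joinpath("afid_protocol.json").read_text()
    entries = json.loads(raw)["afids"]
    table = pd.DataFrame(entries, columns=["afid_id", "label", "description"])
    if len(table) != 32 or sorted(table["afid_id"]) != list(range(1, 33)):
        raise InputError("bundled protocol registry is corrupt: expected ids 1..32")
    if table["label"].duplicated().any():
        raise InputError("bundled protocol registry is corrupt: duplicate labels")
    return table


def _parse_coordinate_system(value: str) -> str:
    v = value.strip().upper()
    # Older Slicer wrote a numeric flag (0 = RAS, 1 = LPS); newer writes a string.
    if v in {"RAS", "0"}:
        return "RAS"
    if v in {"LPS", "1"}:
        return "LPS"
    raise FcsvParseError(f"unknown coordinate system declaration: {value!r}")


def read_fcsv(
    path: str | Path,
    *,
    subject_id: str = "unknown",
    rater_id: str = "unknown",
    space: str = "subject",
) -> FiducialSet:
    """Read a Slicer markups fiducial CSV into a RAS+ :class:`FiducialSet`.

    Files declaring an LPS coordinate system have x and y negated on read.
    The label column is mapped to a protocol id through the registry
    (matching the short label, the bare number, or ``AFIDnn``); unmatched
    labels are preserved with ``afid_id == 0``.
    """
    path = Path(path)
    if not path.exists():
        raise FcsvParseError(f"no such file: {path}")
    lookup = _registry_lookup()
    coordinate_system = "RAS"
    saw_declaration = False
    records: list[FiducialRecord] = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    _, _, value = body.partition("=")
                    coordinate_system = _parse_coordinate_system(value)
                    saw_declaration = True
                continue
            row = next(csv.reader([line]))
            if len(row) < 12:
                raise FcsvParseError(
                    f"{path}:{lineno}: expected >=12 columns "
                    f"({_FCSV_COLUMNS}), got {len(row)}"
                )
            try:
                coord = np.array([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise FcsvParseError(
                    f"{path}:{lineno}: non-numeric coordinate: {row[1:4]}"
                ) from exc
            if coordinate_system == "LPS":
                coord[0] = -coord[0]
                coord[1] = -coord[1]
            label = row[11].strip()
            desc = row[12].strip() if len(row) > 12 else ""
            afid_id = lookup.get(label.upper(), 0)
            records.append(
                FiducialRecord(
                    afid_id=afid_id,
                    label=label,
                    coordinate=coord,
                    rater_id=rater_id,
                    subject_id=subject_id,
                    space=space,
                    description=desc,
                )
            )
    if not records:
        raise FcsvParseError(f"{path}: no fiducial rows found")
    if not saw_declaration and coordinate_system == "RAS":
        pass  # RAS assumed when the header is silent, matching Slicer's default
    return FiducialSet(records=tuple(records), provenance=str(path))


def write_fcsv(
    fiducials: FiducialSet,
    path: str | Path,
    coordinate_system: str = "RAS",
) -> Path:
    """Write a FiducialSet as a Slicer markups fiducial CSV.

    ``coordinate_system`` selects the on-disk convention; LPS output negates
    x and y (the in-memory set is always RAS+).
    """
    coordinate_system = coordinate_system.upper()
    if coordinate_system not in {"RAS", "LPS"}:
        raise InputError(f"coordinate_system must be RAS or LPS, got {coordinate_system!r}")
    path = Path(path)
    lines = [
        "# Markups fiducial file version = 4.11",
        f"# CoordinateSystem = {coordinate_system}",
        f"# columns = {_FCSV_COLUMNS}",
    ]
    for i, rec in enumerate(fiducials, start=1):
        x, y, z = rec.coordinate
        if coordinate_system == "LPS":
            x, y = -x, -y
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{x:.6f},{y:.6f},{z:.6f},"
            f"0,0,0,1,1,1,0,{rec.label},{rec.description},"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_template_consensus() -> FiducialSet:
    """Bundled template-space consensus placements for all 32 landmarks.

    AC and PC carry consensus coordinates; the remaining landmarks are
    approximate template positions (see the bundled file's descriptions) and
    serve as simulation anchors, not as normative references.
    """
    with resources.as_file(
        resources.files("afidreg.data").joinpath("template_consensus.fcsv")
    ) as p:
        return read_fcsv(
            p, subject_id="template", rater_id="consensus", space="template"
        )
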