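"""Bijective mapping between microgrid positions and 96-well plate wells.

Grid squares are visited in a traversal order (row-major, column-major or
serpentine) and collection wells are filled in canonical plate order
(A1, A2, ..., A12, B1, ..., H12), so every traversal yields a bijection
between the 96 grid positions and the 96 wells. Under the default
row-major traversal, grid row r maps to plate row letter (A=1 ... H=8) and
grid column c to plate column number.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Ordering",
    "WellAssignment",
    "assign_wells",
    "well_for_position",
    "position_for_well",
    "well_to_position",
    "normalize_well",
    "parse_well",
    "well_label",
    "export_plate_map",
    "import_plate_map",
]

_WELL_RE = re.compile(r"^([A-Za-z])0*([1-9]\d*)$")


class Ordering(str, Enum):
    ROW_MAJOR = "row_major"
    COLUMN_MAJOR = "column_major"
    SERPENTINE = "serpentine"


def well_label(plate_row: int, plate_col: int) -> str:
    """Canonical label of the well at plate (row, col), 1-based (A1..H12)."""
    if not 1 <= plate_row <= 8 or not 1 <= plate_col <= 12:
        raise ValueError(f"plate position ({plate_row}, {plate_col}) outside 8x12")
    return f"{chr(ord('A') + plate_row - 1)}{plate_col}"


def parse_well(well: str) -> tuple[int, int]:
    """Parse a well label into plate (row, col). Accepts 'a01' style input."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise ValueError(f"unrecognized well label {well!r}")
    row = ord(m.group(1).upper()) - ord("A") + 1
    col = int(m.group(2))
    if row > 8 or col > 12:
        raise ValueError(f"well {well!r} outside a 96-well plate (A1-H12)")
    return row, col


def normalize_well(well: str) -> str:
    """Canonical uppercase, unpadded form: 'a01' -> 'A1'."""
    return well_label(*parse_well(well))


def _traversal_index(
    row: int, col: int, ordering: Ordering, n_rows: int, n_cols: int
) -> int:
    """0-based position of grid square (row, col) in the traversal order."""
    if not 1 <= row <= n_rows or not 1 <= col <= n_cols:
        raise ValueError(f"grid position ({row}, {col}) outside {n_rows}x{n_cols}")
    if ordering == Ordering.ROW_MAJOR:
        return (row - 1) * n_cols + (col - 1)
    if ordering == Ordering.COLUMN_MAJOR:
        return (col - 1) * n_rows + (row - 1)
    if ordering == Ordering.SERPENTINE:
        # odd rows left-to-right, even rows right-to-left
        offset = (col - 1) if row % 2 == 1 else (n_cols - col)
        return (row - 1) * n_cols + offset
    raise ValueError(f"unknown ordering {ordering!r}")


def well_for_position(
    row: int,
    col: int,
    ordering: Ordering = Ordering.ROW_MAJOR,
    n_rows: int = 8,
    n_cols: int = 12,
) -> str:
    """Collection well for grid square (row, col) under a traversal order."""
    k = _traversal_index(row, col, Ordering(ordering), n_rows, n_cols)
    return well_label(k // 12 + 1, k % 12 + 1)


def position_for_well(
    well: str,
    ordering: Ordering = Ordering.ROW_MAJOR,
    n_rows: int = 8,
    n_cols: int = 12,
) -> tuple[int, int]:
    """Inverse of :func:`well_for_position`."""
    prow, pcol = parse_well(well)
    k = (prow - 1) * 12 + (pcol - 1)
    ordering = Ordering(ordering)
    if ordering == Ordering.ROW_MAJOR:
        return k // n_cols + 1, k % n_cols + 1
    if ordering == Ordering.COLUMN_MAJOR:
        return k % n_rows + 1, k // n_rows + 1
    if ordering == Ordering.SERPENTINE:
        row = k // n_cols + 1
        offset = k % n_cols
        col = offset + 1 if row % 2 == 1 else n_cols - offset
        return row, col
    raise ValueError(f"unknown ordering {ordering!r}")


@dataclass(frozen=True)
class WellAssignment:
    """Bijection between the 96 grid squares and the 96 plate wells."""

    ordering: Ordering = Ordering.ROW_MAJOR
    n_rows: int = 8
    n_cols: int = 12
    mapping: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mapping = {
            (r, c): well_for_position(r, c, self.ordering, self.n_rows, self.n_cols)
            for r in range(1, self.n_rows + 1)
            for c in range(1, self.n_cols + 1)
        }
        object.__setattr__(self, "mapping", mapping)

    @property
    def inverse(self) -> dict:
        return {w: pos for pos, w in self.mapping.items()}

    def well(self, row: int, col: int) -> str:
        return self.mapping[(row, col)]

    def position(self, well: str) -> tuple[int, int]:
        w = normalize_well(well)
        try:
            return self.inverse[w]
        except KeyError:
            raise ValueError(f"well {w!r} not covered by this assignment") from None


def assign_wells(
    grid: Sequence, ordering: Ordering = Ordering.ROW_MAJOR
) -> WellAssignment:
    """Assign collection wells to a 96-square grid.

    ``grid`` is a sequence of objects with ``row``/``col`` attributes (or
    (row, col) pairs); the 96 positions must be distinct.
    """
    positions = [
        (sq.row, sq.col) if hasattr(sq, "row") else tuple(sq) for sq in grid
    ]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate grid positions: {dupes}")
    if len(positions) != 96:
        raise ValueError(f"expected 96 squares, got {len(positions)}")
    return WellAssignment(ordering=Ordering(ordering))


def well_to_position(well: str, assignment: WellAssignment) -> tuple[int, int]:
    """Grid (row, col) collected into ``well`` under ``assignment``."""
    return assignment.position(well)


def export_plate_map(assignment: WellAssignment, destination) -> None:
    """Write the assignment as a plate-map CSV with columns well,row,col."""
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "row", "col"])
        for (r, c), well in sorted(assignment.mapping.items()):
            writer.writerow([well, r, c])


def import_plate_map(source) -> dict:
    """Read a plate-map CSV back into a {well: (row, col)} dict.

    Validates the bijection: 96 distinct wells, 96 distinct positions.
    """
    mapping: dict[str, tuple[int, int]] = {}
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"well", "row", "col"} <= set(
            reader.fieldnames
        ):
            raise ValueError("plate map must have columns well,row,col")
        for line in reader:
            well = normalize_well(line["well"])
            if well in mapping:
                raise ValueError(f"duplicate well {well}")
            mapping[well] = (int(line["row"]), int(line["col"]))
    if len(mapping) != 96:
        raise ValueError(f"expected 96 wells, got {len(mapping)}")
    if len(set(mapping.values())) != 96:
        raise ValueError("duplicate grid positions in plate map")
    return mapping
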