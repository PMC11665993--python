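"""Microgrid construction and placement geometry.

A microgrid template is a regular lattice of 96 square dissection shapes
(8 rows x 12 columns by default, one square per well of a 96-well collection
plate). Neighbouring squares are separated by a *bridge*: a strip of intact
tissue whose width is expressed as a fraction of the square side. The grid
is built in a template coordinate frame (micrometres, x to the right, y
downward as on a microscope stage image, origin at the top-left corner of
square row 1 / column 1) and placed onto tissue stage coordinates through
two user-picked reference points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .wellplate import Ordering, well_for_position

__all__ = [
    "Magnification",
    "MicrogridSpec",
    "SquareCut",
    "Placement",
    "TemplatePreset",
    "PRESETS",
    "MEMBRANE_BEAM_WIDTH_UM",
    "TISSUE_BEAM_WIDTH_UM",
    "build_microgrid",
    "place_template",
    "effective_cut_area",
]


class Magnification(str, Enum):
    """Objective magnifications supported by the cutting system."""

    X5 = "5x"
    X10 = "10x"
    X20 = "20x"
    X40 = "40x"
    X63 = "63x"


#: Laser beam width measured on the bare PEN membrane, per objective (um).
MEMBRANE_BEAM_WIDTH_UM = {
    Magnification.X5: 7.8,
    Magnification.X10: 4.5,
    Magnification.X20: 2.6,
    Magnification.X40: 1.8,
    Magnification.X63: 0.8,
}

#: Laser beam width measured on a 20 um liver section, per objective (um).
TISSUE_BEAM_WIDTH_UM = {
    Magnification.X5: 9.1,
    Magnification.X10: 5.2,
    Magnification.X20: 3.6,
    Magnification.X40: 2.1,
    Magnification.X63: 1.1,
}


class MicrogridSpec(BaseModel):
    """Parametric description of a 96-square microgrid template.

    Parameters
    ----------
    square_side
        Nominal side of each square, um. Strictly positive.
    bridge_fraction
        Bridge width as a fraction of the square side (dimensionless,
        ``0 <= f < 1``); the physical bridge width is
        ``bridge_fraction * square_side``.
    n_rows, n_cols
        Lattice shape; the product must equal 96 so the grid maps onto a
        standard 96-well plate.
    magnification
        Objective used for cutting; determines the default beam widths.
    beam_width_tissue, beam_width_membrane
        Laser kerf widths in um. Default to the measured values for the
        chosen magnification.
    ordering
        Traversal order used to assign collection wells.
    """

    square_side: float = Field(gt=0)
    bridge_fraction: float = Field(default=0.12, ge=0, lt=1)
    n_rows: int = Field(default=8, gt=0)
    n_cols: int = Field(default=12, gt=0)
    magnification: Magnification = Magnification.X5
    beam_width_tissue: Optional[float] = Field(default=None, ge=0)
    beam_width_membrane: Optional[float] = Field(default=None, ge=0)
    ordering: Ordering = Ordering.ROW_MAJOR

    @model_validator(mode="after")
    def _check(self) -> "MicrogridSpec":
        if self.n_rows * self.n_cols != 96:
            raise ValueError(
                f"n_rows x n_cols must equal 96, got "
                f"{self.n_rows} x {self.n_cols} = {self.n_rows * self.n_cols}"
            )
        if self.beam_width_tissue is None:
            object.__setattr__(
                self, "beam_width_tissue", TISSUE_BEAM_WIDTH_UM[self.magnification]
            )
        if self.beam_width_membrane is None:
            object.__setattr__(
                self,
                "beam_width_membrane",
                MEMBRANE_BEAM_WIDTH_UM[self.magnification],
            )
        return self

    @property
    def pitch(self) -> float:
        """Centre-to-centre lattice spacing, um."""
        return self.square_side * (1.0 + self.bridge_fraction)

    @property
    def bridge_width(self) -> float:
        """Physical edge-to-edge gap between neighbouring squares, um."""
        return self.bridge_fraction * self.square_side

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the full grid footprint, um."""
        w = self.n_cols * self.square_side + (self.n_cols - 1) * self.bridge_width
        h = self.n_rows * self.square_side + (self.n_rows - 1) * self.bridge_width
        return (w, h)


@dataclass(frozen=True)
class SquareCut:
    """One dissection square of the microgrid.

    ``polygon`` holds the 4 corner points (top-left, bottom-left,
    bottom-right, top-right: counter-clockwise on screen with y pointing
    down), um. After placement the square may be rotated/scaled, so ``side``
    is recomputed from the polygon.
    """

    row: int
    col: int
    polygon: np.ndarray  # (4, 2) float64
    well: Optional[str] = None

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.shape != (4, 2):
            raise ValueError(f"polygon must be 4 corner points, got shape {poly.shape}")
        object.__setattr__(self, "polygon", poly)

    @property
    def center(self) -> np.ndarray:
        """Square centre (x, y), um — mean of the 4 corners."""
        return self.polygon.mean(axis=0)

    @property
    def side(self) -> float:
        """Edge length, um (first edge; all edges equal for a square)."""
        return float(np.linalg.norm(self.polygon[1] - self.polygon[0]))

    @property
    def area(self) -> float:
        """Signed-shoelace absolute area, um^2."""
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass(frozen=True)
class Placement:
    """Two-reference-point placement of a template onto stage coordinates.

    ``ref_point_1`` anchors the top-left corner of square (row 1, col 1);
    ``ref_point_2`` marks the end of the first grid line (right edge of the
    last column). The segment ref1 -> ref2 sets the grid rotation and — in
    ``"similarity"`` mode — also rescales the grid so its first-row extent
    spans the segment. ``"rotation_only"`` keeps the physical template size
    and uses the segment only for orientation.
    """

    ref_point_1: tuple[float, float]
    ref_point_2: tuple[float, float]
    mode: str = "similarity"  # or "rotation_only"

    def __post_init__(self) -> None:
        if self.mode not in ("similarity", "rotation_only"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        d = math.dist(self.ref_point_1, self.ref_point_2)
        if d <= 0.0:
            raise ValueError("reference points must be distinct")


@dataclass(frozen=True)
class TemplatePreset:
    """Bundled characteristics of one published template size.

    ``measured_area`` is the average single-square tissue area actually
    recovered per cut (instrument measurement on a 20 um liver section);
    ``cutting_time_min`` the measured cut-and-collect time for the full
    96-square grid. Both are carried as data, not derived quantities.
    """

    name: str
    square_side: float
    magnification: Magnification
    measured_area: float
    bridge_fraction: float
    cutting_time_min: float

    @property
    def beam_width_tissue(self) -> float:
        return TISSUE_BEAM_WIDTH_UM[self.magnification]

    @property
    def beam_width_membrane(self) -> float:
        return MEMBRANE_BEAM_WIDTH_UM[self.magnification]

    def spec(self, ordering: Ordering = Ordering.ROW_MAJOR) -> MicrogridSpec:
        """Materialize the preset as a :class:`MicrogridSpec`."""
        return MicrogridSpec(
            square_side=self.square_side,
            bridge_fraction=self.bridge_fraction,
            magnification=self.magnification,
            ordering=ordering,
        )


#: The six published template sizes, largest first.
PRESETS: dict[str, TemplatePreset] = {
    p.name: p
    for p in (
        TemplatePreset("500x500", 500.0, Magnification.X5, 246363.0, 0.12, 32.0),
        TemplatePreset("270x270", 270.0, Magnification.X10, 73483.0, 0.15, 19.0),
        TemplatePreset("200x200", 200.0, Magnification.X20, 39969.0, 0.13, 37.0),
        TemplatePreset("100x100", 100.0, Magnification.X40, 10134.0, 0.08, 20.0),
        TemplatePreset("50x50", 50.0, Magnification.X63, 2563.0, 0.10, 29.0),
        TemplatePreset("30x30", 30.0, Magnification.X63, 923.0, 0.13, 24.0),
    )
}


def build_microgrid(spec: MicrogridSpec) -> list[SquareCut]:
    """Lay out the 96 squares of ``spec`` on a regular lattice.

    Squares are returned in row-major order. Square (1, 1) has its top-left
    corner at the template origin; the lattice pitch is
    ``square_side * (1 + bridge_fraction)`` on both axes, so the
    edge-to-edge gap between neighbours is exactly the bridge width.
    Collection wells are assigned according to ``spec.ordering``.
    """
    s = spec.square_side
    pitch = spec.pitch
    squares: list[SquareCut] = []
    for r in range(1, spec.n_rows + 1):
        for c in range(1, spec.n_cols + 1):
            x0 = (c - 1) * pitch
            y0 = (r - 1) * pitch
            poly = np.array(
                [[x0, y0], [x0, y0 + s], [x0 + s, y0 + s], [x0 + s, y0]],
                dtype=float,
            )
            well = well_for_position(r, c, spec.ordering, spec.n_rows, spec.n_cols)
            squares.append(SquareCut(row=r, col=c, polygon=poly, well=well))
    return squares


def _first_row_extent(grid: Sequence[SquareCut]) -> float:
    row1 = [sq for sq in grid if sq.row == 1]
    xs = np.concatenate([sq.polygon[:, 0] for sq in row1])
    return float(xs.max() - xs.min())


def place_template(grid: Sequence[SquareCut], placement: Placement) -> list[SquareCut]:
    """Map a template-frame grid onto stage coordinates.

    Applies the similarity transform defined by ``placement``: translation
    taking the template origin (top-left corner of square (1,1)) to
    ``ref_point_1``, rotation by the angle of the ref1 -> ref2 segment and,
    in similarity mode, isotropic scaling so the first-row extent spans
    exactly that segment.
    """
    if not grid:
        raise ValueError("empty grid")
    origin = grid[0].polygon[0].copy()  # top-left corner of square (1,1)
    ref1 = np.asarray(placement.ref_point_1, dtype=float)
    ref2 = np.asarray(placement.ref_point_2, dtype=float)
    delta = ref2 - ref1
    theta = math.atan2(delta[1], delta[0])
    if placement.mode == "similarity":
        scale = float(np.linalg.norm(delta)) / _first_row_extent(grid)
    else:
        scale = 1.0
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    mat = scale * rot
    placed = []
    for sq in grid:
        poly = (sq.polygon - origin) @ mat.T + ref1
        placed.append(replace(sq, polygon=poly))
    return placed


def effective_cut_area(
    side: float,
    beam_width: float,
    model: str = "nominal",
    measured_area: Optional[float] = None,
    inset_coefficient: float = 0.5,
) -> float:
    """Area of tissue actually recovered from one nominally square cut, um^2.

    The laser kerf destroys a strip of tissue ``beam_width`` wide along the
    cut path, so the collected piece is smaller than the drawn square.

    Models
    ------
    ``"nominal"``
        Ignore the kerf: ``side**2``.
    ``"kerf_inset"``
        Shrink each edge inward by ``inset_coefficient * beam_width``
        (0.5 = kerf centred on the cut path):
        ``(side - inset_coefficient * beam_width)**2``.
    ``"measured"``
        Return ``measured_area`` verbatim (use the bundled per-template
        measured averages from :data:`PRESETS`).
    """
    if side <= beam_width:
        raise ValueError(
            f"square side ({side} um) must exceed the beam width ({beam_width} um)"
        )
    if model == "nominal":
        return side * side
    if model == "kerf_inset":
        inner = side - inset_coefficient * beam_width
        return inner * inner
    if model == "measured":
        if measured_area is None:
            raise ValueError("model 'measured' requires measured_area")
        return float(measured_area)
    raise ValueError(f"unknown area model {model!r}")
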