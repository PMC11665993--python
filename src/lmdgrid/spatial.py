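"""Re-projection of per-well concentrations onto the tissue grid.

Each well's tissue concentration is placed back at the grid square it was
collected from (inverting the well assignment), yielding an
``n_rows x n_cols`` concentration matrix aligned with the tissue: a
low-resolution absolute-quantification image of the section. Missing wells
keep their cause: ``BQL`` (below the calibration range) is distinct from
``LOST`` (cut never captured) — and neither is ever encoded as zero, which
would corrupt downstream statistics.

Matrix orientation follows the stage convention: grid row 1 at the top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from PIL.PngImagePlugin import PngInfo
import tifffile

from .quantify import PlateQuantResult
from .wellplate import WellAssignment

__all__ = ["ConcentrationMap", "plate_to_map", "export_map", "read_map_csv"]

#: Raster colours for cells without a value (RGB).
BQL_COLOR = (150, 80, 200)  # violet: analyte below range, tissue present
LOST_COLOR = (220, 60, 60)  # red: cut never captured
BACKGROUND = (0, 0, 0)


@dataclass
class ConcentrationMap:
    """Spatial matrix of tissue concentrations for one compound.

    ``values`` holds ug/g with NaN where no value exists; ``status`` holds
    the per-cell status string (``ok``/``bql``/``lost``).
    """

    values: np.ndarray  # (n_rows, n_cols) float
    status: np.ndarray  # (n_rows, n_cols) object (str)
    compound: str
    units: str = "ug/g"
    orientation: str = "row 1 at top (stage convention)"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        if self.values.shape != self.status.shape:
            raise ValueError("values and status shapes differ")
        ok_has_value = np.isfinite(self.values[self.status == "ok"])
        if not ok_has_value.all():
            raise ValueError("ok cells must carry finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def plate_to_map(
    result: PlateQuantResult,
    assignment: WellAssignment,
    compound: Optional[str] = None,
) -> ConcentrationMap:
    """Project one compound's per-well results back onto grid coordinates.

    Every well in ``result`` must be covered by ``assignment``; each ok
    well contributes exactly one matrix cell.
    """
    frame = result.wells
    if compound is None:
        compounds = frame.compound.unique()
        if len(compounds) != 1:
            raise ValueError(
                f"plate holds {len(compounds)} compounds; pass compound="
            )
        compound = compounds[0]
    sub = frame[frame.compound == compound]
    if sub.empty:
        raise ValueError(f"no measurements for compound {compound!r}")
    n_rows, n_cols = assignment.n_rows, assignment.n_cols
    values = np.full((n_rows, n_cols), math.nan)
    status = np.full((n_rows, n_cols), "lost", dtype=object)
    seen = np.zeros((n_rows, n_cols), dtype=bool)
    for _, rec in sub.iterrows():
        r, c = assignment.position(rec.well)  # raises on unknown wells
        if seen[r - 1, c - 1]:
            raise ValueError(f"well {rec.well} maps to an already-filled cell")
        seen[r - 1, c - 1] = True
        status[r - 1, c - 1] = rec.status
        if rec.status == "ok":
            values[r - 1, c - 1] = rec.tissue_conc_ug_g
    return ConcentrationMap(values=values, status=status, compound=compound)


def _matrix_frame(cmap: ConcentrationMap) -> pd.DataFrame:
    n_rows, n_cols = cmap.shape
    cells = np.empty((n_rows, n_cols), dtype=object)
    for i in range(n_rows):
        for j in range(n_cols):
            s = cmap.status[i, j]
            cells[i, j] = f"{cmap.values[i, j]:.6f}" if s == "ok" else s.upper()
    return pd.DataFrame(
        cells,
        index=[f"row{r}" for r in range(1, n_rows + 1)],
        columns=[f"col{c}" for c in range(1, n_cols + 1)],
    )


def _render(cmap: ConcentrationMap, scale: str, pixels_per_cell: int) -> np.ndarray:
    vals = cmap.values.copy()
    if scale == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log10(vals)
        vals[~np.isfinite(vals)] = math.nan
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    finite = vals[np.isfinite(vals)]
    if finite.size:
        lo, hi = float(finite.min()), float(finite.max())
        span = hi - lo
    else:
        lo, span = 0.0, 0.0
    n_rows, n_cols = cmap.shape
    rgb = np.zeros((n_rows, n_cols, 3), dtype=np.uint8)
    for i in range(n_rows):
        for j in range(n_cols):
            s = cmap.status[i, j]
            if s == "bql":
                rgb[i, j] = BQL_COLOR
            elif s == "lost":
                rgb[i, j] = LOST_COLOR
            else:
                frac = 0.5 if span == 0 else (vals[i, j] - lo) / span
                # dark-blue -> yellow ramp, monotone in concentration
                rgb[i, j] = (
                    int(round(255 * frac)),
                    int(round(255 * frac)),
                    int(round(96 + 64 * (1 - frac))),
                )
    return np.repeat(np.repeat(rgb, pixels_per_cell, axis=0), pixels_per_cell, axis=1)


def export_map(
    cmap: ConcentrationMap,
    destination: Union[str, Path],
    format: str = "csv",
    scale: str = "linear",
    pixels_per_cell: int = 24,
) -> None:
    """Write the map as a CSV matrix or a PNG/TIFF raster.

    The CSV carries the numeric matrix with row/col headers and the
    literals ``BQL``/``LOST`` for missing cells. Rasters render one block
    of ``pixels_per_cell`` pixels per square, with distinct colours for
    BQL and lost cells; output is deterministic for fixed inputs, and the
    orientation note is embedded in the image metadata.
    """
    destination = Path(destination)
    if format == "csv":
        frame = _matrix_frame(cmap)
        header = (
            f"# compound={cmap.compound}\n# units={cmap.units}\n"
            f"# orientation={cmap.orientation}\n"
        )
        destination.write_text(header + frame.to_csv())
        return
    img = _render(cmap, scale, pixels_per_cell)
    meta = f"compound={cmap.compound}; units={cmap.units}; {cmap.orientation}"
    if format == "png":
        info = PngInfo()
        info.add_text("Description", meta)
        Image.fromarray(img).save(destination, pnginfo=info)
    elif format == "tiff":
        tifffile.imwrite(destination, img, description=meta)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_map_csv(source: Union[str, Path]) -> ConcentrationMap:
    """Inverse of the CSV export (round-trips values to 1e-6 ug/g)."""
    source = Path(source)
    meta: dict[str, str] = {}
    lines = source.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(
        Path(source), skiprows=body_start, index_col=0, dtype=str
    )
    n_rows, n_cols = frame.shape
    values = np.full((n_rows, n_cols), math.nan)
    status = np.full((n_rows, n_cols), "ok", dtype=object)
    for i in range(n_rows):
        for j in range(n_cols):
            cell = str(frame.iat[i, j]).strip()
            if cell.upper() in ("BQL", "LOST"):
                status[i, j] = cell.lower()
            else:
                values[i, j] = float(cell)
    return ConcentrationMap(
        values=values,
        status=status,
        compound=meta.get("compound", ""),
        units=meta.get("units", "ug/g"),
    )
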