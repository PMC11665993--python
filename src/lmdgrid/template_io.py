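"""Template serialization: an open shape-list dialect in XML and CSV.

The instrument vendor's native shape-list container is an undocumented
binary format; this module defines an open, plain-text equivalent carrying
the same information — square vertices in stage micrometres, the collection
well of each shape, the two calibration reference points and the grid
parameters. XML files written here, renamed to ``.txt``, serve as the
importable plain-text form; no bit-compatibility with vendor software is
claimed.

Serialization is deterministic: squares in row-major order, coordinates
with 6 decimal places, period decimal separator. Writing then reading a
document reproduces every coordinate to 1e-6 um and every well assignment
exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from lxml import etree

from .grid import Magnification, MicrogridSpec, SquareCut
from .wellplate import Ordering, normalize_well

__all__ = [
    "TemplateMetadata",
    "TemplateDocument",
    "documents_equal",
    "write_template",
    "read_template",
]

_FMT = "{:.6f}"  # canonical coordinate format: 6 decimals, locale-free

CSV_COLUMNS = ["row", "col", "well", "x1", "y1", "x2", "y2", "x3", "y3", "x4", "y4"]


@dataclass
class TemplateMetadata:
    name: str = ""
    created: str = ""  # ISO timestamp as text; fixed value -> byte-stable files
    calibration_points: tuple = ()  # ((x, y), (x, y)) reference points, um


@dataclass
class TemplateDocument:
    """A microgrid template ready for export: spec, 96 squares, metadata."""

    spec: MicrogridSpec
    squares: list[SquareCut]
    metadata: TemplateMetadata = field(default_factory=TemplateMetadata)

    def validate(self) -> None:
        n = self.spec.n_rows * self.spec.n_cols
        if len(self.squares) != n:
            raise ValueError(f"expected {n} shapes, got {len(self.squares)}")
        wells = [sq.well for sq in self.squares]
        seen: set = set()
        for w in wells:
            if w is None:
                raise ValueError("square without a collection well")
            w = normalize_well(w)
            if w in seen:
                raise ValueError(f"duplicate well assignment: {w}")
            seen.add(w)


def documents_equal(
    a: TemplateDocument, b: TemplateDocument, tol: float = 1e-6
) -> bool:
    """Structural equality: same spec, wells exact, coordinates within tol um."""
    sa_, sb_ = a.spec, b.spec
    if (sa_.n_rows, sa_.n_cols, sa_.magnification, sa_.ordering) != (
        sb_.n_rows,
        sb_.n_cols,
        sb_.magnification,
        sb_.ordering,
    ):
        return False
    for attr in (
        "square_side",
        "bridge_fraction",
        "beam_width_tissue",
        "beam_width_membrane",
    ):
        if abs(getattr(sa_, attr) - getattr(sb_, attr)) > tol:
            return False
    if len(a.squares) != len(b.squares):
        return False
    for sa, sb in zip(a.squares, b.squares):
        if (sa.row, sa.col, sa.well) != (sb.row, sb.col, sb.well):
            return False
        if not np.allclose(sa.polygon, sb.polygon, atol=tol, rtol=0):
            return False
    return True


def _sorted_squares(doc: TemplateDocument) -> list[SquareCut]:
    return sorted(doc.squares, key=lambda s: (s.row, s.col))


# ---------------------------------------------------------------------------
# XML dialect


def _to_xml(doc: TemplateDocument) -> bytes:
    spec = doc.spec
    root = etree.Element(
        "microgrid_template",
        name=doc.metadata.name,
        created=doc.metadata.created,
        square_side=_FMT.format(spec.square_side),
        bridge_fraction=_FMT.format(spec.bridge_fraction),
        n_rows=str(spec.n_rows),
        n_cols=str(spec.n_cols),
        magnification=spec.magnification.value,
        beam_width_tissue=_FMT.format(spec.beam_width_tissue),
        beam_width_membrane=_FMT.format(spec.beam_width_membrane),
        ordering=spec.ordering.value,
        units="um",
    )
    for i, (x, y) in enumerate(doc.metadata.calibration_points, start=1):
        etree.SubElement(
            root,
            "calibration_point",
            id=str(i),
            x=_FMT.format(x),
            y=_FMT.format(y),
        )
    for sq in _sorted_squares(doc):
        shape = etree.SubElement(
            root, "shape", row=str(sq.row), col=str(sq.col), well=sq.well or ""
        )
        for x, y in sq.polygon:
            etree.SubElement(shape, "vertex", x=_FMT.format(x), y=_FMT.format(y))
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _from_xml(data: bytes, source: str) -> TemplateDocument:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{source}: malformed XML: {exc}") from exc
    if root.tag != "microgrid_template":
        raise ValueError(f"{source}: unexpected root element <{root.tag}>")
    try:
        spec = MicrogridSpec(
            square_side=float(root.get("square_side")),
            bridge_fraction=float(root.get("bridge_fraction")),
            n_rows=int(root.get("n_rows")),
            n_cols=int(root.get("n_cols")),
            magnification=Magnification(root.get("magnification")),
            beam_width_tissue=float(root.get("beam_width_tissue")),
            beam_width_membrane=float(root.get("beam_width_membrane")),
            ordering=Ordering(root.get("ordering", "row_major")),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: invalid template attributes: {exc}") from exc
    points = tuple(
        (float(el.get("x")), float(el.get("y")))
        for el in root.findall("calibration_point")
    )
    squares = []
    for el in root.findall("shape"):
        verts = [(float(v.get("x")), float(v.get("y"))) for v in el.findall("vertex")]
        if len(verts) != 4:
            raise ValueError(
                f"{source}: shape at line {el.sourceline} has {len(verts)} vertices"
            )
        squares.append(
            SquareCut(
                row=int(el.get("row")),
                col=int(el.get("col")),
                polygon=np.array(verts, dtype=float),
                well=normalize_well(el.get("well")),
            )
        )
    meta = TemplateMetadata(
        name=root.get("name", ""),
        created=root.get("created", ""),
        calibration_points=points,
    )
    return TemplateDocument(spec=spec, squares=squares, metadata=meta)


# ---------------------------------------------------------------------------
# CSV dialect


def _to_csv(doc: TemplateDocument) -> str:
    spec = doc.spec
    lines = [
        f"# name={doc.metadata.name}",
        f"# created={doc.metadata.created}",
        f"# square_side={_FMT.format(spec.square_side)}",
        f"# bridge_fraction={_FMT.format(spec.bridge_fraction)}",
        f"# n_rows={spec.n_rows}",
        f"# n_cols={spec.n_cols}",
        f"# magnification={spec.magnification.value}",
        f"# beam_width_tissue={_FMT.format(spec.beam_width_tissue)}",
        f"# beam_width_membrane={_FMT.format(spec.beam_width_membrane)}",
        f"# ordering={spec.ordering.value}",
    ]
    for i, (x, y) in enumerate(doc.metadata.calibration_points, start=1):
        lines.append(f"# calibration_point_{i}={_FMT.format(x)},{_FMT.format(y)}")
    lines.append(",".join(CSV_COLUMNS))
    for sq in _sorted_squares(doc):
        coords = ",".join(_FMT.format(v) for v in sq.polygon.ravel())
        lines.append(f"{sq.row},{sq.col},{sq.well},{coords}")
    return "\n".join(lines) + "\n"


def _from_csv(text: str, source: str) -> TemplateDocument:
    meta_kv: dict[str, str] = {}
    rows = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta_kv[key.strip()] = value.strip()
            continue
        if not header_seen:
            if [c.strip() for c in line.split(",")] != CSV_COLUMNS:
                raise ValueError(
                    f"{source}:{lineno}: expected header {','.join(CSV_COLUMNS)}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != len(CSV_COLUMNS):
            raise ValueError(
                f"{source}:{lineno}: expected {len(CSV_COLUMNS)} fields, "
                f"got {len(parts)}"
            )
        try:
            coords = np.array([float(p) for p in parts[3:]], dtype=float)
            rows.append(
                SquareCut(
                    row=int(parts[0]),
                    col=int(parts[1]),
                    polygon=coords.reshape(4, 2),
                    well=normalize_well(parts[2]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: {exc}") from exc
    if not header_seen:
        raise ValueError(f"{source}: missing CSV header")
    required = ["square_side", "bridge_fraction", "n_rows", "n_cols", "magnification"]
    missing = [k for k in required if k not in meta_kv]
    if missing:
        raise ValueError(f"{source}: missing template metadata: {missing}")
    spec = MicrogridSpec(
        square_side=float(meta_kv["square_side"]),
        bridge_fraction=float(meta_kv["bridge_fraction"]),
        n_rows=int(meta_kv["n_rows"]),
        n_cols=int(meta_kv["n_cols"]),
        magnification=Magnification(meta_kv["magnification"]),
        beam_width_tissue=float(meta_kv.get("beam_width_tissue") or "nan"),
        beam_width_membrane=float(meta_kv.get("beam_width_membrane") or "nan"),
        ordering=Ordering(meta_kv.get("ordering", "row_major")),
    )
    points = []
    for i in (1, 2):
        raw = meta_kv.get(f"calibration_point_{i}")
        if raw:
            x, y = raw.split(",")
            points.append((float(x), float(y)))
    meta = TemplateMetadata(
        name=meta_kv.get("name", ""),
        created=meta_kv.get("created", ""),
        calibration_points=tuple(points),
    )
    return TemplateDocument(spec=spec, squares=rows, metadata=meta)


# ---------------------------------------------------------------------------
# public API


def write_template(
    doc: TemplateDocument, destination: Union[str, Path], dialect: str = "xml"
) -> None:
    """Serialize ``doc`` to ``destination`` in the given dialect.

    ``dialect="xml"`` writes the shape-list XML; ``"csv"`` the flat
    one-row-per-square table. A ``.txt`` destination with the XML dialect
    produces the importable plain-text form (identical content).
    """
    doc.validate()
    destination = Path(destination)
    try:
        if dialect == "xml":
            destination.write_bytes(_to_xml(doc))
        elif dialect == "csv":
            destination.write_text(_to_csv(doc))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except OSError as exc:
        raise OSError(f"cannot write template to {destination}: {exc}") from exc


def read_template(source: Union[str, Path]) -> TemplateDocument:
    """Parse a template file, auto-detecting the dialect, and validate it.

    Validation enforces the full shape count (n_rows x n_cols, 96 for the
    standard templates) and unique well assignments.
    """
    source = Path(source)
    data = source.read_bytes()
    stripped = data.lstrip()
    if stripped.startswith(b"<"):
        doc = _from_xml(data, str(source))
    else:
        doc = _from_csv(data.decode("utf-8"), str(source))
    doc.validate()
    return doc
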