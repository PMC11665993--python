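"""Geometry of the 96-square microgrid: lattice, placement, kerf areas."""

import math

import numpy as np
import pytest
import shapely.geometry
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from lmdgrid import (
    PRESETS,
    Magnification,
    MicrogridSpec,
    Placement,
    build_microgrid,
    effective_cut_area,
    place_template,
)

from conftest import TEMPLATE_TABLE


def lattice_bounds(squares):
    pts = np.concatenate([s.polygon for s in squares])
    return pts.min(axis=0), pts.max(axis=0)


class TestBuildMicrogrid:
    def test_extent_and_pitch(self, grid_500, spec_500):
        """12*500 + 11*60 wide, 8*500 + 7*60 tall, pitch 560 um."""
        assert spec_500.pitch == 560.0
        lo, hi = lattice_bounds(grid_500)
        assert lo == pytest.approx((0.0, 0.0), abs=1e-12)
        assert hi == pytest.approx((6660.0, 4420.0), abs=1e-9)
        c00 = grid_500[0].center
        c01 = grid_500[1].center
        assert c01 - c00 == pytest.approx((560.0, 0.0), abs=1e-9)

    def test_zero_bridge_edge_adjacent(self):
        grid = build_microgrid(MicrogridSpec(square_side=500.0, bridge_fraction=0.0))
        gap = grid[1].polygon[:, 0].min() - grid[0].polygon[:, 0].max()
        assert gap == pytest.approx(0.0, abs=1e-12)

    def test_270_preset_gap_matches_published_relative_bridge(self):
        """15% of 270 um -> 40.5 um edge-to-edge gap."""
        grid = build_microgrid(PRESETS["270x270"].spec())
        gap = grid[1].polygon[:, 0].min() - grid[0].polygon[:, 0].max()
        assert gap == pytest.approx(40.5, abs=1e-9)

    @pytest.mark.parametrize("name,side,area,bridge_pct,_l,_e", TEMPLATE_TABLE)
    def test_preset_grids(self, name, side, area, bridge_pct, _l, _e):
        """Each published template yields exactly 96 squares with its
        stated side and edge-to-edge gap."""
        preset = PRESETS[name]
        assert preset.square_side == side
        assert preset.measured_area == area
        assert round(100 * preset.bridge_fraction) == bridge_pct
        grid = build_microgrid(preset.spec())
        assert len(grid) == 96
        assert {(s.row, s.col) for s in grid} == {
            (r, c) for r in range(1, 9) for c in range(1, 13)
        }
        for sq in grid:
            assert sq.side == pytest.approx(side, abs=1e-9)
        gap = grid[1].polygon[:, 0].min() - grid[0].polygon[:, 0].max()
        assert gap == pytest.approx(preset.bridge_fraction * side, abs=1e-6)

    def test_corner_reconstructs_center(self, grid_500):
        for sq in grid_500[:3]:
            mid = (sq.polygon[0] + sq.polygon[2]) / 2
            assert np.allclose(mid, sq.center, atol=1e-6)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(square_side=-1), "square_side"),
            (dict(square_side=100, bridge_fraction=1.0), "bridge_fraction"),
            (dict(square_side=100, n_rows=7), "n_rows"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises((ValidationError, ValueError)) as exc:
            MicrogridSpec(**kwargs)
        assert field in str(exc.value)

    @given(
        side=st.floats(30, 500),
        fraction=st.floats(0, 0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_lattice_property(self, side, fraction):
        """Neighbouring centres differ by exactly the pitch on one axis."""
        spec = MicrogridSpec(square_side=side, bridge_fraction=fraction)
        grid = build_microgrid(spec)
        centers = {(s.row, s.col): s.center for s in grid}
        pitch = spec.pitch
        for (r, c), ctr in centers.items():
            if (r, c + 1) in centers:
                np.testing.assert_allclose(
                    centers[(r, c + 1)] - ctr, (pitch, 0.0), atol=1e-9 * side
                )
            if (r + 1, c) in centers:
                np.testing.assert_allclose(
                    centers[(r + 1, c)] - ctr, (0.0, pitch), atol=1e-9 * side
                )
        # non-overlap: nearest-neighbour edge gap equals the bridge width
        gap_x = grid[1].polygon[:, 0].min() - grid[0].polygon[:, 0].max()
        assert gap_x == pytest.approx(spec.bridge_width, abs=1e-6)


class TestPlacement:
    def test_identity_placement(self, grid_500):
        placed = place_template(
            grid_500, Placement((0.0, 0.0), (6660.0, 0.0))
        )
        for a, b in zip(grid_500, placed):
            np.testing.assert_allclose(a.polygon, b.polygon, atol=1e-9)
            assert a.well == b.well

    def test_rotation_preserves_areas(self, grid_500):
        """ref2 rotated 90 degrees about ref1: areas unchanged."""
        placed = place_template(grid_500, Placement((0.0, 0.0), (0.0, 6660.0)))
        for a, b in zip(grid_500, placed):
            assert b.area == pytest.approx(a.area, rel=1e-6)
        # square (1,1) top-left stays at ref1
        np.testing.assert_allclose(placed[0].polygon[0], (0.0, 0.0), atol=1e-9)

    def test_scaling_doubles_sides(self, grid_500):
        placed = place_template(grid_500, Placement((0.0, 0.0), (2 * 6660.0, 0.0)))
        for a, b in zip(grid_500, placed):
            assert b.side == pytest.approx(2 * a.side, rel=1e-12)

    def test_rotation_only_mode_keeps_size(self, grid_500):
        placed = place_template(
            grid_500,
            Placement((100.0, 50.0), (100.0 + 13320.0, 50.0), mode="rotation_only"),
        )
        for a, b in zip(grid_500, placed):
            assert b.side == pytest.approx(a.side, rel=1e-12)

    def test_coincident_reference_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Placement((1.0, 2.0), (1.0, 2.0))

    @given(
        ref1=st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)),
        angle=st.floats(0, 2 * math.pi),
        dist=st.floats(100, 2e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_placement_is_a_similarity(self, ref1, angle, dist):
        """Angles and pairwise distance ratios are preserved."""
        grid_500 = build_microgrid(MicrogridSpec(square_side=500.0))
        ref2 = (ref1[0] + dist * math.cos(angle), ref1[1] + dist * math.sin(angle))
        placed = place_template(grid_500, Placement(ref1, ref2))
        a = grid_500[0].polygon
        b = placed[0].polygon
        # right angle at the first corner is preserved
        va, wa = a[1] - a[0], a[3] - a[0]
        vb, wb = b[1] - b[0], b[3] - b[0]
        cos_b = np.dot(vb, wb) / (np.linalg.norm(vb) * np.linalg.norm(wb))
        assert abs(cos_b) < 1e-9
        # distance ratio between two arbitrary point pairs is preserved
        d_far_a = np.linalg.norm(grid_500[95].center - grid_500[0].center)
        d_far_b = np.linalg.norm(placed[95].center - placed[0].center)
        ratio_a = d_far_a / np.linalg.norm(va)
        ratio_b = d_far_b / np.linalg.norm(vb)
        assert ratio_b == pytest.approx(ratio_a, rel=1e-9)


class TestEffectiveCutArea:
    def test_nominal(self):
        assert effective_cut_area(500, 9.1, "nominal") == 250000.0

    def test_measured_passthrough(self):
        assert effective_cut_area(500, 9.1, "measured", measured_area=246363) == 246363

    def test_kerf_inset_closed_form(self):
        got = effective_cut_area(100, 2.1, "kerf_inset", inset_coefficient=1.0)
        assert got == pytest.approx((100 - 2.1) ** 2)
        assert got == pytest.approx(9584.41)

    def test_measured_requires_area(self):
        with pytest.raises(ValueError, match="measured_area"):
            effective_cut_area(500, 9.1, "measured")

    def test_side_not_above_beam_rejected(self):
        with pytest.raises(ValueError, match="beam width"):
            effective_cut_area(1.0, 2.0, "nominal")

    @pytest.mark.parametrize("side", [30.0, 50.0, 100.0, 270.0, 500.0])
    @pytest.mark.parametrize("coef", [0.5, 1.0])
    def test_kerf_inset_against_polygon_inset_oracle(self, side, coef):
        """Independent oracle: shrink the square polygon inward by the
        per-edge inset with a mitred negative buffer; areas agree <0.5%."""
        beam = 3.6
        square = shapely.geometry.Polygon(
            [(0, 0), (side, 0), (side, side), (0, side)]
        )
        oracle = square.buffer(-coef * beam / 2.0, join_style=2).area
        got = effective_cut_area(side, beam, "kerf_inset", inset_coefficient=coef)
        assert got == pytest.approx(oracle, rel=0.005)


def test_beam_width_presets_ordered():
    """On tissue the kerf is wider than on the bare membrane, and kerf
    shrinks with magnification."""
    from lmdgrid import MEMBRANE_BEAM_WIDTH_UM, TISSUE_BEAM_WIDTH_UM

    for mag in Magnification:
        assert TISSUE_BEAM_WIDTH_UM[mag] >= MEMBRANE_BEAM_WIDTH_UM[mag]
    tissue = [TISSUE_BEAM_WIDTH_UM[m] for m in Magnification]
    assert tissue == sorted(tissue, reverse=True)
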