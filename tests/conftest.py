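"""Shared fixtures and independent geometry oracles.

The oracles here are deliberately primitive (pure-python ray casting,
direct quadratic-form evaluation) so they stay independent of the
library's shapely-backed mask code.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from impactquant.imaging import EllipseShape, ImagePlane, PolygonShape, Roi


def ray_cast_inside(vertices: np.ndarray, x: float, y: float) -> bool:
    """Classic even-odd ray casting, written independently of shapely."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def ellipse_inside(shape: EllipseShape, x: float, y: float) -> bool:
    """Direct quadratic-form membership test."""
    t = math.radians(shape.angle_deg)
    dx, dy = x - shape.cx, y - shape.cy
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / shape.a) ** 2 + (v / shape.b) ** 2 < 1.0


def random_star_polygon(
    rng: np.random.Generator,
    cx: float,
    cy: float,
    r_min: float,
    r_max: float,
    n_vertices: int = 8,
) -> PolygonShape:
    """Random star-shaped (hence simple) polygon around (cx, cy)."""
    while True:
        angles = np.sort(rng.uniform(0, 2 * math.pi, n_vertices))
        radii = rng.uniform(r_min, r_max, n_vertices)
        verts = np.column_stack(
            [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
        )
        try:
            return PolygonShape(verts)
        except ValueError:  # near-coincident angles: redraw
            continue


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def constant_plane():
    """Factory for uniform planes with controllable metadata."""

    def make(
        value: int = 50,
        shape: tuple[int, int] = (32, 32),
        bit_depth: int = 16,
        exposure_s: float = 1.0,
        pixel_size_um: float = 1.0,
        humidity_state: str = "humid",
    ) -> ImagePlane:
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        return ImagePlane(
            np.full(shape, value, dtype=dtype),
            bit_depth=bit_depth,
            channel="blue",
            exposure_s=exposure_s,
            pixel_size_um=pixel_size_um,
            humidity_state=humidity_state,
        )

    return make


@pytest.fixture
def square_roi():
    """Factory for axis-aligned square signal/background ROIs."""

    def make(x0, y0, side, label="roi", role="signal") -> Roi:
        verts = np.array(
            [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
            dtype=float,
        )
        return Roi(label=label, role=role, shape=PolygonShape(verts))

    return make
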