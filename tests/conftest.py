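import numpy as np
import pytest

from nemaquant import Roi, RoiSet


@pytest.fixture
def rect_roi():
    return Roi("intestine", "intestine", "rectangle", [(20, 10), (60, 30)])


@pytest.fixture
def triangle_roi():
    return Roi("tri", "other", "polygon", [(0, 0), (4, 0), (0, 4)])


def brute_force_point_in_polygon(x, y, vertices):
    """Scalar even-odd (ray crossing) test, written independently of the
    vectorized implementation under test."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (x2 - x1) * (y - y1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_force_mask(roi, width, height):
    """Enumerate every pixel center with scalar point-in-shape tests."""
    out = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            if roi.shape_kind == "rectangle":
                (x1, y1), (x2, y2) = roi.vertices
                out[y, x] = x1 <= x < x2 and y1 <= y < y2
            elif roi.shape_kind == "oval":
                (x1, y1), (x2, y2) = roi.vertices
                a, b = (x2 - x1) / 2, (y2 - y1) / 2
                cx, cy = x1 + a - 0.5, y1 + b - 0.5
                out[y, x] = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1
            else:
                out[y, x] = brute_force_point_in_polygon(x, y, roi.vertices)
    return out
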