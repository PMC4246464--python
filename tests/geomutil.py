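"""Small geometry helpers shared by the tests (independent of the package)."""

import numpy as np


def circle_points(radius, cx=0.0, cy=0.0, n=64, phase=0.0):
    th = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)])


def point_in_polygon(x, y, pts):
    """Even-odd ray casting; independent oracle for rasterization tests."""
    inside = False
    n = len(pts)
    j = n - 1
    for i in range(n):
        xi, yi = pts[i]
        xj, yj = pts[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def shoelace_centroid(pts):
    x = pts[:, 0]
    y = pts[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    return cx, cy
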