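"""Small planar-geometry helpers shared across the pipeline.

Image coordinates throughout: x = column, y = row, origin top-left, y
increases downward.  "Distal" (toward the hand) is up, i.e. smaller y.
"""

from __future__ import annotations

import numpy as np


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed area of a closed polygon given as an (n, 2) array of (x, y).

    Positive for counter-clockwise rings in a y-down frame... sign is
    convention-dependent; callers who only care about magnitude should
    take ``abs``.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (shoelace-based)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return v.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def point_chord_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular-ish distance from ``points`` to segment a-b.

    Distance to the segment (clamped to endpoints) so that deviation
    bounds hold even for points beyond the chord ends.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def rotate_points(points: np.ndarray, angle_deg: float, center=(0.0, 0.0)) -> np.ndarray:
    """Rotate (n, 2) points by ``angle_deg`` about ``center``.

    Positive angles add to the direction angle theta = atan2(dy, dx);
    on screen (y down) this appears clockwise.
    """
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    p = np.asarray(points, dtype=float)
    ctr = np.asarray(center, dtype=float)
    return (p - ctr) @ rot.T + ctr


def wrap_half_turn(angle_deg: float) -> float:
    """Wrap an angle to the half-open interval (-90, 90]."""
    a = float(angle_deg) % 180.0
    if a > 90.0:
        a -= 180.0
    return a


def direction_angle_deg(dx: float, dy: float) -> float:
    """Direction angle of a line, in [0, 180): atan2(dy, dx) mod 180."""
    return float(np.degrees(np.arctan2(dy, dx))) % 180.0


def arc_midpoint(chain: np.ndarray) -> np.ndarray:
    """Arc-length midpoint of an open polyline given as an (n, 2) array."""
    chain = np.asarray(chain, dtype=float)
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        return chain[0].copy()
    target = total / 2.0
    acc = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(np.searchsorted(acc, target) - 1)
    k = max(0, min(k, len(seg) - 1))
    frac = (target - acc[k]) / max(seg[k], 1e-12)
    return chain[k] + frac * (chain[k + 1] - chain[k])
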