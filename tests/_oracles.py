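"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimization/tracing code paths:
the axis oracle is an exhaustive grid search, areas come from shapely,
hole counts from scipy binary morphology.
"""

from __future__ import annotations

import numpy as np


def grid_axis_oracle(points: np.ndarray, frame: str,
                     angle_step_deg: float = 0.1,
                     offset_step: float = 0.5) -> tuple[float, float, float]:
    """Exhaustive (angle, offset) grid minimization of the smoothed loss.

    Returns (min_loss, m, b) in the given fitting frame.  The grid spans
    line angles in (-90, 90) degrees relative to the frame abscissa in
    ``angle_step_deg`` increments and intercept offsets covering the
    residual range in ``offset_step`` increments.
    """
    pts = np.asarray(points, dtype=float)
    if frame == "swapped":
        u, v = pts[:, 1], pts[:, 0]
    else:
        u, v = pts[:, 0], pts[:, 1]
    best = (np.inf, 0.0, 0.0)
    angles = np.arange(-90.0 + angle_step_deg, 90.0, angle_step_deg)
    for ang in angles:
        m = np.tan(np.deg2rad(ang))
        r0 = v - m * u
        bs = np.arange(r0.min(), r0.max() + offset_step, offset_step)
        resid = r0[:, None] - bs[None, :]
        loss = 2.0 * (np.sqrt(1.0 + resid * resid / 2.0) - 1.0)
        totals = loss.sum(axis=0)
        k = int(np.argmin(totals))
        if totals[k] < best[0]:
            best = (float(totals[k]), float(m), float(bs[k]))
    return best


def shapely_ring_area(vertices: np.ndarray) -> float:
    import shapely

    return float(shapely.Polygon(np.asarray(vertices)).area)


def count_holes(binary: np.ndarray) -> int:
    """Number of enclosed background holes, via scipy labelling."""
    from scipy import ndimage

    bg = ~np.asarray(binary).astype(bool)
    padded = np.pad(bg, 1, constant_values=True)
    labeled, n = ndimage.label(padded)
    outside_label = labeled[0, 0]
    return n - 1 if outside_label else n
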