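"""Binary-mask to clean closed contour: binarize, fill holes, denoise,
Sobel edges, trace the largest outer boundary, simplify.

Contour vertices are pixel centers (x = column, y = row); polygons are
closed rings with area measured by the shoelace formula.  Contours are
traced on the filled, thresholded mask — the Sobel edge map is kept for
validation and overlays, where tracing thin ridges would be fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.segmentation import flood

from ._geometry import point_chord_distance, polygon_centroid, shoelace_area

#: Horizontal/vertical Sobel kernels (x to the right, y down).
SOBEL_GX = np.array([[-1, 0, 1],
                     [-2, 0, 2],
                     [-1, 0, 1]], dtype=float)
SOBEL_GY = np.array([[-1, -2, -1],
                     [0, 0, 0],
                     [1, 2, 1]], dtype=float)


@dataclass
class ContourConfig:
    gaussian_sigma: float = 1.0
    kernel_size: int = 3  # fixed 3x3 kernel
    min_area_px: float = 50.0
    simplify_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.kernel_size != 3:
            raise ValueError("kernel_size is fixed at 3")
        if self.simplify_tolerance <= 0:
            raise ValueError("simplify_tolerance must be > 0")


@dataclass
class Contour:
    """Ordered closed polyline of pixel coordinates bounding one part.

    ``vertices`` is an (n, 2) float array of (x, y); the ring closes
    implicitly from the last vertex back to the first.  ``source_vertices``
    keeps the pre-simplification ring (with ``source_indices`` mapping
    current vertices into it) so repeated simplification at the same
    tolerance is a no-op, and ``chain`` stores the per-edge
    (direction_deg, length) deltas recorded during simplification.
    """

    vertices: np.ndarray
    part: str = ""
    simplified: bool = False
    source_vertices: np.ndarray | None = None
    source_indices: np.ndarray | None = None
    source_area: float | None = None
    chain: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        if abs(shoelace_area(self.vertices)) <= 0:
            raise ValueError("contour encloses zero area")
        if self.source_vertices is None:
            self.source_vertices = self.vertices.copy()
            self.source_indices = np.arange(len(self.vertices))
            self.source_area = self.area

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.vertices))

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.vertices)

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the ring."""
        v = self.vertices
        return (float(v[:, 0].min()), float(v[:, 1].min()),
                float(v[:, 0].max()), float(v[:, 1].max()))

    def to_ring_list(self) -> list[list[float]]:
        return [[float(x), float(y)] for x, y in self.vertices]


def binarize_part(mask, part: str) -> np.ndarray:
    """Indicator image of one labelled part; errors if the part is empty."""
    binary = mask.part_pixels(part).astype(np.uint8)
    if not binary.any():
        raise ValueError(f"empty part {part!r} in {mask.view.value} mask")
    return binary


def fill_holes(binary: np.ndarray) -> np.ndarray:
    """Close enclosed holes by flood-filling the background and inverting.

    A one-pixel background ring is padded on first so the fill seed at
    the coordinate origin is guaranteed background; the inverted fill is
    OR-ed with the input, so foreground never shrinks.  Idempotent.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        return binary.astype(np.uint8)
    padded = np.pad(binary, 1, mode="constant", constant_values=False)
    outside = flood(padded.astype(np.uint8), (0, 0), connectivity=1)
    filled = ~outside
    return (filled[1:-1, 1:-1] | binary).astype(np.uint8)


def gaussian_kernel_3x3(sigma: float) -> np.ndarray:
    """The 3x3 sampled Gaussian G(x, y), normalized to unit sum."""
    ax = np.array([-1.0, 0.0, 1.0])
    xx, yy = np.meshgrid(ax, ax)
    g = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    return g / g.sum()


def gaussian_denoise(binary: np.ndarray, cfg: ContourConfig | None = None) -> np.ndarray:
    """Convolve with the normalized 3x3 Gaussian; constants map to themselves."""
    cfg = cfg or ContourConfig()
    kernel = gaussian_kernel_3x3(cfg.gaussian_sigma)
    return ndimage.convolve(np.asarray(binary, dtype=float), kernel, mode="nearest")


def threshold_half(smoothed: np.ndarray) -> np.ndarray:
    """Re-binarize the smoothed image at 0.5 before edge detection."""
    return (np.asarray(smoothed, dtype=float) >= 0.5).astype(np.uint8)


def sobel_edges(binary: np.ndarray, cfg: ContourConfig | None = None) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the fixed 3x3 Sobel kernels."""
    img = np.asarray(binary, dtype=float)
    gx = ndimage.convolve(img, SOBEL_GX, mode="nearest")
    gy = ndimage.convolve(img, SOBEL_GY, mode="nearest")
    return np.sqrt(gx ** 2 + gy ** 2)


# Moore neighborhood in clockwise order starting East, as (dy, dx).
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace (Jacob's stopping criterion).

    Returns the ordered outer boundary of a single connected component
    as an (n, 2) array of (x, y) pixel centers.
    """
    padded = np.pad(component.astype(bool), 1)
    ys, xs = np.nonzero(padded)
    start = (int(ys.min()), int(xs[ys == ys.min()].min()))
    # Entered the start pixel moving East (from its West neighbor).
    boundary = [start]
    cur = start
    entry_dir = 0  # index into _MOORE of the direction we moved to reach cur
    first_move: tuple[tuple[int, int], int] | None = None
    max_steps = 4 * padded.size
    for _ in range(max_steps):
        # Scan clockwise starting just after the backtrack direction.
        back = (entry_dir + 4) % 8  # direction pointing back where we came from
        found = None
        for k in range(1, 9):
            d = (back + k) % 8
            dy, dx = _MOORE[d]
            ny, nx = cur[0] + dy, cur[1] + dx
            if padded[ny, nx]:
                found = ((ny, nx), d)
                break
        if found is None:  # isolated pixel
            break
        nxt, d = found
        if first_move is None:
            first_move = (nxt, d)
        elif cur == start and (nxt, d) == first_move:
            break  # re-entered start the same way: loop closed
        cur = nxt
        entry_dir = d
        if cur != start:
            boundary.append(cur)
    # Unpad and convert (row, col) -> (x, y).
    pts = np.array(boundary, dtype=float) - 1.0
    return pts[:, ::-1].copy()


def extract_largest_contour(image: np.ndarray, cfg: ContourConfig | None = None,
                            part: str = "") -> Contour:
    """Trace all outer contours and keep the one with the largest area.

    Accepts a binary image (or any image, thresholded at > 0).  Ties are
    broken by topmost-then-leftmost first vertex.  Raises if no contour
    reaches ``min_area_px``.
    """
    cfg = cfg or ContourConfig()
    binary = np.asarray(image) > 0
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    candidates = []
    for i in range(1, n + 1):
        comp = labeled == i
        if comp.sum() < max(cfg.min_area_px, 3):
            continue  # cannot reach the area floor; skip the trace
        ring = _trace_boundary(comp)
        if len(ring) < 3:
            continue
        area = abs(shoelace_area(ring))
        if area < cfg.min_area_px:
            continue
        candidates.append((area, float(ring[0, 1]), float(ring[0, 0]), ring))
    if not candidates:
        raise ValueError("no valid contour")
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    return Contour(vertices=candidates[0][3], part=part)


def _edge_chain(vertices: np.ndarray) -> list[tuple[float, float]]:
    diffs = np.roll(vertices, -1, axis=0) - vertices
    angles = np.degrees(np.arctan2(diffs[:, 1], diffs[:, 0]))
    lengths = np.linalg.norm(diffs, axis=1)
    return [(float(a), float(l)) for a, l in zip(angles, lengths)]


def simplify_contour(c: Contour, cfg: ContourConfig | None = None) -> Contour:
    """Triangle-elimination simplification with a hard deviation bound.

    Repeatedly deletes the vertex forming the shallowest triangle with
    its ring neighbours, but only while every original vertex absorbed
    into the resulting chord stays within ``simplify_tolerance`` px of it
    and the enclosed area stays within 2% of the original.  Because the
    bound is evaluated against the stored source ring, re-running at the
    same tolerance removes nothing further (idempotent).
    """
    cfg = cfg or ContourConfig()
    tol = cfg.simplify_tolerance
    src = c.source_vertices
    src_idx = list(c.source_indices)
    n_src = len(src)
    keep = list(src_idx)  # indices into src of surviving vertices

    def chord_cost(pos: int) -> float:
        """Max deviation of all source vertices spanned by removing keep[pos]."""
        a = src[keep[(pos - 1) % len(keep)]]
        b = src[keep[(pos + 1) % len(keep)]]
        lo = keep[(pos - 1) % len(keep)]
        hi = keep[(pos + 1) % len(keep)]
        if hi > lo:
            span = np.arange(lo + 1, hi)
        else:  # wraps around the ring
            span = np.concatenate([np.arange(lo + 1, n_src), np.arange(0, hi)])
        if len(span) == 0:
            return np.inf
        return float(point_chord_distance(src[span], a, b).max())

    area0 = c.source_area if c.source_area is not None else c.area
    costs = [chord_cost(i) for i in range(len(keep))]
    while len(keep) > 3:
        pos = int(np.argmin(costs))
        if costs[pos] > tol:
            break
        trial = keep[:pos] + keep[pos + 1:]
        new_area = abs(shoelace_area(src[trial]))
        if abs(new_area - area0) > 0.02 * area0:
            costs[pos] = np.inf  # would violate the area budget; freeze it
            continue
        keep = trial
        del costs[pos]
        m = len(keep)
        for p in ((pos - 1) % m, pos % m):
            costs[p] = chord_cost(p)

    verts = src[keep]
    if abs(shoelace_area(verts)) <= 0:
        raise ValueError("contour degenerated to zero area during simplification")
    return Contour(
        vertices=verts,
        part=c.part,
        simplified=True,
        source_vertices=src,
        source_indices=np.asarray(keep),
        source_area=area0,
        chain=_edge_chain(verts),
    )


def extract_part_contour(mask, part: str, cfg: ContourConfig | None = None,
                         simplify: bool = True) -> Contour:
    """Full per-part pipeline: binarize, fill, denoise+threshold, trace, simplify."""
    cfg = cfg or ContourConfig()
    binary = binarize_part(mask, part)
    filled = fill_holes(binary)
    smoothed = threshold_half(gaussian_denoise(filled, cfg))
    contour = extract_largest_contour(smoothed, cfg, part=part)
    if simplify:
        contour = simplify_contour(contour, cfg)
    return contour
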