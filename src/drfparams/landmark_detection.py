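"""Anatomical landmark detection by rotating-line search.

All detectors assume canonical orientation (distal up, right wrist):
in AP the radius sits at larger x than the ulna, so the radial styloid
side is +x and the ulnar side is -x; in LAT the volar side is +x.

The rotating line is a full line anchored at a contour extreme point,
starting horizontal (slope 0) and rotated in small angular increments;
the landmark is the first intersection with the contour whose distance
from the anchor exceeds a fraction of the part's width ("significantly
distant").  Sweeps are capped to guarantee termination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import arc_midpoint, polygon_centroid
from .axis_fitting import AxisLine
from .contour_extraction import Contour


@dataclass
class RotatingLineConfig:
    step_deg: float = 0.01
    min_dist_frac: float = 0.25
    max_sweep_deg: float = 180.0
    coarse_step_deg: float = 0.5  # bracket pass before refining at step_deg

    def __post_init__(self) -> None:
        if not (0 < self.step_deg <= 1):
            raise ValueError("step_deg must be in (0, 1]")
        if not (0 < self.min_dist_frac < 1):
            raise ValueError("min_dist_frac must be in (0, 1)")


@dataclass
class LandmarkSet:
    """Named landmark points; AP and LAT entries never mix views.

    AP: ST (styloid tip) and UBR (ulnar border of radius) on the distal
    radius, UH (ulnar head surface midpoint) and ul_UBR on the ulna.
    LAT: DJ (articular rim apex) and VJB (opposite rim) on the distal
    radius, plus the volar/dorsal displacement call.
    """

    ST: tuple[float, float] | None = None
    UBR: tuple[float, float] | None = None
    UH: tuple[float, float] | None = None
    ul_UBR: tuple[float, float] | None = None
    DJ: tuple[float, float] | None = None
    VJB: tuple[float, float] | None = None
    displacement: str | None = None  # "volar" | "dorsal"

    def to_dict(self) -> dict:
        out = {}
        for name in ("ST", "UBR", "UH", "ul_UBR", "DJ", "VJB"):
            p = getattr(self, name)
            out[name] = None if p is None else [float(p[0]), float(p[1])]
        out["displacement"] = self.displacement
        return out


def _line_contour_hits(vertices: np.ndarray, center: np.ndarray,
                       direction: np.ndarray) -> np.ndarray:
    """Intersections of the infinite line (center, direction) with the ring edges."""
    p = vertices
    q = np.roll(vertices, -1, axis=0)
    normal = np.array([-direction[1], direction[0]])
    sp = (p - center) @ normal
    sq = (q - center) @ normal
    crossing = (sp * sq) <= 0
    crossing &= ~((np.abs(sp) < 1e-12) & (np.abs(sq) < 1e-12))  # skip collinear edges
    if not crossing.any():
        return np.empty((0, 2))
    denom = sp[crossing] - sq[crossing]
    denom = np.where(np.abs(denom) < 1e-15, 1e-15, denom)
    t = sp[crossing] / denom
    return p[crossing] + t[:, None] * (q[crossing] - p[crossing])


def rotating_line_first_hit(contour: Contour, center, sweep_toward: int,
                            min_dist: float,
                            cfg: RotatingLineConfig | None = None) -> np.ndarray | None:
    """Sweep a line about ``center`` from horizontal; return the first distant hit.

    ``sweep_toward`` selects which half of the line rotates downward:
    +1 dips the +x end (a clockwise turn on screen), -1 dips the -x end.
    At each angle, contour intersections at distance >= ``min_dist`` from
    the center qualify; the qualifying hit nearest the center at the
    first qualifying angle is returned, or None if the sweep cap is
    reached.  A coarse pass brackets the first qualifying angle, then
    the bracket is rescanned at ``step_deg``; the hit set only grows
    with the sweep angle for the convex-ish rims this targets, so the
    bracketing is exact.
    """
    cfg = cfg or RotatingLineConfig()
    ctr = np.asarray(center, dtype=float)
    verts = contour.vertices
    sign = 1.0 if sweep_toward >= 0 else -1.0

    def probe(angle_deg: float) -> np.ndarray | None:
        t = np.deg2rad(angle_deg)
        d = np.array([np.cos(t), sign * np.sin(t)])
        hits = _line_contour_hits(verts, ctr, d)
        if len(hits) == 0:
            return None
        dist = np.linalg.norm(hits - ctr, axis=1)
        ok = dist >= min_dist
        if not ok.any():
            return None
        return hits[ok][np.argmin(dist[ok])]

    coarse = np.arange(0.0, cfg.max_sweep_deg + 1e-9, cfg.coarse_step_deg)
    bracket_hi = None
    for a in coarse:
        if probe(a) is not None:
            bracket_hi = a
            break
    if bracket_hi is None:
        return None
    lo = max(bracket_hi - cfg.coarse_step_deg, 0.0)
    for a in np.arange(lo, bracket_hi + cfg.step_deg / 2, cfg.step_deg):
        hit = probe(a)
        if hit is not None:
            return hit
    return probe(bracket_hi)


def _topmost(contour: Contour, tie_max_x: bool) -> np.ndarray:
    """Topmost point of a contour, scanned on the raw (pre-simplification)
    ring so corner vertices dropped by simplification still count."""
    vertices = contour.source_vertices if contour.source_vertices is not None \
        else contour.vertices
    ymin = vertices[:, 1].min()
    ties = vertices[np.abs(vertices[:, 1] - ymin) < 1e-9]
    idx = np.argmax(ties[:, 0]) if tie_max_x else np.argmin(ties[:, 0])
    return ties[idx].copy()


def contour_width(contour: Contour) -> float:
    xmin, _, xmax, _ = contour.bbox()
    return xmax - xmin


def detect_ST(radius_contour: Contour) -> np.ndarray:
    """Styloid tip: topmost contour vertex, ties toward the radial side (+x)."""
    return _topmost(radius_contour, tie_max_x=True)


def detect_UBR(radius_contour: Contour, ST, ref_axis: AxisLine | None = None,
               cfg: RotatingLineConfig | None = None) -> np.ndarray:
    """Ulnar border of the radius via the rotating line anchored at ST.

    The sweep dips the ulnar (-x) end of the line so the first distant
    intersection lands on the ulnar corner of the articular surface.
    """
    cfg = cfg or RotatingLineConfig()
    min_dist = cfg.min_dist_frac * contour_width(radius_contour)
    hit = rotating_line_first_hit(radius_contour, ST, sweep_toward=-1,
                                  min_dist=min_dist, cfg=cfg)
    if hit is None:
        raise ValueError("UBR not found")
    return hit


def _axis_contour_intersections(contour: Contour, axis: AxisLine) -> np.ndarray:
    return _line_contour_hits(contour.vertices, axis.anchor(), axis.direction_distal())


def _point_polyline_distance(p: np.ndarray, chain: np.ndarray) -> float:
    """Distance from a point to an open polyline (segments, not just vertices)."""
    a = chain[:-1]
    b = chain[1:]
    ab = b - a
    ln = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / ln, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - p, axis=1).min())


def _arc_between(contour: Contour, p_start: np.ndarray, p_end: np.ndarray,
                 must_contain: np.ndarray) -> np.ndarray:
    """Vertex chain along the ring from p_start to p_end passing near a point.

    Both endpoints are snapped onto their nearest edges; of the two arcs
    joining them, the one whose polyline passes closest to
    ``must_contain`` is returned (endpoints included).
    """
    verts = contour.vertices
    n = len(verts)

    def edge_of(p: np.ndarray) -> int:
        a = verts
        b = np.roll(verts, -1, axis=0)
        ab = b - a
        ln = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-12)
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / ln, 0.0, 1.0)
        proj = a + t[:, None] * ab
        return int(np.argmin(np.linalg.norm(proj - p, axis=1)))

    i, j = edge_of(p_start), edge_of(p_end)

    def forward_chain(a: int, b: int) -> list[int]:
        """Vertex indices strictly after edge a up to and including edge b's start... i.e.
        the ring vertices traversed going forward from edge a to edge b."""
        if a == b:
            return []
        span = (b - a) % n
        return [(a + k) % n for k in range(1, span + 1)]

    arc_a = np.array([p_start] + [verts[k] for k in forward_chain(i, j)] + [p_end])
    arc_b = np.array([p_end] + [verts[k] for k in forward_chain(j, i)] + [p_start])

    return arc_a if _point_polyline_distance(must_contain, arc_a) <= \
        _point_polyline_distance(must_contain, arc_b) else arc_b


def detect_UH(ulna_contour: Contour, ulna_axis: AxisLine,
              cfg: RotatingLineConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ulnar head surface midpoint and the facing corner ul_UBR.

    From the ulna's topmost vertex, a rotating line dipping toward the
    radius (+x) finds ul_UBR, the radial-facing corner of the flat
    distal surface.  The fitted ulna axis must pierce the surface arc
    between the two (this validates that the arc really is the distal
    joint surface); UH is the arc-length midpoint of that arc.
    """
    cfg = cfg or RotatingLineConfig()
    top = _topmost(ulna_contour, tie_max_x=False)
    min_dist = cfg.min_dist_frac * contour_width(ulna_contour)
    ul_ubr = rotating_line_first_hit(ulna_contour, top, sweep_toward=+1,
                                     min_dist=min_dist, cfg=cfg)
    if ul_ubr is None:
        raise ValueError("ul_UBR not found")
    hits = _axis_contour_intersections(ulna_contour, ulna_axis)
    if len(hits) == 0:
        raise ValueError("ulna axis does not intersect the ulna contour")
    distal_hit = hits[np.argmin(hits[:, 1])]
    arc = _arc_between(ulna_contour, top, ul_ubr, must_contain=distal_hit)
    # The axis must actually pierce this arc, else we grabbed the wrong side.
    if _point_polyline_distance(distal_hit, arc) > 3.0:
        raise ValueError("ulna axis does not intersect the distal surface arc")
    return arc_midpoint(arc), ul_ubr


def detect_DJ(lat_radius_contour: Contour) -> np.ndarray:
    """Articular rim apex in LAT: the topmost contour vertex.

    With volar tilt the apex is the dorsal rim; with dorsal tilt the
    volar rim ends up topmost instead.  Ties are broken away from the
    contour centroid (the rim corners are the outermost points), then
    toward the dorsal (-x) side.
    """
    verts = lat_radius_contour.source_vertices \
        if lat_radius_contour.source_vertices is not None \
        else lat_radius_contour.vertices
    ymin = verts[:, 1].min()
    ties = verts[np.abs(verts[:, 1] - ymin) < 1e-9]
    cx = float(polygon_centroid(lat_radius_contour.vertices)[0])
    spread = np.abs(ties[:, 0] - cx)
    outer = ties[np.abs(spread - spread.max()) < 1e-9]
    return outer[np.argmin(outer[:, 0])].copy()


def classify_displacement(lat_radius_contour: Contour, lat_axis: AxisLine) -> str:
    """Volar/dorsal call from the side of the shaft axis the fragment centroid is on."""
    centroid = polygon_centroid(lat_radius_contour.vertices)
    offset = float((centroid - lat_axis.anchor()) @ lat_axis.perpendicular_radial())
    if abs(offset) <= 0.5:
        warnings.warn("fragment centroid within 0.5 px of the shaft axis; "
                      "displacement call is ambiguous, returning dorsal", RuntimeWarning)
        return "dorsal"
    return "volar" if offset > 0 else "dorsal"


def detect_VJB(lat_radius_contour: Contour, DJ, displacement: str,
               cfg: RotatingLineConfig | None = None) -> np.ndarray:
    """Opposite articular rim via the rotating line anchored at the DJ apex.

    Volar displacement sweeps toward the volar (+x) side, dorsal toward
    -x; the same minimum-distance rule as UBR applies.
    """
    cfg = cfg or RotatingLineConfig()
    if displacement not in ("volar", "dorsal"):
        raise ValueError(f"unknown displacement {displacement!r}")
    sweep = +1 if displacement == "volar" else -1
    min_dist = cfg.min_dist_frac * contour_width(lat_radius_contour)
    hit = rotating_line_first_hit(lat_radius_contour, DJ, sweep_toward=sweep,
                                  min_dist=min_dist, cfg=cfg)
    if hit is None:
        raise ValueError("VJB not found")
    return hit


def detect_rim_pair(lat_radius_contour: Contour, lat_axis: AxisLine,
                    cfg: RotatingLineConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray, str]:
    """Detect both articular rims and label them anatomically.

    Runs the apex + rotating-line procedure, then assigns DJ to the
    dorsal rim and VJB to the volar rim by their projections on the
    volar perpendicular of the shaft axis — the apex itself may be
    either rim depending on the tilt sign.  Returns (DJ, VJB,
    displacement).
    """
    apex = detect_DJ(lat_radius_contour)
    displacement = classify_displacement(lat_radius_contour, lat_axis)
    other = detect_VJB(lat_radius_contour, apex, displacement, cfg)
    p_volar = lat_axis.perpendicular_radial()
    if float((apex - other) @ p_volar) < 0:
        dj, vjb = apex, other
    else:
        dj, vjb = other, apex
    return dj, vjb, displacement
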