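"""Synthetic biplane wrist phantoms with exact ground truth.

Each phantom is a pair of label masks (AP: distal radius, proximal
radius, ulna; LAT: distal radius fragment, proximal radius shaft) whose
landmark coordinates and radiographic parameters are known analytically,
so every pipeline stage can be tested end to end without clinical data.

Shapes are stylized capsules/polygons, not anatomy.  Two deliberate
geometric choices make the rotating-line landmark procedures well
posed: articular edges sag slightly below their chord, so the first
"significantly distant" intersection of the rotating line really is the
rim corner; and the ulna carries a small styloid nub so its sweep
anchor stays the same vertex under boundary noise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from ._geometry import arc_midpoint, rotate_points
from .axis_fitting import AxisLine
from .landmark_detection import LandmarkSet
from .mask_io import AP_LABELS, LAT_LABELS, LabelMask, Laterality, View
from .radiographic_params import RadiographicParams, assemble_params


class Displacement(str, enum.Enum):
    VOLAR = "volar"
    DORSAL = "dorsal"


@dataclass
class PhantomSpec:
    """Requested ground-truth geometry for one synthetic case."""

    RA_true: float = 22.0        # degrees
    RL_true: float = 11.0        # px
    UV_true: float = 0.0         # signed px
    PT_true: float = 11.0        # degrees
    displacement: Displacement = Displacement.VOLAR
    shaft_angle_deg: float = 90.0  # 90 = vertical shafts
    image_size: tuple[int, int] = (512, 512)
    noise_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.displacement = Displacement(self.displacement)
        if not (0.0 <= self.RA_true <= 45.0):
            raise ValueError("RA_true must be in [0, 45] degrees")
        scale = min(self.image_size) / 512.0
        if not (2.0 * scale <= self.RL_true <= 30.0 * scale):
            raise ValueError("RL_true out of range")
        if abs(self.UV_true) > 10.0:
            raise ValueError("|UV_true| must be <= 10 px")
        if abs(self.PT_true) > 35.0:
            raise ValueError("|PT_true| must be <= 35 degrees")
        if self.noise_px < 0:
            raise ValueError("noise_px must be >= 0")
        if min(self.image_size) < 256:
            raise ValueError("phantom needs at least a 256 px image")


@dataclass
class PhantomTruth:
    landmarks: LandmarkSet
    ap_axis_theta: float
    lat_axis_theta: float
    ap_axis: AxisLine
    lat_axis: AxisLine
    params: RadiographicParams
    areas: dict[str, float] = field(default_factory=dict)  # analytic silhouette areas

    def to_dict(self) -> dict:
        return {
            "landmarks": self.landmarks.to_dict(),
            "ap_axis_theta": float(self.ap_axis_theta),
            "lat_axis_theta": float(self.lat_axis_theta),
            "params": self.params.to_dict(),
            "areas": {k: float(v) for k, v in self.areas.items()},
        }


@dataclass
class PhantomCase:
    spec: PhantomSpec
    ap: LabelMask
    lat: LabelMask
    truth: PhantomTruth


def _sagged_edge(a: np.ndarray, b: np.ndarray, sag: float, n: int = 17,
                 flat_at: str | None = None) -> np.ndarray:
    """Points from a to b displaced downward (+y) below their chord.

    Excludes a, includes b.  The sag is what makes the rotating-line
    search well posed: the first distant intersection is the far corner,
    not a mid-edge point.  ``flat_at`` ("start"/"end") selects a profile
    with zero slope at that endpoint, used where the endpoint is a
    topmost-apex landmark whose wedge must not be sharpened; elsewhere a
    plain sine profile keeps a linear-in-distance margin at both ends.
    """
    t = np.linspace(0.0, 1.0, n)[1:]
    if flat_at == "start":
        profile = (27.0 / 4.0) * t ** 2 * (1.0 - t)
    elif flat_at == "end":
        profile = (27.0 / 4.0) * t * (1.0 - t) ** 2
    else:
        profile = np.sin(np.pi * t)
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    pts[:, 1] += sag * profile
    return pts


def _jitter_ring(ring: np.ndarray, noise: float, rng: np.random.Generator,
                 protected: np.ndarray, spacing: float = 1.5) -> np.ndarray:
    """Densify the ring and perturb vertices along local normals.

    Vertices within 2 px of a protected landmark keep their exact
    position so the generator's truth stays on the silhouette.
    """
    dense: list[np.ndarray] = []
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        length = np.linalg.norm(b - a)
        k = max(int(np.ceil(length / spacing)), 1)
        t = np.linspace(0.0, 1.0, k, endpoint=False)
        dense.append(a[None, :] + t[:, None] * (b - a)[None, :])
    pts = np.concatenate(dense)
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tangent = nxt - prv
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    tangent = tangent / np.maximum(norm, 1e-12)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    amp = rng.uniform(-noise, noise, len(pts))
    if len(protected):
        d = np.linalg.norm(pts[:, None, :] - protected[None, :, :], axis=2).min(axis=1)
        amp[d < 2.0] = 0.0
    return pts + amp[:, None] * normal


def _paint(canvas: np.ndarray, ring: np.ndarray, code: int) -> None:
    rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=canvas.shape)
    canvas[rr, cc] = code


def _shoelace(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def generate_phantom(spec: PhantomSpec) -> tuple[LabelMask, LabelMask, PhantomTruth]:
    """Build one AP + LAT mask pair and its exact truth record."""
    rows, cols = spec.image_size
    s = min(rows, cols) / 512.0
    cx, cy = cols / 2.0, rows / 2.0
    rng = np.random.default_rng(spec.seed)
    ra_rad = np.deg2rad(spec.RA_true)
    if ra_rad < 1e-9:
        raise ValueError("RA_true = 0 puts the styloid at infinity; "
                         "use RA_true >= a few degrees")
    w_art = spec.RL_true / np.tan(ra_rad)

    # ------------------------------------------------------------- AP view
    r_ubr = 0.30 * rows
    x_ubr = cx - 0.02 * cols
    ubr = np.array([x_ubr, r_ubr])
    st = np.array([x_ubr + w_art, r_ubr - spec.RL_true])
    # wide (~120 deg) styloid wedge: an acute apex erodes under the 3x3
    # Gaussian + threshold and biases ST (and hence RA/RL) proximally
    shoulder = st + np.array([16.0 * s, 14.0 * s])
    r_frag_bot = r_ubr + 0.12 * rows
    # Articular sag scales with the chord: on short chords (high RA, low
    # RL) a fixed few-px sag is comparable to the raster erosion of the
    # styloid anchor, and the rotating line can clip mid-edge.
    chord = float(np.hypot(w_art, spec.RL_true))
    sag_ap = float(np.clip(0.25 * chord, 4.0 * s, 12.0 * s))
    ap_distal = np.concatenate([
        [st, shoulder, [shoulder[0], r_frag_bot], [x_ubr - 3.0 * s, r_frag_bot],
         [x_ubr - 3.0 * s, r_ubr + 6.0 * s], ubr],
        # concave articular edge back to ST, flat where it meets the styloid
        _sagged_edge(ubr, st, sag=sag_ap, flat_at="end")[:-1],
    ])
    r_bone_bot = rows - 0.08 * rows
    ap_proximal = np.array([
        [x_ubr - 3.0 * s, r_frag_bot + 6.0 * s],
        [shoulder[0], r_frag_bot + 6.0 * s],
        [shoulder[0], r_bone_bot],
        [x_ubr - 3.0 * s, r_bone_bot],
    ])

    # Ulna: styloid nub on the ulnar (left) corner, then a gently sagging
    # flat distal surface.  The whole bone is placed so the arc-length
    # midpoint of that surface sits exactly UV_true px distal to UBR.
    w_u = 0.07 * cols
    ux = x_ubr - 0.12 * cols
    x_l = ux - w_u / 2.0
    x_r = ux + w_u / 2.0
    top_local = np.concatenate([
        [[0.0, -3.0 * s]],
        _sagged_edge(np.array([6.0 * s, 0.0]), np.array([w_u, 0.0]), sag=2.0 * s),
    ])
    top_local = np.concatenate([[top_local[0]], [[6.0 * s, 0.0]], top_local[1:]])
    mid_local = arc_midpoint(top_local)
    r_surface = (r_ubr - spec.UV_true) - mid_local[1]
    top = top_local + np.array([x_l, r_surface])
    uh = np.array([x_l + mid_local[0], r_ubr - spec.UV_true])
    ul_ubr = top[-1].copy()  # radial-facing corner of the surface
    ulna = np.concatenate([
        top,
        [[x_r, r_bone_bot], [x_l, r_bone_bot]],
    ])
    ulna_center = np.array([ux, (r_surface + r_bone_bot) / 2.0])

    # ------------------------------------------------------------ LAT view
    pt_rad = np.deg2rad(spec.PT_true)
    w_lat = 0.11 * cols
    shift = (0.02 * cols) if spec.displacement is Displacement.VOLAR else -(0.02 * cols)
    frag_cx = cx + shift
    rd = 0.28 * rows
    dorsal = np.array([frag_cx - w_lat / 2.0, rd])           # dorsal rim (-x)
    volar = np.array([frag_cx + w_lat / 2.0, rd + w_lat * np.tan(pt_rad)])
    r_lat_bot = max(dorsal[1], volar[1]) + 0.11 * rows
    lat_distal = np.concatenate([
        [dorsal],
        _sagged_edge(dorsal, volar, sag=4.0 * s),
        [[volar[0] + 3.0 * s, r_lat_bot], [dorsal[0] - 3.0 * s, r_lat_bot]],
    ])
    w_s = 0.085 * cols
    lat_proximal = np.array([
        [cx - w_s / 2.0, r_lat_bot + 6.0 * s],
        [cx + w_s / 2.0, r_lat_bot + 6.0 * s],
        [cx + w_s / 2.0, r_bone_bot],
        [cx - w_s / 2.0, r_bone_bot],
    ])
    shaft_center = np.array([cx, (r_lat_bot + r_bone_bot) / 2.0])

    # Anatomical rim labelling: DJ is always the dorsal rim, VJB the
    # volar rim, whichever of the two happens to be the topmost apex.
    dj, vjb = dorsal, volar

    # -------------------------------------------- global rotation + noise
    phi = spec.shaft_angle_deg - 90.0
    center = np.array([cx, cy])

    def place(ring: np.ndarray) -> np.ndarray:
        return rotate_points(ring, phi, center)

    rings = {
        "ap_distal": place(ap_distal), "ap_proximal": place(ap_proximal),
        "ulna": place(ulna), "lat_distal": place(lat_distal),
        "lat_proximal": place(lat_proximal),
    }
    margin = 10.0
    for name, ring in rings.items():
        if (ring[:, 0].min() < margin or ring[:, 0].max() > cols - margin
                or ring[:, 1].min() < margin or ring[:, 1].max() > rows - margin):
            raise ValueError(f"phantom part {name} out of frame")

    lm_pts = {
        "ST": place(st[None, :])[0], "UBR": place(ubr[None, :])[0],
        "UH": place(uh[None, :])[0], "ul_UBR": place(ul_ubr[None, :])[0],
        "DJ": place(dj[None, :])[0], "VJB": place(vjb[None, :])[0],
    }
    protected_ap = np.array([lm_pts["ST"], lm_pts["UBR"]])
    protected_ulna = np.array([rings["ulna"][0], lm_pts["ul_UBR"]])
    protected_lat = np.array([lm_pts["DJ"], lm_pts["VJB"]])
    if spec.noise_px > 0:
        rings["ap_distal"] = _jitter_ring(rings["ap_distal"], spec.noise_px, rng, protected_ap)
        rings["ap_proximal"] = _jitter_ring(rings["ap_proximal"], spec.noise_px, rng, np.empty((0, 2)))
        rings["ulna"] = _jitter_ring(rings["ulna"], spec.noise_px, rng, protected_ulna)
        rings["lat_distal"] = _jitter_ring(rings["lat_distal"], spec.noise_px, rng, protected_lat)
        rings["lat_proximal"] = _jitter_ring(rings["lat_proximal"], spec.noise_px, rng, np.empty((0, 2)))

    ap_canvas = np.zeros((rows, cols), dtype=np.uint8)
    _paint(ap_canvas, rings["ap_distal"], AP_LABELS["distal_radius"])
    _paint(ap_canvas, rings["ap_proximal"], AP_LABELS["proximal_radius"])
    _paint(ap_canvas, rings["ulna"], AP_LABELS["ulna"])
    lat_canvas = np.zeros((rows, cols), dtype=np.uint8)
    _paint(lat_canvas, rings["lat_distal"], LAT_LABELS["distal_radius"])
    _paint(lat_canvas, rings["lat_proximal"], LAT_LABELS["proximal_radius"])

    ap_mask = LabelMask(ap_canvas, View.AP, dict(AP_LABELS),
                        laterality=Laterality.RIGHT)
    lat_mask = LabelMask(lat_canvas, View.LAT, dict(LAT_LABELS),
                         laterality=Laterality.RIGHT)

    landmarks = LandmarkSet(
        ST=tuple(lm_pts["ST"]), UBR=tuple(lm_pts["UBR"]), UH=tuple(lm_pts["UH"]),
        ul_UBR=tuple(lm_pts["ul_UBR"]), DJ=tuple(lm_pts["DJ"]), VJB=tuple(lm_pts["VJB"]),
        displacement=spec.displacement.value,
    )
    theta = spec.shaft_angle_deg % 180.0
    ap_axis = AxisLine.from_theta(theta, place(ulna_center[None, :])[0])
    lat_axis = AxisLine.from_theta(theta, place(shaft_center[None, :])[0])
    params = assemble_params(landmarks, ap_axis, lat_axis, spacing=None)
    truth = PhantomTruth(
        landmarks=landmarks, ap_axis_theta=theta, lat_axis_theta=theta,
        ap_axis=ap_axis, lat_axis=lat_axis, params=params,
        areas={name: _shoelace(ring) for name, ring in rings.items()},
    )
    return ap_mask, lat_mask, truth


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "RA_true": (10.0, 30.0),
    "RL_true": (8.0, 14.0),
    "UV_true": (-3.0, 3.0),
    "PT_true": (-20.0, 20.0),
    "shaft_angle_deg": (90.0, 90.0),
    "noise_px": (0.0, 0.0),
}


def generate_batch(n: int, ranges: dict | None = None, seed: int = 0,
                   image_size: tuple[int, int] = (512, 512)) -> list[PhantomCase]:
    """Sample ``n`` phantom specs uniformly within ``ranges``, reproducibly.

    Displacement is coupled to the tilt sign (volar tilt -> volar
    displacement) so the lateral rotating-line procedure is well posed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng_ranges = dict(DEFAULT_RANGES)
    rng_ranges.update(ranges or {})
    for key, (lo, hi) in rng_ranges.items():
        if hi < lo:
            raise ValueError(f"impossible range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        draw = {key: float(rng.uniform(lo, hi)) for key, (lo, hi) in rng_ranges.items()}
        spec = PhantomSpec(
            RA_true=draw["RA_true"], RL_true=draw["RL_true"],
            UV_true=draw["UV_true"], PT_true=draw["PT_true"],
            displacement=Displacement.VOLAR if draw["PT_true"] >= 0 else Displacement.DORSAL,
            shaft_angle_deg=draw["shaft_angle_deg"], noise_px=draw["noise_px"],
            image_size=image_size, seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        ap, lat, truth = generate_phantom(spec)
        cases.append(PhantomCase(spec=spec, ap=ap, lat=lat, truth=truth))
    return cases


def write_case(case: PhantomCase, out_dir, stem: str) -> dict[str, Path]:
    """Write one case as two mask PNGs plus metadata and truth JSON."""
    from .mask_io import write_label_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ap": write_label_mask(case.ap, out / f"{stem}_ap.png"),
        "lat": write_label_mask(case.lat, out / f"{stem}_lat.png"),
    }
    meta = {"pixel_spacing_mm": None, "laterality": "right"}
    (out / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    (out / f"{stem}_truth.json").write_text(json.dumps(case.truth.to_dict(), indent=2))
    paths["meta"] = out / f"{stem}_meta.json"
    paths["truth"] = out / f"{stem}_truth.json"
    return paths
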