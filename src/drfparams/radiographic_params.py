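"""Radiographic parameters RA, RL, UV, PT from landmarks and reference axes.

Sign conventions (canonical right wrist, distal up):
  * RA > 0 when the styloid tip is distal to the ulnar border of the
    radius along the baseline axis (normal anatomy).
  * UV > 0 when the distal ulnar surface is distal to the sigmoid-notch
    level (ulna relatively long).
  * PT > 0 for volar tilt: the volar rim proximal to the dorsal rim.
Angles are frame-relative, so they are invariant to global rotation and
to the px/mm calibration; lengths scale linearly with pixel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis_fitting import AxisLine
from .landmark_detection import LandmarkSet


@dataclass
class RadiographicParams:
    RA_deg: float
    RL: float
    UV: float
    PT_deg: float
    reference_angle_deg: float
    units: str = "px"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-90.0 < self.RA_deg <= 90.0):
            raise ValueError("RA out of range")
        if not (-90.0 < self.PT_deg <= 90.0):
            raise ValueError("PT out of range")
        if self.RL < 0:
            raise ValueError("RL must be >= 0")
        if self.units not in ("px", "mm"):
            raise ValueError("units must be 'px' or 'mm'")

    def to_dict(self) -> dict:
        return {
            "RA_deg": float(self.RA_deg), "RL": float(self.RL),
            "UV": float(self.UV), "PT_deg": float(self.PT_deg),
            "reference_angle_deg": float(self.reference_angle_deg),
            "units": self.units, "warnings": list(self.warnings),
        }


def _as_vec(p) -> np.ndarray:
    return np.asarray(p, dtype=float).reshape(2)


def perpendicular_projection_distance(P, Q, axis: AxisLine) -> float:
    """Signed projection of P - Q on the distally pointing axis direction.

    Equals the distance between the two perpendiculars to the axis
    erected through P and Q, with sign positive when P is distal to Q.
    """
    u = axis.direction_distal()
    if not np.isfinite(u).all() or np.linalg.norm(u) < 1e-12:
        raise ValueError("degenerate axis")
    return float((_as_vec(P) - _as_vec(Q)) @ u)


def compute_RA(ST, UBR, ref_axis: AxisLine) -> float:
    """Angle between segment ST-UBR and the perpendicular to the baseline.

    Computed from direction vectors via atan2 and wrapped to (-90, 90],
    which reproduces the arctan-difference form in the canonical frame
    without quadrant ambiguity.
    """
    d = _as_vec(ST) - _as_vec(UBR)
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("ST and UBR coincide")
    along = d @ ref_axis.direction_distal()
    across = abs(d @ ref_axis.perpendicular_radial())
    return float(np.degrees(np.arctan2(along, across)))


def compute_RL(ST, UBR, ref_axis: AxisLine, spacing: float = 1.0) -> float:
    """Distance along the baseline between the ST and UBR perpendiculars."""
    return abs(perpendicular_projection_distance(ST, UBR, ref_axis)) * spacing


def compute_UV(UH, UBR, ref_axis: AxisLine, spacing: float = 1.0) -> float:
    """Signed baseline offset of the ulnar head surface vs the sigmoid notch."""
    return perpendicular_projection_distance(UH, UBR, ref_axis) * spacing


def compute_PT(VJB, DJ, lat_axis: AxisLine) -> float:
    """Tilt of the articular rim line relative to the shaft perpendicular.

    Role-agnostic in its two rim points: the volar rim is identified by
    its component along the canonical volar perpendicular, so swapping
    which rim was detected as the apex leaves the result unchanged.
    """
    v = _as_vec(VJB) - _as_vec(DJ)
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("VJB and DJ coincide")
    u = lat_axis.direction_distal()
    p_volar = lat_axis.perpendicular_radial()
    raw = float(np.degrees(np.arctan2(-(v @ u), v @ p_volar)))
    if raw > 90.0:
        raw -= 180.0
    elif raw <= -90.0:
        raw += 180.0
    return raw


def assemble_params(landmarks: LandmarkSet, ap_ref: AxisLine, lat_ref: AxisLine,
                    spacing: float | None = None) -> RadiographicParams:
    """Populate all four parameters from a complete landmark set."""
    for name in ("ST", "UBR", "UH", "DJ", "VJB"):
        if getattr(landmarks, name) is None:
            raise ValueError(f"missing landmark {name}")
    warns: list[str] = []
    if spacing is None:
        spacing_val, units = 1.0, "px"
        warns.append("no pixel spacing supplied; RL/UV reported in px")
    else:
        spacing_val, units = float(spacing), "mm"
    return RadiographicParams(
        RA_deg=compute_RA(landmarks.ST, landmarks.UBR, ap_ref),
        RL=compute_RL(landmarks.ST, landmarks.UBR, ap_ref, spacing_val),
        UV=compute_UV(landmarks.UH, landmarks.UBR, ap_ref, spacing_val),
        PT_deg=compute_PT(landmarks.VJB, landmarks.DJ, lat_ref),
        reference_angle_deg=float(ap_ref.theta_deg),
        units=units,
        warnings=warns,
    )
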