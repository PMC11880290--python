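"""Central-axis fitting from random interior points.

The axis is the line minimizing a smoothed-Manhattan loss over points
sampled inside the bone contour, optimized by gradient descent.  Bones
are near-vertical, so whenever the point cloud is taller than wide the
fit runs in a swapped frame (x as a function of y) to keep the slope
O(1); the residual definition is unchanged, only the roles of the
coordinates swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from ._geometry import direction_angle_deg
from .contour_extraction import Contour, extract_part_contour
from .mask_io import View


@dataclass
class AxisFitConfig:
    n_points: int = 500
    seed: int = 0
    alpha: float = 1e-3
    max_iter: int = 5000
    tol: float = 1e-8
    backtracking: bool = True  # line search on alpha; False = fixed-step descent

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class AxisLine:
    """A fitted central axis.

    ``m``/``b`` live in the fitting frame: ``y = m x + b`` for frame
    ``"xy"``, ``x = m y + b`` for frame ``"swapped"``.  ``theta_deg`` is
    the direction angle in image coordinates, in [0, 180), with 90 =
    vertical.
    """

    m: float
    b: float
    frame: str = "swapped"
    theta_deg: float = 90.0
    loss: float = 0.0
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.frame not in ("xy", "swapped"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.loss < 0:
            raise ValueError("loss must be >= 0")

    @classmethod
    def from_theta(cls, theta_deg: float, point) -> "AxisLine":
        """Exact axis through ``point`` at direction ``theta_deg`` (analytic use)."""
        theta = float(theta_deg) % 180.0
        x0, y0 = float(point[0]), float(point[1])
        t = np.deg2rad(theta)
        if 45.0 <= theta < 135.0:  # near-vertical: x = m y + b
            m = np.cos(t) / np.sin(t)
            return cls(m=float(m), b=x0 - float(m) * y0, frame="swapped", theta_deg=theta)
        m = np.tan(t)
        return cls(m=float(m), b=y0 - float(m) * x0, frame="xy", theta_deg=theta)

    def direction_distal(self) -> np.ndarray:
        """Unit direction along the axis pointing distally (smaller row)."""
        if self.frame == "swapped":
            d = np.array([self.m, 1.0])
        else:
            d = np.array([1.0, self.m])
        d = d / np.linalg.norm(d)
        if d[1] > 0 or (d[1] == 0 and d[0] < 0):
            d = -d
        return d

    def perpendicular_radial(self) -> np.ndarray:
        """Unit perpendicular; with a distal-up axis this points toward +x
        (the radial side in AP, the volar side in LAT, after canonicalization)."""
        u = self.direction_distal()
        return np.array([-u[1], u[0]])

    def anchor(self) -> np.ndarray:
        """One point on the line."""
        if self.frame == "swapped":
            return np.array([self.b, 0.0])
        return np.array([0.0, self.b])

    def to_dict(self) -> dict:
        return {
            "m": float(self.m), "b": float(self.b), "frame": self.frame,
            "theta_deg": float(self.theta_deg), "loss": float(self.loss),
            "converged": bool(self.converged), "n_iter": int(self.n_iter),
        }


def sample_interior_points(c: Contour, cfg: AxisFitConfig,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Rejection-sample ``n_points`` points strictly inside the contour polygon.

    Deterministic for a fixed seed (points are accepted in draw order).
    """
    if c.area < 100.0:
        raise ValueError("contour too small to host interior points")
    poly = shapely.Polygon(c.vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    rng = rng or np.random.default_rng(cfg.seed)
    xmin, ymin, xmax, ymax = poly.bounds
    out: list[np.ndarray] = []
    need = cfg.n_points
    for _ in range(200):
        batch = max(4 * need, 64)
        xs = rng.uniform(xmin, xmax, batch)
        ys = rng.uniform(ymin, ymax, batch)
        inside = shapely.contains_xy(poly, xs, ys)
        pts = np.column_stack([xs[inside], ys[inside]])
        out.append(pts[:need])
        need -= min(need, len(pts))
        if need == 0:
            return np.concatenate(out)
    raise ValueError("rejection sampling failed: contour too thin to host points")


def smoothed_distance(d) -> np.ndarray | float:
    """2(sqrt(1 + d^2/2) - 1): quadratic near 0, linear (slope sqrt(2)) at infinity."""
    d = np.asarray(d, dtype=float)
    out = 2.0 * (np.sqrt(1.0 + d * d / 2.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def _smoothed_distance_grad(d: np.ndarray) -> np.ndarray:
    return d / np.sqrt(1.0 + d * d / 2.0)


def axis_loss(points: np.ndarray, m: float, b: float) -> float:
    """Sum over points of the smoothed residual f(y - (m x + b))."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("no points")
    r = pts[:, 1] - (m * pts[:, 0] + b)
    return float(np.sum(smoothed_distance(r)))


def choose_frame(points: np.ndarray) -> str:
    """"swapped" when the cloud's vertical extent exceeds the horizontal."""
    pts = np.asarray(points, dtype=float)
    dx = pts[:, 0].max() - pts[:, 0].min()
    dy = pts[:, 1].max() - pts[:, 1].min()
    return "swapped" if dy > dx else "xy"


def fit_axis(points: np.ndarray, cfg: AxisFitConfig | None = None,
             frame: str | None = None) -> AxisLine:
    """Gradient-descent minimization of the smoothed-Manhattan axis loss.

    Starts from slope 0 with the intercept at the cloud centroid.  With
    backtracking (default) each accepted step is guaranteed not to
    increase the loss; ``backtracking=False`` keeps the raw fixed-alpha
    update rule.  The loss is convex in (m, b), so descent reaches the
    global minimum.
    """
    cfg = cfg or AxisFitConfig()
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    if np.allclose(pts, pts[0]):
        raise ValueError("points are all coincident")
    frame = frame or choose_frame(pts)
    if frame == "swapped":
        u, v = pts[:, 1], pts[:, 0]
    else:
        u, v = pts[:, 0], pts[:, 1]
    # Center the abscissa for conditioning; m is unaffected, b is shifted back.
    u0 = float(u.mean())
    uc = u - u0
    m, b = 0.0, float(v.mean())

    def loss_at(mm: float, bb: float) -> float:
        r = v - (mm * uc + bb)
        return float(np.sum(smoothed_distance(r)))

    def grad_at(mm: float, bb: float) -> np.ndarray:
        r = v - (mm * uc + bb)
        g = _smoothed_distance_grad(r)
        return np.array([float(np.sum(-g * uc)), float(np.sum(-g))])

    cur = loss_at(m, b)
    theta = np.array([m, b])
    grad = grad_at(m, b)
    step = cfg.alpha
    converged = False
    stalls = 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        if cfg.backtracking:
            # Armijo backtracking from a Barzilai-Borwein trial step: plain
            # non-increase acceptance can cycle on the saturated (linear)
            # tails of the robust loss, and a fixed small step crawls
            # along the shallow (m, b) valley.
            t = step
            gnorm2 = float(grad @ grad)
            accepted = False
            for _ in range(80):
                trial = theta - t * grad
                new = loss_at(trial[0], trial[1])
                if new <= cur - 1e-4 * t * gnorm2:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                converged = True
                break
            new_grad = grad_at(trial[0], trial[1])
            s = trial - theta
            y = new_grad - grad
            sy = float(s @ y)
            step = float(s @ s) / sy if sy > 1e-18 else t * 2.0
            step = float(np.clip(step, 1e-12, 1e6))
            theta, prev, cur, grad = trial, cur, new, new_grad
        else:
            theta = theta - cfg.alpha * grad
            prev, cur = cur, loss_at(theta[0], theta[1])
            grad = grad_at(theta[0], theta[1])
        stalls = stalls + 1 if prev - cur < cfg.tol * max(cur, 1.0) else 0
        if stalls >= 2:
            converged = True
            break
    m, b = float(theta[0]), float(theta[1])
    if not converged:
        warnings.warn("axis fit did not converge within max_iter", RuntimeWarning)
    b_full = b - m * u0
    if frame == "swapped":
        theta = direction_angle_deg(m, 1.0)
    else:
        theta = direction_angle_deg(1.0, m)
    return AxisLine(m=float(m), b=float(b_full), frame=frame, theta_deg=theta,
                    loss=float(cur), converged=converged, n_iter=it)


def reference_axis(mask, cfg: AxisFitConfig | None = None,
                   contour_cfg=None) -> AxisLine:
    """Fit the baseline shaft axis: the ulna in AP, the proximal radius in LAT.

    The shaft parts are the most fracture-stable bones in each view,
    which is what makes them usable as the measurement baseline.
    """
    cfg = cfg or AxisFitConfig()
    part = "ulna" if View(mask.view) is View.AP else "proximal_radius"
    contour = extract_part_contour(mask, part, contour_cfg)
    pts = sample_interior_points(contour, cfg)
    return fit_axis(pts, cfg)
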