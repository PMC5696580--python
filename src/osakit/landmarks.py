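"""Synthetic facial landmark generation with controllable ground truth.

Stands in for an automatic landmarking stage: starting from a fixed,
hand-drawn mean shape per view (a 24-point profile including the neck, and
a 52-point frontal grid, both in y-down pixel coordinates on a nominal
640x480 image), targeted deformations are applied so the landmark set
attains requested craniofacial measurements exactly:

- TRS angle: the stomion is rotated about the ramus at constant radius.
- cervicomental contour ratio: the four interior chain points are displaced
  perpendicular to the chain diagonal with a sinusoidal bulge profile; the
  bulge amplitude is solved by bisection (the ratio is strictly monotone in
  it: displacing the contour toward the rectangle's bottom-right vertex —
  the fuller-neck direction — shrinks the measured polygon).
- face-width ratio: the midface landmark pair is moved symmetrically about
  the face midline.

Optional isotropic Gaussian jitter emulates landmarking noise; the stored
ground truth always refers to the unjittered construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .craniofacial import (
    CHAIN_INDICES,
    CraniofacialMeasurements,
    LandmarkSet,
    cervicomental_contour_ratio,
    face_width_ratio,
    trs_angle,
)

__all__ = ["LandmarkGroundTruth", "generate_landmarks", "MEAN_PROFILE", "MEAN_FRONTAL"]


# hand-drawn mean profile shape, 24 points, face oriented rightward,
# y-down pixels; anatomical indices: stomion=6, ramus=16, tragion=18,
# cervicomental chain = 11, 12, 20, 21, 22, 23
MEAN_PROFILE = np.array([
    [300.0, 60.0],   # 0  forehead top
    [292.0, 95.0],   # 1  forehead
    [286.0, 125.0],  # 2  glabella
    [282.0, 145.0],  # 3  nasion
    [270.0, 170.0],  # 4  nose bridge
    [255.0, 195.0],  # 5  nose tip
    [265.0, 240.0],  # 6  stomion
    [262.0, 210.0],  # 7  subnasale
    [263.0, 228.0],  # 8  upper lip
    [266.0, 252.0],  # 9  lower lip
    [272.0, 278.0],  # 10 chin front
    [335.0, 298.0],  # 11 chain: under-chin / upper-right rectangle corner
    [316.0, 314.4],  # 12 chain interior
    [288.0, 295.0],  # 13 gnathion
    [320.0, 270.0],  # 14 jawline
    [345.0, 262.0],  # 15 mandible angle
    [358.0, 248.0],  # 16 ramus
    [368.0, 215.0],  # 17 ear lobe
    [372.0, 185.0],  # 18 tragion
    [365.0, 150.0],  # 19 ear top
    [297.0, 330.8],  # 20 chain interior
    [278.0, 347.2],  # 21 chain interior
    [259.0, 363.6],  # 22 chain interior
    [240.0, 380.0],  # 23 chain: neck base / bottom-left rectangle corner
])


def _build_mean_frontal() -> np.ndarray:
    """Schematic 52-point frontal grid: outline, brows, eyes, nose, mouth."""
    pts = np.zeros((52, 2))
    cx, cy = 320.0, 240.0
    # 0-14: face outline ellipse, ear-to-ear over the chin
    ang = np.linspace(-0.15 * np.pi, 1.15 * np.pi, 15)
    pts[0:15, 0] = cx + 95.0 * np.cos(ang)
    pts[0:15, 1] = cy + 125.0 * np.sin(ang)
    # 15-24: brows
    for k, x in enumerate(np.linspace(cx - 70, cx - 15, 5)):
        pts[15 + k] = (x, cy - 60.0)
    for k, x in enumerate(np.linspace(cx + 15, cx + 70, 5)):
        pts[20 + k] = (x, cy - 60.0)
    # 25-30: right eye (subject right, image left), 28 = inner canthus
    eye = np.array([[-62, 0], [-52, -6], [-40, -6], [-30, 0], [-40, 6], [-52, 6]])
    pts[25:31] = eye * 1.0 + (cx, cy - 30.0)
    # 31-36: left eye, 34 = inner canthus
    pts[31:37] = eye * np.array([-1, 1]) + (cx, cy - 30.0)
    # 37-43: nose
    nose = np.array([[0, -25], [0, 0], [-16, 18], [-8, 22], [0, 24], [8, 22], [16, 18]])
    pts[37:44] = nose + (cx, cy + 10.0)
    # 44-51: mouth
    mouth = np.array([[-30, 0], [-15, -8], [0, -10], [15, -8], [30, 0],
                      [15, 8], [0, 10], [-15, 8]])
    pts[44:52] = mouth + (cx, cy + 70.0)
    return pts


MEAN_FRONTAL = _build_mean_frontal()
# midface pair (outline indices 2 and 12) sits at cheekbone height in the
# mean shape; inner canthi are 28 and 34
_MIDLINE_X = 320.0


@dataclass(frozen=True)
class LandmarkGroundTruth:
    landmark_set: LandmarkSet
    true_measurements: CraniofacialMeasurements


def _set_trs_angle(points: np.ndarray, target_deg: float) -> None:
    """Rotate the stomion about the ramus so the TRS angle hits the target."""
    ramus, stomion, tragion = points[16], points[6], points[18]
    u = stomion - ramus
    v = tragion - ramus
    radius = np.linalg.norm(u)
    v_hat = v / np.linalg.norm(v)
    side = np.sign(v[0] * u[1] - v[1] * u[0]) or 1.0  # keep stomion on its side
    th = np.deg2rad(target_deg) * side
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    points[6] = ramus + radius * (rot @ v_hat)


def _chain_points(bulge: float) -> np.ndarray:
    """Interior chain points for a given perpendicular bulge amplitude.

    Positive bulge displaces toward the rectangle's bottom-right vertex
    (fuller neck, smaller ratio); negative toward the hollow of a slim neck.
    """
    p11, p23 = MEAN_PROFILE[11], MEAN_PROFILE[23]
    d = p23 - p11
    n = np.array([-d[1], d[0]])
    n /= np.linalg.norm(n)
    v = np.array([p11[0], p23[1]])  # bottom-right vertex
    if np.dot(v - (p11 + p23) / 2.0, n) < 0:
        n = -n
    t = np.array([0.2, 0.4, 0.6, 0.8])
    return p11 + np.outer(t, d) + bulge * np.outer(np.sin(np.pi * t), n)


def _set_cervicomental_ratio(points: np.ndarray, target: float) -> None:
    p11, p23 = MEAN_PROFILE[11], MEAN_PROFILE[23]
    # bulge bounds keep the chain strictly inside the rectangle
    half_w = 0.48 * min(abs(p11[0] - p23[0]), abs(p11[1] - p23[1]))

    def ratio_of(bulge: float) -> float:
        pts = points.copy()
        pts[[12, 20, 21, 22]] = _chain_points(bulge)
        import warnings

        with warnings.catch_warnings():
            # bracket endpoints may probe out-of-rectangle bulges
            warnings.simplefilter("ignore")
            return cervicomental_contour_ratio(LandmarkSet("profile", pts))

    lo, hi = ratio_of(half_w), ratio_of(-half_w)
    if not (lo <= target <= hi):
        raise ValueError(
            f"cervicomental ratio {target} not attainable (range {lo:.3f}-{hi:.3f})"
        )
    bulge = optimize.brentq(lambda b: ratio_of(b) - target, -half_w, half_w,
                            xtol=1e-12)
    points[[12, 20, 21, 22]] = _chain_points(bulge)


def _set_face_width_ratio(points: np.ndarray, target: float) -> None:
    inter = np.linalg.norm(points[28] - points[34])
    half = 0.5 * target * inter
    for idx, sign in ((2, -1.0), (12, 1.0)):
        y = points[idx, 1]
        points[idx] = (_MIDLINE_X + sign * half, y)


def generate_landmarks(
    view: str,
    target: CraniofacialMeasurements | None = None,
    jitter_px: float = 0.0,
    seed: int = 0,
) -> LandmarkGroundTruth:
    """Build a landmark set attaining the target measurements.

    Target fields that are NaN (or the whole target omitted) keep the mean
    shape's value for that measurement.  With ``jitter_px == 0`` the
    measurements recomputed from the returned landmarks reproduce the
    target to better than 1e-6 relative.
    """
    if view == "profile":
        points = MEAN_PROFILE.copy()
        if target is not None and not np.isnan(target.trs_angle):
            if not 0.0 < target.trs_angle < 180.0:
                raise ValueError("TRS angle target must lie in (0, 180)")
            _set_trs_angle(points, target.trs_angle)
        if target is not None and not np.isnan(target.cervicomental_contour_ratio):
            _set_cervicomental_ratio(points, target.cervicomental_contour_ratio)
    elif view == "frontal":
        points = MEAN_FRONTAL.copy()
        if target is not None and not np.isnan(target.face_width_ratio):
            if target.face_width_ratio <= 0:
                raise ValueError("face-width ratio target must be positive")
            _set_face_width_ratio(points, target.face_width_ratio)
    else:
        raise ValueError("view must be 'profile' or 'frontal'")

    clean = LandmarkSet(view, points.copy())
    if view == "profile":
        truth = CraniofacialMeasurements(
            cervicomental_contour_ratio=cervicomental_contour_ratio(clean),
            face_width_ratio=np.nan,
            trs_angle=trs_angle(clean),
        )
    else:
        truth = CraniofacialMeasurements(
            cervicomental_contour_ratio=np.nan,
            face_width_ratio=face_width_ratio(clean),
            trs_angle=np.nan,
        )
    if jitter_px > 0:
        rng = np.random.default_rng(seed)
        points = points + rng.normal(0.0, jitter_px, size=points.shape)
    return LandmarkGroundTruth(
        landmark_set=LandmarkSet(view, points), true_measurements=truth
    )
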