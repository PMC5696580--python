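"""Uncalibrated craniofacial measurements from 2-D facial landmarks.

Three measurements designed to survive an uncontrolled photographic setup
(no pixel-to-metric calibration, webcam images, y-down pixel coordinates):

- cervicomental contour ratio: area under the anterior-neck contour within
  its bounding rectangle, divided by the rectangle area; decreases as fat
  deposition under the chin fills the region.
- face-width ratio: midface width / interocular width (frontal view).
- tragion-ramus-stomion angle: the interior angle at the mandible ramus
  between rays to the stomion and the tragion; captures mandibular
  retraction.

All three are invariant to translation, rotation and uniform scaling of the
landmark set — the point of using ratios and angles in the first place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "CraniofacialMeasurements",
    "PROFILE_SCHEMA",
    "FRONTAL_SCHEMA",
    "polygon_area",
    "cervicomental_contour_ratio",
    "face_width_ratio",
    "trs_angle",
    "measure",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

# Named anatomical indices.  The profile view uses 24 points including the
# neck; the frontal view uses a 52-point face-identification grid.  The
# exact placement of the cervicomental chain (11, 12, 20-23, traced
# equidistantly along the under-chin/anterior-neck contour) is this
# package's documented interpretation of the published landmark figures.
PROFILE_SCHEMA = {
    "stomion": 6,
    "chain_upper_right": 11,  # also the rectangle's upper-right corner
    "chain_1": 12,
    "ramus": 16,
    "tragion": 18,
    "chain_2": 20,
    "chain_3": 21,
    "chain_4": 22,
    "chain_lower_left": 23,  # also the rectangle's bottom-left corner
}
CHAIN_INDICES = (11, 12, 20, 21, 22, 23)

FRONTAL_SCHEMA = {
    "midface_right": 2,
    "midface_left": 12,
    "interocular_right": 28,  # inner canthus, right eye
    "interocular_left": 34,  # inner canthus, left eye
}

_CARDINALITY = {"frontal": 52, "profile": 24}


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered 2-D landmarks in y-down pixel coordinates."""

    view: str
    points: np.ndarray
    schema: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if self.view not in _CARDINALITY:
            raise ValueError("view must be 'frontal' or 'profile'")
        if pts.shape != (_CARDINALITY[self.view], 2):
            raise ValueError(
                f"{self.view} view requires {_CARDINALITY[self.view]} (x, y) points"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if not self.schema:
            default = PROFILE_SCHEMA if self.view == "profile" else FRONTAL_SCHEMA
            object.__setattr__(self, "schema", dict(default))

    def named(self, name: str) -> np.ndarray:
        return self.points[self.schema[name]]

    def transformed(self, scale: float = 1.0, angle_deg: float = 0.0,
                    shift=(0.0, 0.0)) -> "LandmarkSet":
        """Similarity-transformed copy (for invariance checks)."""
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = scale * self.points @ rot.T + np.asarray(shift, dtype=float)
        return LandmarkSet(self.view, pts, dict(self.schema))


@dataclass(frozen=True)
class CraniofacialMeasurements:
    cervicomental_contour_ratio: float
    face_width_ratio: float
    trs_angle: float

    def __post_init__(self) -> None:
        if not np.isnan(self.cervicomental_contour_ratio):
            if not 0.0 < self.cervicomental_contour_ratio <= 1.0:
                raise ValueError("cervicomental ratio must lie in (0, 1]")
        if not np.isnan(self.face_width_ratio) and self.face_width_ratio <= 0:
            raise ValueError("face-width ratio must be positive")
        if not np.isnan(self.trs_angle):
            if not 0.0 < self.trs_angle < 180.0:
                raise ValueError("TRS angle must lie in (0, 180) degrees")


def polygon_area(points: np.ndarray) -> float:
    """Absolute shoelace area of a polygon given by ordered vertices."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def cervicomental_contour_ratio(profile: LandmarkSet) -> float:
    """Area ratio of the cervicomental polygon to its bounding rectangle.

    The rectangle is axis-aligned, spanned by the chain's lower-left
    landmark (23) and upper-right landmark (11) in y-down coordinates.  The
    polygon is the closed path 11 -> 12 -> 20 -> 21 -> 22 -> 23 -> V -> 11,
    where V is the rectangle's bottom-right vertex.  Chain points falling
    outside the rectangle are clipped to it (with a warning).
    """
    if profile.view != "profile":
        raise ValueError("cervicomental ratio requires the profile view")
    p11 = profile.points[11]
    p23 = profile.points[23]
    x_left, x_right = p23[0], p11[0]
    y_top, y_bottom = p11[1], p23[1]  # y-down: bottom has the larger y
    if np.isclose(x_left, x_right) or np.isclose(y_top, y_bottom):
        raise ValueError("degenerate cervicomental rectangle")
    if x_left > x_right or y_top > y_bottom:
        raise ValueError(
            "landmark 23 must lie below-left of landmark 11 (y-down pixels)"
        )
    chain = profile.points[list(CHAIN_INDICES)].copy()
    clipped = chain.copy()
    clipped[:, 0] = np.clip(clipped[:, 0], x_left, x_right)
    clipped[:, 1] = np.clip(clipped[:, 1], y_top, y_bottom)
    if not np.allclose(chain, clipped):
        warnings.warn("cervicomental chain landmarks clipped to rectangle",
                      stacklevel=2)
    v = np.array([x_right, y_bottom])
    poly = np.vstack([clipped, v])
    rect_area = (x_right - x_left) * (y_bottom - y_top)
    ratio = polygon_area(poly) / rect_area
    return float(min(ratio, 1.0))


def face_width_ratio(frontal: LandmarkSet) -> float:
    """Midface width divided by interocular width (frontal view)."""
    if frontal.view != "frontal":
        raise ValueError("face-width ratio requires the frontal view")
    mid = np.linalg.norm(frontal.named("midface_right") - frontal.named("midface_left"))
    inter = np.linalg.norm(
        frontal.named("interocular_right") - frontal.named("interocular_left")
    )
    if inter == 0:
        raise ValueError("zero interocular distance")
    return float(mid / inter)


def trs_angle(profile: LandmarkSet) -> float:
    """Interior angle (degrees) at the ramus between stomion and tragion."""
    if profile.view != "profile":
        raise ValueError("TRS angle requires the profile view")
    ramus = profile.named("ramus")
    u = profile.named("stomion") - ramus
    v = profile.named("tragion") - ramus
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident landmarks give a zero-length ray")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def measure(
    profile: LandmarkSet | None = None, frontal: LandmarkSet | None = None
) -> CraniofacialMeasurements:
    """All three measurements; NaN where the required view is absent."""
    return CraniofacialMeasurements(
        cervicomental_contour_ratio=(
            cervicomental_contour_ratio(profile) if profile is not None else np.nan
        ),
        face_width_ratio=face_width_ratio(frontal) if frontal is not None else np.nan,
        trs_angle=trs_angle(profile) if profile is not None else np.nan,
    )


def write_landmarks_csv(lms: LandmarkSet, path) -> None:
    """CSV with columns (index, x, y); the header names the schema."""
    df = pd.DataFrame(
        {"index": np.arange(len(lms.points)),
         "x": lms.points[:, 0], "y": lms.points[:, 1]}
    )
    with open(path, "w") as fh:
        fh.write(f"# schema: {lms.view}-{len(lms.points)}\n")
        df.to_csv(fh, index=False)


def read_landmarks_csv(path) -> LandmarkSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# schema:"):
            raise ValueError("landmark CSV missing schema header")
        view = header.split(":", 1)[1].strip().split("-")[0]
        df = pd.read_csv(fh)
    pts = df.sort_values("index")[["x", "y"]].to_numpy()
    return LandmarkSet(view=view, points=pts)
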