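"""Vertebral midplane geometry and signed intervertebral angles.

The sagittal pose of each cervical vertebra is summarised by a *midplane
line* constructed from its four vertebral-body corner landmarks (Frobin's
bisecting-midplane scheme): the line through the midpoint of the two
anterior corners and the midpoint of the two posterior corners.  The
occiput (C0) and atlas (C1) have no rectangular body, so they are carried
as an explicit two-point reference axis (anterior point, posterior point).

The signed intervertebral angle of a joint is the orientation difference
between the midplane lines of the two adjacent vertebrae, wrapped into
(-90, +90] degrees.  Coordinates are millimetres in the sagittal plane,
x anterior-positive, y cranial-positive; a positive joint angle denotes
extension (posterior closing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

LEVELS: tuple[str, ...] = ("C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7")
JOINTS: tuple[str, ...] = tuple(f"{a}/{b}" for a, b in zip(LEVELS[:-1], LEVELS[1:]))

#: landmark labels for a four-corner vertebral body, in the fixed schema order:
#: anterior-superior, posterior-superior, posterior-inferior, anterior-inferior
CORNER_ORDER: tuple[str, ...] = ("AS", "PS", "PI", "AI")
#: landmark labels for a two-point reference axis (C0, C1)
AXIS_ORDER: tuple[str, ...] = ("ANT", "POST")
TWO_POINT_LEVELS: frozenset[str] = frozenset({"C0", "C1"})


class GeometryError(ValueError):
    """Degenerate landmark geometry (coincident midpoints, zero-length axis)."""


class SchemaError(ValueError):
    """Landmark input violates the image schema (missing/duplicate levels...)."""


def wrap_half_turn(angle_deg):
    """Wrap angles (degrees) into the half-turn interval (-90, +90].

    A line's orientation is only defined modulo 180 degrees; this fixes the
    representative.  Works on scalars and ndarrays.
    """
    wrapped = np.mod(np.asarray(angle_deg, dtype=float) + 90.0, 180.0) - 90.0
    # np.mod maps onto [-90, 90); move the closed end to +90
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    if np.ndim(angle_deg) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Point2D:
    """A sagittal-plane point in millimetres (x anterior, y cranial)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class VertebraLandmarks:
    """Landmarks of one vertebra in one image.

    ``four_corner`` mode carries the vertebral-body corners in the order
    AS, PS, PI, AI; ``two_point_axis`` carries an anterior point then a
    posterior point of the conventional reference line (used for C0/C1).
    """

    level: str
    mode: str
    points: tuple[Point2D, ...]

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise SchemaError(f"unknown vertebral level {self.level!r}")
        expected_mode = "two_point_axis" if self.level in TWO_POINT_LEVELS else "four_corner"
        if self.mode != expected_mode:
            raise SchemaError(f"level {self.level} must use mode {expected_mode!r}, got {self.mode!r}")
        object.__setattr__(self, "points", tuple(self.points))
        if self.mode == "two_point_axis":
            if len(self.points) != 2:
                raise SchemaError(f"{self.level}: two_point_axis needs 2 points, got {len(self.points)}")
            if self.points[0] == self.points[1]:
                raise GeometryError(f"{self.level}: the two axis points coincide")
        else:
            if len(self.points) != 4:
                raise SchemaError(f"{self.level}: four_corner needs 4 points, got {len(self.points)}")
            poly = Polygon([(p.x, p.y) for p in self.points])
            if not poly.is_valid or poly.area == 0.0:
                raise GeometryError(
                    f"{self.level}: corners do not form a simple quadrilateral "
                    "(check the AS, PS, PI, AI ordering)"
                )

    @classmethod
    def from_corners(cls, level: str, as_, ps, pi, ai) -> "VertebraLandmarks":
        pts = tuple(p if isinstance(p, Point2D) else Point2D(*p) for p in (as_, ps, pi, ai))
        return cls(level=level, mode="four_corner", points=pts)

    @classmethod
    def from_axis(cls, level: str, anterior, posterior) -> "VertebraLandmarks":
        pts = tuple(p if isinstance(p, Point2D) else Point2D(*p) for p in (anterior, posterior))
        return cls(level=level, mode="two_point_axis", points=pts)


@dataclass(frozen=True)
class MidplaneLine:
    """Oriented vertebral reference line: anchor point + anterior-pointing unit direction."""

    anchor: Point2D
    direction: tuple[float, float]
    level: str

    @property
    def orientation_deg(self) -> float:
        """Line orientation in degrees, in (-90, +90] (0 = horizontal)."""
        return wrap_half_turn(math.degrees(math.atan2(self.direction[1], self.direction[0])))


@dataclass
class JointAngleSet:
    """The seven signed intervertebral angles of one upright-position image."""

    image_id: object
    angles: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.angles) != set(JOINTS):
            raise SchemaError(
                f"image {self.image_id!r}: expected the 7 joints {list(JOINTS)}, got {sorted(self.angles)}"
            )


def _anterior_unit(vec: np.ndarray) -> tuple[float, float]:
    """Normalise and fix the sign so the direction points anteriorly (+x; ties: +y)."""
    d = vec / np.linalg.norm(vec)
    if d[0] < 0.0 or (d[0] == 0.0 and d[1] < 0.0):
        d = -d
    return (float(d[0]), float(d[1]))


def midplane_line(v: VertebraLandmarks) -> MidplaneLine:
    """Construct the vertebral midplane line from one vertebra's landmarks.

    For a four-corner body the line bisects the body: it joins the midpoint of
    the anterior corners (AS, AI) to the midpoint of the posterior corners
    (PS, PI).  For a two-point axis it joins the two supplied points.
    """
    pts = np.array([p.as_array() for p in v.points])
    if v.mode == "four_corner":
        ant_mid = (pts[0] + pts[3]) / 2.0  # AS, AI
        post_mid = (pts[1] + pts[2]) / 2.0  # PS, PI
    else:
        ant_mid, post_mid = pts[0], pts[1]
    chord = ant_mid - post_mid
    if np.linalg.norm(chord) < 1e-12:
        raise GeometryError(f"{v.level}: anterior and posterior midpoints coincide (degenerate body)")
    anchor = (ant_mid + post_mid) / 2.0
    return MidplaneLine(anchor=Point2D(*anchor), direction=_anterior_unit(chord), level=v.level)


def signed_angle(upper: MidplaneLine, lower: MidplaneLine) -> float:
    """Signed intervertebral angle (degrees) between adjacent midplane lines.

    Defined as orientation(lower) - orientation(upper), wrapped into
    (-90, +90]; positive means extension under the package's coordinate
    convention.  Antisymmetric in its arguments except exactly on the +90
    wrap boundary.
    """
    return wrap_half_turn(lower.orientation_deg - upper.orientation_deg)


def joint_angles(image: Iterable[VertebraLandmarks], image_id: object = None) -> JointAngleSet:
    """Compute the seven joint angles C0/C1..C6/C7 of one image.

    `image` must contain exactly one landmark set per level C0..C7.
    """
    by_level: dict[str, VertebraLandmarks] = {}
    for v in image:
        if v.level in by_level:
            raise SchemaError(f"image {image_id!r}: duplicate level {v.level}")
        by_level[v.level] = v
    if set(by_level) != set(LEVELS):
        raise SchemaError(
            f"image {image_id!r}: need one landmark set per level C0..C7, found {sorted(by_level)}"
        )
    lines = {lvl: midplane_line(by_level[lvl]) for lvl in LEVELS}
    angles = {
        joint: signed_angle(lines[upper], lines[lower])
        for joint, upper, lower in zip(JOINTS, LEVELS[:-1], LEVELS[1:])
    }
    return JointAngleSet(image_id=image_id, angles=angles)


# ---------------------------------------------------------------------------
# batch (whole-study) path
# ---------------------------------------------------------------------------

IMAGE_KEY = ["subject_id", "condition", "position"]


def _required_landmarks(level: str) -> tuple[str, ...]:
    return AXIS_ORDER if level in TWO_POINT_LEVELS else CORNER_ORDER


def angle_table(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Joint angles for every image of a long-format landmark table.

    `landmarks` uses the study schema (columns subject_id, condition,
    position, level, landmark, x_mm, y_mm).  Returns a DataFrame indexed by
    (subject_id, condition, position) with one column per joint, in degrees.
    Uses the same midpoint construction as :func:`midplane_line`, vectorised
    over all images.
    """
    wide = landmarks.pivot_table(
        index=IMAGE_KEY,
        columns=["level", "landmark"],
        values=["x_mm", "y_mm"],
        aggfunc="first",
    )
    n_images = len(wide)

    def col(coord: str, level: str, lm: str) -> np.ndarray:
        key = (coord, level, lm)
        if key not in wide.columns:
            raise SchemaError(f"landmark {lm} missing for level {level}")
        vals = wide[key].to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = wide.index[np.isnan(vals)][0]
            raise SchemaError(f"image {bad}: missing landmark {lm} at level {level}")
        return vals

    orient = np.empty((n_images, len(LEVELS)))
    for i, lvl in enumerate(LEVELS):
        if lvl in TWO_POINT_LEVELS:
            ax, ay = col("x_mm", lvl, "ANT"), col("y_mm", lvl, "ANT")
            px, py = col("x_mm", lvl, "POST"), col("y_mm", lvl, "POST")
        else:
            ax = (col("x_mm", lvl, "AS") + col("x_mm", lvl, "AI")) / 2.0
            ay = (col("y_mm", lvl, "AS") + col("y_mm", lvl, "AI")) / 2.0
            px = (col("x_mm", lvl, "PS") + col("x_mm", lvl, "PI")) / 2.0
            py = (col("y_mm", lvl, "PS") + col("y_mm", lvl, "PI")) / 2.0
        dx, dy = ax - px, ay - py
        if np.any((dx == 0.0) & (dy == 0.0)):
            bad = wide.index[(dx == 0.0) & (dy == 0.0)][0]
            raise GeometryError(f"image {bad}: degenerate geometry at level {lvl}")
        orient[:, i] = wrap_half_turn(np.degrees(np.arctan2(dy, dx)))

    angles = wrap_half_turn(orient[:, 1:] - orient[:, :-1])
    return pd.DataFrame(angles, index=wide.index, columns=list(JOINTS))


def landmarks_to_objects(image_rows: pd.DataFrame) -> list[VertebraLandmarks]:
    """Convert one image's schema rows into validated VertebraLandmarks objects."""
    out: list[VertebraLandmarks] = []
    for lvl in LEVELS:
        rows = image_rows[image_rows["level"] == lvl]
        wanted = _required_landmarks(lvl)
        pts: dict[str, Point2D] = {}
        for lm in wanted:
            sel = rows[rows["landmark"] == lm]
            if len(sel) != 1:
                raise SchemaError(f"level {lvl}: expected exactly one {lm} landmark, found {len(sel)}")
            pts[lm] = Point2D(float(sel["x_mm"].iloc[0]), float(sel["y_mm"].iloc[0]))
        if lvl in TWO_POINT_LEVELS:
            out.append(VertebraLandmarks.from_axis(lvl, pts["ANT"], pts["POST"]))
        else:
            out.append(VertebraLandmarks.from_corners(lvl, pts["AS"], pts["PS"], pts["PI"], pts["AI"]))
    return out
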