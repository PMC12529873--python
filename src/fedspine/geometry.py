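"""Landmark schema and lumbopelvic angle geometry.

The sagittal annotation scheme has 29 keypoints: the four corners of the six
vertebral bodies T12–L5 (24), the anterior/posterior extremes and midpoint of
the superior sacral endplate (3), and the two femoral head centers (2).

From these landmarks the four lumbopelvic parameters are computed with the
standard clinical (Duval-Beaupère) definitions:

* Sacral slope (SS): acute angle between the superior sacral endplate and the
  horizontal.
* Pelvic tilt (PT): signed angle between the vertical and the segment joining
  the bicoxofemoral point H (midpoint of the femoral head centers) to the
  sacral endplate midpoint M; positive when M lies posterior to H.
* Pelvic incidence (PI): angle between the perpendicular to the sacral
  endplate at M and the segment M→H. Satisfies PI = PT + SS.
* Lumbar lordosis (LL): sagittal angle between the superior endplate of an
  upper lumbar vertebra (L1 by default, T12 selectable) and the sacral
  endplate, positive for lordotic (posteriorly opening) curvature.

Coordinates follow the image convention: continuous, 0-based, pixel centers,
origin at the top-left, y pointing down.  Which screen direction is anterior
is recorded explicitly per image (`Facing`), so all angle computations are
performed in a canonical frame with anterior = +x.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Landmark schema
# --------------------------------------------------------------------------

VERTEBRAE: tuple[str, ...] = ("T12", "L1", "L2", "L3", "L4", "L5")
CORNERS: tuple[str, ...] = (
    "anterior_superior",
    "posterior_superior",
    "anterior_inferior",
    "posterior_inferior",
)
SACRUM_POINTS: tuple[str, ...] = ("S1_anterior", "S1_posterior", "S1_midpoint")
FEMORAL_POINTS: tuple[str, ...] = ("femoral_head_left", "femoral_head_right")

#: Canonical ordering of the 29 landmark names.
LANDMARK_NAMES: tuple[str, ...] = (
    tuple(f"{v}_{c}" for v in VERTEBRAE for c in CORNERS)
    + SACRUM_POINTS
    + FEMORAL_POINTS
)

N_LANDMARKS = len(LANDMARK_NAMES)  # 29

#: Anatomical grouping used for per-level error reporting.
LEVELS: dict[str, tuple[str, ...]] = {
    **{v: tuple(f"{v}_{c}" for c in CORNERS) for v in VERTEBRAE},
    "sacrum": SACRUM_POINTS,
    "femoral_heads": FEMORAL_POINTS,
}

_DEGENERATE_TOL = 1e-9


class Facing(str, enum.Enum):
    """Screen direction of the patient's anterior side."""

    ANTERIOR_IS_PLUS_X = "anterior_is_plus_x"
    ANTERIOR_IS_MINUS_X = "anterior_is_minus_x"


class InvalidGeometryError(ValueError):
    """Raised when landmarks are degenerate for an angle computation."""


class UnitError(ValueError):
    """Raised when physical units of two landmark sets are inconsistent."""


@dataclass
class LandmarkSet:
    """The named keypoints of one sagittal image.

    Parameters
    ----------
    points
        Mapping landmark name -> (x, y) continuous pixel coordinates.
    pixel_spacing_mm
        Isotropic physical pixel size, mm per pixel (> 0).
    facing
        Which screen direction is anatomically anterior.
    image_size
        (width, height) of the image in pixels.
    """

    points: dict[str, tuple[float, float]]
    pixel_spacing_mm: float
    facing: Facing = Facing.ANTERIOR_IS_PLUS_X
    image_size: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.pixel_spacing_mm > 0:
            raise UnitError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")
        self.facing = Facing(self.facing)

    def point(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.points[name], dtype=float)
        except KeyError:
            raise InvalidGeometryError(f"landmark {name!r} is missing") from None

    def canonical(self, name: str) -> np.ndarray:
        """Coordinates in the canonical frame (anterior = +x, y down)."""
        p = self.point(name)
        if self.facing is Facing.ANTERIOR_IS_MINUS_X:
            p = np.array([-p[0], p[1]])
        return p

    def with_points(self, points: dict[str, tuple[float, float]]) -> "LandmarkSet":
        return LandmarkSet(points, self.pixel_spacing_mm, self.facing, self.image_size)


@dataclass(frozen=True)
class AngleSet:
    """The four lumbopelvic parameters, in degrees."""

    SS: float
    PT: float
    PI: float
    LL: float

    def as_dict(self) -> dict[str, float]:
        return {"SS": self.SS, "PT": self.PT, "PI": self.PI, "LL": self.LL}


ANGLE_NAMES = ("SS", "PI", "PT", "LL")


@dataclass(frozen=True)
class LandmarkError:
    """Euclidean localization errors in millimetres."""

    per_point: dict[str, float]
    per_level: dict[str, float]

    @property
    def mean_mm(self) -> float:
        return float(np.mean(list(self.per_point.values())))


# --------------------------------------------------------------------------
# Angle computations
# --------------------------------------------------------------------------


def _line_angle_deg(lm: LandmarkSet, anterior_name: str, posterior_name: str) -> float:
    """Signed slope of an endplate line in the canonical frame.

    Positive when the anterior end of the line lies lower (larger y) than the
    posterior end, which is the usual orientation of the sacral endplate.
    """
    d = lm.canonical(anterior_name) - lm.canonical(posterior_name)
    n = math.hypot(d[0], d[1])
    if n < _DEGENERATE_TOL:
        raise InvalidGeometryError(
            f"degenerate endplate: {anterior_name} == {posterior_name}"
        )
    if d[0] < 0:  # endplates are undirected lines
        d = -d
    return math.degrees(math.atan2(d[1], d[0]))


def _sacral_slope_signed(lm: LandmarkSet) -> float:
    return _line_angle_deg(lm, "S1_anterior", "S1_posterior")


def _bicoxofemoral_point(lm: LandmarkSet) -> np.ndarray:
    return 0.5 * (lm.canonical("femoral_head_left") + lm.canonical("femoral_head_right"))


def compute_SS(lm: LandmarkSet) -> float:
    """Sacral slope: unsigned acute angle of the sacral endplate, degrees."""
    return abs(_sacral_slope_signed(lm))


def compute_PT(lm: LandmarkSet) -> float:
    """Pelvic tilt, degrees, positive when M lies posterior to H."""
    v = _bicoxofemoral_point(lm) - lm.canonical("S1_midpoint")  # M -> H
    if math.hypot(v[0], v[1]) < _DEGENERATE_TOL:
        raise InvalidGeometryError("bicoxofemoral point coincides with sacral midpoint")
    # Angle of M->H measured from the downward vertical, positive anterior:
    # equals the angle of H->M from the upward vertical, positive posterior.
    return math.degrees(math.atan2(v[0], v[1]))


def compute_PI(lm: LandmarkSet) -> float:
    """Pelvic incidence, degrees.

    Signed angle at M between the caudal perpendicular to the sacral endplate
    and the segment M→H, positive when H lies anterior to the perpendicular.
    Geometrically identical to PT + SS for any valid landmark set.
    """
    m = lm.canonical("S1_midpoint")
    h = _bicoxofemoral_point(lm)
    v = h - m
    if math.hypot(v[0], v[1]) < _DEGENERATE_TOL:
        raise InvalidGeometryError("bicoxofemoral point coincides with sacral midpoint")
    d = lm.canonical("S1_anterior") - lm.canonical("S1_posterior")
    if math.hypot(d[0], d[1]) < _DEGENERATE_TOL:
        raise InvalidGeometryError("degenerate sacral endplate")
    if d[0] < 0:
        d = -d
    n = np.array([-d[1], d[0]])  # caudal (downward) endplate normal
    theta_mh = math.atan2(v[0], v[1])
    theta_n = math.atan2(n[0], n[1])
    pi = math.degrees(theta_mh - theta_n)
    # wrap to (-180, 180]
    if pi > 180.0:
        pi -= 360.0
    elif pi <= -180.0:
        pi += 360.0
    return pi


def compute_LL(lm: LandmarkSet, upper_level: str = "L1") -> float:
    """Lumbar lordosis, degrees, positive for lordotic curvature.

    Angle between the superior endplate of ``upper_level`` (L1 or T12) and
    the sacral endplate.
    """
    if upper_level not in ("L1", "T12"):
        raise ValueError(f"upper_level must be 'L1' or 'T12', got {upper_level!r}")
    theta_sacral = _sacral_slope_signed(lm)
    theta_upper = _line_angle_deg(
        lm, f"{upper_level}_anterior_superior", f"{upper_level}_posterior_superior"
    )
    return theta_sacral - theta_upper


def compute_angles(lm: LandmarkSet, upper_level: str = "L1") -> AngleSet:
    """All four lumbopelvic parameters from one landmark set."""
    return AngleSet(
        SS=compute_SS(lm),
        PT=compute_PT(lm),
        PI=compute_PI(lm),
        LL=compute_LL(lm, upper_level=upper_level),
    )


# --------------------------------------------------------------------------
# Error metrics
# --------------------------------------------------------------------------


def landmark_error(pred: LandmarkSet, gt: LandmarkSet) -> LandmarkError:
    """Per-point and per-level Euclidean distances in millimetres."""
    if not math.isclose(pred.pixel_spacing_mm, gt.pixel_spacing_mm, rel_tol=1e-9):
        raise UnitError(
            f"pixel spacing mismatch: {pred.pixel_spacing_mm} vs {gt.pixel_spacing_mm}"
        )
    if set(pred.points) != set(gt.points):
        raise ValueError("landmark sets have different schemas")
    spacing = gt.pixel_spacing_mm
    per_point = {
        name: float(np.linalg.norm(pred.point(name) - gt.point(name)) * spacing)
        for name in gt.points
    }
    per_level = {
        level: float(np.mean([per_point[n] for n in names]))
        for level, names in LEVELS.items()
        if all(n in per_point for n in names)
    }
    return LandmarkError(per_point=per_point, per_level=per_level)


def angle_abs_error(pred: AngleSet, gt: AngleSet) -> dict[str, float]:
    """Per-angle absolute difference |pred - gt| in degrees."""
    p, g = pred.as_dict(), gt.as_dict()
    return {k: abs(p[k] - g[k]) for k in p}


# --------------------------------------------------------------------------
# Annotation validation (inclusion filter)
# --------------------------------------------------------------------------


def validate_annotation(lm: LandmarkSet) -> list[str]:
    """Check one annotation against the inclusion rule.

    An image is includable only when every landmark of the schema is present,
    finite, and inside the field of view; this mirrors the exclusion of
    images without complete landmark visibility.  Returns a list of violation
    strings; an empty list means the sample is includable.
    """
    violations: list[str] = []
    w, h = lm.image_size
    for name in LANDMARK_NAMES:
        if name not in lm.points:
            violations.append(f"missing_landmark:{name}")
            continue
        x, y = lm.points[name]
        if not (math.isfinite(x) and math.isfinite(y)):
            violations.append(f"non_finite_coordinate:{name}")
            continue
        if w > 0 and h > 0:
            if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
                violations.append(f"out_of_field:{name}")
    for name in lm.points:
        if name not in LANDMARK_NAMES:
            violations.append(f"unknown_landmark:{name}")
    return violations


# --------------------------------------------------------------------------
# Annotation file I/O
# --------------------------------------------------------------------------


@dataclass
class Annotation:
    """One image's landmark annotation with study identifiers."""

    image_id: str
    patient_id: str
    center_id: str
    visit: int
    landmarks: LandmarkSet

    def to_record(self) -> dict:
        return {
            "image_id": self.image_id,
            "patient_id": self.patient_id,
            "center_id": self.center_id,
            "visit": self.visit,
            "pixel_spacing_mm": self.landmarks.pixel_spacing_mm,
            "facing": self.landmarks.facing.value,
            "image_size": list(self.landmarks.image_size),
            "points": {k: [float(v[0]), float(v[1])] for k, v in self.landmarks.points.items()},
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Annotation":
        lm = LandmarkSet(
            points={k: (float(v[0]), float(v[1])) for k, v in rec["points"].items()},
            pixel_spacing_mm=float(rec["pixel_spacing_mm"]),
            facing=Facing(rec["facing"]),
            image_size=tuple(rec.get("image_size", (0, 0))),
        )
        return cls(
            image_id=str(rec["image_id"]),
            patient_id=str(rec["patient_id"]),
            center_id=str(rec["center_id"]),
            visit=int(rec["visit"]),
            landmarks=lm,
        )


def write_annotations_json(annotations: list[Annotation], path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_record() for a in annotations], fh, indent=1, sort_keys=True)


def read_annotations_json(path) -> list[Annotation]:
    with open(path) as fh:
        return [Annotation.from_record(rec) for rec in json.load(fh)]


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    """Flat dialect: one row per landmark point."""
    rows = []
    for a in annotations:
        for name, (x, y) in a.landmarks.points.items():
            rows.append(
                {
                    "image_id": a.image_id,
                    "patient_id": a.patient_id,
                    "center_id": a.center_id,
                    "visit": a.visit,
                    "pixel_spacing_mm": a.landmarks.pixel_spacing_mm,
                    "facing": a.landmarks.facing.value,
                    "image_width": a.landmarks.image_size[0],
                    "image_height": a.landmarks.image_size[1],
                    "landmark": name,
                    "x": x,
                    "y": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations_csv(path) -> list[Annotation]:
    df = pd.read_csv(path)
    annotations = []
    for image_id, grp in df.groupby("image_id", sort=False):
        first = grp.iloc[0]
        lm = LandmarkSet(
            points={r.landmark: (float(r.x), float(r.y)) for r in grp.itertuples()},
            pixel_spacing_mm=float(first.pixel_spacing_mm),
            facing=Facing(first.facing),
            image_size=(int(first.image_width), int(first.image_height)),
        )
        annotations.append(
            Annotation(
                image_id=str(image_id),
                patient_id=str(first.patient_id),
                center_id=str(first.center_id),
                visit=int(first.visit),
                landmarks=lm,
            )
        )
    return annotations
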