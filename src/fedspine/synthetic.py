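"""Synthetic multi-hospital spine-radiograph cohorts.

Real sagittal radiographs cannot be redistributed, so this module generates
pseudo-radiographs whose ground truth is exact by construction: lumbopelvic
angles are sampled from center-specific distributions, a landmark skeleton is
built so that recomputing SS/PT/PI/LL from the landmarks returns the sampled
angles (the closure contract), and a stylized image is rendered around the
landmarks with center-specific appearance (intensity, contrast, noise,
occasional occluding bars standing in for instrumentation).

The default four-center configuration mirrors the statistical structure of a
cross-silo study: unequal center sizes (45/35/14/6% of patients), 3–4
follow-up images per patient with small between-visit angle changes, and real
between-center heterogeneity in both angle distributions and image
appearance (one smaller center is younger and more variable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk, line_aa

from .geometry import (
    Annotation,
    AngleSet,
    Facing,
    InvalidGeometryError,
    LandmarkSet,
    compute_angles,
    write_annotations_csv,
    write_annotations_json,
)
from .utils import derive_seed

# --------------------------------------------------------------------------
# Center profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CenterProfile:
    """Generative description of one hospital's cohort.

    Angles: PI ~ N(pi_mean, pi_sd); PT = PI * f with f ~ N(pt_fraction_mean,
    pt_fraction_sd); SS = PI - PT; LL = ll_slope * PI + ll_intercept +
    N(0, ll_sd).  Appearance: affine intensity transform plus Gaussian pixel
    noise and occasional occluding bars.
    """

    center_id: str
    share: float
    pi_mean: float = 52.0
    pi_sd: float = 9.0
    pt_fraction_mean: float = 0.25
    pt_fraction_sd: float = 0.06
    ll_slope: float = 0.9
    ll_intercept: float = 10.0
    ll_sd: float = 5.0
    intensity_shift: float = 0.0
    contrast_scale: float = 1.0
    noise_sd: float = 0.03
    occlusion_prob: float = 0.1
    visits_min: int = 3
    visits_max: int = 4

    def __post_init__(self) -> None:
        if self.pi_sd < 0 or self.pt_fraction_sd < 0 or self.ll_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.visits_min > self.visits_max or self.visits_min < 1:
            raise ValueError("need 1 <= visits_min <= visits_max")


#: Four centers emulating one large, one medium and two small hospitals;
#: the smallest center has a younger, more diverse cohort (lower mean PI,
#: larger spread) and the noisiest images.
DEFAULT_PROFILES: tuple[CenterProfile, ...] = (
    CenterProfile("BCN", 0.45, pi_mean=54, pi_sd=9, pt_fraction_mean=0.26,
                  ll_slope=0.85, ll_intercept=12, intensity_shift=0.00,
                  contrast_scale=1.00, noise_sd=0.03, occlusion_prob=0.10),
    CenterProfile("BOR", 0.35, pi_mean=50, pi_sd=8, pt_fraction_mean=0.24,
                  ll_slope=0.90, ll_intercept=8, intensity_shift=0.06,
                  contrast_scale=0.90, noise_sd=0.05, occlusion_prob=0.10),
    CenterProfile("MAD", 0.14, pi_mean=58, pi_sd=10, pt_fraction_mean=0.30,
                  pt_fraction_sd=0.07, ll_slope=0.80, ll_intercept=14,
                  ll_sd=6, intensity_shift=-0.05, contrast_scale=1.15,
                  noise_sd=0.04, occlusion_prob=0.08),
    CenterProfile("IST", 0.06, pi_mean=42, pi_sd=12, pt_fraction_mean=0.20,
                  pt_fraction_sd=0.08, ll_slope=0.95, ll_intercept=6,
                  ll_sd=7, intensity_shift=0.03, contrast_scale=1.05,
                  noise_sd=0.07, occlusion_prob=0.18),
)


@dataclass
class SpineSample:
    """One synthetic image with exact ground truth."""

    image: np.ndarray  # (H, W) grayscale in [0, 1]
    landmarks: LandmarkSet
    true_angles: AngleSet
    patient_id: str
    center_id: str
    visit: int
    seed_trace: tuple[int, ...] = ()

    @property
    def image_id(self) -> str:
        return f"{self.patient_id}-V{self.visit}"

    def to_annotation(self) -> Annotation:
        return Annotation(
            image_id=self.image_id,
            patient_id=self.patient_id,
            center_id=self.center_id,
            visit=self.visit,
            landmarks=self.landmarks,
        )


# --------------------------------------------------------------------------
# Angle sampling
# --------------------------------------------------------------------------


def _sample_angles_rng(profile: CenterProfile, rng: np.random.Generator) -> AngleSet:
    for _ in range(200):
        pi = rng.normal(profile.pi_mean, profile.pi_sd)
        f = rng.normal(profile.pt_fraction_mean, profile.pt_fraction_sd)
        pt = pi * f
        ss = pi - pt
        ll = profile.ll_slope * pi + profile.ll_intercept + rng.normal(0.0, profile.ll_sd)
        if 1.0 <= ss <= 85.0 and -80.0 < pt < 80.0 and -80.0 < ll < 170.0:
            return AngleSet(SS=ss, PT=pt, PI=pi, LL=ll)
    # pathological profile: clamp to the valid ranges while keeping PI = PT + SS
    pi = float(np.clip(profile.pi_mean, 20.0, 85.0))
    f = float(np.clip(profile.pt_fraction_mean, 0.05, 0.6))
    pt = pi * f
    ll = float(np.clip(profile.ll_slope * pi + profile.ll_intercept, -80.0, 170.0))
    return AngleSet(SS=pi - pt, PT=pt, PI=pi, LL=ll)


def sample_angles(profile: CenterProfile, rng_seed: int) -> AngleSet:
    """Draw one patient's lumbopelvic angles; deterministic per seed.

    PI = PT + SS holds exactly by construction; draws falling outside the
    valid angle ranges are rejected and redrawn.
    """
    return _sample_angles_rng(profile, np.random.default_rng(rng_seed))


# --------------------------------------------------------------------------
# Landmark construction
# --------------------------------------------------------------------------

# Nominal adult anatomy, millimetres; scaled down uniformly when the canvas
# is too small to hold it at the requested pixel spacing.
_SACRAL_PLATE_MM = 35.0
_VERTEBRA_HEIGHT_MM = 24.0
_DISC_HEIGHT_MM = 9.0
_VERTEBRA_WIDTH_MM = 34.0
_PELVIC_THICKNESS_MM = 65.0
_FEMORAL_OFFSET_MM = 4.0

_STACK_BOTTOM_UP = ("L5", "L4", "L3", "L2", "L1", "T12")


def _upn(phi: float) -> np.ndarray:
    """Cranial (upward) unit normal of an endplate with slope ``phi`` rad."""
    return np.array([math.sin(phi), -math.cos(phi)])


def build_landmarks(
    angles: AngleSet,
    morphology_seed: int,
    canvas: tuple[int, int] = (256, 256),
    spacing_mm: float = 0.5,
    facing: Facing = Facing.ANTERIOR_IS_PLUS_X,
) -> LandmarkSet:
    """Construct a 29-landmark skeleton realizing the given angles exactly.

    The sacral endplate is placed at slope SS, the bicoxofemoral point at
    angle PT from the vertical below-anterior of the sacral midpoint, and the
    lumbar column along a curve whose endplate slopes interpolate from the
    sacral plate to the L1 superior plate (which subtends exactly LL with the
    sacral plate).  Per-vertebra heights and widths are jittered by
    ``morphology_seed``.  If the skeleton leaves the canvas the anatomy is
    retried at progressively smaller scale; landmarks are stored as
    continuous coordinates, so recomputing the angles from the result matches
    ``angles`` to well below 1e-6 degrees.
    """
    w, h = canvas
    rng = np.random.default_rng(morphology_seed)
    # all stochastic morphology drawn once so the retry loop is deterministic
    jit = {
        "anchor": rng.uniform(-0.02, 0.02, size=2),
        "plate_len": _SACRAL_PLATE_MM * rng.uniform(0.95, 1.05),
        "pelvic_t": _PELVIC_THICKNESS_MM * rng.uniform(0.92, 1.08),
        "fem_dx": _FEMORAL_OFFSET_MM * rng.uniform(0.8, 1.2),
        "fem_dy": rng.uniform(-1.0, 1.0),
        "heights": _VERTEBRA_HEIGHT_MM * rng.uniform(0.90, 1.10, size=6),
        "discs": _DISC_HEIGHT_MM * rng.uniform(0.85, 1.15, size=6),
        "widths": _VERTEBRA_WIDTH_MM
        * (1.0 - 0.015 * np.arange(6))
        * rng.uniform(0.92, 1.08, size=6),
        "plate_jit": np.deg2rad(rng.uniform(-2.0, 2.0, size=(6, 2))),
    }
    scale = 1.0
    for _ in range(15):
        pts = _construct(angles, jit, scale, canvas, spacing_mm)
        xy = np.array(list(pts.values()))
        if (
            xy[:, 0].min() >= 1.0
            and xy[:, 1].min() >= 1.0
            and xy[:, 0].max() <= w - 2.0
            and xy[:, 1].max() <= h - 2.0
        ):
            if facing is Facing.ANTERIOR_IS_MINUS_X:
                pts = {k: ((w - 1.0) - x, y) for k, (x, y) in pts.items()}
            return LandmarkSet(
                points=pts,
                pixel_spacing_mm=spacing_mm,
                facing=facing,
                image_size=canvas,
            )
        scale *= 0.85
    raise InvalidGeometryError(
        f"could not fit anatomy with angles {angles} on canvas {canvas}"
    )


def _construct(
    angles: AngleSet,
    jit: dict,
    scale: float,
    canvas: tuple[int, int],
    spacing_mm: float,
) -> dict[str, tuple[float, float]]:
    w, h = canvas

    def px(mm: float) -> float:
        return mm * scale / spacing_mm

    ss = math.radians(angles.SS)
    pt = math.radians(angles.PT)
    ll = math.radians(angles.LL)

    m = np.array(
        [(0.58 + jit["anchor"][0]) * w, (0.68 + jit["anchor"][1]) * h]
    )
    pts: dict[str, tuple[float, float]] = {}

    # sacral endplate at slope SS (anterior end lower, y down)
    d = np.array([math.cos(ss), math.sin(ss)])
    half = 0.5 * px(jit["plate_len"])
    pts["S1_anterior"] = tuple(m + half * d)
    pts["S1_posterior"] = tuple(m - half * d)
    pts["S1_midpoint"] = tuple(m)

    # bicoxofemoral point at angle PT from the downward vertical
    hpt = m + px(jit["pelvic_t"]) * np.array([math.sin(pt), math.cos(pt)])
    off = np.array([px(jit["fem_dx"]), px(jit["fem_dy"])])
    pts["femoral_head_left"] = tuple(hpt + off)
    pts["femoral_head_right"] = tuple(hpt - off)

    # lumbar column: superior-plate slopes interpolate from SS to SS - LL;
    # the L1 superior plate (k = 5) is exact so LL closes, the rest jittered
    cur = m.copy()
    phi_prev = ss
    for k, name in enumerate(_STACK_BOTTOM_UP, start=1):
        sup = ss - ll * k / 5.0
        inf = ss - ll * (k - 0.6) / 5.0
        if name not in ("L1",):
            sup += jit["plate_jit"][k - 1, 0]
        inf += jit["plate_jit"][k - 1, 1]
        m_inf = cur + px(jit["discs"][k - 1]) * _upn(0.5 * (phi_prev + inf))
        m_sup = m_inf + px(jit["heights"][k - 1]) * _upn(0.5 * (inf + sup))
        half_w = 0.5 * px(jit["widths"][k - 1])
        e_inf = np.array([math.cos(inf), math.sin(inf)])
        e_sup = np.array([math.cos(sup), math.sin(sup)])
        pts[f"{name}_anterior_inferior"] = tuple(m_inf + half_w * e_inf)
        pts[f"{name}_posterior_inferior"] = tuple(m_inf - half_w * e_inf)
        pts[f"{name}_anterior_superior"] = tuple(m_sup + half_w * e_sup)
        pts[f"{name}_posterior_superior"] = tuple(m_sup - half_w * e_sup)
        cur = m_sup
        phi_prev = sup
    return pts


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def render_image(
    lm: LandmarkSet, profile: CenterProfile, rng_seed: int
) -> np.ndarray:
    """Render a stylized pseudo-radiograph around the landmarks.

    Vertebral outlines and the sacral plate are drawn as bright anti-aliased
    strokes, femoral heads as filled circles, on a soft-tissue-like gradient
    background; the profile's intensity shift, contrast scale, pixel noise
    and (with some probability) an occluding bar are then applied.  The
    landmarks themselves are never modified.
    """
    w, h = lm.image_size
    rng = np.random.default_rng(rng_seed)
    img = 0.20 + 0.08 * np.linspace(0.0, 1.0, h)[:, None] * np.ones((h, w))

    def stroke(p0, p1, value=0.85):
        r0, c0 = int(round(p0[1])), int(round(p0[0]))
        r1, c1 = int(round(p1[1])), int(round(p1[0]))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        img[rr, cc] = np.maximum(img[rr, cc], value * val)

    for v in _STACK_BOTTOM_UP:
        c = {s: lm.points[f"{v}_{s}"] for s in
             ("anterior_superior", "posterior_superior",
              "anterior_inferior", "posterior_inferior")}
        stroke(c["anterior_superior"], c["posterior_superior"])
        stroke(c["posterior_superior"], c["posterior_inferior"])
        stroke(c["posterior_inferior"], c["anterior_inferior"])
        stroke(c["anterior_inferior"], c["anterior_superior"])
    stroke(lm.points["S1_anterior"], lm.points["S1_posterior"], value=0.95)

    plate_len = np.linalg.norm(
        np.asarray(lm.points["S1_anterior"]) - np.asarray(lm.points["S1_posterior"])
    )
    radius = max(1.5, 0.30 * plate_len)
    for name in ("femoral_head_left", "femoral_head_right"):
        x, y = lm.points[name]
        rr, cc = disk((y, x), radius, shape=(h, w))
        img[rr, cc] = np.maximum(img[rr, cc], 0.55)

    if rng.uniform() < profile.occlusion_prob:
        # instrumentation surrogate: a bright bar; landmarks stay untouched
        x0 = int(rng.integers(0, max(1, w - 3)))
        bw = int(rng.integers(2, max(3, w // 16)))
        img[:, x0 : min(w, x0 + bw)] = 0.95

    img = img * profile.contrast_scale + profile.intensity_shift
    if profile.noise_sd > 0:
        img = img + rng.normal(0.0, profile.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# --------------------------------------------------------------------------
# Cohort generation and splitting
# --------------------------------------------------------------------------


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Floors the exact quotas and hands the remaining units to the largest
    fractional parts, ties broken by position — fully deterministic.
    """
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = sorted(range(len(weights)), key=lambda i: (-(quota[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    profiles: list[CenterProfile] | tuple[CenterProfile, ...] = DEFAULT_PROFILES,
    n_patients: int = 120,
    rng_seed: int = 0,
    canvas: tuple[int, int] = (256, 256),
    spacing_mm: float = 0.5,
) -> list[SpineSample]:
    """Generate a deterministic multi-center cohort of annotated images.

    Patients are apportioned to centers by their share (largest-remainder
    rounding); each patient receives 3–4 visits (per the profile) whose
    angles differ by at most ~2 degrees from the patient's baseline.
    """
    if n_patients < len(profiles):
        raise ValueError("need at least one patient per center")
    shares = np.array([p.share for p in profiles])
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError(f"center shares must sum to 1, got {shares.sum()}")
    counts = largest_remainder(shares, n_patients)

    samples: list[SpineSample] = []
    for ci, (profile, n_c) in enumerate(zip(profiles, counts)):
        for j in range(int(n_c)):
            rng = np.random.default_rng(
                np.random.SeedSequence([rng_seed, ci, j])
            )
            base = _sample_angles_rng(profile, rng)
            morph_seed = int(rng.integers(2**31))
            n_visits = int(rng.integers(profile.visits_min, profile.visits_max + 1))
            patient_id = f"{profile.center_id}-P{j:03d}"
            for v in range(1, n_visits + 1):
                dpi = rng.uniform(-1.5, 1.5)
                dll = rng.uniform(-1.5, 1.5)
                pi_v = base.PI + dpi
                pt_v = pi_v * (base.PT / base.PI)
                target = AngleSet(SS=pi_v - pt_v, PT=pt_v, PI=pi_v, LL=base.LL + dll)
                lm = build_landmarks(
                    target, morph_seed, canvas=canvas, spacing_mm=spacing_mm
                )
                img_seed = derive_seed(rng_seed, ci, j, v)
                image = render_image(lm, profile, img_seed)
                samples.append(
                    SpineSample(
                        image=image.astype(np.float32),
                        landmarks=lm,
                        true_angles=compute_angles(lm),
                        patient_id=patient_id,
                        center_id=profile.center_id,
                        visit=v,
                        seed_trace=(rng_seed, ci, j, v, img_seed),
                    )
                )
    return samples


@dataclass
class SplitAssignment:
    """Patient-level train/validation/test assignment."""

    by_image: dict[str, str]
    by_patient: dict[str, str]

    def images(self, split: str) -> list[str]:
        return [i for i, s in self.by_image.items() if s == split]

    def of(self, image_id: str) -> str:
        return self.by_image[image_id]

    def patients(self, split: str) -> set[str]:
        return {p for p, s in self.by_patient.items() if s == split}


SPLITS = ("train", "validation", "test")


def split_cohort(
    samples: list[SpineSample],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
) -> SplitAssignment:
    """Center-stratified random split at the patient level.

    Within each center, patients are shuffled and apportioned to
    train/validation/test at the requested fractions (largest-remainder
    rounding, so per-center counts are within one patient of the targets).
    All images of a patient share one split, preventing leakage.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    centers: dict[str, list[str]] = {}
    patient_center: dict[str, str] = {}
    for s in samples:
        if s.patient_id not in patient_center:
            centers.setdefault(s.center_id, []).append(s.patient_id)
            patient_center[s.patient_id] = s.center_id

    by_patient: dict[str, str] = {}
    for ci, center in enumerate(sorted(centers)):
        patients = sorted(centers[center])
        if len(patients) < 3:
            warnings.warn(
                f"center {center} has {len(patients)} patient(s); "
                "some splits will be empty",
                stacklevel=2,
            )
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, ci]))
        rng.shuffle(patients)
        counts = largest_remainder(np.array(fractions), len(patients))
        idx = 0
        for split, n in zip(SPLITS, counts):
            for p in patients[idx : idx + n]:
                by_patient[p] = split
            idx += n
    by_image = {s.image_id: by_patient[s.patient_id] for s in samples}
    return SplitAssignment(by_image=by_image, by_patient=by_patient)


def samples_in_split(
    samples: list[SpineSample], split: SplitAssignment, name: str,
    center: str | None = None,
) -> list[SpineSample]:
    return [
        s
        for s in samples
        if split.of(s.image_id) == name and (center is None or s.center_id == center)
    ]


# --------------------------------------------------------------------------
# On-disk cohort format
# --------------------------------------------------------------------------


def write_cohort(samples: list[SpineSample], outdir) -> None:
    """Write PNG images plus JSON/CSV annotations."""
    import os

    os.makedirs(outdir, exist_ok=True)
    annotations = []
    for s in samples:
        iio.imwrite(
            os.path.join(outdir, f"{s.image_id}.png"),
            (np.clip(s.image, 0, 1) * 255).astype(np.uint8),
        )
        annotations.append(s.to_annotation())
    write_annotations_json(annotations, os.path.join(outdir, "annotations.json"))
    write_annotations_csv(annotations, os.path.join(outdir, "annotations.csv"))


def write_split(split: SplitAssignment, samples: list[SpineSample], path) -> None:
    import pandas as pd

    rows = [
        {
            "image_id": s.image_id,
            "patient_id": s.patient_id,
            "center_id": s.center_id,
            "split": split.of(s.image_id),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(indir) -> list[SpineSample]:
    """Load a cohort written by :func:`write_cohort`.

    Landmarks (and hence ground-truth angles) are exact; images come back
    8-bit quantized.
    """
    import os

    from .geometry import read_annotations_json

    annotations = read_annotations_json(os.path.join(indir, "annotations.json"))
    samples = []
    for a in annotations:
        img = iio.imread(os.path.join(indir, f"{a.image_id}.png"))
        samples.append(
            SpineSample(
                image=np.asarray(img, dtype=np.float32) / 255.0,
                landmarks=a.landmarks,
                true_angles=compute_angles(a.landmarks),
                patient_id=a.patient_id,
                center_id=a.center_id,
                visit=a.visit,
            )
        )
    return samples


def read_split(path) -> SplitAssignment:
    import pandas as pd

    df = pd.read_csv(path)
    by_image = dict(zip(df["image_id"].astype(str), df["split"].astype(str)))
    by_patient = {
        str(p): str(s)
        for p, s in zip(df["patient_id"].astype(str), df["split"].astype(str))
    }
    return SplitAssignment(by_image=by_image, by_patient=by_patient)
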