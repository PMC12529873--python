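"""Shared fixtures: small synthetic cohorts and independent angle oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from fedspine.geometry import AngleSet, LandmarkSet
from fedspine.model import ModelConfig
from fedspine.synthetic import (
    CenterProfile,
    DEFAULT_PROFILES,
    build_landmarks,
    generate_cohort,
    split_cohort,
)

EQUAL_PROFILES = tuple(
    CenterProfile(
        center_id=c, share=0.25, pi_mean=pm, pi_sd=8.0,
        noise_sd=0.03, occlusion_prob=0.0,
    )
    for c, pm in zip(("A", "B", "C", "D"), (54, 50, 58, 44))
)


@pytest.fixture(scope="session")
def cohort500():
    """~500 samples across the four default heterogeneous centers."""
    return generate_cohort(
        DEFAULT_PROFILES, n_patients=150, rng_seed=42, canvas=(64, 64), spacing_mm=2.0
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 4-center cohort at 32x32 for training/federated tests."""
    return generate_cohort(
        EQUAL_PROFILES, n_patients=40, rng_seed=7, canvas=(32, 32), spacing_mm=4.0
    )


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_cohort(small_cohort, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(input_size=32, n_stacks=1, base_channels=4)


def landmarks_from_angles(
    ss=39.0, pt=13.0, ll=55.0, seed=0, canvas=(256, 256), spacing=0.5
) -> LandmarkSet:
    angles = AngleSet(SS=ss, PT=pt, PI=ss + pt, LL=ll)
    return build_landmarks(angles, seed, canvas=canvas, spacing_mm=spacing)


# --------------------------------------------------------------------------
# Independent brute-force angle oracle
# --------------------------------------------------------------------------


def _canon(lm: LandmarkSet, name: str) -> np.ndarray:
    x, y = lm.points[name]
    if lm.facing.value == "anterior_is_minus_x":
        x = -x
    return np.array([x, y], dtype=float)


def oracle_angles(lm: LandmarkSet, upper_level: str = "L1") -> AngleSet:
    """Read the four angles by rotating the frame so the sacral plate is horizontal.

    Independent of the library implementation: uses an explicit rotation
    matrix plus arccos/cross-product sign reads instead of atan2 identities.
    """
    ant = _canon(lm, "S1_anterior")
    post = _canon(lm, "S1_posterior")
    m = _canon(lm, "S1_midpoint")
    h = 0.5 * (_canon(lm, "femoral_head_left") + _canon(lm, "femoral_head_right"))

    d = ant - post
    if d[0] < 0:
        d = -d
    d = d / np.linalg.norm(d)
    # signed plate slope via arccos + sign of the y component (y down)
    ss_signed = math.degrees(math.acos(np.clip(d[0], -1, 1))) * np.sign(d[1] or 1.0)
    if d[1] == 0:
        ss_signed = 0.0
    ss = abs(ss_signed)

    # rotate all pelvis points about M by -ss_signed: plate becomes horizontal
    t = math.radians(-ss_signed)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    h_rot = m + rot @ (h - m)
    # plate horizontal => its perpendicular is vertical; PI is the angle of
    # M->H from straight down, positive anterior
    v = h_rot - m
    pi_mag = math.degrees(math.acos(np.clip(v[1] / np.linalg.norm(v), -1, 1)))
    pi = pi_mag * (1.0 if v[0] >= 0 else -1.0)

    # PT read directly in the unrotated frame
    u = h - m
    pt_mag = math.degrees(math.acos(np.clip(u[1] / np.linalg.norm(u), -1, 1)))
    pt = pt_mag * (1.0 if u[0] >= 0 else -1.0)

    # LL: angle between the two endplate lines with an orientation sign
    e = _canon(lm, f"{upper_level}_anterior_superior") - _canon(
        lm, f"{upper_level}_posterior_superior"
    )
    if e[0] < 0:
        e = -e
    e = e / np.linalg.norm(e)
    cosang = np.clip(d @ e, -1, 1)
    ll_mag = math.degrees(math.acos(cosang))
    cross = d[0] * e[1] - d[1] * e[0]
    ll = ll_mag * (1.0 if cross <= 0 else -1.0)
    return AngleSet(SS=ss, PT=pt, PI=pi, LL=ll)


def random_landmark_sets(n: int, seed: int):
    """Valid landmark sets spanning the clinical angle ranges."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ss = rng.uniform(5, 70)
        pt = rng.uniform(-15, 35)
        ll = rng.uniform(-10, 90)
        angles = AngleSet(SS=ss, PT=pt, PI=ss + pt, LL=ll)
        out.append(
            (angles, build_landmarks(angles, int(rng.integers(2**31)),
                                     canvas=(256, 256), spacing_mm=0.5))
        )
    return out
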