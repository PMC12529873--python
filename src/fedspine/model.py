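"""Stacked-hourglass landmark localizer with a DSNT head, in pure numpy.

The network predicts one spatial heatmap per landmark; a spatial softmax
turns each heatmap into a probability distribution and the differentiable
spatial-to-numerical transform (DSNT) converts it to coordinates as the
expectation over fixed coordinate grids with values (2k - (n + 1)) / n for
k = 1..n, so outputs live in (-1, 1) independently of resolution.

Training minimizes, per landmark, the Euclidean distance between predicted
and ground-truth normalized coordinates plus a divergence D(hm_gt, hm_p)
between the predicted heatmap and a Gaussian target heatmap rendered at the
ground-truth location (Jensen–Shannon by default, Kullback–Leibler by
config).  With several hourglass stacks the loss is averaged over the
per-stack outputs (intermediate supervision); the last stack makes the
prediction.

Gradients are hand-derived (no autodiff library is used); tests verify them
against finite differences.
"""

from __future__ import annotations

import io
import json
import math
from collections import OrderedDict
from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure
from skimage.transform import resize as sk_resize

from .geometry import LANDMARK_NAMES, LandmarkSet
from .nn import (
    Adam,
    ParamVector,
    conv2d,
    conv2d_backward,
    relu,
    relu_backward,
    spatial_softmax,
    spatial_softmax_backward,
    upsample2,
    upsample2_backward,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The reference setting is 768×768 input with two hourglass stacks; the
    desk preset used throughout the tests is 64×64, one stack, 16 channels.
    """

    input_size: int = 64
    n_stacks: int = 1
    base_channels: int = 16
    heatmap_stride: int = 4
    n_landmarks: int = len(LANDMARK_NAMES)
    sigma_hm: float = 1.0
    divergence: str = "js"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.heatmap_stride not in (2, 4):
            raise ValueError("heatmap_stride must be 2 or 4")
        if self.input_size % (self.heatmap_stride * 4) != 0:
            raise ValueError("input_size must be divisible by heatmap_stride * 4")
        if self.sigma_hm <= 0:
            raise ValueError("sigma_hm must be > 0")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")
        if self.divergence not in ("js", "kl"):
            raise ValueError("divergence must be 'js' or 'kl'")

    @property
    def heatmap_size(self) -> int:
        return self.input_size // self.heatmap_stride

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


# --------------------------------------------------------------------------
# Coordinate conventions
# --------------------------------------------------------------------------


def dsnt_grid(n: int, dtype=np.float64) -> np.ndarray:
    """DSNT coordinate grid: (2k - (n + 1)) / n for k = 1..n."""
    k = np.arange(1, n + 1, dtype=dtype)
    return (2.0 * k - (n + 1)) / n


def norm_from_px(px: np.ndarray, size: int) -> np.ndarray:
    """Map continuous pixel coordinates (0-based centers) to (-1, 1)."""
    return (2.0 * np.asarray(px, dtype=np.float64) + 1.0 - size) / size


def px_from_norm(norm: np.ndarray, size: int) -> np.ndarray:
    return (np.asarray(norm, dtype=np.float64) * size + size - 1.0) / 2.0


def dsnt_expect(hm: np.ndarray) -> np.ndarray:
    """DSNT: heatmap expectation over the coordinate grids.

    hm: (..., h, w) normalized heatmaps.  Returns (..., 2) with (x, y).
    """
    h, w = hm.shape[-2:]
    gx = dsnt_grid(w, hm.dtype)
    gy = dsnt_grid(h, hm.dtype)
    x = (hm * gx[None, :]).sum(axis=(-2, -1))
    y = (hm * gy[:, None]).sum(axis=(-2, -1))
    return np.stack([x, y], axis=-1)


def _dsnt_backward(dcoords: np.ndarray, h: int, w: int, dtype) -> np.ndarray:
    gx = dsnt_grid(w, dtype)
    gy = dsnt_grid(h, dtype)
    return (
        dcoords[..., 0:1, None] * gx[None, None, :]
        + dcoords[..., 1:2, None] * gy[None, :, None]
    ).reshape(dcoords.shape[:-1] + (h, w))


def target_heatmap(gt_norm: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Gaussian target heatmaps at the ground-truth locations.

    gt_norm: (N, L, 2) normalized coordinates.  Returns (N, L, h, w) maps,
    each renormalized to sum to exactly 1.
    """
    n = config.heatmap_size
    dtype = config.np_dtype
    centers = (np.asarray(gt_norm, dtype=np.float64) * n + n - 1.0) / 2.0  # heatmap px
    idx = np.arange(n, dtype=np.float64)
    dx2 = (idx[None, None, :] - centers[..., 0][..., None]) ** 2  # (N, L, w)
    dy2 = (idx[None, None, :] - centers[..., 1][..., None]) ** 2  # (N, L, h)
    inv = 1.0 / (2.0 * config.sigma_hm**2)
    hm = np.exp(-(dy2[..., :, None] + dx2[..., None, :]) * inv)
    hm /= hm.sum(axis=(-2, -1), keepdims=True)
    return hm.astype(dtype)


# --------------------------------------------------------------------------
# Divergences and the training loss
# --------------------------------------------------------------------------

_EPS = 1e-12


def kl_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """KL(p || q) summed over the last two axes."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    t = np.where(p > 0, p * (np.log(p + _EPS) - np.log(q + _EPS)), 0.0)
    return t.sum(axis=(-2, -1))


def js_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Jensen–Shannon divergence (nats) summed over the last two axes."""
    m = 0.5 * (np.asarray(p, dtype=np.float64) + np.asarray(q, dtype=np.float64))
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def _divergence_and_grad(hm_gt, hm_p, kind: str):
    """Mean divergence over (N, L) and its gradient with respect to hm_p."""
    count = float(np.prod(hm_gt.shape[:-2])) or 1.0
    if kind == "js":
        value = js_divergence(hm_gt, hm_p).sum() / count
        m = 0.5 * (hm_gt + hm_p)
        grad = 0.5 * (np.log(hm_p + _EPS) - np.log(m + _EPS)) / count
    elif kind == "kl":
        value = kl_divergence(hm_gt, hm_p).sum() / count
        grad = -(hm_gt / (hm_p + _EPS)) / count
    else:  # pragma: no cover
        raise ValueError(kind)
    return float(value), grad


def _check_normalized(hm: np.ndarray, what: str) -> None:
    sums = hm.sum(axis=(-2, -1))
    if not np.all(np.abs(sums - 1.0) < 1e-5):
        raise ValueError(f"{what} heatmaps are not normalized to sum 1")


def loss(
    pred_coords: np.ndarray,
    gt_coords: np.ndarray,
    hm_p: np.ndarray,
    hm_gt: np.ndarray,
    divergence: str = "js",
) -> float:
    """Per-landmark Euclidean distance plus heatmap divergence.

    mean_{batch, landmarks} ||p - gt||_2 + D(hm_gt, hm_p), coordinates in
    normalized units.  Both heatmap stacks must be spatially normalized.
    """
    _check_normalized(hm_p, "predicted")
    _check_normalized(hm_gt, "target")
    diff = np.asarray(pred_coords, dtype=np.float64) - np.asarray(
        gt_coords, dtype=np.float64
    )
    euc = float(np.sqrt((diff**2).sum(axis=-1)).mean())
    div, _ = _divergence_and_grad(
        np.asarray(hm_gt, np.float64), np.asarray(hm_p, np.float64), divergence
    )
    return euc + div


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------


class HourglassNet:
    """Small encoder–decoder landmark localizer with DSNT output."""

    def __init__(self, config: ModelConfig):
        self.cfg = config

    # -- parameters ---------------------------------------------------------

    def param_shapes(self) -> "OrderedDict[str, tuple[int, ...]]":
        c = self.cfg.base_channels
        nl = self.cfg.n_landmarks
        shapes: "OrderedDict[str, tuple[int, ...]]" = OrderedDict()
        shapes["stem1.W"] = (c, 1, 3, 3)
        shapes["stem1.b"] = (c,)
        shapes["stem2.W"] = (c, c, 3, 3)
        shapes["stem2.b"] = (c,)
        for s in range(self.cfg.n_stacks):
            for name in ("skip", "down", "bott", "post"):
                shapes[f"hg{s}.{name}.W"] = (c, c, 3, 3)
                shapes[f"hg{s}.{name}.b"] = (c,)
            shapes[f"hg{s}.head.W"] = (nl, c, 1, 1)
            shapes[f"hg{s}.head.b"] = (nl,)
            if s < self.cfg.n_stacks - 1:
                shapes[f"hg{s}.remap.W"] = (c, nl, 1, 1)
                shapes[f"hg{s}.remap.b"] = (c,)
        return shapes

    def init_params(self, seed: int) -> ParamVector:
        """He-normal weight initialization, biases zero, seeded."""
        rng = np.random.default_rng(seed)
        dtype = self.cfg.np_dtype
        arrays: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for name, shape in self.param_shapes().items():
            if name.endswith(".b"):
                arrays[name] = np.zeros(shape, dtype=dtype)
            else:
                fan_in = int(np.prod(shape[1:]))
                std = math.sqrt(2.0 / fan_in)
                arrays[name] = (rng.normal(0.0, std, size=shape)).astype(dtype)
        return ParamVector(arrays)

    # -- forward ------------------------------------------------------------

    def _forward(self, params: ParamVector, images: np.ndarray) -> dict:
        cfg = self.cfg
        x = np.asarray(images, dtype=cfg.np_dtype)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != cfg.input_size or x.shape[-2] != cfg.input_size:
            raise ValueError(
                f"expected {cfg.input_size}x{cfg.input_size} input, got {x.shape}"
            )
        P = params.arrays
        st: dict = {"x": x}
        a1, st["c1"] = conv2d(x, P["stem1.W"], P["stem1.b"], stride=2)
        r1, st["m1"] = relu(a1)
        st["r1"] = r1
        stem2_stride = 2 if cfg.heatmap_stride == 4 else 1
        a2, st["c2"] = conv2d(r1, P["stem2.W"], P["stem2.b"], stride=stem2_stride)
        feat, st["m2"] = relu(a2)
        st["stem2_stride"] = stem2_stride

        st["stacks"] = []
        st["raws"] = []
        for s in range(cfg.n_stacks):
            sc: dict = {"feat_in": feat}
            a, sc["c_skip"] = conv2d(feat, P[f"hg{s}.skip.W"], P[f"hg{s}.skip.b"])
            skip, sc["m_skip"] = relu(a)
            a, sc["c_down"] = conv2d(feat, P[f"hg{s}.down.W"], P[f"hg{s}.down.b"], stride=2)
            downr, sc["m_down"] = relu(a)
            a, sc["c_bott"] = conv2d(downr, P[f"hg{s}.bott.W"], P[f"hg{s}.bott.b"])
            bott, sc["m_bott"] = relu(a)
            merged, sc["m_merge"] = relu(upsample2(bott) + skip)
            a, sc["c_post"] = conv2d(merged, P[f"hg{s}.post.W"], P[f"hg{s}.post.b"])
            post, sc["m_post"] = relu(a)
            raw, sc["c_head"] = conv2d(post, P[f"hg{s}.head.W"], P[f"hg{s}.head.b"])
            st["raws"].append(raw)
            if s < cfg.n_stacks - 1:
                rem, sc["c_remap"] = conv2d(raw, P[f"hg{s}.remap.W"], P[f"hg{s}.remap.b"])
                feat = feat + post + rem
            st["stacks"].append(sc)

        st["hms"] = [spatial_softmax(raw) for raw in st["raws"]]
        st["coords"] = [dsnt_expect(hm) for hm in st["hms"]]
        return st

    def forward(self, params: ParamVector, images: np.ndarray):
        """Run the network; returns (heatmaps per stack, normalized coords).

        Coordinates are the DSNT expectation of the last stack's heatmaps,
        shape (N, n_landmarks, 2) in (-1, 1).
        """
        st = self._forward(params, images)
        return st["hms"], st["coords"][-1]

    # -- loss + gradients ---------------------------------------------------

    def loss_and_grads(
        self,
        params: ParamVector,
        images: np.ndarray,
        gt_norm: np.ndarray,
        hm_gt: np.ndarray | None = None,
    ):
        """Training loss (averaged over stacks) and parameter gradients."""
        cfg = self.cfg
        st = self._forward(params, images)
        if hm_gt is None:
            hm_gt = target_heatmap(gt_norm, cfg)
        gt = np.asarray(gt_norm, dtype=cfg.np_dtype)
        n_stacks = cfg.n_stacks
        n, nl = gt.shape[:2]
        hsz = cfg.heatmap_size

        total = 0.0
        draws = []
        last_euc = 0.0
        for s in range(n_stacks):
            p = st["coords"][s]
            diff = p - gt
            dist = np.sqrt((diff.astype(np.float64) ** 2).sum(axis=-1))
            euc = float(dist.mean())
            div, ddiv = _divergence_and_grad(
                hm_gt.astype(np.float64), st["hms"][s].astype(np.float64), cfg.divergence
            )
            total += (euc + div) / n_stacks
            last_euc = euc
            dcoords = diff / np.maximum(dist, _EPS)[..., None] / (n * nl) / n_stacks
            dhm = ddiv / n_stacks + _dsnt_backward(
                dcoords.astype(np.float64), hsz, hsz, np.float64
            )
            draws.append(
                spatial_softmax_backward(
                    dhm, st["hms"][s].astype(np.float64)
                ).astype(cfg.np_dtype)
            )

        grads = self._backward(params, st, draws)
        return total, grads, {"euclid_norm": last_euc}

    def _backward(self, params: ParamVector, st: dict, draws: list) -> ParamVector:
        cfg = self.cfg
        g = {k: np.zeros_like(v) for k, v in params.items()}
        dfeat = np.zeros_like(st["stacks"][-1]["feat_in"])
        for s in range(cfg.n_stacks - 1, -1, -1):
            sc = st["stacks"][s]
            draw = draws[s].copy()
            dpost = np.zeros_like(sc["m_post"], dtype=draw.dtype)
            dfeat_local = np.zeros_like(dfeat)
            if s < cfg.n_stacks - 1:
                # feat_out = feat_in + post + remap(raw)
                dfeat_local += dfeat
                dpost += dfeat
                drem, dw, db = conv2d_backward(dfeat, sc["c_remap"])
                g[f"hg{s}.remap.W"] += dw
                g[f"hg{s}.remap.b"] += db
                draw += drem
            dp, dw, db = conv2d_backward(draw, sc["c_head"])
            g[f"hg{s}.head.W"] += dw
            g[f"hg{s}.head.b"] += db
            dpost += dp
            da = relu_backward(dpost, sc["m_post"])
            dmerged, dw, db = conv2d_backward(da, sc["c_post"])
            g[f"hg{s}.post.W"] += dw
            g[f"hg{s}.post.b"] += db
            dmp = relu_backward(dmerged, sc["m_merge"])
            dskip = dmp
            dbott = upsample2_backward(dmp)
            da = relu_backward(dbott, sc["m_bott"])
            ddownr, dw, db = conv2d_backward(da, sc["c_bott"])
            g[f"hg{s}.bott.W"] += dw
            g[f"hg{s}.bott.b"] += db
            da = relu_backward(ddownr, sc["m_down"])
            dfi, dw, db = conv2d_backward(da, sc["c_down"])
            g[f"hg{s}.down.W"] += dw
            g[f"hg{s}.down.b"] += db
            dfeat_local += dfi
            da = relu_backward(dskip, sc["m_skip"])
            dfi, dw, db = conv2d_backward(da, sc["c_skip"])
            g[f"hg{s}.skip.W"] += dw
            g[f"hg{s}.skip.b"] += db
            dfeat_local += dfi
            dfeat = dfeat_local

        da = relu_backward(dfeat, st["m2"])
        dr1, dw, db = conv2d_backward(da, st["c2"])
        g["stem2.W"] += dw
        g["stem2.b"] += db
        da = relu_backward(dr1, st["m1"])
        _, dw, db = conv2d_backward(da, st["c1"])
        g["stem1.W"] += dw
        g["stem1.b"] += db
        return ParamVector(OrderedDict((k, g[k]) for k in params.keys()))

    # -- prediction ---------------------------------------------------------

    def predict_px(self, params: ParamVector, images: np.ndarray, batch_size: int = 16):
        """Predicted landmark positions in input-image pixels, (N, L, 2)."""
        outs = []
        images = np.asarray(images)
        for i in range(0, len(images), batch_size):
            _, coords = self.forward(params, images[i : i + batch_size])
            outs.append(px_from_norm(coords, self.cfg.input_size))
        return np.concatenate(outs, axis=0)


def make_optimizer(params: ParamVector) -> Adam:
    return Adam(params)


# --------------------------------------------------------------------------
# Data augmentation (train-time only)
# --------------------------------------------------------------------------


def augment(
    image: np.ndarray,
    lm: LandmarkSet,
    rng_seed: int,
    max_rotation_deg: float = 10.0,
) -> tuple[np.ndarray, LandmarkSet]:
    """Photometric + rotation augmentation, deterministic per seed.

    Applies (each with some probability) CLAHE, coarse dropout, brightness
    and contrast shifts, Gaussian blurring, pixel noise, and a random
    rotation in [-max_rotation_deg, +max_rotation_deg].  Rotation transforms
    the landmarks with the same matrix about the image center; photometric
    transforms leave the landmarks untouched.
    """
    rng = np.random.default_rng(rng_seed)
    img = np.asarray(image, dtype=np.float64).copy()
    h, w = img.shape

    if rng.uniform() < 0.25:
        img = exposure.equalize_adapthist(np.clip(img, 0, 1), clip_limit=0.02)
    if rng.uniform() < 0.5:
        c = rng.uniform(0.85, 1.15)
        b = rng.uniform(-0.10, 0.10)
        img = img * c + b
    if rng.uniform() < 0.3:
        img = ndi.gaussian_filter(img, sigma=rng.uniform(0.3, 1.0))
    if rng.uniform() < 0.3:
        img = img + rng.normal(0.0, rng.uniform(0.005, 0.03), size=img.shape)
    if rng.uniform() < 0.3:
        for _ in range(int(rng.integers(1, 4))):  # coarse dropout
            bh = int(rng.integers(2, max(3, h // 8)))
            bw = int(rng.integers(2, max(3, w // 8)))
            r0 = int(rng.integers(0, max(1, h - bh)))
            c0 = int(rng.integers(0, max(1, w - bw)))
            img[r0 : r0 + bh, c0 : c0 + bw] = float(img.mean())

    out_lm = lm
    theta = rng.uniform(-max_rotation_deg, max_rotation_deg) if rng.uniform() < 0.7 else 0.0
    if theta != 0.0:
        img, out_lm = rotate_sample(img, lm, theta)

    return np.clip(img, 0.0, 1.0), out_lm


def rotate_sample(
    image: np.ndarray, lm: LandmarkSet, angle_deg: float
) -> tuple[np.ndarray, LandmarkSet]:
    """Rotate an image about its center; landmarks get the same rotation.

    A landmark at p maps to c + R(θ)·(p − c) with c the image center in
    pixel-center coordinates; the image is resampled bilinearly through the
    inverse map so content stays aligned with the transformed landmarks.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    # resampling pulls from the inverse map; R(-t) in (x, y) becomes this
    # same matrix expression in (row, col) order after swapping both axes
    mat = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    center_rc = center[::-1]
    offset = center_rc - mat @ center_rc
    img = ndi.affine_transform(img, mat, offset=offset, order=1, mode="nearest")
    points = {
        k: tuple(center + rot @ (np.asarray(v, dtype=float) - center))
        for k, v in lm.points.items()
    }
    return img, lm.with_points(points)


# --------------------------------------------------------------------------
# Aspect-preserving resize
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResizeTransform:
    """Affine map from original pixels to resized-and-padded pixels."""

    scale: float
    pad_x: float
    pad_y: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=np.float64)
        out = (xy + 0.5) * self.scale - 0.5
        return out + np.array([self.pad_x, self.pad_y])

    def invert(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=np.float64) - np.array([self.pad_x, self.pad_y])
        return (xy + 0.5) / self.scale - 0.5


def resize_with_aspect(
    image: np.ndarray, lm: LandmarkSet | None, target_size: int
) -> tuple[np.ndarray, LandmarkSet | None, ResizeTransform]:
    """Scale the longest side to ``target_size`` (bicubic) and pad square.

    Padding is symmetric with the median intensity of the image border;
    landmarks are mapped by the same affine transform, which is returned so
    predictions can be mapped back to the original pixel frame.
    """
    h, w = image.shape
    scale = target_size / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    nh, nw = min(nh, target_size), min(nw, target_size)
    resized = sk_resize(
        np.asarray(image, dtype=np.float64), (nh, nw), order=3, anti_aliasing=scale < 1
    )
    border = np.concatenate(
        [resized[0, :], resized[-1, :], resized[:, 0], resized[:, -1]]
    )
    fill = float(np.median(border))
    pad_top = (target_size - nh) // 2
    pad_left = (target_size - nw) // 2
    out = np.full((target_size, target_size), fill, dtype=resized.dtype)
    out[pad_top : pad_top + nh, pad_left : pad_left + nw] = resized
    tf = ResizeTransform(scale=scale, pad_x=float(pad_left), pad_y=float(pad_top))

    new_lm = None
    if lm is not None:
        pts = {
            k: tuple(tf.apply(np.asarray(v, dtype=float)))
            for k, v in lm.points.items()
        }
        new_lm = LandmarkSet(
            points=pts,
            pixel_spacing_mm=lm.pixel_spacing_mm / scale,
            facing=lm.facing,
            image_size=(target_size, target_size),
        )
    return out, new_lm, tf


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------


def save_checkpoint(path, params: ParamVector, config: ModelConfig, metadata: dict | None = None) -> None:
    """Single-archive checkpoint: parameters + config + training metadata."""
    payload = {f"param::{k}": v for k, v in params.items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    payload["__meta__"] = np.frombuffer(
        json.dumps(metadata or {}, sort_keys=True).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path):
    with np.load(path) as npz:
        cfg = ModelConfig(**json.loads(bytes(npz["__config__"]).decode()))
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = OrderedDict()
        net = HourglassNet(cfg)
        for name in net.param_shapes():
            arrays[name] = npz[f"param::{name}"]
    return ParamVector(arrays), cfg, meta
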