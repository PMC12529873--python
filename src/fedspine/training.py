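"""Centralized and per-hospital local training loops.

Three study arms share one epoch engine: a *centralized* model trained on the
pooled multi-center training split, per-hospital *local* models trained only
on their own center's split, and (via :mod:`fedspine.federated`) federated
clients that run the same epochs between aggregation rounds.

Defaults follow the reference schedules: 200 epochs, Adam with learning rate
1e-4 reduced ×0.1 after 50 epochs, early stopping after 10 validation epochs
without improvement, batch size 8.  Checkpoint selection returns the
parameters of the epoch with the best (lowest) validation metric — the mean
landmark Euclidean error in millimetres by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import LANDMARK_NAMES
from .model import HourglassNet, ModelConfig, augment, norm_from_px, target_heatmap
from .nn import Adam, ParamVector
from .synthetic import SpineSample, SplitAssignment, samples_in_split

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Schedule for one (non-federated) training run."""

    mode: str = "centralized"  # centralized | local | federated-client
    epochs: int = 200
    lr: float = 0.0001
    lr_decay_factor: float = 0.1
    lr_decay_after: int = 50
    early_stop_patience: int = 10
    batch_size: int = 8
    seed: int = 0
    augment: bool = True
    max_rotation_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.lr <= 0 or self.batch_size < 1:
            raise ValueError("epochs >= 0, lr > 0 and batch_size >= 1 required")


def lr_schedule(index: int, base_lr: float, factor: float, after: int | None) -> float:
    """Step learning-rate decay: base before ``after``, base×factor from it on."""
    if index < 0:
        raise ValueError("schedule index must be >= 0")
    if after is None or index < after:
        return base_lr
    return base_lr * factor


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement.

    "No improvement" means the metric is not strictly below the best seen so
    far minus a small tolerance.
    """

    def __init__(self, patience: int, tol: float = 1e-6):
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.stale = 0

    def update(self, metric: float) -> bool:
        """Record one epoch's metric; returns True when training should stop."""
        if metric < self.best - self.tol:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class FitResult:
    """Outcome of one training run."""

    best_params: ParamVector
    best_val_metric: float
    stopped_epoch: int
    history: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------------
# Data plumbing
# --------------------------------------------------------------------------


def samples_to_arrays(samples: list[SpineSample], model_cfg: ModelConfig):
    """Stack images and normalized ground-truth coordinates."""
    imgs = np.stack([np.asarray(s.image) for s in samples]).astype(model_cfg.np_dtype)
    gt_px = np.array(
        [[s.landmarks.points[n] for n in LANDMARK_NAMES] for s in samples]
    )
    return imgs, norm_from_px(gt_px, model_cfg.input_size)


def mean_landmark_error_mm(
    net: HourglassNet,
    params: ParamVector,
    samples: list[SpineSample],
    batch_size: int = 32,
) -> float:
    """Mean per-point Euclidean error in mm over ``samples`` (model frame)."""
    if not samples:
        raise ValueError("empty evaluation set")
    imgs = np.stack([np.asarray(s.image) for s in samples])
    pred = net.predict_px(params, imgs, batch_size=batch_size)
    gt = np.array([[s.landmarks.points[n] for n in LANDMARK_NAMES] for s in samples])
    spacing = np.array([s.landmarks.pixel_spacing_mm for s in samples])
    err_px = np.linalg.norm(pred - gt, axis=-1)  # (N, L)
    return float((err_px * spacing[:, None]).mean())


# --------------------------------------------------------------------------
# Epoch engine
# --------------------------------------------------------------------------


def run_one_epoch(
    net: HourglassNet,
    params: ParamVector,
    opt: Adam,
    samples: list[SpineSample],
    lr: float,
    epoch_rng: np.random.Generator,
    cfg: TrainConfig,
    prox: tuple[float, ParamVector] | None = None,
) -> float:
    """One pass over ``samples`` in shuffled mini-batches; returns mean loss.

    ``prox``, if given, is (mu, global_params): the proximal penalty
    (mu/2)·||θ − θ_global||² is added to the objective and its gradient —
    the client-side modification used by FedProx.
    """
    order = epoch_rng.permutation(len(samples))
    losses = []
    for start in range(0, len(samples), cfg.batch_size):
        batch = [samples[i] for i in order[start : start + cfg.batch_size]]
        if cfg.augment:
            aug = []
            for s in batch:
                seed = int(epoch_rng.integers(2**31))
                img, lm = augment(
                    s.image, s.landmarks, seed, max_rotation_deg=cfg.max_rotation_deg
                )
                aug.append(replace_sample(s, img, lm))
            batch = aug
        imgs, gt = samples_to_arrays(batch, net.cfg)
        loss_val, grads, _ = net.loss_and_grads(params, imgs, gt)
        if prox is not None:
            mu, ref = prox
            if mu != 0.0:
                loss_val += 0.5 * mu * (params - ref).sq_norm()
                for k, g in grads.items():
                    g += mu * (params[k] - ref[k])
        opt.step(params, grads, lr)
        losses.append(loss_val)
    return float(np.mean(losses)) if losses else 0.0


def replace_sample(s: SpineSample, image, landmarks) -> SpineSample:
    return SpineSample(
        image=image,
        landmarks=landmarks,
        true_angles=s.true_angles,
        patient_id=s.patient_id,
        center_id=s.center_id,
        visit=s.visit,
        seed_trace=s.seed_trace,
    )


def epoch_rng(seed: int, epoch_index: int) -> np.random.Generator:
    """The shuffle/augment stream for one epoch, a pure function of its inputs."""
    return np.random.default_rng(np.random.SeedSequence([seed, epoch_index]))


# --------------------------------------------------------------------------
# Fit loop with validation checkpointing
# --------------------------------------------------------------------------


def fit(
    train_samples: list[SpineSample],
    val_samples: list[SpineSample],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_params: ParamVector | None = None,
    val_metric_fn=None,
) -> FitResult:
    """Train with per-epoch validation, LR decay, early stopping.

    ``val_metric_fn(net, params, epoch) -> float`` may replace the default
    validation metric (mean landmark error in mm); lower is better.
    Deterministic given seeds: same inputs, bit-identical result.
    """
    if not train_samples:
        raise ValueError("empty training split")
    net = HourglassNet(model_cfg)
    params = init_params.copy() if init_params is not None else net.init_params(train_cfg.seed)
    opt = Adam(params)
    stopper = EarlyStopper(train_cfg.early_stop_patience)
    best_params = params.copy()
    best_val = np.inf
    history: list[dict] = []
    stopped_epoch = 0

    def default_metric(net_, params_, _epoch):
        return mean_landmark_error_mm(net_, params_, val_samples)

    metric_fn = val_metric_fn or default_metric

    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(
            epoch, train_cfg.lr, train_cfg.lr_decay_factor, train_cfg.lr_decay_after
        )
        train_loss = run_one_epoch(
            net, params, opt, train_samples, lr, epoch_rng(train_cfg.seed, epoch), train_cfg
        )
        val = float(metric_fn(net, params, epoch))
        history.append(
            {"epoch": epoch, "lr": lr, "train_loss": train_loss, "val_metric": val}
        )
        if val < best_val - stopper.tol:
            best_val = val
            best_params = params.copy()
        stopped_epoch = epoch + 1
        if stopper.update(val):
            break

    if not history:  # epochs == 0: return the initial parameters
        best_params, best_val = params.copy(), np.inf
    return FitResult(
        best_params=best_params,
        best_val_metric=float(best_val),
        stopped_epoch=stopped_epoch,
        history=history,
    )


# --------------------------------------------------------------------------
# Study arms
# --------------------------------------------------------------------------


def _assert_patient_disjoint(split: SplitAssignment) -> None:
    # by construction each patient has exactly one split; keep a hard check
    seen: dict[str, str] = {}
    for p, s in split.by_patient.items():
        if p in seen and seen[p] != s:  # pragma: no cover
            raise RuntimeError(f"patient {p} appears in two splits")
        seen[p] = s


def train_centralized(
    samples: list[SpineSample],
    split: SplitAssignment,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_params: ParamVector | None = None,
) -> FitResult:
    """One model on the pooled multi-center training split."""
    _assert_patient_disjoint(split)
    train = samples_in_split(samples, split, "train")
    val = samples_in_split(samples, split, "validation")
    return fit(train, val, model_cfg, train_cfg, init_params=init_params)


def train_local(
    samples: list[SpineSample],
    split: SplitAssignment,
    center: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_params: ParamVector | None = None,
) -> FitResult:
    """One hospital-specific model on a single center's splits."""
    _assert_patient_disjoint(split)
    train = samples_in_split(samples, split, "train", center=center)
    val = samples_in_split(samples, split, "validation", center=center)
    if not val:  # degenerate tiny center: validate on its train data
        val = train
    return fit(train, val, model_cfg, train_cfg, init_params=init_params)
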