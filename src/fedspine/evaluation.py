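"""Evaluation surface: landmark errors, angle errors, cross-site testing, PCP.

For every trained model and every center's held-out test split this module
computes per-point/per-level Euclidean localization errors (mm) and the
absolute error of the four lumbopelvic parameters derived from the predicted
landmarks, stratified into internal vs external testing.  Percentage-of-
correct-predictions (PCP) curves report, per angle and pooled, the fraction
of predictions within 1°–15° of the ground truth (inclusive thresholds).

Angle errors are computed in the original pixel frame (predictions are mapped
back through any resize transform before angles are measured), and errors are
aggregated per image first, then averaged across images.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    ANGLE_NAMES,
    LANDMARK_NAMES,
    LEVELS,
    InvalidGeometryError,
    LandmarkSet,
    angle_abs_error,
    compute_angles,
    landmark_error,
)
from .model import HourglassNet, ModelConfig, ResizeTransform
from .nn import ParamVector
from .synthetic import SpineSample, SplitAssignment


class LeakageError(RuntimeError):
    """Raised when an evaluation set overlaps the training data."""


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


@dataclass
class EvalRecord:
    """One (model, test center) evaluation."""

    model_id: str
    train_center: str  # center id or "all"
    test_center: str
    scope: str  # internal | external
    n_images: int
    landmark_mean_mm: float
    landmark_median_mm: float
    per_level_mm: dict[str, float]
    angle_stats: dict[str, dict[str, float]]  # angle -> {mean, sd, median}
    angle_errors: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def pooled_angle_mae(self) -> float:
        """Mean absolute angle error pooled over the four parameters."""
        return float(
            np.nanmean(np.concatenate([self.angle_errors[a] for a in ANGLE_NAMES]))
        )


@dataclass
class PCPCurve:
    """Fraction of predictions within each error threshold (degrees)."""

    thresholds: np.ndarray
    fraction: np.ndarray  # same length, values in [0, 1]


# --------------------------------------------------------------------------
# Prediction plumbing
# --------------------------------------------------------------------------


def predict_landmark_sets(
    params: ParamVector,
    model_cfg: ModelConfig,
    samples: list[SpineSample],
    transforms: list[ResizeTransform] | None = None,
    batch_size: int = 32,
) -> list[LandmarkSet]:
    """Predicted landmarks as LandmarkSets in the original pixel frame.

    ``transforms``, when given, maps each prediction back from the model's
    input frame to the sample's original frame.
    """
    net = HourglassNet(model_cfg)
    imgs = np.stack([np.asarray(s.image) for s in samples])
    pred = net.predict_px(params, imgs, batch_size=batch_size)  # (N, L, 2)
    out = []
    for i, s in enumerate(samples):
        xy = pred[i]
        if transforms is not None:
            xy = transforms[i].invert(xy)
        pts = {name: (float(x), float(y)) for name, (x, y) in zip(LANDMARK_NAMES, xy)}
        out.append(s.landmarks.with_points(pts))
    return out


def evaluate_predictions(
    preds: list[LandmarkSet],
    samples: list[SpineSample],
    model_id: str,
    train_center: str,
    test_center: str,
    scope: str,
) -> EvalRecord:
    """Score a list of predicted landmark sets against ground truth."""
    if not samples:
        raise ValueError("empty evaluation set")
    per_point_mm = []
    per_level = {lvl: [] for lvl in LEVELS}
    angle_err = {a: [] for a in ANGLE_NAMES}
    for pred_lm, s in zip(preds, samples):
        le = landmark_error(pred_lm, s.landmarks)
        per_point_mm.append(np.mean(list(le.per_point.values())))
        for lvl, v in le.per_level.items():
            per_level[lvl].append(v)
        try:
            pa = compute_angles(pred_lm)
            err = angle_abs_error(pa, s.true_angles)
        except InvalidGeometryError:
            err = {a: np.nan for a in ANGLE_NAMES}  # degenerate prediction
        for a in ANGLE_NAMES:
            angle_err[a].append(err[a])
    angle_err = {a: np.asarray(v, dtype=float) for a, v in angle_err.items()}
    return EvalRecord(
        model_id=model_id,
        train_center=train_center,
        test_center=test_center,
        scope=scope,
        n_images=len(samples),
        landmark_mean_mm=float(np.mean(per_point_mm)),
        landmark_median_mm=float(np.median(per_point_mm)),
        per_level_mm={lvl: float(np.mean(v)) for lvl, v in per_level.items() if v},
        angle_stats={
            a: {
                "mean": float(np.nanmean(v)),
                "sd": float(np.nanstd(v)),
                "median": float(np.nanmedian(v)),
            }
            for a, v in angle_err.items()
        },
        angle_errors=angle_err,
    )


def _check_no_leakage(samples: list[SpineSample], split: SplitAssignment) -> None:
    train_patients = split.patients("train") | split.patients("validation")
    for s in samples:
        if split.of(s.image_id) != "test":
            raise LeakageError(f"image {s.image_id} is not in the test split")
        if s.patient_id in train_patients:  # pragma: no cover - split contract
            raise LeakageError(f"patient {s.patient_id} leaks into training")


def evaluate_model(
    params: ParamVector,
    model_cfg: ModelConfig,
    samples: list[SpineSample],
    split: SplitAssignment,
    model_id: str,
    train_center: str,
    test_center: str | None = None,
    transforms: list[ResizeTransform] | None = None,
) -> EvalRecord:
    """Evaluate one model on one test set, with a hard leakage check."""
    _check_no_leakage(samples, split)
    centers = {s.center_id for s in samples}
    tc = test_center or (centers.pop() if len(centers) == 1 else "pooled")
    scope = "internal" if train_center in ("all", tc) else "external"
    preds = predict_landmark_sets(params, model_cfg, samples, transforms=transforms)
    return evaluate_predictions(preds, samples, model_id, train_center, tc, scope)


def cross_site_matrix(
    models: dict[str, tuple[ParamVector, str]],
    samples: list[SpineSample],
    split: SplitAssignment,
    model_cfg: ModelConfig,
) -> list[EvalRecord]:
    """Every model × every center's test split.

    ``models`` maps model_id -> (params, train_center), train_center being a
    center id for local models or "all" for centralized/federated ones.
    Local models are internal on their own center and external elsewhere;
    global models count as internal everywhere.
    """
    centers = sorted({s.center_id for s in samples})
    if len(centers) < 2:
        raise ValueError("cross-site evaluation needs at least two centers")
    records = []
    for model_id in sorted(models):
        params, train_center = models[model_id]
        for center in centers:
            test = [
                s
                for s in samples
                if s.center_id == center and split.of(s.image_id) == "test"
            ]
            if not test:
                continue
            records.append(
                evaluate_model(
                    params, model_cfg, test, split, model_id, train_center,
                    test_center=center,
                )
            )
    return records


# --------------------------------------------------------------------------
# PCP curves
# --------------------------------------------------------------------------

DEFAULT_THRESHOLDS = np.arange(1.0, 16.0)


def pcp(errors, thresholds=DEFAULT_THRESHOLDS) -> PCPCurve:
    """Percentage of correct predictions: P(error <= τ) per threshold τ.

    The comparison is inclusive: an error exactly equal to the threshold
    counts as correct.
    """
    errors = np.asarray(list(errors), dtype=float)
    errors = errors[np.isfinite(errors)]
    if errors.size == 0:
        raise ValueError("PCP of an empty error list is undefined")
    thresholds = np.asarray(thresholds, dtype=float)
    frac = np.array([(errors <= t).mean() for t in thresholds])
    return PCPCurve(thresholds=thresholds, fraction=frac)


def pcp_curves_from_records(records: list[EvalRecord]) -> dict[str, PCPCurve]:
    """Pooled and per-angle PCP curves per model (errors pooled over centers)."""
    curves: dict[str, PCPCurve] = {}
    by_model: dict[str, list[EvalRecord]] = {}
    for r in records:
        by_model.setdefault(r.model_id, []).append(r)
    for model_id, recs in sorted(by_model.items()):
        pooled = []
        for a in ANGLE_NAMES:
            errs = np.concatenate([r.angle_errors[a] for r in recs])
            curves[f"{model_id}:{a}"] = pcp(errs)
            pooled.append(errs)
        curves[f"{model_id}:pooled"] = pcp(np.concatenate(pooled))
    return curves


# --------------------------------------------------------------------------
# Report files
# --------------------------------------------------------------------------


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "model_id": r.model_id,
            "train_center": r.train_center,
            "test_center": r.test_center,
            "scope": r.scope,
            "n_images": r.n_images,
            "landmark_mean_mm": r.landmark_mean_mm,
            "landmark_median_mm": r.landmark_median_mm,
        }
        for lvl, v in r.per_level_mm.items():
            row[f"level_{lvl}_mm"] = v
        for a in ANGLE_NAMES:
            for stat, v in r.angle_stats[a].items():
                row[f"{a}_{stat}_deg"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _box_stats(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = float(v[v >= q1 - 1.5 * iqr].min())
    hi = float(v[v <= q3 + 1.5 * iqr].max())
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": lo, "whisker_high": hi}


def report(records: list[EvalRecord], pcp_curves: dict[str, PCPCurve], outdir) -> list[str]:
    """Write tidy CSVs, a JSON summary and figures; deterministic contents."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no records to report")
    os.makedirs(outdir, exist_ok=True)
    written = []

    df = records_to_frame(records)
    p = os.path.join(outdir, "records.csv")
    df.to_csv(p, index=False)
    written.append(p)

    pcp_rows = [
        {"curve": name, "threshold_deg": t, "fraction": f}
        for name, c in sorted(pcp_curves.items())
        for t, f in zip(c.thresholds, c.fraction)
    ]
    p = os.path.join(outdir, "pcp.csv")
    pd.DataFrame(pcp_rows).to_csv(p, index=False)
    written.append(p)

    box_rows = []
    by_model: dict[str, list[EvalRecord]] = {}
    for r in records:
        by_model.setdefault(r.model_id, []).append(r)
    summary = {}
    for model_id, recs in sorted(by_model.items()):
        pooled = {}
        for a in ANGLE_NAMES:
            errs = np.concatenate([r.angle_errors[a] for r in recs])
            pooled[a] = float(np.nanmean(errs))
            box_rows.append({"model_id": model_id, "angle": a, **_box_stats(errs)})
        summary[model_id] = {
            "pooled_angle_mae_deg": float(np.mean(list(pooled.values()))),
            "per_angle_mae_deg": pooled,
            "landmark_mean_mm": float(
                np.average([r.landmark_mean_mm for r in recs],
                           weights=[r.n_images for r in recs])
            ),
            "n_images": int(sum(r.n_images for r in recs)),
        }
    p = os.path.join(outdir, "boxplot_stats.csv")
    pd.DataFrame(box_rows).to_csv(p, index=False)
    written.append(p)
    p = os.path.join(outdir, "summary.json")
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    written.append(p)

    # figures (cosmetic; the numbers live in the CSVs)
    fig, ax = plt.subplots(figsize=(7, 4))
    levels = [lvl for lvl in LEVELS if any(lvl in r.per_level_mm for r in records)]
    for model_id, recs in sorted(by_model.items()):
        means = [
            np.mean([r.per_level_mm[lvl] for r in recs if lvl in r.per_level_mm])
            for lvl in levels
        ]
        ax.plot(levels, means, marker="o", label=model_id)
    ax.set_ylabel("mean landmark error (mm)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = os.path.join(outdir, "per_vertebra.png")
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, c in sorted(pcp_curves.items()):
        if name.endswith(":pooled"):
            ax.plot(c.thresholds, 100 * c.fraction, label=name.split(":")[0])
    ax.set_xlabel("error threshold (deg)")
    ax.set_ylabel("% predictions within threshold")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = os.path.join(outdir, "pcp.png")
    fig.savefig(p)
    plt.close(fig)
    written.append(p)
    return written
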