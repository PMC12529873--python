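"""Desk-scale end-to-end study: centralized vs local vs FedAvg.

Runs the full pipeline — synthetic 4-center cohort, patient-level split,
centralized/local/federated training from a shared initialization, and the
cross-site evaluation matrix — at a size a single CPU handles in minutes:
~120 patients (3–4 visits each), 64×64 images at 2 mm/px, a one-stack
8-channel localizer, 30 local epochs per hospital, 5 local epochs × 6
federated rounds (30 total passes), and a centralized budget of 20 epochs —
preserving the 200:300 centralized-to-federated epoch proportion of the
reference schedules.  The qualitative questions mirror the full-scale study:
does federated averaging beat hospital-local models on external test data,
and does it stay close to centralized training?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalRecord, cross_site_matrix
from .federated import FLSchedule, run_fl
from .model import HourglassNet, ModelConfig
from .synthetic import (
    DEFAULT_PROFILES,
    SpineSample,
    generate_cohort,
    samples_in_split,
    split_cohort,
)
from .training import TrainConfig, train_centralized, train_local
from .utils import derive_seed


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and schedules of the desk-scale study."""

    n_patients: int = 120
    canvas: tuple[int, int] = (64, 64)
    spacing_mm: float = 2.0
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(
            input_size=64, n_stacks=1, base_channels=8, heatmap_stride=4
        )
    )
    centralized_epochs: int = 20
    local_epochs: int = 30
    fed_local_epochs: int = 5
    fed_rounds: int = 6
    lr: float = 2e-3  # tiny model at low resolution tolerates a higher LR
    batch_size: int = 8


def run_study(seed: int, config: StudyConfig = StudyConfig()) -> dict:
    """One full study replicate; everything derives from ``seed``.

    Returns a dict with the evaluation records plus the headline summary
    numbers (pooled and external angle MAEs per arm).
    """
    cohort = generate_cohort(
        DEFAULT_PROFILES,
        n_patients=config.n_patients,
        rng_seed=derive_seed(seed, 11),
        canvas=config.canvas,
        spacing_mm=config.spacing_mm,
    )
    split = split_cohort(cohort, rng_seed=derive_seed(seed, 13))
    centers = sorted({s.center_id for s in cohort})

    net = HourglassNet(config.model)
    init = net.init_params(derive_seed(seed, 17))  # shared across arms

    base_cfg = TrainConfig(
        epochs=config.centralized_epochs,
        lr=config.lr,
        batch_size=config.batch_size,
        early_stop_patience=10,
        lr_decay_after=50,
        augment=False,
        seed=derive_seed(seed, 19),
    )

    central = train_centralized(cohort, split, config.model, base_cfg, init_params=init)

    locals_fit = {}
    for ci, center in enumerate(centers):
        cfg_c = TrainConfig(
            mode="local",
            epochs=config.local_epochs,
            lr=config.lr,
            batch_size=config.batch_size,
            early_stop_patience=10,
            lr_decay_after=50,
            augment=False,
            seed=derive_seed(seed, 23, ci),
        )
        locals_fit[center] = train_local(
            cohort, split, center, config.model, cfg_c, init_params=init
        )

    schedule = FLSchedule(
        strategy="fedavg",
        local_epochs=config.fed_local_epochs,
        rounds=config.fed_rounds,
        client_lr=config.lr,
        lr_decay_after=15,
        batch_size=config.batch_size,
    )
    train_by_center = {
        c: samples_in_split(cohort, split, "train", center=c) for c in centers
    }
    val_pooled = samples_in_split(cohort, split, "validation")
    fed_params, fed_history, _ = run_fl(
        train_by_center, val_pooled, schedule, config.model,
        rng_seed=derive_seed(seed, 29), init_params=init,
    )

    models = {
        "centralized": (central.best_params, "all"),
        "fedavg": (fed_params, "all"),
        **{f"local:{c}": (locals_fit[c].best_params, c) for c in centers},
    }
    records = cross_site_matrix(models, cohort, split, config.model)

    return {
        "records": records,
        "history": {"fedavg": fed_history},
        "split": split,
        "centers": centers,
        **summarize(records, centers),
    }


def summarize(records: list[EvalRecord], centers: list[str]) -> dict:
    """Headline numbers from a cross-site record list.

    External errors are means over ordered (train center c, test center
    t != c) pairs; for the federated/centralized models the same pairs are
    used (their per-pair error is their error on t), keeping the comparison
    weighted identically.
    """
    by = {(r.model_id, r.test_center): r for r in records}
    pairs = [(c, t) for c in centers for t in centers if t != c]

    def pooled(model_id: str) -> float:
        recs = [r for r in records if r.model_id == model_id]
        return float(
            np.average(
                [r.pooled_angle_mae() for r in recs],
                weights=[r.n_images for r in recs],
            )
        )

    def external_local() -> float:
        return float(
            np.mean([by[(f"local:{c}", t)].pooled_angle_mae() for c, t in pairs])
        )

    def external_global(model_id: str) -> float:
        return float(np.mean([by[(model_id, t)].pooled_angle_mae() for _, t in pairs]))

    local_internal = float(
        np.mean([by[(f"local:{c}", c)].pooled_angle_mae() for c in centers])
    )
    return {
        "centralized_pooled_mae_deg": pooled("centralized"),
        "fedavg_pooled_mae_deg": pooled("fedavg"),
        "fedavg_external_mae_deg": external_global("fedavg"),
        "centralized_external_mae_deg": external_global("centralized"),
        "local_external_mae_deg": external_local(),
        "local_internal_mae_deg": local_internal,
        "fedavg_to_centralized_ratio": pooled("fedavg") / pooled("centralized"),
        "n_test_images": int(
            sum(r.n_images for r in records if r.model_id == "fedavg")
        ),
    }
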