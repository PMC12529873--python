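"""Cross-silo federated protocols: FedAvg, FedOpt, FedProx.

All three are expressed as pure operations on named parameter vectors plus a
synchronous round loop.  Each round the server broadcasts the global
parameters, every client trains ``local_epochs`` epochs on its own private
split and returns only its updated parameters and training-set size (the
privacy boundary: no samples cross the server interface), and the server
aggregates:

* FedAvg — sample-size-weighted average Σ (n_k / Σn) θ_k.
* FedOpt — the averaged client delta is treated as a pseudo-gradient fed to
  a server-side adaptive-moment optimizer (FedAdam-style); a plain-average
  mode with server LR 1 reduces exactly to FedAvg.
* FedProx — FedAvg aggregation, but each client's objective carries a
  proximal penalty (μ/2)·||θ − θ_global||² limiting client drift.

Client updates are always reduced in sorted client-id order so results are
machine-reproducible regardless of the caller's ordering.

Default schedules follow the reference configuration: FedAvg 10 local epochs
× 30 rounds (client LR 1e-4, ×0.1 after 15 rounds), FedOpt 3 × 100 (client
1e-3, server 1e-4), FedProx 10 × 100 (client 1e-4); batch size 8 everywhere.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np

from .model import HourglassNet, ModelConfig
from .nn import Adam, ParamVector
from .synthetic import SpineSample
from .training import (
    TrainConfig,
    epoch_rng,
    lr_schedule,
    mean_landmark_error_mm,
    run_one_epoch,
)
from .utils import derive_seed


class AggregationError(ValueError):
    """Raised for empty or non-conformant aggregation inputs."""


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass
class ClientUpdate:
    """One hospital's post-round parameters; the unit of aggregation."""

    params: ParamVector
    n_samples: int
    client_id: str
    round_metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise AggregationError("client update must carry n_samples > 0")


@dataclass(frozen=True)
class FLSchedule:
    """Hyperparameters of one federated run."""

    strategy: str  # fedavg | fedopt | fedprox
    local_epochs: int
    rounds: int
    client_lr: float
    server_lr: float | None = None
    lr_decay_factor: float = 0.1
    lr_decay_after: int | None = None  # in rounds
    mu: float = 0.0  # FedProx proximal coefficient
    server_betas: tuple[float, float] = (0.9, 0.999)
    server_tau: float = 1e-9
    fedopt_plain: bool = False  # plain-average mode (equivalence testing)
    server_damping: float | None = None  # optional FedProx server-LR damping
    batch_size: int = 8

    def __post_init__(self) -> None:
        if self.strategy not in ("fedavg", "fedopt", "fedprox"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.local_epochs < 1 or self.rounds < 0:
            raise ValueError("local_epochs >= 1 and rounds >= 0 required")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.strategy == "fedopt" and self.server_lr is None:
            raise ValueError("fedopt requires a server_lr")

    @classmethod
    def default(cls, strategy: str, **overrides) -> "FLSchedule":
        """Reference schedule for each strategy."""
        base = {
            "fedavg": dict(
                strategy="fedavg", local_epochs=10, rounds=30, client_lr=1e-4,
                lr_decay_after=15,
            ),
            "fedopt": dict(
                strategy="fedopt", local_epochs=3, rounds=100, client_lr=1e-3,
                server_lr=1e-4,
            ),
            "fedprox": dict(
                strategy="fedprox", local_epochs=10, rounds=100, client_lr=1e-4,
                server_lr=1e-5, mu=0.01,
            ),
        }[strategy]
        base.update(overrides)
        return cls(**base)

    @property
    def total_local_epochs(self) -> int:
        return self.local_epochs * self.rounds


@dataclass
class ServerState:
    """The server's view of a federated run."""

    global_params: ParamVector
    round_index: int = 0
    m: dict | None = None  # FedOpt first moments
    v: dict | None = None  # FedOpt second moments


# --------------------------------------------------------------------------
# Aggregation operators
# --------------------------------------------------------------------------


def _check_conformant(updates: list[ClientUpdate]) -> list[ClientUpdate]:
    if not updates:
        raise AggregationError("no client updates to aggregate")
    updates = sorted(updates, key=lambda u: u.client_id)  # reproducible reduction
    layout = list(updates[0].params.keys())
    for u in updates[1:]:
        if list(u.params.keys()) != layout:
            raise AggregationError("client parameter layouts differ")
        for k in layout:
            if u.params[k].shape != updates[0].params[k].shape:
                raise AggregationError(f"shape mismatch in {k}")
    return updates


def fedavg_aggregate(updates: list[ClientUpdate]) -> ParamVector:
    """Sample-size-weighted parameter average, Σ (n_k / Σn) θ_k."""
    updates = _check_conformant(updates)
    total = float(sum(u.n_samples for u in updates))
    out: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for k in updates[0].params.keys():
        acc = np.zeros_like(updates[0].params[k])
        for u in updates:
            acc += (u.n_samples / total) * u.params[k]
        out[k] = acc
    return ParamVector(out)


def fedopt_server_step(
    state: ServerState, updates: list[ClientUpdate], schedule: FLSchedule
) -> ServerState:
    """Adaptive server update on the pseudo-gradient g = θ_global − avg(θ_k).

    In plain-average mode the step is θ ← θ − η·g (exactly the weighted
    average when η = 1); otherwise FedAdam-style moments are maintained,
    without bias correction, and θ ← θ − η·m / (√v + τ).
    """
    avg = fedavg_aggregate(updates)
    lr = schedule.server_lr if schedule.server_lr is not None else 1.0
    if schedule.fedopt_plain:
        if lr == 1.0:
            new = avg.copy()  # exact reduction to FedAvg
        else:
            new = state.global_params - (state.global_params - avg).scale(lr)
        return ServerState(global_params=new, round_index=state.round_index + 1)

    b1, b2 = schedule.server_betas
    g = state.global_params - avg
    m = state.m or {k: np.zeros_like(p) for k, p in state.global_params.items()}
    v = state.v or {k: np.zeros_like(p) for k, p in state.global_params.items()}
    new_arrays: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for k, p in state.global_params.items():
        m[k] = b1 * m[k] + (1 - b1) * g[k]
        v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
        new_arrays[k] = p - (lr * m[k] / (np.sqrt(v[k]) + schedule.server_tau)).astype(
            p.dtype
        )
    return ServerState(
        global_params=ParamVector(new_arrays),
        round_index=state.round_index + 1,
        m=m,
        v=v,
    )


def fedprox_client_objective(
    base_loss, params: ParamVector, global_params: ParamVector, mu: float
) -> float:
    """Proximal local objective: base_loss(θ) + (μ/2)·||θ − θ_global||²."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    penalty = 0.5 * mu * (params - global_params).sq_norm() if mu != 0.0 else 0.0
    return float(base_loss(params)) + penalty


# --------------------------------------------------------------------------
# Clients and the round loop
# --------------------------------------------------------------------------


class Client:
    """One hospital: private training samples behind a narrow interface.

    The only thing a client ever returns is a :class:`ClientUpdate`
    (parameters + sample count + scalar metrics); raw samples never cross
    the server boundary.
    """

    def __init__(self, client_id: str, train_samples: list[SpineSample], seed: int):
        self.client_id = client_id
        self._samples = train_samples
        self.seed = seed
        self.epochs_trained = 0

    @property
    def n_samples(self) -> int:
        return len(self._samples)

    def train_round(
        self,
        global_params: ParamVector,
        schedule: FLSchedule,
        round_index: int,
        model_cfg: ModelConfig,
        train_cfg: TrainConfig,
        dry_run: bool = False,
    ) -> ClientUpdate:
        params = global_params.copy()
        losses: list[float] = []
        if dry_run:
            self.epochs_trained += schedule.local_epochs
        else:
            net = HourglassNet(model_cfg)
            opt = Adam(params)
            lr = lr_schedule(
                round_index, schedule.client_lr, schedule.lr_decay_factor,
                schedule.lr_decay_after,
            )
            prox = (
                (schedule.mu, global_params)
                if schedule.strategy == "fedprox" and schedule.mu > 0
                else None
            )
            for e in range(schedule.local_epochs):
                global_epoch = round_index * schedule.local_epochs + e
                losses.append(
                    run_one_epoch(
                        net, params, opt, self._samples, lr,
                        epoch_rng(self.seed, global_epoch), train_cfg, prox=prox,
                    )
                )
                self.epochs_trained += 1
        return ClientUpdate(
            params=params,
            n_samples=self.n_samples,
            client_id=self.client_id,
            round_metrics={"train_loss": losses[-1] if losses else np.nan},
        )


def run_round(
    state: ServerState,
    clients: list[Client],
    schedule: FLSchedule,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    dry_run: bool = False,
) -> tuple[ServerState, list[ClientUpdate]]:
    """One synchronous federated round: broadcast, local training, aggregate."""
    if not clients:
        raise AggregationError("a round needs at least one client")
    updates = [
        c.train_round(
            state.global_params, schedule, state.round_index, model_cfg, train_cfg,
            dry_run=dry_run,
        )
        for c in sorted(clients, key=lambda c: c.client_id)
    ]
    if schedule.strategy == "fedopt":
        return fedopt_server_step(state, updates, schedule), updates
    new = fedavg_aggregate(updates)
    if schedule.strategy == "fedprox" and schedule.server_damping is not None:
        # optional damped server step mirroring a configured server LR
        new = state.global_params - (state.global_params - new).scale(
            schedule.server_damping
        )
    return (
        ServerState(global_params=new, round_index=state.round_index + 1),
        updates,
    )


def run_fl(
    train_by_center: dict[str, list[SpineSample]],
    val_samples: list[SpineSample],
    schedule: FLSchedule,
    model_cfg: ModelConfig,
    rng_seed: int,
    init_params: ParamVector | None = None,
    train_cfg: TrainConfig | None = None,
    dry_run: bool = False,
):
    """Full federated run with pooled-validation checkpoint selection.

    Returns (best_params, history, clients); history has one record per round
    with the pooled validation metric, per-client sizes and losses.  With
    ``dry_run`` no gradients are computed — the loop only exercises its
    scheduling counters (each client's ``epochs_trained``).
    """
    net = HourglassNet(model_cfg)
    if train_cfg is None:
        train_cfg = TrainConfig(
            mode="federated-client", epochs=schedule.local_epochs,
            lr=schedule.client_lr, batch_size=schedule.batch_size, augment=False,
        )
    clients = [
        Client(cid, samples, seed=derive_seed(rng_seed, i))
        for i, (cid, samples) in enumerate(sorted(train_by_center.items()))
    ]
    params0 = (
        init_params.copy() if init_params is not None else net.init_params(rng_seed)
    )
    state = ServerState(global_params=params0)
    best_params = state.global_params.copy()
    best_val = np.inf
    history: list[dict] = []
    for r in range(schedule.rounds):
        state, updates = run_round(
            state, clients, schedule, model_cfg, train_cfg, dry_run=dry_run
        )
        rec: dict = {"round": r, "clients": {}}
        for u in updates:
            rec["clients"][u.client_id] = {
                "n_samples": u.n_samples, **u.round_metrics
            }
        if not dry_run and val_samples:
            val = mean_landmark_error_mm(net, state.global_params, val_samples)
            rec["val_metric"] = val
            if val < best_val - 1e-12:
                best_val = val
                best_params = state.global_params.copy()
        else:
            best_params = state.global_params.copy()
        history.append(rec)
    if not history:
        best_params = state.global_params.copy()
    return best_params, history, clients
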