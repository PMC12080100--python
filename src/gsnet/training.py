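"""Training: target normalization, masked multi-target MSE, the Adam
schedule with its epoch-50 learning-rate drop, early stopping,
repeat-and-select training, and the frozen / fine-tune transfer modes.

Targets are z-scored with statistics fitted on the training split only;
entries whose availability mask is off contribute exactly zero to both the
loss and every parameter gradient (they are multiplied out before any
reduction, so the zero is algebraic, not numerical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from .model import GNNModel
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "NormStats",
    "Example",
    "fit_normalization",
    "masked_mse",
    "train",
    "train_repeats",
    "select_best",
    "top_k_summary",
    "evaluate",
    "TrainResult",
]

TRANSFER_MODES = ("fresh", "transfer_frozen", "transfer_finetune")


@dataclass
class TrainConfig:
    lr_initial: float = 1e-4
    lr_after_switch: float = 1e-5
    lr_switch_epoch: int = 50  # lr drops starting with epoch 51
    batch_size: int = 64
    patience: int = 10  # early stopping on validation loss (strict improvement)
    max_epochs: int = 500
    fixed_epochs: int | None = None  # e.g. 10 for rSASA, 100 for pKa regimes
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("lr_initial", "lr_after_switch", "batch_size", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class NormStats:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * self.sd + self.mean


@dataclass
class Example:
    """One training example: a featurized graph plus its (masked) targets.

    ``residue_index`` is set for per-residue heads (rSASA, pKa) and selects
    the readout center; ``y``/``mask`` are length-6 for the global6 head and
    length-1 otherwise.
    """

    graph: object
    y: np.ndarray
    mask: np.ndarray = field(default=None)
    residue_index: int | None = None

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        if self.mask is None:
            self.mask = np.ones_like(self.y, dtype=bool)
        self.mask = np.atleast_1d(np.asarray(self.mask, dtype=bool))


def fit_normalization(examples: list[Example]) -> NormStats:
    """Per-target mean/sd over masked-in training values only."""
    Y = np.stack([e.y for e in examples])
    M = np.stack([e.mask for e in examples])
    n_per = M.sum(axis=0)
    if (n_per < 2).any():
        raise ValueError(f"need >= 2 masked-in records per target, got counts {n_per}")
    mean = np.array([Y[M[:, j], j].mean() for j in range(Y.shape[1])])
    sd = np.array([Y[M[:, j], j].std(ddof=0) for j in range(Y.shape[1])])
    if (sd <= 0).any():
        raise ValueError("zero-variance target; cannot normalize")
    return NormStats(mean=mean, sd=sd)


def normalize_examples(examples: list[Example], stats: NormStats) -> list[Example]:
    return [Example(graph=e.graph, y=stats.apply(e.y), mask=e.mask, residue_index=e.residue_index) for e in examples]


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """MSE over masked-in entries; masked-out entries contribute exactly 0
    to loss and gradients, and the denominator counts only masked-in entries."""
    mask = np.asarray(mask, dtype=float)
    n_in = mask.sum()
    if n_in == 0:
        logger.warning("batch fully masked; loss defined as 0")
        return pred.sum() * 0.0
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    sq = diff * diff * Tensor(mask)
    return sq.sum() * (1.0 / n_in)


def _batch_forward(model: GNNModel, batch: list[Example], rng=None) -> Tensor:
    preds = [model.forward(e.graph, e.residue_index, rng).reshape(1, -1) for e in batch]
    return concat(preds, axis=0)


def _batch_loss(model: GNNModel, batch: list[Example], rng=None) -> Tensor:
    pred = _batch_forward(model, batch, rng)
    target = np.stack([e.y for e in batch])
    mask = np.stack([e.mask for e in batch])
    return masked_mse(pred, target, mask)


def evaluate(model: GNNModel, examples: list[Example]) -> float:
    """Validation loss (eval mode, no dropout), averaged over all entries."""
    was = model.training
    model.eval()
    loss = _batch_loss(model, examples).data.item()
    model.train(was)
    return float(loss)


@dataclass
class TrainResult:
    model: GNNModel
    history: pd.DataFrame
    best_val_loss: float
    best_epoch: int
    repeat_index: int = 0


def train(
    model: GNNModel,
    train_set: list[Example],
    val_set: list[Example],
    config: TrainConfig,
    mode: str = "fresh",
) -> TrainResult:
    """Train ``model`` in place and return it with its best-epoch weights.

    Modes: ``fresh`` and ``transfer_finetune`` optimize every parameter
    (for fine-tuning the caller loads a pretrained checkpoint first);
    ``transfer_frozen`` optimizes only the output head — the message-passing
    parameters are bit-identical before and after.

    Schedule: Adam at ``lr_initial``, dropped to ``lr_after_switch`` from
    epoch ``lr_switch_epoch``+1 on (optimizer moments are not reset). With
    ``fixed_epochs`` set the run is exactly that long; otherwise it stops
    after ``patience`` epochs without strict validation improvement.
    """
    if mode not in TRANSFER_MODES:
        raise ValueError(f"mode must be one of {TRANSFER_MODES}")
    params = model.head_parameters() if mode == "transfer_frozen" else model.parameters()
    opt = Adam(params, lr=config.lr_initial)
    rng = np.random.default_rng(config.seed)
    n_epochs = config.fixed_epochs if config.fixed_epochs is not None else config.max_epochs

    best_val = np.inf
    best_state = None
    best_epoch = -1
    since_improve = 0
    rows = []
    order = np.arange(len(train_set))
    model.train(True)
    for epoch in range(1, n_epochs + 1):
        opt.lr = config.lr_initial if epoch <= config.lr_switch_epoch else config.lr_after_switch
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[j] for j in order[start : start + config.batch_size]]
            loss = _batch_loss(model, batch, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.data.item())
        val_loss = evaluate(model, val_set) if val_set else float("nan")
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), "val_loss": val_loss, "lr": opt.lr})
        if val_set and val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        if config.fixed_epochs is None and val_set and since_improve >= config.patience:
            break
    model.eval()
    if best_state is not None and config.fixed_epochs is None:
        model.load_state_dict(best_state)
    elif val_set:
        best_val = val_loss
        best_epoch = len(rows)
    return TrainResult(model=model, history=pd.DataFrame(rows), best_val_loss=float(best_val), best_epoch=best_epoch)


def train_repeats(
    model_factory,
    train_set: list[Example],
    val_set: list[Example],
    config: TrainConfig,
    mode: str = "fresh",
) -> list[TrainResult]:
    """Run ``config.n_repeats`` independent trainings (seeded streams)."""
    results = []
    for rep in range(config.n_repeats):
        model = model_factory(rep)
        cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + 1000 * rep})
        res = train(model, train_set, val_set, cfg, mode=mode)
        res.repeat_index = rep
        results.append(res)
    return results


def select_best(results: list[TrainResult]) -> int:
    """Index of the repeat with the lowest validation loss (ties → lowest index)."""
    if not results:
        raise ValueError("no completed repeats")
    losses = [r.best_val_loss for r in results]
    return int(np.argmin(losses))  # argmin returns the first minimum


def top_k_summary(values_by_repeat: list[float], selector: list[float], k: int = 10) -> dict:
    """Mean ± SEM of ``values_by_repeat`` over the ``k`` repeats with the
    lowest ``selector`` (e.g. test RMSE of the top-10 by validation RMSE)."""
    order = np.argsort(selector, kind="stable")[:k]
    vals = np.asarray(values_by_repeat)[order]
    sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return {"mean": float(vals.mean()), "sem": float(sem), "indices": order.tolist()}
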