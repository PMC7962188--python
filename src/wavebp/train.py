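"""Training protocol: subject-aware 70/15/15 split, Adam + MSE at batch 4,
early stopping with patience 5, best-validation checkpointing.

Splitting defaults to subject level so that no subject contributes windows
to more than one of train/validation/test; this is the stricter reading of
"completely separated" splits and prevents within-subject leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, ParameterError, SplitError, StateError
from .nn import Adam
from .nn.layers import DTYPE
from .preprocess import NormalizationParams, denormalize, normalize
from .unet1d import UNet1D

__all__ = ["TrainConfig", "TrainingHistory", "split_dataset", "train_model",
           "predict_abp"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 5
    min_improvement: float = 1e-6   # validation-loss decrease that counts
    split_fractions: tuple = (0.70, 0.15, 0.15)
    split_unit: str = "subject"     # or "window"
    seed: int = 0

    def validate(self) -> None:
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("batch_size and max_epochs must be >= 1")
        f = self.split_fractions
        if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ParameterError(
                "split_fractions must be three positive numbers summing to 1")
        if self.split_unit not in ("subject", "window"):
            raise ParameterError("split_unit must be 'subject' or 'window'")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0     # 1-based
    stopped_epoch: int = 0  # 1-based
    stop_reason: str = ""

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]


def _largest_remainder(n: int, fractions) -> list[int]:
    """Integer apportionment of n items by the largest-remainder method.

    When ``n >= len(fractions)`` every part receives at least one item (the
    deficit is taken from the largest part), so small cohorts still yield a
    usable train/val/test partition.
    """
    quotas = [f * n for f in fractions]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in sorted(range(len(fractions)), key=lambda i: -remainders[i]):
        if sum(counts) == n:
            break
        counts[i] += 1
    if n >= len(fractions):
        for i, c in enumerate(counts):
            if c == 0:
                counts[counts.index(max(counts))] -= 1
                counts[i] = 1
    return counts


def split_dataset(pairs, config: TrainConfig | None = None):
    """Partition window pairs into (train, val, test).

    With ``split_unit='subject'`` whole subjects are assigned to splits and
    sizes approximate the fractions by largest-remainder apportionment of
    subject counts; deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    config.validate()
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("cannot split an empty dataset")
    rng = np.random.default_rng(config.seed)
    if config.split_unit == "subject":
        subjects = sorted({p.subject_id for p in pairs})
        if len(subjects) < 3:
            raise SplitError(
                f"subject-level split needs >= 3 subjects, got {len(subjects)}")
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        counts = _largest_remainder(len(order), config.split_fractions)
        train_s = set(order[:counts[0]])
        val_s = set(order[counts[0]:counts[0] + counts[1]])
        splits = (
            [p for p in pairs if p.subject_id in train_s],
            [p for p in pairs if p.subject_id in val_s],
            [p for p in pairs if p.subject_id not in train_s | val_s])
    else:
        order = rng.permutation(len(pairs))
        counts = _largest_remainder(len(pairs), config.split_fractions)
        idx = (order[:counts[0]], order[counts[0]:counts[0] + counts[1]],
               order[counts[0] + counts[1]:])
        splits = tuple([pairs[i] for i in part] for part in idx)
    if any(len(s) == 0 for s in splits):
        raise SplitError("a split received no windows; need more data")
    return splits


def _to_arrays(pairs, norm: NormalizationParams):
    x = np.stack([normalize(p.ppg_w, norm.ppg_min, norm.ppg_max)
                  for p in pairs])[:, None, :].astype(DTYPE)
    y = np.stack([normalize(p.abp_w, norm.abp_min, norm.abp_max)
                  for p in pairs])[:, None, :].astype(DTYPE)
    return x, y


def _mse_eval(model: UNet1D, x: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> float:
    total = 0.0
    for i in range(0, len(x), batch_size):
        pred = model.forward(x[i:i + batch_size])
        total += float(np.sum((pred - y[i:i + batch_size]) ** 2))
    return total / y.size


def train_model(model: UNet1D, train_pairs, val_pairs,
                config: TrainConfig | None = None,
                norm: NormalizationParams | None = None,
                val_loss_fn=None, verbose: bool = False):
    """Minimize MSE on normalized windows; early-stop on validation loss.

    ``norm`` must be fitted on the training split. Training stops when the
    validation loss has not improved by at least ``config.min_improvement``
    for ``config.patience`` consecutive epochs, or at ``max_epochs``; the
    returned model carries the weights of the best-validation epoch.
    ``val_loss_fn(model) -> float``, when given, replaces the validation MSE
    evaluation (used for protocol tests).
    """
    config = config or TrainConfig()
    config.validate()
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ParameterError("empty training set")
    if norm is None:
        from .preprocess import fit_normalization
        norm = fit_normalization(train_pairs)
    x_tr, y_tr = _to_arrays(train_pairs, norm)
    if val_loss_fn is None:
        if not val_pairs:
            raise ParameterError("empty validation set")
        x_va, y_va = _to_arrays(list(val_pairs), norm)
        val_loss_fn = lambda m: _mse_eval(m, x_va, y_va)  # noqa: E731

    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    epochs_no_improve = 0
    n = len(x_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        running = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, train=True)
            diff = pred - yb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            running += loss * len(idx)
            opt.zero_grad()
            model.backward((2.0 * diff / diff.size).astype(DTYPE))
            opt.step()
        train_loss = running / n
        val_loss = float(val_loss_fn(model))
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.6f}  "
                  f"val {val_loss:.6f}")
        if val_loss < best_val - config.min_improvement:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            epochs_no_improve = 0
        else:
            epochs_no_improve += 1
        history.stopped_epoch = epoch
        if epochs_no_improve >= config.patience:
            history.stop_reason = "early-stopping"
            break
    else:
        history.stop_reason = "max-epochs"
    model.set_weights(best_weights)
    return model, history


def predict_abp(model: UNet1D, ppg_window_raw,
                norm_params: NormalizationParams) -> np.ndarray:
    """Predict one or more ABP windows (mmHg) from raw PPG windows.

    Normalizes the input with the PPG min/max, runs the network, and
    de-normalizes the output with the saved ABP min/max.
    """
    if norm_params is None:
        raise StateError("norm_params is required (fit on training split)")
    x = np.asarray(ppg_window_raw, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    xn = normalize(x, norm_params.ppg_min, norm_params.ppg_max)
    yn = model.predict(xn.astype(DTYPE))
    y = denormalize(yn.astype(np.float64), norm_params.abp_min,
                    norm_params.abp_max)
    return y[0] if single else y
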