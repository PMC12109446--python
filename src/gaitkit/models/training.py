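"""Training loop (Adam, L1 loss, best-validation checkpointing) and
sliding-window inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..preprocess import Normalizer
from ..types import SignalRecording
from ..windows import DatasetSplit, WindowPair, stack_pairs
from ._autodiff import Tensor
from ._layers import Module
from .architectures import ModelConfig, build_network


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """A network plus everything needed to apply it to new recordings."""

    network: Module
    config: ModelConfig
    in_channels: int
    channel_names: tuple[str, ...] = ()
    normalizer: Normalizer | None = None
    history: list[dict] = field(default_factory=list)
    best_val_mae: float = float("nan")
    best_epoch: int = -1

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Stance probabilities for an (N, ω, C) batch of windows."""
        from ._autodiff import no_grad

        self.network.set_training(False)
        out = []
        with no_grad():
            for start in range(0, len(X), batch_size):
                pred = self.network(Tensor(X[start : start + batch_size]))
                out.append(np.atleast_1d(pred.data))
        return np.concatenate(out)

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.network.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.network.parameters(), weights, strict=True):
            p.data = w.copy()


def build_model(cfg: ModelConfig, in_channels: int,
                channel_names: tuple[str, ...] = ()) -> TrainedModel:
    return TrainedModel(
        network=build_network(cfg, in_channels),
        config=cfg,
        in_channels=in_channels,
        channel_names=tuple(channel_names),
    )


def _mae(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.abs(model.predict(X) - y)))


def train(model: TrainedModel, split: DatasetSplit,
          cfg: ModelConfig | None = None, verbose: bool = False) -> TrainedModel:
    """Minimize mean |prediction − label| with Adam; keep best-validation weights.

    Validation MAE is measured after every epoch; the weights with the
    lowest validation MAE are restored at the end (ties go to the earlier
    epoch).  Deterministic for a fixed config seed.
    """
    cfg = cfg or model.config
    if not split.train or not split.val:
        raise ValueError("train and validation partitions must be non-empty")
    Xtr, ytr = stack_pairs(split.train)
    Xva, yva = stack_pairs(split.val)
    if Xtr.shape[2] != model.in_channels:
        raise ValueError(
            f"window channel count {Xtr.shape[2]} != model in_channels "
            f"{model.in_channels}"
        )
    rng = np.random.default_rng(cfg.seed + 1)  # batch-order substream
    opt = Adam(model.network.parameters(), lr=cfg.lr)
    best_weights = model.get_weights()
    best_val, best_epoch = np.inf, -1
    for epoch in range(cfg.epochs):
        model.network.set_training(True)
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model.network(Tensor(Xtr[idx]))
            loss = (pred - Tensor(ytr[idx])).abs().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_mae = float(np.mean(losses))
        val_mae = _mae(model, Xva, yva)
        model.history.append(
            {"epoch": epoch, "train_mae": train_mae, "val_mae": val_mae}
        )
        if val_mae < best_val:
            best_val, best_epoch = val_mae, epoch
            best_weights = model.get_weights()
        if verbose:
            print(f"epoch {epoch:3d}  train {train_mae:.4f}  val {val_mae:.4f}")
    model.set_weights(best_weights)
    model.best_val_mae = float(best_val)
    model.best_epoch = best_epoch
    return model


def predict_trace(model: TrainedModel, rec: SignalRecording,
                  window: int = 40) -> np.ndarray:
    """Sliding-window stance-probability trace for one preprocessed recording.

    The returned trace has length n − ω and is aligned to samples
    ω … n−1 (the label each window predicts); the first ω samples of the
    recording have no prediction.
    """
    n = rec.n_samples
    if n <= window:
        raise ValueError(f"recording length {n} must exceed window {window}")
    mat = rec.channel_matrix()
    if mat.shape[1] != model.in_channels:
        raise ValueError(
            f"recording has {mat.shape[1]} channels, model expects "
            f"{model.in_channels}"
        )
    X = np.stack([mat[t : t + window] for t in range(n - window)])
    return model.predict(X)


def save_checkpoint(model: TrainedModel, path) -> None:
    """Single-file checkpoint: weights + config + normalization stats."""
    import json

    meta = {
        "config": {**vars(model.config),
                   "tcn_dilations": list(model.config.tcn_dilations)},
        "in_channels": model.in_channels,
        "channel_names": list(model.channel_names),
        "normalizer": None
        if model.normalizer is None
        else {"mean": model.normalizer.mean, "std": model.normalizer.std},
        "history": model.history,
        "best_val_mae": model.best_val_mae,
        "best_epoch": model.best_epoch,
    }
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, meta=json.dumps(meta), **weights)


def load_checkpoint(path) -> TrainedModel:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
    cfg_dict = meta["config"]
    cfg_dict["tcn_dilations"] = tuple(cfg_dict["tcn_dilations"])
    cfg = ModelConfig(**cfg_dict)
    model = build_model(cfg, meta["in_channels"], tuple(meta["channel_names"]))
    model.set_weights(weights)
    if meta["normalizer"] is not None:
        model.normalizer = Normalizer(**meta["normalizer"])
    model.history = meta["history"]
    model.best_val_mae = meta["best_val_mae"]
    model.best_epoch = meta["best_epoch"]
    return model
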