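"""The convolutional autoencoder used for artifact screening.

Architecture (full scale, input 500x500x1):

    Conv2D(126, 2x2, ReLU)          -> 500 x 500 x 126
    MaxPool(2x2)                    -> 250 x 250 x 126
    Conv2D(256, 5x5, ReLU)          -> 250 x 250 x 256
    MaxPool(2x2)                    -> 125 x 125 x 256   (bottleneck)
    ConvTranspose(256, 5x5, s2, ReLU) -> 250 x 250 x 256
    ConvTranspose(126, 2x2, s2, ReLU) -> 500 x 500 x 126
    Conv2D(1, 2x2, ReLU)            -> 500 x 500 x 1

The model is trained with the input as its own target (MSE loss, Adam) on
artifact-free images only, so structures absent from authentic data
reconstruct poorly. A ``scale`` knob shrinks the input side and filter
counts together for desk-scale runs; the default configuration reproduces
the full architecture above.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .nn import Adam, Conv2D, ConvTranspose2D, MaxPool2D, Sequential


@dataclass(frozen=True)
class CAEConfig:
    input_side: int = 500
    filters: tuple[int, int] = (126, 256)
    kernels: tuple[int, int] = (2, 5)
    pool: int = 2
    epochs: int = 8
    batch_size: int = 2
    learning_rate: float = 1e-3
    seed: int = 0
    scale: float = 1.0

    def validate(self) -> None:
        if self.effective_side % self.pool**2:
            raise ValidationError(
                f"input_side {self.effective_side} must be divisible by pool^2 = {self.pool**2}"
            )
        if min(self.effective_filters) < 1:
            raise ValidationError(f"filters must be >= 1, got {self.filters}")
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")

    @property
    def effective_side(self) -> int:
        return int(round(self.input_side * self.scale))

    @property
    def effective_filters(self) -> tuple[int, int]:
        return tuple(max(1, int(round(f * self.scale))) for f in self.filters)

    def replace(self, **kw) -> "CAEConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        d["kernels"] = list(self.kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CAEConfig":
        d = dict(d)
        d["filters"] = tuple(d["filters"])
        d["kernels"] = tuple(d["kernels"])
        return cls(**d)


@dataclass
class ValidationMetrics:
    """Per-epoch model quality on held-out images.

    ``mse_clean`` is the mean per-image reconstruction MSE over artifact-free
    validation images; ``pct_diff`` is the percent excess of the mean MSE of
    artifact-laden over artifact-free validation images — the quantity the
    screening method needs to be large.
    """

    mse_clean: float
    pct_diff: float | None = None


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    mse_clean: float | None = None
    pct_diff: float | None = None


class CAE:
    """A (possibly trained) convolutional autoencoder."""

    def __init__(self, config: CAEConfig):
        config.validate()
        self.config = config
        f1, f2 = config.effective_filters
        k1, k2 = config.kernels
        p = config.pool
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
        self.model = Sequential([
            Conv2D(1, f1, k1, rng),
            MaxPool2D(p),
            Conv2D(f1, f2, k2, rng),
            MaxPool2D(p),
            ConvTranspose2D(f2, f2, k2, p, rng),
            ConvTranspose2D(f2, f1, k1, p, rng),
            Conv2D(f1, 1, k1, rng),
        ])
        self.history: list[EpochRecord] = []

    # -- shape bookkeeping -------------------------------------------------

    def layer_output_shapes(self) -> list[tuple[int, int, int]]:
        s = self.config.effective_side
        return self.model.output_shapes((s, s, 1))

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        return self.layer_output_shapes()[3]

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return self.layer_output_shapes()[-1]

    # -- inference ---------------------------------------------------------

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValidationError(f"expected (H, W) or (N, H, W) images, got shape {arr.shape}")
        s = self.config.effective_side
        if arr.shape[1:] != (s, s):
            raise ValidationError(
                f"image side {arr.shape[1:]} does not match model input side {s}"
            )
        return arr[..., None]

    def reconstruct(self, images: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Forward pass; returns reconstructions with the input's shape."""
        single = np.asarray(images).ndim == 2
        x = self._as_batch(images)
        bs = batch_size or self.config.batch_size
        out = np.concatenate(
            [self.model.forward(x[i:i + bs]) for i in range(0, len(x), bs)]
        )[..., 0]
        return out[0] if single else out

    def per_image_mse(self, images: np.ndarray) -> np.ndarray:
        """Mean squared reconstruction error of each image."""
        x = self._as_batch(images)[..., 0].astype(np.float64)
        rec = self.reconstruct(x.astype(np.float32)).astype(np.float64)
        return ((x - rec) ** 2).mean(axis=(1, 2))

    # -- training ----------------------------------------------------------

    def validation_metrics(self, clean_val: np.ndarray,
                           artifact_val: np.ndarray | None = None) -> ValidationMetrics:
        """MSE on artifact-free images and, when artifact-laden validation
        images are supplied, the percent difference between the two groups."""
        clean_val = np.asarray(clean_val)
        if clean_val.size == 0:
            raise ValidationError("clean validation set is empty")
        mse_clean = float(self.per_image_mse(clean_val).mean())
        pct = None
        if artifact_val is not None:
            artifact_val = np.asarray(artifact_val)
            if artifact_val.size == 0:
                raise ValidationError("artifact validation set is empty")
            mse_art = float(self.per_image_mse(artifact_val).mean())
            pct = 100.0 * (mse_art - mse_clean) / mse_clean if mse_clean > 0 else np.inf
        return ValidationMetrics(mse_clean=mse_clean, pct_diff=pct)

    def train(self, clean_train: np.ndarray,
              clean_val: np.ndarray | None = None,
              artifact_val: np.ndarray | None = None,
              select_best: bool = False,
              verbose: bool = False) -> "CAE":
        """Fit the autoencoder on artifact-free images (input = target).

        Runs ``config.epochs`` epochs of Adam on MSE loss, shuffling each
        epoch with the config seed. When validation sets are given, records
        per-epoch :class:`ValidationMetrics`; with ``select_best`` the
        weights of the epoch with the largest percent difference are kept
        instead of the final ones (a low clean MSE does not necessarily give
        the best artifact separation).
        """
        x = self._as_batch(clean_train)
        if len(x) == 0:
            raise ValidationError("training set is empty")
        if select_best and (clean_val is None or artifact_val is None):
            raise ValidationError("select_best requires both validation sets")
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
        opt = Adam(self.model.layers, lr=cfg.learning_rate)
        self.history = []
        best = (-np.inf, None)
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), cfg.batch_size):
                batch = x[order[i:i + cfg.batch_size]]
                losses.append(self.model.train_batch(batch, batch, opt))
            rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)))
            if clean_val is not None:
                vm = self.validation_metrics(clean_val, artifact_val)
                rec.mse_clean, rec.pct_diff = vm.mse_clean, vm.pct_diff
                if select_best and vm.pct_diff is not None and vm.pct_diff > best[0]:
                    best = (vm.pct_diff, self._weight_copy())
            self.history.append(rec)
            if verbose:
                print(f"epoch {epoch}: train_loss={rec.train_loss:.3e} "
                      f"mse_clean={rec.mse_clean} pct_diff={rec.pct_diff}")
        if select_best and best[1] is not None:
            self._set_weights(best[1])
        return self

    def _weight_copy(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.model.layers]

    def _set_weights(self, weights):
        for l, w in zip(self.model.layers, weights):
            for k in l.params:
                l.params[k][...] = w[k]

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write config + weights + history to one ``.npz`` archive."""
        arrays = {}
        for i, l in enumerate(self.model.layers):
            for k, v in l.params.items():
                arrays[f"layer{i}_{k}"] = v
        meta = {"config": self.config.to_dict(),
                "history": [dataclasses.asdict(r) for r in self.history]}
        np.savez_compressed(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            model = cls(CAEConfig.from_dict(meta["config"]))
            for i, l in enumerate(model.model.layers):
                for k in l.params:
                    stored = data[f"layer{i}_{k}"]
                    if stored.shape != l.params[k].shape:
                        raise ValidationError(
                            f"stored weights for layer {i}/{k} have shape {stored.shape}, "
                            f"expected {l.params[k].shape}"
                        )
                    l.params[k][...] = stored
        model.history = [EpochRecord(**r) for r in meta["history"]]
        return model


def build_cae(config: CAEConfig | None = None) -> CAE:
    """Construct an untrained autoencoder from a configuration."""
    return CAE(config or CAEConfig())
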