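"""The configurable encoder-decoder dense segmentation CNN.

The architecture follows a fixed skeleton whose per-layer hyperparameters
are supplied by a :class:`~neoseg.config_space.NetworkConfiguration`:

* three encoder dense blocks separated by two searchable pooling stages
  (each 2x window, stride 2, max or average);
* three decoder dense blocks with parameter-free nearest-neighbour 2x
  upsampling before the first two, restoring the input extent;
* a searchable final feature convolution, then a fixed 1x1(x1) convolution
  projecting to the class count, and a per-voxel softmax.

Each dense block stacks three convolution -> batch-norm -> ReLU layers with
dense connectivity: layer ``l`` receives the block input concatenated with
the outputs of all earlier layers in the block, so the third layer sees
``C_in + N1 + N2`` channels.  The block output is the third layer's output.

Filter "length x width" maps to the two in-plane kernel extents; for 3D
inputs the third kernel extent is ``min(length, 3)`` to keep volumetric
kernels small.  All convolutions use same-padding, so the output label map
has the input's spatial extent for every genotype.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._engine import (
    Adam,
    BatchNorm,
    ConvND,
    Pool2,
    ReLU,
    Upsample2,
    ce_dice_loss_and_grad,
    softmax_channel,
)
from .config_space import ConvLayerAction, NetworkConfiguration, PoolingAction
from .metrics import LabelVolume

__all__ = [
    "ShapeError",
    "DataError",
    "TrainingSettings",
    "TrainingHistory",
    "ModelSpec",
    "SegmentationModel",
    "build_model",
    "train_candidate",
    "predict_segmentation",
    "DOWNSAMPLE_FACTOR",
]

DOWNSAMPLE_FACTOR = 4  # two 2x pooling stages


class ShapeError(ValueError):
    """Raised when an input extent is incompatible with the architecture."""


class DataError(ValueError):
    """Raised for empty or malformed training datasets."""


@dataclass
class TrainingSettings:
    """Candidate-training settings.

    ``max_epochs``/``patience_epochs`` default to 200/15: training stops at
    the epoch cap or after ``patience_epochs`` consecutive epochs without
    improvement of the monitored quantity (validation mean Dice when a
    validation set is supplied, otherwise the negative training loss).
    """

    max_epochs: int = 200
    patience_epochs: int = 15
    batch_size: int = 8
    patch_shape: Tuple[int, ...] = (32, 32, 32)
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience_epochs must not exceed max_epochs")


@dataclass
class TrainingHistory:
    epochs: List[int] = field(default_factory=list)
    losses: List[float] = field(default_factory=list)
    metrics: List[float] = field(default_factory=list)
    diverged: bool = False

    def append(self, epoch: int, loss: float, metric: float) -> None:
        self.epochs.append(epoch)
        self.losses.append(loss)
        self.metrics.append(metric)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss", "monitored_metric"])
            for e, l, m in zip(self.epochs, self.losses, self.metrics):
                writer.writerow([e, l, m])


@dataclass
class ModelSpec:
    """Architecture-level description resolved from a genotype."""

    config: NetworkConfiguration
    n_modalities: int
    n_classes: int = 4
    spatial_rank: int = 3

    def __post_init__(self) -> None:
        if self.spatial_rank not in (2, 3):
            raise ShapeError(f"spatial_rank must be 2 or 3, got {self.spatial_rank}")


def _kernel_for(action: ConvLayerAction, spatial_rank: int) -> Tuple[int, ...]:
    if spatial_rank == 2:
        return (action.filter_length, action.filter_width)
    return (action.filter_length, action.filter_width, min(action.filter_length, 3))


class _ConvUnit:
    """convolution -> batch normalisation -> ReLU."""

    def __init__(self, in_ch: int, action: ConvLayerAction, spatial_rank: int,
                 rng: np.random.Generator) -> None:
        self.conv = ConvND(in_ch, action.n_filters, _kernel_for(action, spatial_rank), rng)
        self.bn = BatchNorm(action.n_filters)
        self.relu = ReLU()
        self.out_channels = action.n_filters

    @property
    def params(self):
        return self.conv.params + self.bn.params

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class _DenseBlock:
    """Three conv units with dense (concatenating) connectivity."""

    def __init__(self, in_ch: int, actions: Sequence[ConvLayerAction],
                 spatial_rank: int, rng: np.random.Generator) -> None:
        assert len(actions) == 3
        self.in_channels = in_ch
        n1, n2 = actions[0].n_filters, actions[1].n_filters
        self.units = [
            _ConvUnit(in_ch, actions[0], spatial_rank, rng),
            _ConvUnit(in_ch + n1, actions[1], spatial_rank, rng),
            _ConvUnit(in_ch + n1 + n2, actions[2], spatial_rank, rng),
        ]
        self.out_channels = actions[2].n_filters
        self.layer_in_channels = [u.conv.in_channels for u in self.units]

    @property
    def params(self):
        return [p for u in self.units for p in u.params]

    def forward(self, x, train=True):
        h1 = self.units[0].forward(x, train)
        h2 = self.units[1].forward(np.concatenate([x, h1], axis=1), train)
        h3 = self.units[2].forward(np.concatenate([x, h1, h2], axis=1), train)
        return h3

    def backward(self, dh3):
        c0 = self.in_channels
        n1 = self.units[0].out_channels
        d_in3 = self.units[2].backward(dh3)
        dx = d_in3[:, :c0]
        dh1 = d_in3[:, c0:c0 + n1]
        dh2 = d_in3[:, c0 + n1:]
        d_in2 = self.units[1].backward(dh2)
        dx = dx + d_in2[:, :c0]
        dh1 = dh1 + d_in2[:, c0:]
        dx = dx + self.units[0].backward(dh1)
        return dx


class SegmentationModel:
    """A trainable instance of the configurable encoder-decoder network."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        cfg = spec.config
        acts = cfg.conv_actions
        rank = spec.spatial_rank

        self.enc1 = _DenseBlock(spec.n_modalities, acts[0:3], rank, rng)
        self.pool1 = Pool2("max" if cfg.pooling_actions[0] is PoolingAction.MAX else "avg")
        self.enc2 = _DenseBlock(self.enc1.out_channels, acts[3:6], rank, rng)
        self.pool2 = Pool2("max" if cfg.pooling_actions[1] is PoolingAction.MAX else "avg")
        self.enc3 = _DenseBlock(self.enc2.out_channels, acts[6:9], rank, rng)
        self.up1 = Upsample2()
        self.dec1 = _DenseBlock(self.enc3.out_channels, acts[9:12], rank, rng)
        self.up2 = Upsample2()
        self.dec2 = _DenseBlock(self.dec1.out_channels, acts[12:15], rank, rng)
        self.dec3 = _DenseBlock(self.dec2.out_channels, acts[15:18], rank, rng)
        self.feature_unit = _ConvUnit(self.dec3.out_channels, acts[18], rank, rng)
        self.class_head = ConvND(
            self.feature_unit.out_channels, spec.n_classes, (1,) * rank, rng
        )
        self.blocks = [self.enc1, self.enc2, self.enc3, self.dec1, self.dec2, self.dec3]

    @property
    def params(self):
        ps = [p for blk in self.blocks for p in blk.params]
        return ps + self.feature_unit.params + self.class_head.params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def _check_input(self, x: np.ndarray) -> None:
        rank = self.spec.spatial_rank
        if x.ndim != rank + 2:
            raise ShapeError(
                f"expected (batch, modalities, {rank} spatial axes), got shape {x.shape}"
            )
        if x.shape[1] != self.spec.n_modalities:
            raise ShapeError(
                f"model expects {self.spec.n_modalities} modalities, got {x.shape[1]}"
            )
        for s in x.shape[2:]:
            if s % DOWNSAMPLE_FACTOR != 0:
                raise ShapeError(
                    f"spatial extent {s} is not divisible by the total "
                    f"downsampling factor {DOWNSAMPLE_FACTOR}"
                )

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.enc1.forward(x, train)
        h = self.pool1.forward(h, train)
        h = self.enc2.forward(h, train)
        h = self.pool2.forward(h, train)
        h = self.enc3.forward(h, train)
        h = self.up1.forward(h, train)
        h = self.dec1.forward(h, train)
        h = self.up2.forward(h, train)
        h = self.dec2.forward(h, train)
        h = self.dec3.forward(h, train)
        h = self.feature_unit.forward(h, train)
        return self.class_head.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-voxel class probabilities, shape (batch, n_classes, *spatial)."""
        return softmax_channel(self.forward_logits(x, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.class_head.backward(dlogits)
        d = self.feature_unit.backward(d)
        d = self.dec3.backward(d)
        d = self.dec2.backward(d)
        d = self.up2.backward(d)
        d = self.dec1.backward(d)
        d = self.up1.backward(d)
        d = self.enc3.backward(d)
        d = self.pool2.backward(d)
        d = self.enc2.backward(d)
        d = self.pool1.backward(d)
        self.enc1.backward(d)


def build_model(
    config: NetworkConfiguration,
    n_modalities: int,
    n_classes: int = 4,
    spatial_rank: int = 3,
    seed: int = 0,
) -> SegmentationModel:
    """Instantiate a trainable model for one genotype."""
    spec = ModelSpec(config, n_modalities, n_classes, spatial_rank)
    return SegmentationModel(spec, seed=seed)


def _as_arrays(dataset) -> Tuple[np.ndarray, np.ndarray]:
    images, labels = [], []
    for img, lab in dataset:
        lab_arr = lab.labels if isinstance(lab, LabelVolume) else np.asarray(lab)
        images.append(np.asarray(img, dtype=np.float32))
        labels.append(np.asarray(lab_arr))
    if not images:
        raise DataError("dataset is empty")
    return np.stack(images), np.stack(labels)


def train_candidate(
    model: SegmentationModel,
    dataset,
    settings: TrainingSettings,
    rng: Optional[np.random.Generator] = None,
    val_dataset=None,
    val_labels: Sequence[int] = (1, 2, 3),
) -> Tuple[SegmentationModel, TrainingHistory]:
    """Train a candidate network with early stopping.

    ``dataset`` is an iterable of (multimodal image, label volume) pairs.
    The monitored metric is the validation mean Dice over ``val_labels``
    when ``val_dataset`` is given, otherwise the negative training loss.
    A non-finite loss marks the history as diverged and stops training; the
    search maps that to quality 0 rather than crashing.
    """
    from .metrics import mean_quality  # local import avoids cycle at module load

    if rng is None:
        rng = np.random.default_rng(settings.seed)
    x_all, y_all = _as_arrays(dataset)
    if val_dataset is not None:
        xv, yv = _as_arrays(val_dataset)

    optimizer = Adam(model.params, lr=settings.learning_rate)
    history = TrainingHistory()
    best_metric = -np.inf
    stall = 0
    n = len(x_all)
    for epoch in range(1, settings.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            logits = model.forward_logits(x_all[idx], train=True)
            loss, dlogits = ce_dice_loss_and_grad(logits, y_all[idx])
            if not np.isfinite(loss):
                history.diverged = True
                history.append(epoch, float(loss), float("nan"))
                return model, history
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= n_batches

        if val_dataset is not None:
            dices = []
            for i in range(len(xv)):
                pred = predict_segmentation(model, xv[i])
                truth = LabelVolume(yv[i].astype(np.int64))
                dices.append(mean_quality(pred, truth, list(val_labels)))
            metric = float(np.mean(dices))
        else:
            metric = -epoch_loss
        history.append(epoch, float(epoch_loss), metric)

        if metric > best_metric:
            best_metric = metric
            stall = 0
        else:
            stall += 1
            if stall >= settings.patience_epochs:
                break
    return model, history


def predict_segmentation(model: SegmentationModel, volume: np.ndarray) -> LabelVolume:
    """Argmax segmentation of one multimodal volume (modalities first)."""
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != model.spec.spatial_rank + 1:
        raise ShapeError(
            f"expected (modalities, {model.spec.spatial_rank} spatial axes), "
            f"got shape {volume.shape}"
        )
    probs = model.forward(volume[None], train=False)[0]
    return LabelVolume(np.argmax(probs, axis=0).astype(np.int64))
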