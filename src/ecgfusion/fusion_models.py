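"""Customized AlexNet and scalogram/phasogram fusion strategies S1–S6.

The base network is an AlexNet variant for 224x224 single-channel inputs:
a rescaling layer (integer image -> [0,1]), five convolution groups each
followed by batch normalization (groups 1, 2 and 5 also max-pool), then
three dense layers with dropout after the first two and a 5-way softmax.

Fusion strategies over the scalogram (magnitude^2) and phasogram (phase)
modalities:

* S1 / S2  — base model on scalograms only / phasograms only;
* S3       — early fusion: both modalities stacked as a 2-channel input;
* S4       — intermediate fusion after the fourth convolution group
             (channel-axis concatenation, 12x12x384 + 12x12x384);
* S5       — intermediate fusion after Flatten (6400 + 6400 features);
* S6       — intermediate fusion after the first dense layer (dropout on
             that layer removed; 4096 + 4096 features).

Late fusion (S7a–h) lives in :mod:`ecgfusion.late_fusion`.

Strides, kernel sizes and padding are uniquely determined by the published
output-shape/parameter table of the architecture: Conv1 is 11x11 stride 4
valid ((224-11)/4+1 = 54, 11*11*96+96 = 11,712 params), Conv2 is 5x5 same,
Conv3–5 are 3x3 same, all pools are 3x3 stride 2 valid; batch norm carries
4 parameters per channel of which the 2 running statistics are frozen.
A ``width_scale`` < 1 together with a smaller ``input_size`` gives a
reduced configuration of the same topology for CPU-scale experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import (Adam, BatchNorm, Concatenate, Conv2D, Dense, Dropout,
                  Flatten, MaxPool2D, Rescaling, Sequential, TwoBranchModel,
                  softmax, softmax_cross_entropy)

CLASSES = ("N", "S", "V", "F", "Q")

STRATEGIES = ("S1", "S2", "S3", "S4", "S5", "S6")

# cut points, counted in published layer numbering (1=Input ... 21=FC8):
# S4 branches end after BN4 (layer 12); S5 after Flatten (16);
# S6 after FC6 (17), with the dropout Dr6 removed.
_CUT_AFTER = {"S4": "BN4", "S5": "Flatten", "S6": "FC6"}


@dataclass
class FusionModelSpec:
    """Declarative description of one fusion strategy instance."""

    strategy: str = "S1"
    n_classes: int = 5
    input_size: int = 224
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_classes < 2 or self.input_size < 32:
            raise ValueError("invalid spec")

    @property
    def input_channels(self) -> int:
        return 1 if self.strategy in ("S1", "S2") else 2


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (Adam, eta=1e-4, B=32, <=30 epochs,
    early stopping with 5 epochs of patience on validation loss)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 30
    patience_epochs: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience_epochs) <= 0:
            raise ValueError("TrainConfig fields must be positive")
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience exceeds max_epochs")


def _layer_defs(spec: FusionModelSpec, suffix: str = ""):
    """Full base layer list with names; width-scaled channel counts."""
    w = spec.width_scale

    def ch(c):
        return max(1, round(c * w))

    return [
        Rescaling(name="Rescaling" + suffix),
        Conv2D(ch(96), 11, stride=4, padding="valid", name="Conv1" + suffix),
        BatchNorm(name="BN1" + suffix),
        MaxPool2D(3, 2, name="Pool1" + suffix),
        Conv2D(ch(256), 5, padding="same", name="Conv2" + suffix),
        BatchNorm(name="BN2" + suffix),
        MaxPool2D(3, 2, name="Pool2" + suffix),
        Conv2D(ch(384), 3, padding="same", name="Conv3" + suffix),
        BatchNorm(name="BN3" + suffix),
        Conv2D(ch(384), 3, padding="same", name="Conv4" + suffix),
        BatchNorm(name="BN4" + suffix),
        Conv2D(ch(256), 3, padding="same", name="Conv5" + suffix),
        BatchNorm(name="BN5" + suffix),
        MaxPool2D(3, 2, name="Pool5" + suffix),
        Flatten(name="Flatten" + suffix),
        Dense(ch(4096), activation="relu", name="FC6" + suffix),
        Dropout(0.5, name="Dr6" + suffix),
        Dense(ch(4096), activation="relu", name="FC7" + suffix),
        Dropout(0.5, name="Dr7" + suffix),
        Dense(spec.n_classes, activation=None, name="FC8" + suffix),
    ]


class FusionModel:
    """A built, trainable model plus its spec and bookkeeping."""

    def __init__(self, spec: FusionModelSpec, net):
        self.spec = spec
        self.net = net

    def forward(self, x, training=False, capture=None):
        return self.net.forward(x, training=training, capture=capture)

    def backward(self, grad, capture=None):
        return self.net.backward(grad, capture=capture)

    def iter_layers(self):
        return self.net.iter_layers()

    def get_weights(self):
        return [(copy.deepcopy(l.params), copy.deepcopy(l.state))
                for l in self.iter_layers()]

    def set_weights(self, weights):
        for layer, (p, s) in zip(self.iter_layers(), weights):
            layer.params = copy.deepcopy(p)
            layer.state = copy.deepcopy(s)


def build_model(spec: FusionModelSpec) -> FusionModel:
    """Build the network for one strategy; verifies the canonical shape
    chain (54 -> 26 -> 12 -> 5 spatial) for full-size specs."""
    rng = np.random.default_rng(spec.seed)
    shape_in = (spec.input_size, spec.input_size, spec.input_channels)

    if spec.strategy in ("S1", "S2", "S3"):
        net = Sequential(_layer_defs(spec), shape_in, rng)
    else:
        cut = _CUT_AFTER[spec.strategy]
        defs_a = _layer_defs(spec, suffix="a")
        defs_b = _layer_defs(spec, suffix="b")
        names = [l.name[:-1] for l in defs_a]
        icut = names.index(cut) + 1
        prefix_a = defs_a[:icut]
        prefix_b = defs_b[:icut]
        tail_src = _layer_defs(spec)[icut:]
        if spec.strategy == "S6":
            # branches end at FC6; its dropout is removed entirely
            tail_src = [l for l in tail_src if l.name != "Dr6"]
        branch_shape = (spec.input_size, spec.input_size, 1)
        ba = Sequential(prefix_a, branch_shape, rng)
        bb = Sequential(prefix_b, branch_shape, rng)
        axis = -1  # channel axis for S4, feature axis for S5/S6 (both last)
        net = TwoBranchModel(ba, bb, Concatenate(axis=axis), tail_src,
                             shape_in, rng)

    model = FusionModel(spec, net)
    if spec.input_size == 224 and spec.width_scale == 1.0:
        _check_canonical_shapes(model)
    return model


def _check_canonical_shapes(model: FusionModel):
    """Published output-shape chain for the full-size architecture."""
    expected = {
        "Conv1": (54, 54, 96), "Pool1": (26, 26, 96),
        "Conv2": (26, 26, 256), "Pool2": (12, 12, 256),
        "Conv3": (12, 12, 384), "Conv4": (12, 12, 384),
        "Conv5": (12, 12, 256), "Pool5": (5, 5, 256),
        "Flatten": (6400,), "FC6": (4096,), "FC7": (4096,),
    }
    for name, shape, _ in layer_summary(model):
        base = name.rstrip("ab")
        if base in expected and shape != expected[base]:
            raise ValueError(
                f"layer {name}: shape {shape} != expected {expected[base]}")


def layer_summary(model: FusionModel):
    """Per-layer (name, output_shape, n_params) rows, tracing shapes by
    rebuilding the chain arithmetic (shapes are fixed at build)."""
    rows = []
    for layer in model.iter_layers():
        shape = getattr(layer, "out_shape", None)
        if shape is None:
            # non-spatial layers know their output via build-time shape
            shape = getattr(layer, "_built_shape", None)
        n = layer.n_trainable + layer.n_non_trainable
        rows.append((layer.name, shape, n))
    # Re-derive shapes by a dry forward of one zero sample (cheap, exact)
    x = np.zeros((1,) + (model.spec.input_size, model.spec.input_size,
                         model.spec.input_channels), dtype=np.float32)
    shapes = {}

    def record(seq, x):
        for layer in seq.layers:
            x = layer.forward(x, training=False)
            shapes[layer.name] = x.shape[1:]
        return x

    net = model.net
    if isinstance(net, Sequential):
        record(net, x)
    else:
        za = record(net.branch_a, x[..., 0:1])
        zb = record(net.branch_b, x[..., 1:2])
        z = net.concat.forward([za, zb], False)
        shapes[net.concat.name] = z.shape[1:]
        record(net.tail, z)
    return [(name, shapes.get(name), n) for name, _, n in rows]


def count_parameters(model: FusionModel):
    """(total, trainable, non_trainable) — non-trainable are the batch-norm
    running mean/variance, 2 per channel per BN layer."""
    trainable = sum(l.n_trainable for l in model.iter_layers())
    non_trainable = sum(l.n_non_trainable for l in model.iter_layers())
    return trainable + non_trainable, trainable, non_trainable


def _to_onehot(labels, n_classes):
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        idx = np.array([CLASSES.index(s) for s in labels])
    else:
        idx = labels.astype(int)
    out = np.zeros((len(idx), n_classes), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out, idx


def _stratified_holdout(idx_labels, fraction, rng):
    """Per-class round(fraction * n) holdout, at least 1 where possible."""
    val = []
    for c in np.unique(idx_labels):
        members = np.flatnonzero(idx_labels == c)
        members = rng.permutation(members)
        k = max(1, round(len(members) * fraction)) if len(members) > 1 else 0
        val.extend(members[:k])
    val = np.sort(np.array(val, dtype=int))
    train = np.setdiff1d(np.arange(len(idx_labels)), val)
    return train, val


def train_model(model: FusionModel, images, labels, config: TrainConfig):
    """Train with Adam / cross-entropy / early stopping; returns history.

    ``images`` is (n, H, W, C) on the 0–255 image scale; ``labels`` are
    class symbols or integer indices.  The best-validation-loss weights
    are restored on early stop.
    """
    images = np.asarray(images, dtype=np.float32)
    n_classes = model.spec.n_classes
    y, idx = _to_onehot(labels, n_classes)
    present = np.unique(idx)
    if len(present) < n_classes:
        missing = [CLASSES[c] for c in range(n_classes) if c not in present]
        raise ValueError(f"classes absent from training labels: {missing}")

    rng = np.random.default_rng(config.seed)
    tr, va = _stratified_holdout(idx, config.validation_fraction, rng)
    opt = Adam(model.net, lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = images[batch], y[batch]
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch + 1}")
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(batch))
            hits += int((logits.argmax(1) == yb.argmax(1)).sum())
            seen += len(batch)
        history["loss"].append(float(np.sum(losses) / seen))
        history["accuracy"].append(hits / seen)

        vl, va_acc = _evaluate_loss(model, images[va], y[va],
                                    config.batch_size)
        history["val_loss"].append(vl)
        history["val_accuracy"].append(va_acc)

        if vl < best_val:
            best_val = vl
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience_epochs:
                break

    model.set_weights(best_weights)
    return model, history


def _evaluate_loss(model, images, y, batch_size):
    losses, hits = [], 0
    for start in range(0, len(images), batch_size):
        xb = images[start:start + batch_size]
        yb = y[start:start + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        hits += int((logits.argmax(1) == yb.argmax(1)).sum())
    n = len(images)
    return float(np.sum(losses) / n), hits / n


def predict_proba(model: FusionModel, images, batch_size=64):
    """Class-probability matrix, rows summing to 1."""
    images = np.asarray(images, dtype=np.float32)
    out = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start:start + batch_size],
                               training=False)
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


def grad_cam(model: FusionModel, image, target_class, layer="Conv5"):
    """Gradient-weighted class-activation heatmap for one input image.

    The gradient of the target-class logit is taken at the named
    convolutional layer; channel-mean gradients weight the activations,
    the sum is rectified, bilinearly upsampled to the model input size and
    max-normalized to [0, 1].
    """
    from skimage.transform import resize

    available = [l.name for l in model.iter_layers()]
    if layer not in available:
        raise KeyError(f"layer {layer!r} not in model (have {available})")
    x = np.asarray(image, dtype=np.float32)[None]
    logits = model.forward(x, training=False, capture={layer})
    acts = model.net._captured[layer]          # (1, h, w, c)
    dlogits = np.zeros_like(logits)
    dlogits[0, int(target_class)] = 1.0
    model.backward(dlogits, capture={layer})
    grads = model.net._grad_captured[layer]    # (1, h, w, c)
    weights = grads.mean(axis=(1, 2))          # (1, c)
    cam = np.maximum((acts * weights[:, None, None, :]).sum(-1)[0], 0.0)
    size = model.spec.input_size
    cam = resize(cam, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam
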