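"""Patch-based residual CNN translating multi-contrast patches to stain patches.

The network maps ``k x k x C`` input patches to ``k x k`` target
intensity patches.  Architecture: an input convolution (C -> F) and a
second convolution (F -> F), each followed by a rectified linear unit;
``n`` residual blocks of [conv F -> F, ReLU, conv F -> F] with an
identity skip connection added to the block output; then two tail
convolutions (F -> F with ReLU, and F -> 1).  All convolutions are
3 x 3 with same zero-padding, so the spatial extent ``k x k`` is
preserved end to end; the total convolutional layer count is
``2 n + 4`` (64 layers for the default 30 blocks).  There are no
normalization layers.  Weights are initialized as (semi-)orthogonal
matrices.

Training uses stochastic gradient descent with momentum on a mean
absolute error (L1) loss over patch voxels, a staircase learning-rate
schedule, early stopping on a held-out validation patch set, and
selection of the epoch with the lowest validation loss.

The forward/backward passes are implemented directly on numpy: patches
are tiny, so each convolution reduces to one dense matrix product via
im2col, which keeps desk-scale training fast without a deep-learning
framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .patches import NormalizationStats, PatchSet, ScalarStats
from .volumes import MultiContrastVolume, TargetVolume

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedModel",
    "build_mrh",
    "train",
    "transfer_train",
    "predict_patch",
    "translate_volume",
    "extract_features",
    "count_parameters",
    "conv_parameter_count",
]


# --------------------------------------------------------------------------
# Specs and configs
# --------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Architecture description.

    ``n_end_layers`` is fixed at 4 (two head and two tail convolutions);
    the total convolutional layer count is ``2 * n_residual_blocks + 4``.
    """

    in_channels: int
    n_residual_blocks: int = 30
    channels_per_layer: int = 64
    kernel_size: int = 3
    patch_size: int = 3
    n_end_layers: int = 4
    residual_init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0:
            raise ValueError("patch size k must be odd")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.n_end_layers != 4:
            raise ValueError("architecture uses exactly 4 non-residual layers")
        if self.in_channels < 1 or self.n_residual_blocks < 1:
            raise ValueError("need >= 1 input channel and >= 1 residual block")

    @property
    def n_conv_layers(self) -> int:
        return 2 * self.n_residual_blocks + self.n_end_layers


@dataclass
class TrainingConfig:
    """SGD-with-momentum schedule for patch training.

    Defaults: batch 128, momentum 0.9, initial learning rate 0.1
    multiplied by 0.1 every 10 epochs (staircase), at most 60 epochs,
    early stopping after 5 epochs without validation improvement, and
    an L1 loss averaged over batch and patch voxels.
    """

    learning_rate: float = 0.1
    lr_factor: float = 0.1
    lr_step_epochs: int = 10
    momentum: float = 0.9
    batch_size: int = 128
    max_epochs: int = 60
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_factor, self.batch_size) <= 0:
            raise ValueError("rates and batch size must be > 0")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-indexed epoch (staircase schedule)."""
        return self.learning_rate * self.lr_factor ** ((epoch - 1) // self.lr_step_epochs)


# --------------------------------------------------------------------------
# Convolution layer (im2col + dense matmul)
# --------------------------------------------------------------------------

def _orthogonal(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """(Semi-)orthogonal matrix of the given (rows, cols) shape."""
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q[:rows, :cols])


class Conv2d:
    """Same-padded 2D convolution over (N, C, H, W), weights (Cout, Cin*kh*kw)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.W = _orthogonal((c_out, c_in * k * k), rng).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.trainable = True
        self._cols: np.ndarray | None = None
        self._in_hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        y = cols @ self.W.T + self.b
        if keep:
            self._cols = cols
            self._in_hw = (H, W)
        return y.reshape(N, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray, grads: dict) -> np.ndarray:
        N, _, H, W = dy.shape
        k, p = self.k, self.k // 2
        dy2 = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1).reshape(N * H * W, self.c_out), dtype=np.float32
        )
        if self.trainable:
            grads[id(self)] = (dy2.T @ self._cols, dy2.sum(axis=0))
        dcols = (dy2 @ self.W).reshape(N, H, W, self.c_in, k, k)
        dxp = np.zeros((N, self.c_in, H + 2 * p, W + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + H, dj : dj + W] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + H, p : p + W]

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size


def conv_parameter_count(c_in: int, c_out: int, k: int = 3) -> int:
    """Closed-form parameter count of one conv layer (weights + biases)."""
    return c_out * (c_in * k * k + 1)


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------

class MRHNet:
    """The residual patch-translation network (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, K, C = spec.channels_per_layer, spec.kernel_size, spec.in_channels
        self.head = Conv2d(C, F, K, rng)
        self.post_head = Conv2d(F, F, K, rng)
        self.blocks = []
        for _ in range(spec.n_residual_blocks):
            c1, c2 = Conv2d(F, F, K, rng), Conv2d(F, F, K, rng)
            # down-scale the residual branch output at init so the stack
            # stays near-identity at depth (stabilizes the LR-0.1 schedule)
            c2.W *= np.float32(spec.residual_init_scale)
            self.blocks.append((c1, c2))
        self.tail1 = Conv2d(F, F, K, rng)
        self.tail2 = Conv2d(F, 1, K, rng)
        self._relu_masks: list = []

    @property
    def conv_layers(self) -> list[Conv2d]:
        """All convolutions in forward traversal order (length 2n + 4)."""
        layers = [self.head, self.post_head]
        for c1, c2 in self.blocks:
            layers.extend([c1, c2])
        layers.extend([self.tail1, self.tail2])
        return layers

    # -- forward / backward -------------------------------------------------

    def forward(
        self, x: np.ndarray, keep: bool = False, record: list | None = None
    ) -> np.ndarray:
        """Input (N, C, k, k) -> prediction (N, k, k).

        With ``record`` a list, appends each conv layer's output tensor
        (pre-activation, before any skip addition) in traversal order.
        """
        masks = [] if keep else None

        def conv_relu(layer: Conv2d, h: np.ndarray) -> np.ndarray:
            z = layer.forward(h, keep)
            if record is not None:
                record.append(z)
            m = z > 0
            if keep:
                masks.append(m)
            return np.where(m, z, 0.0).astype(np.float32)

        h = conv_relu(self.head, x.astype(np.float32))
        h = conv_relu(self.post_head, h)
        for c1, c2 in self.blocks:
            inner = conv_relu(c1, h)
            z = c2.forward(inner, keep)
            if record is not None:
                record.append(z)
            h = h + z
        h = conv_relu(self.tail1, h)
        y = self.tail2.forward(h, keep)
        if record is not None:
            record.append(y)
        if keep:
            self._relu_masks = masks
        return y[:, 0]

    def backward(self, dy: np.ndarray) -> dict:
        """Gradient of the loss wrt all trainable parameters.

        ``dy`` is dLoss/dPrediction of shape (N, k, k); returns a dict
        keyed by ``id(layer)`` holding (dW, db).
        """
        grads: dict = {}
        masks = list(self._relu_masks)
        d = self.tail2.backward(dy[:, None], grads)
        d = self.tail1.backward(np.where(masks.pop(), d, 0.0), grads)
        for c1, c2 in reversed(self.blocks):
            d_inner = c2.backward(d, grads)
            d_inner = c1.backward(np.where(masks.pop(), d_inner, 0.0), grads)
            d = d + d_inner
        d = self.post_head.backward(np.where(masks.pop(), d, 0.0), grads)
        self.head.backward(np.where(masks.pop(), d, 0.0), grads)
        self._relu_masks = []
        return grads

    # -- weights ------------------------------------------------------------

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W.copy(), l.b.copy()) for l in self.conv_layers]

    def set_weights(self, weights) -> None:
        for l, (W, b) in zip(self.conv_layers, weights):
            l.W = W.copy()
            l.b = b.copy()

    def clone(self) -> "MRHNet":
        net = MRHNet(self.spec, seed=0)
        net.set_weights(self.get_weights())
        return net


def build_mrh(spec: NetworkSpec, seed: int = 0) -> MRHNet:
    """Construct an untrained network with orthogonal initial weights."""
    return MRHNet(spec, seed)


def count_parameters(net: MRHNet, trainable_only: bool = False) -> int:
    return sum(
        l.n_parameters for l in net.conv_layers if l.trainable or not trainable_only
    )


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained network plus everything needed to apply it to raw data."""

    spec: NetworkSpec
    network: MRHNet
    norm_stats: NormalizationStats | None
    target_stats: ScalarStats | None
    channel_labels: list[str] | None
    history: dict = field(default_factory=dict)
    selected_epoch: int = 0
    config: TrainingConfig | None = None


def _patch_tensors(ps: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    x = np.ascontiguousarray(ps.inputs.transpose(0, 3, 1, 2), dtype=np.float32)
    y = np.ascontiguousarray(ps.targets, dtype=np.float32)
    return x, y


def _eval_mae(net: MRHNet, x: np.ndarray, y: np.ndarray, batch: int = 2048) -> float:
    if x.shape[0] == 0:
        return float("nan")
    total = 0.0
    for i in range(0, x.shape[0], batch):
        pred = net.forward(x[i : i + batch])
        total += float(np.abs(pred - y[i : i + batch]).sum())
    return total / y.size


def _sgd_loop(
    net: MRHNet,
    train_ps: PatchSet,
    val_ps: PatchSet,
    config: TrainingConfig,
) -> tuple[dict, int]:
    """Run the SGD schedule in place; returns (history, selected_epoch)."""
    x, y = _patch_tensors(train_ps)
    xv, yv = _patch_tensors(val_ps)
    use_val = xv.shape[0] > 0
    rng = np.random.default_rng(config.seed)
    velocity = {id(l): (np.zeros_like(l.W), np.zeros_like(l.b))
                for l in net.conv_layers if l.trainable}

    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_epoch = 0
    best_weights = net.get_weights()
    n = x.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            pred = net.forward(xb, keep=True)
            resid = pred - yb
            loss = float(np.abs(resid).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or re-check input normalization"
                )
            epoch_loss += loss * xb.shape[0]
            grad = np.sign(resid).astype(np.float32) / resid.size
            grads = net.backward(grad)
            for layer in net.conv_layers:
                if not layer.trainable:
                    continue
                dW, db = grads[id(layer)]
                vW, vb = velocity[id(layer)]
                vW *= config.momentum
                vW -= lr * dW
                vb *= config.momentum
                vb -= lr * db
                layer.W += vW
                layer.b += vb
        history["train_loss"].append(epoch_loss / n)
        history["lr"].append(lr)
        if use_val:
            vloss = _eval_mae(net, xv, yv)
            history["val_loss"].append(vloss)
            if vloss < best_val:            # strict: earliest epoch wins ties
                best_val = vloss
                best_epoch = epoch
                best_weights = net.get_weights()
            elif epoch - best_epoch >= config.patience:
                break
        else:
            history["val_loss"].append(float("nan"))
            best_epoch = epoch
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    return history, best_epoch


def train(
    net: MRHNet,
    train_ps: PatchSet,
    val_ps: PatchSet,
    config: TrainingConfig | None = None,
) -> TrainedModel:
    """Train on normalized patches; returns the lowest-validation-loss model.

    Patches are expected pre-normalized (carrying their
    NormalizationStats); an empty validation set disables early
    stopping and keeps the final epoch.
    """
    config = config or TrainingConfig()
    if train_ps.n_channels != net.spec.in_channels:
        raise ValueError(
            f"network expects {net.spec.in_channels} channels, "
            f"patches have {train_ps.n_channels}"
        )
    history, selected = _sgd_loop(net, train_ps, val_ps, config)
    return TrainedModel(
        spec=net.spec,
        network=net,
        norm_stats=train_ps.norm_stats,
        target_stats=train_ps.target_stats,
        channel_labels=train_ps.channel_labels,
        history=history,
        selected_epoch=selected,
        config=config,
    )


def transfer_train(
    model: TrainedModel,
    train_ps: PatchSet,
    val_ps: PatchSet,
    config: TrainingConfig | None = None,
    n_trainable_layers: int = 3,
) -> TrainedModel:
    """Refine only the last ``n_trainable_layers`` convolutions on new targets.

    All other weights are frozen (bit-identical before and after).  The
    transfer schedule defaults to the source configuration with the
    initial learning rate lowered to 1e-4 (factor 0.1 unchanged).
    """
    if train_ps.n_channels != model.spec.in_channels:
        raise ValueError(
            f"source model expects {model.spec.in_channels} channels, "
            f"new patches have {train_ps.n_channels}"
        )
    if config is None:
        base = model.config or TrainingConfig()
        config = _dc_replace(base, learning_rate=1e-4)
    net = model.network.clone()
    layers = net.conv_layers
    for layer in layers[: len(layers) - n_trainable_layers]:
        layer.trainable = False
    history, selected = _sgd_loop(net, train_ps, val_ps, config)
    return TrainedModel(
        spec=model.spec,
        network=net,
        norm_stats=train_ps.norm_stats or model.norm_stats,
        target_stats=train_ps.target_stats,
        channel_labels=train_ps.channel_labels or model.channel_labels,
        history=history,
        selected_epoch=selected,
        config=config,
    )


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------

def _normalize_inputs(model: TrainedModel, patches: np.ndarray,
                      already_normalized: bool) -> np.ndarray:
    if already_normalized or model.norm_stats is None:
        return np.asarray(patches, np.float32)
    return model.norm_stats.apply(np.asarray(patches, float)).astype(np.float32)


def predict_patch(
    model: TrainedModel,
    patch: np.ndarray,
    already_normalized: bool = False,
) -> np.ndarray:
    """Predict target patches from raw (or pre-normalized) input patches.

    Accepts one ``(k, k, C)`` patch or a batch ``(n, k, k, C)``; output
    is in target units (stored target scaling is inverted).
    """
    single = patch.ndim == 3
    patches = patch[None] if single else patch
    k, C = model.spec.patch_size, model.spec.in_channels
    if patches.shape[1:] != (k, k, C):
        raise ValueError(
            f"expected patches of shape ({k}, {k}, {C}), got {patches.shape[1:]}"
        )
    x = _normalize_inputs(model, patches, already_normalized)
    pred = model.network.forward(
        np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    )
    if model.target_stats is not None:
        pred = model.target_stats.invert(pred)
    return pred[0] if single else pred


def translate_volume(
    model: TrainedModel,
    volume: MultiContrastVolume,
    mask: np.ndarray,
    axis: int = 0,
    aggregation: str = "overlap-average",
    background: float = 0.0,
    batch: int = 8192,
) -> TargetVolume:
    """Apply the network over a whole volume, slice by slice.

    A ``k x k`` window slides at stride 1 over every slice
    perpendicular to ``axis`` (edge-replicated at borders so every
    voxel owns a centered patch).  ``overlap-average`` sets each voxel
    to the mean of all patch predictions covering it; ``center-only``
    uses only the center prediction of the voxel's own patch.  The
    result is one 3D volume — reslicing it along other axes is just a
    view of the same data.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if aggregation not in ("overlap-average", "center-only"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if model.channel_labels and volume.channel_labels:
        if list(volume.channel_labels) != list(model.channel_labels):
            raise ValueError("volume channel labels do not match the model")
    k = model.spec.patch_size
    half = k // 2
    data = np.moveaxis(volume.data, axis, 0)        # (S, H, W, C)
    S, H, W, C = data.shape
    out = np.zeros((S, H, W), dtype=np.float64)
    cnt = np.zeros((S, H, W), dtype=np.float64)

    for s in range(S):
        sl = np.pad(data[s], ((half, half), (half, half), (0, 0)), mode="edge")
        win = np.lib.stride_tricks.sliding_window_view(sl, (k, k), axis=(0, 1))
        patches = win.transpose(0, 1, 3, 4, 2).reshape(H * W, k, k, C)
        preds = np.empty((H * W, k, k), dtype=np.float64)
        for i in range(0, H * W, batch):
            preds[i : i + batch] = predict_patch(model, patches[i : i + batch])
        preds = preds.reshape(H, W, k, k)
        if aggregation == "center-only":
            out[s] = preds[:, :, half, half]
            cnt[s] = 1.0
        else:
            for di in range(k):
                for dj in range(k):
                    oi, oj = di - half, dj - half
                    ti0, ti1 = max(0, oi), min(H, H + oi)
                    tj0, tj1 = max(0, oj), min(W, W + oj)
                    si0, sj0 = ti0 - oi, tj0 - oj
                    out[s, ti0:ti1, tj0:tj1] += preds[
                        si0 : si0 + ti1 - ti0, sj0 : sj0 + tj1 - tj0, di, dj
                    ]
                    cnt[s, ti0:ti1, tj0:tj1] += 1.0
    out /= cnt
    out = np.moveaxis(out, 0, axis)
    result = np.full(volume.shape, background, dtype=np.float32)
    m = np.asarray(mask, bool)
    result[m] = out[m]
    return TargetVolume(result, "prediction", volume.voxel_size, volume.affine.copy())


def extract_features(
    model: TrainedModel,
    patchset: PatchSet,
    layer: int = -1,
    already_normalized: bool = False,
    batch: int = 4096,
) -> np.ndarray:
    """Flattened activations of one conv layer for every patch.

    ``layer`` indexes the conv layers in traversal order (negative
    indices allowed); the recorded tensor is the convolution output
    before any activation or skip addition, so the final layer's
    features equal the flattened predictions.
    """
    n_layers = model.spec.n_conv_layers
    if not -n_layers <= layer < n_layers:
        raise ValueError(f"layer {layer} out of range for {n_layers} layers")
    layer = layer % n_layers
    x = _normalize_inputs(model, patchset.inputs, already_normalized)
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    feats = []
    for i in range(0, x.shape[0], batch):
        record: list = []
        model.network.forward(x[i : i + batch], record=record)
        feats.append(record[layer].reshape(record[layer].shape[0], -1))
    return np.concatenate(feats, axis=0)
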