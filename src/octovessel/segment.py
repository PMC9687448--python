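"""Atrous/ASPP encoder–decoder semantic segmentation of microvessel candidates.

The network follows the DeepLab-v3+ family: a separable-convolution encoder
with stride and dilation (batch normalization and ReLU after every
convolution), an atrous spatial pyramid pooling block merging several
dilation rates with image-level pooling, and a decoder that restores full
resolution through a low-level skip connection.  The backbone is a scaled
encoder sized for CPU training on phantoms; the dilation rates are chosen so
the analytic receptive field covers the whole pre-processed frame.

Training uses Adam with class-weighted cross-entropy (inverse median
frequency), an L2 weight penalty, a stepped learning-rate schedule and
relative-improvement early stopping.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from . import nn
from .preprocess import PreprocessedFrame


@dataclasses.dataclass
class SegModelConfig:
    """Architecture of the candidate segmentation network."""

    backbone_depth: int = 2  # encoder stages (each halves resolution)
    base_channels: int = 8
    aspp_dilation_rates: tuple[int, ...] = (8, 16, 32)
    aspp_channels: int = 16
    output_stride: int = 4
    input_hw: tuple[int, int] = (256, 200)  # (A-lines, depth) the net must cover

    def __post_init__(self) -> None:
        if 2**self.backbone_depth != self.output_stride:
            raise ValueError("output_stride must equal 2**backbone_depth")
        rf = receptive_field(self)
        if rf < max(self.input_hw):
            raise ValueError(
                f"receptive field {rf} px does not cover input {self.input_hw}; "
                "increase the ASPP dilation rates"
            )


def _encoder_descriptors(config: SegModelConfig) -> list[tuple[int, int, int]]:
    """(kernel, stride, dilation) of each encoder convolution, in order."""
    desc = [(3, 2, 1), (3, 1, 1)]  # entry stage
    for _ in range(config.backbone_depth - 1):
        desc += [(3, 2, 1), (3, 1, 1)]
    desc += [(3, 1, 2)]  # dilated tail
    return desc


def receptive_field(config: SegModelConfig) -> int:
    """Analytic receptive field (pixels, either axis) along the deepest path.

    Standard recurrence: rf += (k-1)*d*jump after each convolution, jump *=
    stride; the deepest path runs through the largest ASPP dilation rate.
    (The image-level pooling branch is global and excluded — this is the
    convolutional bound.)
    """
    rf, jump = 1, 1
    for k, s, d in _encoder_descriptors(config) + [(3, 1, max(config.aspp_dilation_rates))]:
        rf += (k - 1) * d * jump
        jump *= s
    return rf


def _sep_conv(cin: int, cout: int, stride: int, dilation: int, rng, name: str) -> list[nn.Layer]:
    """Depthwise-separable conv: depthwise 3x3 then pointwise 1x1, BN+ReLU after each."""
    return [
        nn.Conv2d(cin, cin, 3, stride=stride, dilation=dilation, groups=cin, rng=rng, name=f"{name}.dw"),
        nn.BatchNorm2d(cin, name=f"{name}.dw_bn"),
        nn.ReLU(),
        nn.Conv2d(cin, cout, 1, rng=rng, name=f"{name}.pw"),
        nn.BatchNorm2d(cout, name=f"{name}.pw_bn"),
        nn.ReLU(),
    ]


class SegNet(nn.Layer):
    """Encoder + ASPP + decoder; maps (N,1,H,W) to per-pixel 2-class logits (N,2,H,W)."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels

        entry = [
            nn.Conv2d(1, c, 3, stride=2, rng=rng, name="entry"),
            nn.BatchNorm2d(c, name="entry_bn"),
            nn.ReLU(),
            nn.Conv2d(c, c, 3, rng=rng, name="entry2"),
            nn.BatchNorm2d(c, name="entry2_bn"),
            nn.ReLU(),
        ]
        stages: list[nn.Layer] = []
        chans = c
        # low-level skip taps right after the entry stage (stride 2)
        self._skip_after = len(entry)
        self._skip_channels = c
        for si in range(config.backbone_depth - 1):
            stages += _sep_conv(chans, chans * 2, stride=2, dilation=1, rng=rng, name=f"stage{si}")
            chans *= 2
        stages += _sep_conv(chans, chans, stride=1, dilation=2, rng=rng, name="tail")
        self.encoder = entry + stages

        ca = config.aspp_channels
        branches = [nn.Sequential(
            nn.Conv2d(chans, ca, 1, rng=rng, name="aspp_1x1"),
            nn.BatchNorm2d(ca, name="aspp_1x1_bn"), nn.ReLU(),
        )]
        for r in config.aspp_dilation_rates:
            branches.append(nn.Sequential(
                nn.Conv2d(chans, ca, 3, dilation=r, rng=rng, name=f"aspp_d{r}"),
                nn.BatchNorm2d(ca, name=f"aspp_d{r}_bn"), nn.ReLU(),
            ))
        self._pool_branch = nn.Sequential(
            nn.GlobalAvgPool(),
            nn.Conv2d(chans, ca, 1, rng=rng, name="aspp_pool"),
            nn.BatchNorm2d(ca, name="aspp_pool_bn"), nn.ReLU(),
        )
        self._pool_broadcast = nn.Broadcast2d((1, 1))
        self.aspp_branches = branches
        n_branch = len(branches) + 1
        self.aspp_project = nn.Sequential(
            nn.Conv2d(ca * n_branch, 2 * c, 1, rng=rng, name="aspp_proj"),
            nn.BatchNorm2d(2 * c, name="aspp_proj_bn"), nn.ReLU(),
        )

        self.skip_project = nn.Sequential(
            nn.Conv2d(self._skip_channels, c, 1, rng=rng, name="skip_proj"),
            nn.BatchNorm2d(c, name="skip_proj_bn"), nn.ReLU(),
        )
        self.up1 = nn.BilinearResize((1, 1))
        self.decoder = nn.Sequential(
            nn.Conv2d(3 * c, 2 * c, 3, rng=rng, name="dec1"),
            nn.BatchNorm2d(2 * c, name="dec1_bn"), nn.ReLU(),
        )
        self.up2 = nn.BilinearResize((1, 1))
        self.refine = nn.Sequential(
            nn.Conv2d(2 * c, c, 3, rng=rng, name="refine"),
            nn.BatchNorm2d(c, name="refine_bn"), nn.ReLU(),
        )
        self.head = nn.Conv2d(c, 2, 1, rng=rng, name="head")

    # -- plumbing ----------------------------------------------------------

    def _modules(self) -> list[nn.Layer]:
        return (self.encoder + self.aspp_branches
                + [self._pool_branch, self._pool_broadcast, self.aspp_project,
                   self.skip_project, self.up1, self.decoder, self.up2,
                   self.refine, self.head])

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for m in self._modules():
            m.train(mode)

    # -- forward/backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        self._in_hw = x.shape[2:]
        h = x
        skip = None
        for i, layer in enumerate(self.encoder):
            h = layer.forward(h)
            if i + 1 == self._skip_after:
                skip = h
        feats = [b.forward(h) for b in self.aspp_branches]
        pooled = self._pool_branch.forward(h)
        self._pool_broadcast.out_hw = h.shape[2:]
        feats.append(self._pool_broadcast.forward(pooled))
        self._aspp_splits = np.cumsum([f.shape[1] for f in feats])[:-1]
        a = self.aspp_project.forward(np.concatenate(feats, axis=1))

        sk = self.skip_project.forward(skip)
        self.up1.out_hw = sk.shape[2:]
        a_up = self.up1.forward(a)
        self._dec_split = a_up.shape[1]
        d = self.decoder.forward(np.concatenate([a_up, sk], axis=1))
        self.up2.out_hw = self._in_hw
        return self.head.forward(self.refine.forward(self.up2.forward(d)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.up2.backward(self.refine.backward(self.head.backward(grad)))
        g = self.decoder.backward(g)
        g_aup = np.ascontiguousarray(g[:, : self._dec_split])
        g_sk = np.ascontiguousarray(g[:, self._dec_split :])
        g_a = self.up1.backward(g_aup)
        g_skip = self.skip_project.backward(g_sk)

        g_feats = np.split(self.aspp_project.backward(g_a), self._aspp_splits, axis=1)
        g_h = None
        for b, gf in zip(self.aspp_branches, g_feats[:-1]):
            d = b.backward(np.ascontiguousarray(gf))
            g_h = d if g_h is None else g_h + d
        g_pool = self._pool_broadcast.backward(np.ascontiguousarray(g_feats[-1]))
        g_h = g_h + self._pool_branch.backward(g_pool)

        for i in range(len(self.encoder) - 1, -1, -1):
            g_h = self.encoder[i].backward(g_h)
            if i == self._skip_after:
                g_h = g_h + g_skip  # gradient flowing through the skip tap
        return g_h


def build_segnet(config: SegModelConfig | None = None, seed: int = 0) -> SegNet:
    """Instantiate the segmentation network with seeded initial parameters."""
    return SegNet(config or SegModelConfig(), seed=seed)


# --- training --------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    """Shared training protocol of the segmentation and classification networks."""

    lr0: float = 0.001
    drop_factor: float = 0.2
    drop_period: float = 0.5  # epochs between multiplicative LR drops
    max_epochs: int = 50
    early_stop_min_rel: float = 1e-4  # 0.01% relative improvement
    early_stop_patience: int = 5
    l2_weight: float = 1e-5
    batch_size: int = 8
    seed: int = 0
    class_weight_mode: str = "inverse_median_frequency"

    def __post_init__(self) -> None:
        if self.lr0 <= 0 or not (0 < self.drop_factor < 1) or self.max_epochs < 1:
            raise ValueError("invalid training configuration")


def class_weights(pixel_class_freqs: Sequence[float]) -> np.ndarray:
    """Inverse-median-frequency class weights: weight_c = median(freqs)/freq_c."""
    freqs = np.asarray(pixel_class_freqs, dtype=float)
    if (freqs <= 0).any():
        raise ValueError("every class must appear in the training set")
    if not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise ValueError("class frequencies must sum to 1")
    return np.median(freqs) / freqs


def _pixel_freqs(labels: np.ndarray, valid: np.ndarray) -> np.ndarray:
    pos = int((labels[valid] == 1).sum())
    tot = int(valid.sum())
    neg = tot - pos
    return np.array([neg / tot, pos / tot])


def train_segmenter(
    model: SegNet,
    images: np.ndarray,
    labels: np.ndarray,
    valid_masks: np.ndarray,
    tc: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    val_valid: np.ndarray | None = None,
    val_loss_override: Callable[[int], float] | None = None,
) -> dict:
    """Train the segmentation network; returns the loss/LR history.

    ``images``/``labels``/``valid_masks`` are (n, H, W) stacks; pixels with a
    false valid flag are excluded from the loss.  ``val_loss_override`` lets a
    harness drive the early-stopping logic with a synthetic validation curve.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tc.seed)
    wts = class_weights(_pixel_freqs(labels, valid_masks.astype(bool)))
    opt = nn.Adam(model.params(), lr=tc.lr0, l2=tc.l2_weight)
    stopper = nn.EarlyStopper(tc.early_stop_min_rel, tc.early_stop_patience)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}

    x_all = images[:, None].astype(np.float32)
    y_all = labels.astype(np.int64)
    v_all = valid_masks.astype(bool)
    n_batches = max(1, -(-n // tc.batch_size))

    def eval_loss(x, y, v) -> float:
        model.train(False)
        tot, cnt = 0.0, 0
        for i in range(0, x.shape[0], tc.batch_size):
            logits = model.forward(x[i : i + tc.batch_size])
            loss, _ = nn.softmax_cross_entropy(logits, y[i : i + tc.batch_size], wts, v[i : i + tc.batch_size])
            tot += loss * (x[i : i + tc.batch_size].shape[0])
            cnt += x[i : i + tc.batch_size].shape[0]
        model.train(True)
        return tot / cnt

    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        model.train(True)
        ep_loss = 0.0
        for bi in range(n_batches):
            idx = order[bi * tc.batch_size : (bi + 1) * tc.batch_size]
            if idx.size == 0:
                continue
            epoch_float = epoch + bi / n_batches
            opt.lr = nn.step_lr(tc.lr0, tc.drop_factor, tc.drop_period, epoch_float)
            logits = model.forward(x_all[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, y_all[idx], wts, v_all[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
        ep_loss /= n_batches

        if val_loss_override is not None:
            val_loss = float(val_loss_override(epoch))
        elif val_images is not None:
            val_loss = eval_loss(val_images[:, None].astype(np.float32),
                                 val_labels.astype(np.int64), val_valid.astype(bool))
        else:
            val_loss = ep_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(ep_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(nn.step_lr(tc.lr0, tc.drop_factor, tc.drop_period, float(epoch)))
        if stopper.update(val_loss):
            break
    model.train(False)
    return history


def predict_mask(model: SegNet, pf: PreprocessedFrame, threshold: float | None = None) -> np.ndarray:
    """Binary candidate mask for one pre-processed frame.

    Per-pixel argmax over the two classes by default, or a probability
    threshold on the vessel class; invalid pixels are forced to 0.
    """
    model.train(False)
    x = pf.image[None, None].astype(np.float32)
    logits = model.forward(x)[0]
    if logits.shape[1:] != pf.image.shape:
        raise ValueError("model output shape does not match the input frame")
    if threshold is None:
        mask = (logits[1] > logits[0]).astype(np.uint8)
    else:
        prob = nn.softmax(logits[None], axis=1)[0, 1]
        mask = (prob >= threshold).astype(np.uint8)
    mask[~pf.valid_mask] = 0
    return mask


def predict_masks(model: SegNet, pfs: list[PreprocessedFrame], threshold: float | None = None,
                  batch_size: int = 8) -> np.ndarray:
    """Vectorized predict_mask over equally sized frames."""
    model.train(False)
    x = np.stack([pf.image for pf in pfs])[:, None].astype(np.float32)
    masks = np.empty((len(pfs),) + pfs[0].image.shape, dtype=np.uint8)
    for i in range(0, len(pfs), batch_size):
        logits = model.forward(x[i : i + batch_size])
        if threshold is None:
            m = (logits[:, 1] > logits[:, 0]).astype(np.uint8)
        else:
            m = (nn.softmax(logits, axis=1)[:, 1] >= threshold).astype(np.uint8)
        masks[i : i + batch_size] = m
    for mi, pf in zip(masks, pfs):
        mi[~pf.valid_mask] = 0
    return masks


def saliency_map(model: SegNet, pf: PreprocessedFrame, on_detections: bool = True) -> np.ndarray:
    """Input-gradient saliency, min-max scaled to [0, 1].

    The vessel-class score is summed over the pixels the model labels vessel
    (falling back to all pixels when nothing is detected, or when
    ``on_detections`` is False) and |d score / d input| is reported per
    input pixel.  Invalid pixels (padding, guidewire blanking) carry no
    image evidence and are set to zero.
    """
    model.train(False)
    x = pf.image[None, None].astype(np.float32)
    logits = model.forward(x)
    seed_grad = np.zeros((1, 2) + pf.image.shape, dtype=np.float32)
    detected = logits[0, 1] > logits[0, 0]
    if on_detections and detected.any():
        seed_grad[0, 1][detected] = 1.0
    else:
        seed_grad[0, 1] = 1.0
    for p in model.params():
        p.zero_grad()
    dx = model.backward(seed_grad)[0, 0]
    mag = np.abs(dx)
    mag[~pf.valid_mask] = 0.0
    rng_ = mag.max() - mag.min()
    return (mag - mag.min()) / rng_ if rng_ > 0 else np.zeros_like(mag)
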