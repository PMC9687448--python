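"""Candidate extraction and shallow-CNN microvessel/non-microvessel classification.

Connected components of the segmentation mask (8-connectivity, circular
across the θ edge) become candidates; each candidate's tight bounding box is
padded by 3 pixels of image context, resized to 30x30 and classified by a
small CNN (three 3x3 convolutions with 8/16/32 filters and stride 2, two
max-pooling layers, one fully connected layer, softmax over two classes).
Candidates judged non-microvessel are erased from the mask.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import nn
from .augment import rotate_patch_augment
from .preprocess import PreprocessedFrame
from .segment import TrainConfig

PATCH_SIZE = 30
PAD_PX = 3


@dataclasses.dataclass(eq=False)
class CandidateBlob:
    """One connected segmentation component in a frame.

    The bounding box is the tight circular extent of the pixel set:
    ``aline_max``/``r_max`` are half-open, and ``aline_max`` may exceed the
    A-line count when the blob straddles the θ wrap (indices are taken
    modulo the frame height).
    """

    frame: int
    pixels: np.ndarray  # (n, 2) int: (A-line, depth)
    aline_min: int
    aline_max: int
    r_min: int
    r_max: int
    area_px: int
    centroid: tuple[float, float]

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return self.aline_min, self.aline_max, self.r_min, self.r_max


def _circular_interval(values: np.ndarray, n: int) -> tuple[int, int]:
    """Minimal circular half-open interval covering the given A-line indices."""
    u = np.unique(values)
    if u.size == n:
        return 0, n
    ext = np.concatenate([u, u[:1] + n])
    gaps = np.diff(ext)
    gi = int(np.argmax(gaps))
    start = int(ext[gi + 1]) % n
    width = n - int(gaps[gi]) + 1
    return start, start + width


def extract_blobs(mask: np.ndarray, frame: int = 0, min_area: int = 1) -> list[CandidateBlob]:
    """Connected components under 8-connectivity with circular θ adjacency.

    Blobs are sorted by (frame, centroid A-line, centroid depth).
    """
    mask = np.asarray(mask).astype(bool)
    n_a, n_d = mask.shape
    lab, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_lab == 0:
        return []
    # merge labels adjacent across the θ wrap (rows 0 and n_a-1)
    parent = list(range(n_lab + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if n_a > 1:
        top, bot = lab[0], lab[n_a - 1]
        for c in range(n_d):
            if top[c] == 0:
                continue
            for cc in (c - 1, c, c + 1):
                if 0 <= cc < n_d and bot[cc] != 0:
                    union(int(top[c]), int(bot[cc]))

    roots: dict[int, list[int]] = {}
    for l in range(1, n_lab + 1):
        roots.setdefault(find(l), []).append(l)

    blobs = []
    for members in roots.values():
        sel = np.isin(lab, members)
        alines, depths = np.nonzero(sel)
        if alines.size < min_area:
            continue
        a0, a1 = _circular_interval(alines, n_a)
        # circular centroid along θ: unwrap into the covering interval
        unwrapped = np.where(alines < a0, alines + n_a, alines) if a1 > n_a else alines
        centroid = (float(unwrapped.mean()) % n_a, float(depths.mean()))
        blobs.append(CandidateBlob(
            frame=frame,
            pixels=np.stack([alines, depths], axis=1),
            aline_min=a0, aline_max=a1,
            r_min=int(depths.min()), r_max=int(depths.max()) + 1,
            area_px=int(alines.size),
            centroid=centroid,
        ))
    blobs.sort(key=lambda b: (b.frame, b.centroid[0], b.centroid[1]))
    return blobs


@dataclasses.dataclass(eq=False)
class CandidatePatch:
    """A 30x30 context patch around a candidate, fed to the classifier."""

    image: np.ndarray
    blob: CandidateBlob | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}")


def make_patch(blob: CandidateBlob, pf: PreprocessedFrame, pad: int = PAD_PX) -> CandidatePatch:
    """Crop the blob's padded bounding box from the pre-processed image.

    The tight box is expanded by ``pad`` pixels of image context on each
    edge (θ edges wrap, depth edges replicate) and bilinearly resized to
    30x30, keeping the candidate at the patch centre.
    """
    img = pf.image
    n_a, n_d = img.shape
    rows = np.arange(blob.aline_min - pad, blob.aline_max + pad) % n_a
    cols = np.clip(np.arange(blob.r_min - pad, blob.r_max + pad), 0, n_d - 1)
    crop = img[np.ix_(rows, cols)]
    if crop.shape == (PATCH_SIZE, PATCH_SIZE):
        out = crop.astype(np.float32)
    else:
        out = _sk_resize(crop.astype(np.float64), (PATCH_SIZE, PATCH_SIZE), order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True).astype(np.float32)
    return CandidatePatch(np.clip(out, 0.0, 1.0), blob=blob)


class PatchClassifier(nn.Sequential):
    """Three conv (8/16/32 filters, 3x3, stride 2) + two maxpool + FC + softmax."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        super().__init__(
            nn.Conv2d(1, 8, 3, stride=2, rng=rng, name="c1"),
            nn.BatchNorm2d(8, name="c1_bn"), nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Conv2d(8, 16, 3, stride=2, rng=rng, name="c2"),
            nn.BatchNorm2d(16, name="c2_bn"), nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Conv2d(16, 32, 3, stride=2, rng=rng, name="c3"),
            nn.BatchNorm2d(32, name="c3_bn"), nn.ReLU(),
            nn.Flatten(),
            nn.Linear(32, 2, rng=rng, name="fc"),
        )

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(n, 2) softmax probabilities for (n, 30, 30) patch images."""
        self.train(False)
        x = np.asarray(patches, dtype=np.float32)[:, None]
        return nn.softmax(self.forward(x), axis=1)


def build_classifier(seed: int = 0) -> PatchClassifier:
    return PatchClassifier(seed=seed)


def assemble_training_patches(
    patches: Sequence[CandidatePatch],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Augment positives 7x by rotation; negatives stay untouched.

    Returns shuffled (images, labels); with the protocol ratio of 1 positive
    per 7 negatives this balances the classes 1:1.
    """
    imgs, labels = [], []
    for p in patches:
        if p.label is None:
            raise ValueError("training patches must be labelled")
        if p.label == 1:
            for rot in rotate_patch_augment(p.image):
                imgs.append(rot)
                labels.append(1)
        else:
            imgs.append(p.image)
            labels.append(0)
    x = np.asarray(imgs, dtype=np.float32)
    y = np.asarray(labels, dtype=np.int64)
    if rng is not None:
        order = rng.permutation(len(y))
        x, y = x[order], y[order]
    return x, y


def train_classifier(
    model: PatchClassifier,
    patches: Sequence[CandidatePatch],
    tc: TrainConfig,
    val_patches: Sequence[CandidatePatch] | None = None,
) -> dict:
    """Train the candidate classifier with the shared protocol; returns history."""
    labels = {p.label for p in patches}
    if labels <= {0} or labels <= {1}:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(tc.seed)
    x, y = assemble_training_patches(patches, rng)
    if val_patches is not None:
        xv = np.asarray([p.image for p in val_patches], dtype=np.float32)
        yv = np.asarray([p.label for p in val_patches], dtype=np.int64)
    else:
        xv, yv = x, y

    opt = nn.Adam(model.params(), lr=tc.lr0, l2=tc.l2_weight)
    stopper = nn.EarlyStopper(tc.early_stop_min_rel, tc.early_stop_patience)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    n = x.shape[0]
    n_batches = max(1, -(-n // tc.batch_size))
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        model.train(True)
        ep_loss = 0.0
        for bi in range(n_batches):
            idx = order[bi * tc.batch_size : (bi + 1) * tc.batch_size]
            if idx.size == 0:
                continue
            opt.lr = nn.step_lr(tc.lr0, tc.drop_factor, tc.drop_period, epoch + bi / n_batches)
            logits = model.forward(x[idx][:, None])
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
        ep_loss /= n_batches
        model.train(False)
        vlogits = model.forward(xv[:, None])
        val_loss, _ = nn.softmax_cross_entropy(vlogits, yv)
        history["epoch"].append(epoch)
        history["train_loss"].append(ep_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(nn.step_lr(tc.lr0, tc.drop_factor, tc.drop_period, float(epoch)))
        if stopper.update(val_loss):
            break
    model.train(False)
    return history


def filter_candidates(
    mask: np.ndarray,
    blobs: Sequence[CandidateBlob],
    classifier: PatchClassifier,
    pf: PreprocessedFrame,
    threshold: float = 0.5,
) -> tuple[np.ndarray, list[dict]]:
    """Erase candidates the classifier rejects; keep microvessel blobs untouched.

    Returns (cleaned mask, decision table); the cleaned mask is always a
    subset of the input mask.
    """
    cleaned = np.asarray(mask).astype(np.uint8).copy()
    decisions: list[dict] = []
    if blobs:
        imgs = np.stack([make_patch(b, pf).image for b in blobs])
        probs = classifier.predict_proba(imgs)[:, 1]
    else:
        probs = np.empty(0)
    for bi, blob in enumerate(blobs):
        keep = bool(probs[bi] >= threshold)
        if not keep:
            cleaned[blob.pixels[:, 0], blob.pixels[:, 1]] = 0
        decisions.append({
            "blob_id": bi, "frame": blob.frame,
            "aline_min": blob.aline_min, "aline_max": blob.aline_max,
            "r_min": blob.r_min, "r_max": blob.r_max,
            "area_px": blob.area_px, "probability": float(probs[bi]), "kept": keep,
        })
    return cleaned, decisions
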