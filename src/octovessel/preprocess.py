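"""Polar-domain pre-processing: guidewire removal, lumen alignment, ROI crop, denoising.

The five steps run in a fixed order on each raw polar frame: (1) detect and
blank the guidewire and its shadow band, (2) detect the lumen boundary,
(3) pixel-shift every A-line left so tissue starts at depth 0, (4) crop the
radial region of interest (300 pixels = 1.5 mm at 5 µm/pixel by default),
(5) Gaussian denoise (7x7 kernel, sigma 1).  All bookkeeping needed to map
pre-processed coordinates back to the raw raster is retained.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import PolarPullback

DEFAULTS = {
    "roi_depth": 300,
    "denoise_kernel": 7,
    "denoise_sigma": 1.0,
    "lumen_jump": 3,
    "lumen_min_run": 5,
    "guidewire_alpha": 1.0,
    "guidewire_beta": 0.5,
    "guidewire_gamma": 0.02,
    "shadow_threshold": 0.55,
    "guidewire_widths": (10, 40),
}


@dataclasses.dataclass(eq=False)
class PreprocessedFrame:
    """A lumen-aligned, guidewire-blanked, ROI-cropped, denoised polar frame.

    ``lumen_offset[i]`` is the raw depth index of the lumen boundary on
    A-line i (the shift applied); ``guidewire_interval`` is the blanked
    circular A-line interval as (start, width); ``valid_mask`` is False
    where zero padding or blanking was applied.
    """

    image: np.ndarray  # (alines, roi_depth)
    lumen_offset: np.ndarray  # (alines,) int
    guidewire_interval: tuple[int, int]  # (start, width), width 0 = none
    valid_mask: np.ndarray  # bool, same shape as image
    raw_depth: int = 0

    def to_raw_coords(self, aline: int, depth: int) -> tuple[int, int]:
        """Map a pre-processed (A-line, depth) pixel back to the raw raster."""
        return aline, depth + int(self.lumen_offset[aline])

    def guidewire_alines(self) -> np.ndarray:
        start, width = self.guidewire_interval
        n = self.image.shape[0]
        return (start + np.arange(width)) % n


# --- denoising -------------------------------------------------------------

def gaussian_kernel(kernel: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side length."""
    if kernel % 2 == 0:
        raise ValueError("kernel size must be odd")
    r = kernel // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def denoise(frame: np.ndarray, kernel: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with reflected borders."""
    k = gaussian_kernel(kernel, sigma)
    return ndimage.convolve(np.asarray(frame, dtype=np.float64), k, mode="reflect")


# --- lumen boundary --------------------------------------------------------

def _first_run_at_least(mask_row: np.ndarray, start: int, min_run: int) -> int:
    """First index >= start beginning a run of >= min_run consecutive True."""
    idx = np.flatnonzero(mask_row[start:])
    if idx.size == 0:
        return -1
    # run-length encode the supra-threshold indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_run:
            return int(idx[s]) + start
    return -1


def segment_lumen(
    frame: np.ndarray,
    catheter_radius_px: int,
    jump: int = 3,
    min_run: int = 5,
) -> np.ndarray:
    """Per-A-line lumen boundary (depth index of first tissue pixel).

    Baseline detector: on the angularly smoothed frame, the first depth past
    the catheter mask where intensity exceeds an Otsu threshold for at least
    ``min_run`` consecutive pixels; the raw estimates are then smoothed by a
    dynamic program over A-lines with circular θ, limiting adjacent-A-line
    steps to ``jump`` pixels.  The interface is pluggable, so a learned
    detector can replace it.
    """
    frame = np.asarray(frame, dtype=np.float64)
    n_a, n_d = frame.shape
    sm = ndimage.gaussian_filter1d(frame, sigma=1.0, axis=0, mode="wrap", truncate=3.0)
    search = sm[:, catheter_radius_px:]
    if search.max() <= 0:
        raise ValueError("no lumen found: frame is empty beyond the catheter")
    try:
        thresh = threshold_otsu(search)
    except ValueError:  # single-valued image
        thresh = float(search.max()) / 2.0
    above = sm >= thresh
    est = np.array([_first_run_at_least(above[a], catheter_radius_px, min_run) for a in range(n_a)])
    if (est < 0).all():
        raise ValueError("no lumen found: no A-line exceeds the threshold")

    # unary cost: distance to the per-A-line estimate, capped; missing = flat
    cap = 25.0
    unary = np.empty((n_a, n_d))
    depths = np.arange(n_d, dtype=float)
    for a in range(n_a):
        unary[a] = cap if est[a] < 0 else np.minimum(np.abs(depths - est[a]), cap)

    step_cost = 0.75
    offsets = np.arange(-jump, jump + 1)

    def run_dp(anchor: int) -> tuple[float, np.ndarray]:
        dp = np.full(n_d, np.inf)
        dp[anchor] = unary[0, anchor]
        back = np.zeros((n_a, n_d), dtype=np.int32)
        for a in range(1, n_a):
            best = np.full(n_d, np.inf)
            arg = np.zeros(n_d, dtype=np.int32)
            for o in offsets:
                cand = np.roll(dp, o) + step_cost * abs(o)
                if o > 0:
                    cand[:o] = np.inf
                elif o < 0:
                    cand[o:] = np.inf
                better = cand < best
                best[better] = cand[better]
                arg[better] = np.arange(n_d)[better] - o
            dp = best + unary[a]
            back[a] = arg
        # close the circle: last state must be within `jump` of the anchor
        close = np.full(n_d, np.inf)
        lo, hi = max(anchor - jump, 0), min(anchor + jump + 1, n_d)
        close[lo:hi] = step_cost * np.abs(np.arange(lo, hi) - anchor)
        total = dp + close
        end = int(np.argmin(total))
        path = np.empty(n_a, dtype=int)
        path[-1] = end
        for a in range(n_a - 1, 0, -1):
            path[a - 1] = back[a, path[a]]
        return float(total[end]), path

    valid_est = est[est >= 0]
    anchors = np.unique(np.clip(
        np.round(np.percentile(valid_est, [10, 30, 50, 70, 90])).astype(int), 0, n_d - 1))
    best_cost, best_path = np.inf, None
    for anchor in anchors:
        cost, path = run_dp(int(anchor))
        if cost < best_cost:
            best_cost, best_path = cost, path
    return best_path


# --- guidewire shadow ------------------------------------------------------

def _interval_scores(frame: np.ndarray, boundary: np.ndarray, widths: np.ndarray,
                     alpha: float, beta: float, shadow_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Static score of every (start, width) circular interval.

    Each A-line contributes its normalized beyond-lumen darkness relative to
    the shadow threshold, minus a bright-leading-reflection bonus; interval
    score is the sum, so the minimum covers exactly the guidewire-like band
    (dark A-lines contribute negatively, bright ones positively).
    """
    n_a, n_d = frame.shape
    cols = np.arange(n_d)[None, :]
    beyond = cols >= boundary[:, None]
    s = (frame * beyond).sum(axis=1) / np.maximum(beyond.sum(axis=1), 1)
    norm = s / max(np.median(s), 1e-9)
    edge = np.array([frame[a, boundary[a]: min(boundary[a] + 4, n_d)].mean() for a in range(n_a)])
    gain = alpha * (norm - shadow_threshold) - beta * (edge - np.median(edge))
    cg = np.concatenate([[0.0], np.cumsum(np.concatenate([gain, gain]))])
    starts = np.arange(n_a)
    scores = np.stack([cg[starts + w] - cg[starts] for w in widths])
    return scores, norm


def detect_guidewire(
    frame: np.ndarray,
    lumen_boundary: np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.5,
    shadow_threshold: float = 0.55,
    widths: tuple[int, int] = (10, 40),
) -> tuple[int, int]:
    """Guidewire A-line interval of one frame as (start, width); width 0 = none."""
    intervals = detect_guidewire_stack(
        frame[None], lumen_boundary[None], alpha=alpha, beta=beta,
        shadow_threshold=shadow_threshold, widths=widths, gamma=0.0,
    )
    return intervals[0]


def detect_guidewire_stack(
    frames: np.ndarray,
    boundaries: np.ndarray,
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 0.02,
    shadow_threshold: float = 0.55,
    widths: tuple[int, int] = (10, 40),
    top_k: int = 6,
) -> list[tuple[int, int]]:
    """Temporally smooth guidewire detection over a frame stack.

    Per frame, candidate circular intervals are scored by darkness of the
    beyond-lumen band minus the brightness of the leading reflection; a
    dynamic program across frames adds a drift penalty between interval
    centres and picks the jointly best sequence.  Frames whose darkest
    normalized A-line stays above ``shadow_threshold`` get an empty interval.
    """
    n_f, n_a, _ = frames.shape
    width_grid = np.arange(widths[0], widths[1] + 1, 2)
    cand: list[list[tuple[int, int, float]]] = []  # per frame: (start, width, score)
    empty: list[bool] = []
    for fi in range(n_f):
        scores, norm = _interval_scores(frames[fi], boundaries[fi], width_grid, alpha, beta, shadow_threshold)
        if norm.min() >= shadow_threshold:
            cand.append([(0, 0, 0.0)])
            empty.append(True)
            continue
        empty.append(False)
        flat = np.argsort(scores, axis=None)[: top_k * 4]
        picks: list[tuple[int, int, float]] = []
        centers: list[float] = []
        for f in flat:
            wi, start = divmod(int(f), n_a)
            w = int(width_grid[wi])
            c = (start + w / 2) % n_a
            if any(min(abs(c - pc), n_a - abs(c - pc)) < 5 for pc in centers):
                continue
            picks.append((start, w, float(scores[wi, start])))
            centers.append(c)
            if len(picks) == top_k:
                break
        cand.append(picks)

    # Viterbi over per-frame candidates with a centre-drift cost
    def center(c: tuple[int, int, float]) -> float:
        return (c[0] + c[1] / 2) % n_a

    dp = [c[2] for c in cand[0]]
    back: list[list[int]] = [[0] * len(cand[0])]
    for fi in range(1, n_f):
        prev = cand[fi - 1]
        cur = cand[fi]
        row_cost, row_back = [], []
        for cc in cur:
            best, arg = np.inf, 0
            for pi, pc in enumerate(prev):
                drift = 0.0
                if cc[1] and pc[1]:
                    d = abs(center(cc) - center(pc))
                    drift = gamma * min(d, n_a - d)
                val = dp[pi] + drift
                if val < best:
                    best, arg = val, pi
            row_cost.append(best + cc[2])
            row_back.append(arg)
        dp = row_cost
        back.append(row_back)
    idx = int(np.argmin(dp))
    path = [0] * n_f
    for fi in range(n_f - 1, -1, -1):
        path[fi] = idx
        idx = back[fi][idx]
    out = []
    for fi in range(n_f):
        s, w, _ = cand[fi][path[fi]]
        out.append((0, 0) if empty[fi] else (int(s), int(w)))
    return out


# --- alignment -------------------------------------------------------------

def pixel_shift(frame: np.ndarray, lumen_boundary: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift each A-line left so the lumen boundary lands at depth 0.

    Returns (shifted frame, offsets, valid mask); the right side is
    zero-padded and flagged invalid.
    """
    frame = np.asarray(frame)
    n_a, n_d = frame.shape
    offsets = np.asarray(lumen_boundary, dtype=int)
    if offsets.shape != (n_a,) or offsets.min() < 0 or offsets.max() >= n_d:
        raise ValueError("lumen boundary indices out of range")
    shifted = np.zeros_like(frame)
    valid = np.zeros((n_a, n_d), dtype=bool)
    for a in range(n_a):
        keep = n_d - offsets[a]
        shifted[a, :keep] = frame[a, offsets[a]:]
        valid[a, :keep] = True
    return shifted, offsets, valid


def unshift(shifted: np.ndarray, offsets: np.ndarray, raw_depth: int) -> np.ndarray:
    """Invert pixel_shift over the valid region (zeros elsewhere)."""
    n_a = shifted.shape[0]
    out = np.zeros((n_a, raw_depth), dtype=shifted.dtype)
    for a in range(n_a):
        keep = raw_depth - offsets[a]
        out[a, offsets[a]:] = shifted[a, :keep]
    return out


def crop_roi(shifted: np.ndarray, roi_depth: int = 300, pad_to_roi: bool = False) -> tuple[np.ndarray, bool]:
    """Keep the first min(roi_depth, depth) columns; optionally zero-pad up to roi_depth.

    Returns (cropped frame, padded flag); padding only ever happens when the
    available depth is smaller than ``roi_depth`` and ``pad_to_roi`` is set.
    """
    n_a, n_d = shifted.shape
    keep = min(roi_depth, n_d)
    out = shifted[:, :keep]
    padded = False
    if pad_to_roi and keep < roi_depth:
        out = np.pad(out, ((0, 0), (0, roi_depth - keep)))
        padded = True
    return np.ascontiguousarray(out), padded


# --- full pipeline ---------------------------------------------------------

def preprocess_frame(
    frame: np.ndarray,
    catheter_radius_px: int,
    config: dict | None = None,
    lumen_boundary: np.ndarray | None = None,
    guidewire_interval: tuple[int, int] | None = None,
) -> PreprocessedFrame:
    """Run the five pre-processing steps on one raw polar frame.

    ``lumen_boundary`` / ``guidewire_interval`` can be supplied (e.g. from a
    stack-level temporal detection); otherwise they are detected here.
    """
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    frame = np.asarray(frame, dtype=np.float64)
    n_a, n_d = frame.shape
    if lumen_boundary is None:
        lumen_boundary = segment_lumen(frame, catheter_radius_px, jump=cfg["lumen_jump"],
                                       min_run=cfg["lumen_min_run"])
    if guidewire_interval is None:
        guidewire_interval = detect_guidewire(
            frame, lumen_boundary, alpha=cfg["guidewire_alpha"], beta=cfg["guidewire_beta"],
            shadow_threshold=cfg["shadow_threshold"], widths=tuple(cfg["guidewire_widths"]),
        )
    start, width = guidewire_interval
    blanked = frame.copy()
    gw_alines = (start + np.arange(width)) % n_a
    blanked[gw_alines] = 0.0
    shifted, offsets, valid = pixel_shift(blanked, lumen_boundary)
    valid[gw_alines] = False
    cropped, _ = crop_roi(shifted, cfg["roi_depth"])
    valid_c, _ = crop_roi(valid, cfg["roi_depth"])
    smooth = denoise(cropped, kernel=cfg["denoise_kernel"], sigma=cfg["denoise_sigma"])
    smooth[~valid_c] = 0.0
    return PreprocessedFrame(
        image=smooth.astype(np.float32),
        lumen_offset=offsets,
        guidewire_interval=(int(start), int(width)),
        valid_mask=valid_c,
        raw_depth=n_d,
    )


def preprocess_pullback(
    pullback: PolarPullback,
    catheter_radius_px: int,
    config: dict | None = None,
) -> list[PreprocessedFrame]:
    """Pre-process every frame, with temporally smoothed guidewire detection."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    boundaries = np.stack([
        segment_lumen(pullback.data[fi], catheter_radius_px, jump=cfg["lumen_jump"],
                      min_run=cfg["lumen_min_run"])
        for fi in range(pullback.n_frames)
    ])
    intervals = detect_guidewire_stack(
        pullback.data.astype(np.float64), boundaries,
        alpha=cfg["guidewire_alpha"], beta=cfg["guidewire_beta"], gamma=cfg["guidewire_gamma"],
        shadow_threshold=cfg["shadow_threshold"], widths=tuple(cfg["guidewire_widths"]),
    )
    return [
        preprocess_frame(pullback.data[fi], catheter_radius_px, cfg,
                         lumen_boundary=boundaries[fi], guidewire_interval=intervals[fi])
        for fi in range(pullback.n_frames)
    ]


def shift_labels(labels: np.ndarray, pf: PreprocessedFrame) -> np.ndarray:
    """Carry a label frame through the same shift/crop as its image frame.

    Label pixels lost to guidewire blanking remain in the raster but are
    excluded from training losses via ``pf.valid_mask``.
    """
    shifted, _, _ = pixel_shift(labels, pf.lumen_offset)
    cropped, _ = crop_roi(shifted, pf.image.shape[1])
    return cropped
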