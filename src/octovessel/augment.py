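"""Polar-domain offset augmentation and classifier patch rotation.

A pullback's frames are stacked along the A-line axis into one tall 2-D
array whose rotation angle runs from 0 to N x 360 deg.  Shifting the
starting A-line re-frames that array into new polar frames with no data loss
or distortion; the default protocol takes nine shifts of 55 A-lines each.
Classifier patches containing microvessels are additionally rotated at
30 deg steps from 30 to 180 deg, multiplying positives seven-fold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import PolarPullback

ROTATION_ANGLES = (30, 60, 90, 120, 150, 180)


@dataclasses.dataclass
class ConcatenatedPullback:
    """All frames stacked along the A-line axis: ((N*alines) x depth)."""

    data: np.ndarray
    alines_per_frame: int

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] // self.alines_per_frame

    def frame_boundaries(self) -> np.ndarray:
        return np.arange(self.n_frames + 1) * self.alines_per_frame


def concat_pullback(pullback: PolarPullback | np.ndarray, alines_per_frame: int | None = None) -> ConcatenatedPullback:
    """Stack frames in pullback order; row j of frame k lands at row k*alines + j."""
    if isinstance(pullback, PolarPullback):
        data = pullback.data
        alines = pullback.alines_per_frame
    else:
        data = np.asarray(pullback)
        if data.ndim != 3:
            raise ValueError("expected a 3-D stack")
        alines = data.shape[1] if alines_per_frame is None else alines_per_frame
    if data.shape[0] < 1:
        raise ValueError("need at least one frame")
    big = data.reshape(-1, data.shape[2])
    return ConcatenatedPullback(big, alines)


def offset_augment(
    concat: ConcatenatedPullback,
    shift_alines: int = 55,
    n_shifts: int = 9,
) -> list[np.ndarray]:
    """Re-frame the concatenated array at shifted starting A-lines.

    Augmented set s (s = 1..n_shifts) starts at row s*shift_alines and cuts
    consecutive blocks of ``alines_per_frame`` rows into frames; a trailing
    incomplete frame is dropped (a pullback is not circular along its axis).
    Returns ``n_shifts`` stacks of shape (frames, alines, depth).
    """
    if shift_alines < 1 or n_shifts < 1:
        raise ValueError("shift_alines and n_shifts must be >= 1")
    rows, depth = concat.data.shape
    if shift_alines >= rows:
        raise ValueError("shift_alines exceeds the concatenated array")
    alines = concat.alines_per_frame
    out = []
    for s in range(1, n_shifts + 1):
        start = s * shift_alines
        avail = rows - start
        n_frames = avail // alines
        if n_frames < 1:
            out.append(np.empty((0, alines, depth), dtype=concat.data.dtype))
            continue
        block = concat.data[start : start + n_frames * alines]
        out.append(block.reshape(n_frames, alines, depth).copy())
    return out


def rotate_patch_augment(patch: np.ndarray, angles=ROTATION_ANGLES) -> list[np.ndarray]:
    """Original patch plus rotations about its centre (bilinear, edge-replicated).

    With the default six angles this yields seven patches per positive, the
    multiplicity used when assembling classifier training sets; negatives
    are never augmented.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    out = [patch.copy()]
    for ang in angles:
        rot = ndimage.rotate(patch, ang, reshape=False, order=1, mode="nearest")
        out.append(rot)
    return out
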