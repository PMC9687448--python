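"""Readers and writers for pullbacks, label volumes, tables and run configuration.

A pullback travels as a multi-page TIFF (one page per frame, frame x A-line x
depth raster) next to a JSON metadata sidecar, or as a directory of per-frame
PNG/TIFF images plus the same sidecar.  Candidate and track tables are CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

SIDECAR_NAME = "metadata.json"


@dataclasses.dataclass
class PolarPullback:
    """A polar-domain IVOCT pullback: intensity stack plus physical metadata.

    ``data`` is (frame, A-line, depth) with values in [0, 1]; depth is the
    radial axis r, the A-line axis is the catheter rotation angle θ and is
    circular (row 0 adjacent to the last row).
    """

    data: np.ndarray
    radial_px_um: float = 5.0
    frame_pitch_mm: float = 0.2
    segment_id: str = "segment-0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("pullback data must be 3-D (frame, A-line, depth)")
        if not np.isfinite(self.data).all():
            raise ValueError("pullback intensities must be finite")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("pullback intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def alines_per_frame(self) -> int:
        return self.data.shape[1]

    @property
    def depth_px(self) -> int:
        return self.data.shape[2]

    def metadata(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "alines_per_frame": self.alines_per_frame,
            "depth_px": self.depth_px,
            "radial_px_um": self.radial_px_um,
            "frame_pitch_mm": self.frame_pitch_mm,
            "segment_id": self.segment_id,
        }


@dataclasses.dataclass
class LabelVolume:
    """Binary microvessel labels aligned with a pullback (1 = microvessel)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        vals = np.unique(self.data)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("label volume values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)


def _normalize(raster: np.ndarray) -> np.ndarray:
    """Map an integer raster onto [0, 1] by the dtype maximum; floats pass through."""
    if np.issubdtype(raster.dtype, np.integer):
        return raster.astype(np.float32) / np.iinfo(raster.dtype).max
    return raster.astype(np.float32)


def write_pullback(pullback: PolarPullback, path: str | Path) -> Path:
    """Write a pullback as multi-page float32 TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        path.mkdir(parents=True, exist_ok=True)
        tiff_path = path / "pullback.tif"
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        tiff_path = path
    tifffile.imwrite(tiff_path, pullback.data, photometric="minisblack")
    sidecar = tiff_path.with_name(SIDECAR_NAME)
    sidecar.write_text(json.dumps(pullback.metadata(), indent=1))
    return tiff_path


def read_pullback(path: str | Path) -> PolarPullback:
    """Read a pullback from a multi-page TIFF or a directory of per-frame images.

    A ``metadata.json`` sidecar must sit next to the TIFF (or inside the
    directory); its frame count and raster dimensions must match the pixel
    data.  Integer rasters are normalized to [0, 1] by the dtype maximum.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        sidecar = path / SIDECAR_NAME
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        tiffs = sorted(path.glob("pullback.tif")) or sorted(path.glob("pullback.tiff"))
        if tiffs:
            raster = tifffile.imread(tiffs[0])
        else:
            frames = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
            if not frames:
                raise FileNotFoundError(f"no frame images in {path}")
            raster = np.stack([np.asarray(iio.imread(p)) for p in frames])
    else:
        sidecar = path.with_name(SIDECAR_NAME)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        raster = tifffile.imread(path)
    meta = json.loads(sidecar.read_text())
    if raster.ndim == 2:
        raster = raster[None]
    expected = (meta["n_frames"], meta["alines_per_frame"], meta["depth_px"])
    if raster.shape != expected:
        raise ValueError(f"raster shape {raster.shape} does not match sidecar {expected}")
    return PolarPullback(
        data=np.clip(_normalize(raster), 0.0, 1.0),
        radial_px_um=float(meta["radial_px_um"]),
        frame_pitch_mm=float(meta["frame_pitch_mm"]),
        segment_id=str(meta.get("segment_id", "segment-0")),
    )


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.data, photometric="minisblack")
    return path


def read_labels(path: str | Path) -> LabelVolume:
    return LabelVolume(tifffile.imread(path))


# --- run configuration -----------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "preset": "desk",  # desk: 256 A-lines x 200 depth; fidelity: 496 x 360
        "n_frames": 40,
        "n_microvessels": 3,
        "n_side_branches": 1,
        "n_calcifications": 1,
    },
    "preprocess": {
        "roi_depth": 300,
        "denoise_kernel": 7,
        "denoise_sigma": 1.0,
        "lumen_jump": 3,
        "lumen_min_run": 5,
        "guidewire_alpha": 1.0,
        "guidewire_beta": 0.5,
        "guidewire_gamma": 0.02,
        "shadow_threshold": 0.55,
    },
    "augment": {
        "shift_alines": 55,
        "n_shifts": 9,
        "include_original": True,
        "rotation_angles": [30, 60, 90, 120, 150, 180],
    },
    "segment": {
        "base_channels": 8,
        "aspp_dilation_rates": [8, 16, 32],
        "output_stride": 4,
        "threshold": None,  # None = per-pixel argmax
    },
    "classify": {
        "patch_size": 30,
        "pad_px": 3,
        "min_blob_area": 1,
    },
    "train": {
        "lr0": 0.001,
        "drop_factor": 0.2,
        "drop_period": 0.5,
        "max_epochs": 50,
        "early_stop_patience": 5,
        "early_stop_min_rel": 1e-4,
        "l2_weight": 1e-5,
        "batch_size": 8,
    },
    "track": {
        "min_frames": 3,
    },
    "evaluate": {
        "n_folds": 5,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Resolve the run configuration: documented defaults overlaid by a YAML file."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must hold a mapping")
    return _deep_merge(json.loads(json.dumps(DEFAULT_CONFIG)), user)
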