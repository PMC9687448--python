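"""Seeded synthetic polar-domain IVOCT pullback generator with exact ground truth.

The phantom emulates the structures an intravascular OCT microvessel pipeline
must detect or reject: speckled, depth-attenuated tissue beyond a smoothly
varying lumen boundary; a bright guidewire casting an angular shadow band;
signal-poor tubuloluminal microvessels persisting over several consecutive
frames; lumen-connected side branches; and sharp-bordered dark calcification
confusers.  Only microvessel pixels are labelled positive — side branches,
calcifications and lumen belong to the "other" class.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import LabelVolume, PolarPullback


@dataclasses.dataclass
class PhantomParams:
    """Geometry and texture parameters of the synthetic pullback.

    Defaults follow the fidelity raster (496 A-lines x 360 depth pixels at
    5 µm/pixel radially, 0.2 mm frame pitch from 36 mm/s at 180 fps); the
    ``desk`` preset (256 x 200, 40 frames) keeps every structure but runs
    quickly on one CPU.
    """

    n_frames: int = 40
    alines_per_frame: int = 496
    depth_px: int = 360
    radial_px_um: float = 5.0
    frame_pitch_mm: float = 0.2
    catheter_radius_px: int = 14
    lumen_radius_px: float = 60.0
    lumen_radius_var_px: float = 6.0
    attenuation_mu: float = 0.012  # per-pixel exponential decay beyond the lumen
    speckle_shape: float = 4.0  # gamma shape of multiplicative speckle
    n_microvessels: int = 3
    n_side_branches: int = 1
    n_calcifications: int = 1
    vessel_frames_min: int = 3
    vessel_frames_max: int = 12
    vessel_radius_px: tuple[int, int] = (4, 10)  # ~40-100 um radius at 5 um/px
    vessel_contrast: float = 0.18  # interior intensity multiplier
    vessel_drift_px: float = 1.5  # max centre drift per frame
    vessel_margin_px: int = 4  # clearance from the lumen boundary
    guidewire_width_alines: tuple[int, int] = (18, 30)
    shadow_attenuation: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("n_frames", "alines_per_frame", "depth_px", "n_microvessels",
                      "n_side_branches", "n_calcifications"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if self.vessel_frames_min < 1:
            raise ValueError("vessel_frames_min must be >= 1")
        max_lumen = self.lumen_radius_px + self.lumen_radius_var_px
        needed = max_lumen + self.vessel_margin_px + 2 * self.vessel_radius_px[1] + 4
        if self.depth_px <= needed:
            raise ValueError(
                f"impossible geometry: depth_px={self.depth_px} leaves no room for "
                f"vessels beyond the lumen (needs > {needed:.0f})"
            )

    @classmethod
    def desk(cls, **overrides) -> "PhantomParams":
        """Small raster for fast CPU runs: 256 A-lines x 200 depth, 40 frames."""
        base = dict(
            n_frames=40, alines_per_frame=256, depth_px=200,
            catheter_radius_px=10, lumen_radius_px=50.0, lumen_radius_var_px=5.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def fidelity(cls, **overrides) -> "PhantomParams":
        return cls(**overrides)


@dataclasses.dataclass(eq=False)
class Tube:
    """One microvessel (or confuser) tube: per-frame ellipse centres and radii."""

    frame_start: int
    frame_stop: int  # half-open
    centers: np.ndarray  # (n_frames_of_tube, 2) float: (A-line, depth)
    radius_alines: float
    radius_depth: float

    @property
    def n_frames(self) -> int:
        return self.frame_stop - self.frame_start


@dataclasses.dataclass(eq=False)
class SideBranch:
    frame_start: int
    frame_stop: int
    aline_start: int  # circular half-open interval [aline_start, aline_start+width)
    width_alines: int
    depth_extent_px: int


@dataclasses.dataclass(eq=False)
class GroundTruthScene:
    """Exact geometry of everything placed in the phantom."""

    lumen_boundary: np.ndarray  # (n_frames, alines) int depth index of first tissue pixel
    guidewire_interval: list[tuple[int, int]]  # per frame (start, width) circular A-lines
    microvessel_tubes: list[Tube]
    side_branches: list[SideBranch]
    calcifications: list[Tube]
    alines_per_frame: int = 0

    def to_json(self, path: str | Path) -> None:
        def tube_dict(t: Tube) -> dict:
            return {
                "frame_start": t.frame_start, "frame_stop": t.frame_stop,
                "centers": t.centers.tolist(),
                "radius_alines": t.radius_alines, "radius_depth": t.radius_depth,
            }

        payload = {
            "lumen_boundary": self.lumen_boundary.tolist(),
            "guidewire_interval": [list(iv) for iv in self.guidewire_interval],
            "microvessel_tubes": [tube_dict(t) for t in self.microvessel_tubes],
            "side_branches": [dataclasses.asdict(b) for b in self.side_branches],
            "calcifications": [tube_dict(t) for t in self.calcifications],
            "alines_per_frame": self.alines_per_frame,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthScene":
        raw = json.loads(Path(path).read_text())

        def tube(d: dict) -> Tube:
            return Tube(d["frame_start"], d["frame_stop"], np.asarray(d["centers"], dtype=float),
                        d["radius_alines"], d["radius_depth"])

        return cls(
            lumen_boundary=np.asarray(raw["lumen_boundary"], dtype=int),
            guidewire_interval=[tuple(iv) for iv in raw["guidewire_interval"]],
            microvessel_tubes=[tube(d) for d in raw["microvessel_tubes"]],
            side_branches=[SideBranch(**d) for d in raw["side_branches"]],
            calcifications=[tube(d) for d in raw["calcifications"]],
            alines_per_frame=raw["alines_per_frame"],
        )


def _circular_dist(a: np.ndarray | float, b: float, n: int):
    d = np.abs(np.asarray(a) - b) % n
    return np.minimum(d, n - d)


def _smooth_boundary(rng: np.random.Generator, p: PhantomParams) -> np.ndarray:
    """Lumen boundary depth per (frame, A-line): mean radius + smooth harmonics."""
    a = np.arange(p.alines_per_frame)
    f = np.arange(max(p.n_frames, 1))
    theta = 2 * np.pi * a / p.alines_per_frame
    n_harm = 3
    amps = rng.uniform(0.2, 1.0, size=n_harm) * p.lumen_radius_var_px / n_harm
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    drift_phase = rng.uniform(0, 2 * np.pi)
    boundary = np.empty((p.n_frames, p.alines_per_frame))
    for fi in f[: p.n_frames]:
        wob = sum(
            amps[k] * np.sin((k + 1) * theta + phases[k] + 0.05 * fi)
            for k in range(n_harm)
        )
        base = p.lumen_radius_px + 0.3 * p.lumen_radius_var_px * np.sin(0.12 * fi + drift_phase)
        boundary[fi] = base + wob
    lo = p.catheter_radius_px + 3
    hi = p.lumen_radius_px + p.lumen_radius_var_px
    return np.clip(np.round(boundary), lo, hi).astype(int)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  ra: float, rd: float, circular_alines: bool = True) -> np.ndarray:
    """Boolean ellipse in (A-line, depth) raster; the A-line axis wraps."""
    n_a, n_d = shape
    alines = np.arange(n_a)[:, None]
    depths = np.arange(n_d)[None, :]
    da = _circular_dist(alines, center[0], n_a) if circular_alines else np.abs(alines - center[0])
    dd = np.abs(depths - center[1])
    return (da / max(ra, 1e-9)) ** 2 + (dd / max(rd, 1e-9)) ** 2 <= 1.0


def _place_tubes(rng: np.random.Generator, p: PhantomParams, boundary: np.ndarray,
                 gw_centers: np.ndarray, gw_width: int) -> list[Tube]:
    """Sample microvessel tubes: smooth drifting centres, clear of lumen and shadow."""
    tubes: list[Tube] = []
    max_boundary = int(boundary.max())
    occupied: list[tuple[float, float]] = []  # (mean A-line, angular halfwidth)
    for _ in range(p.n_microvessels):
        for _attempt in range(200):
            span = int(rng.integers(p.vessel_frames_min, min(p.vessel_frames_max, p.n_frames) + 1))
            f0 = int(rng.integers(0, p.n_frames - span + 1))
            ra = float(rng.uniform(*p.vessel_radius_px))
            rd = float(rng.uniform(*p.vessel_radius_px))
            a0 = float(rng.uniform(0, p.alines_per_frame))
            d_lo = max_boundary + p.vessel_margin_px + rd + 1
            d_hi = p.depth_px - rd - 2
            if d_hi <= d_lo:
                raise ValueError("impossible geometry: vessel cannot fit between lumen and depth_px")
            d0 = float(rng.uniform(d_lo, min(d_hi, d_lo + 0.6 * (d_hi - d_lo))))
            # stay clear of the guidewire shadow and of other tubes
            if _circular_dist(a0, float(np.mean(gw_centers)), p.alines_per_frame) < gw_width / 2 + ra + 8:
                continue
            if any(_circular_dist(a0, oa, p.alines_per_frame) < ow + ra + 6 for oa, ow in occupied):
                continue
            steps = rng.uniform(-p.vessel_drift_px, p.vessel_drift_px, size=(span, 2))
            steps[0] = 0
            centers = np.cumsum(steps, axis=0) + [a0, d0]
            centers[:, 0] %= p.alines_per_frame
            centers[:, 1] = np.clip(centers[:, 1], d_lo, d_hi)
            tubes.append(Tube(f0, f0 + span, centers, ra, rd))
            occupied.append((a0, ra + abs(steps[:, 0]).sum()))
            break
        else:
            raise ValueError("could not place microvessel without collisions")
    return tubes


def generate_pullback(params: PhantomParams) -> tuple[PolarPullback, LabelVolume, GroundTruthScene]:
    """Render a synthetic pullback, its microvessel label volume and the exact scene.

    Tissue beyond the lumen boundary b follows I0·exp(−μ·(r−b)) modulated by
    multiplicative gamma speckle; structure interiors are darkened relative
    to local tissue; the guidewire is a bright arc at the lumen with an
    attenuated shadow band over its A-line interval.  Identical params and
    seed give bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_f, n_a, n_d = p.n_frames, p.alines_per_frame, p.depth_px

    boundary = _smooth_boundary(rng, p)

    # guidewire: circular interval drifting slowly across frames
    gw_width = int(rng.integers(*p.guidewire_width_alines))
    gw_start0 = float(rng.uniform(0, n_a))
    gw_drift = np.cumsum(rng.uniform(-0.8, 0.8, size=n_f))
    gw_starts = np.round(gw_start0 + gw_drift).astype(int) % n_a
    gw_centers = (gw_starts + gw_width / 2) % n_a

    tubes = _place_tubes(rng, p, boundary, gw_centers, gw_width)

    # side branches: dark wedges contiguous with the lumen
    branches: list[SideBranch] = []
    for _ in range(p.n_side_branches):
        for _attempt in range(200):
            width = int(rng.integers(8, 20))
            span = int(rng.integers(3, max(4, min(8, n_f)) + 1))
            f0 = int(rng.integers(0, n_f - span + 1))
            a0 = int(rng.integers(0, n_a))
            center = (a0 + width / 2) % n_a
            if _circular_dist(center, float(np.mean(gw_centers)), n_a) < gw_width / 2 + width / 2 + 6:
                continue
            if any(_circular_dist(center, float(t.centers[:, 0].mean()), n_a) < width / 2 + t.radius_alines + 6
                   for t in tubes):
                continue
            depth_extent = int(rng.integers(18, 40))
            branches.append(SideBranch(f0, f0 + span, a0, width, depth_extent))
            break
        else:
            raise ValueError("could not place side branch without collisions")

    # calcifications: sharp-bordered dark ellipses in tissue, labelled "other"
    calcs: list[Tube] = []
    max_boundary = int(boundary.max())
    for _ in range(p.n_calcifications):
        for _attempt in range(200):
            ra = float(rng.uniform(8, 14))
            rd = float(rng.uniform(8, 14))
            span = int(rng.integers(3, max(4, min(10, n_f)) + 1))
            f0 = int(rng.integers(0, n_f - span + 1))
            a0 = float(rng.uniform(0, n_a))
            d_lo = max_boundary + 4 + rd
            d_hi = n_d - rd - 2
            if d_hi <= d_lo:
                continue
            d0 = float(rng.uniform(d_lo, d_hi))
            if _circular_dist(a0, float(np.mean(gw_centers)), n_a) < gw_width / 2 + ra + 6:
                continue
            if any(_circular_dist(a0, float(t.centers[:, 0].mean()), n_a) < ra + t.radius_alines + 8 for t in tubes):
                continue
            if any(_circular_dist(a0, (b.aline_start + b.width_alines / 2) % n_a, n_a) < ra + b.width_alines / 2 + 6
                   for b in branches):
                continue
            centers = np.tile([a0, d0], (span, 1)).astype(float)
            calcs.append(Tube(f0, f0 + span, centers, ra, rd))
            break
        else:
            raise ValueError("could not place calcification without collisions")

    stack = np.empty((n_f, n_a, n_d), dtype=np.float32)
    labels = np.zeros((n_f, n_a, n_d), dtype=np.uint8)
    depths = np.arange(n_d)[None, :]
    i0 = 0.85

    for fi in range(n_f):
        b = boundary[fi][:, None]
        beyond = depths >= b
        tissue = i0 * np.exp(-p.attenuation_mu * np.maximum(depths - b, 0.0))
        speckle = rng.gamma(p.speckle_shape, 1.0 / p.speckle_shape, size=(n_a, n_d))
        frame = np.where(beyond, tissue * speckle, 0.0)
        # lumen interior: faint blood-speckle background
        lumen_zone = (depths >= p.catheter_radius_px) & ~beyond
        frame[lumen_zone] = 0.03 * speckle[lumen_zone]
        # catheter sheath: bright thin ring
        sheath = (depths >= p.catheter_radius_px - 2) & (depths < p.catheter_radius_px)
        frame[np.broadcast_to(sheath, frame.shape)] = 0.7

        # structure interiors darken local tissue (multiplicative contrast)
        for t in tubes:
            if t.frame_start <= fi < t.frame_stop:
                c = t.centers[fi - t.frame_start]
                m = _ellipse_mask((n_a, n_d), (c[0], c[1]), t.radius_alines, t.radius_depth)
                frame[m] *= p.vessel_contrast
                labels[fi][m] = 1
        for br in branches:
            if br.frame_start <= fi < br.frame_stop:
                cols = (br.aline_start + np.arange(br.width_alines)) % n_a
                for a in cols:
                    lo = boundary[fi, a]
                    frame[a, lo : lo + br.depth_extent_px] *= 0.12
        for t in calcs:
            if t.frame_start <= fi < t.frame_stop:
                c = t.centers[fi - t.frame_start]
                m = _ellipse_mask((n_a, n_d), (c[0], c[1]), t.radius_alines, t.radius_depth)
                # sharp border: suppress speckle inside, keep a crisp dark plateau
                frame[m] = 0.22 * tissue[m]

        # guidewire: bright arc at the lumen plus an attenuated shadow band
        cols = (gw_starts[fi] + np.arange(gw_width)) % n_a
        for a in cols:
            lo = boundary[fi, a]
            frame[a, lo:] *= p.shadow_attenuation
            frame[a, max(lo - 2, 0) : lo + 3] = 0.95

        stack[fi] = np.clip(frame, 0.0, 1.0)

    scene = GroundTruthScene(
        lumen_boundary=boundary,
        guidewire_interval=[(int(s), gw_width) for s in gw_starts],
        microvessel_tubes=tubes,
        side_branches=branches,
        calcifications=calcs,
        alines_per_frame=n_a,
    )
    pullback = PolarPullback(stack, radial_px_um=p.radial_px_um, frame_pitch_mm=p.frame_pitch_mm,
                             segment_id=f"phantom-{p.seed}")
    return pullback, LabelVolume(labels), scene


def ground_truth_frame_presence(scene: GroundTruthScene) -> set[int]:
    """Frames containing at least one microvessel pixel (from tube spans)."""
    present: set[int] = set()
    for t in scene.microvessel_tubes:
        present.update(range(t.frame_start, t.frame_stop))
    return present
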