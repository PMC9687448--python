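"""Cross-frame linking of microvessel candidates and track quantification.

A microvessel is a signal-poor tubuloluminal structure, unconnected to the
lumen, persisting over consecutive frames.  Per-frame blobs are linked
greedily into tracks when their pixel sets overlap between consecutive
frames; tracks shorter than the persistence threshold or touching the lumen
boundary (depth 0–1 after pixel shifting) are rejected.  Kept tracks are
quantified as length = frames × frame pitch and an equivalent-circle mean
diameter from the per-frame areas.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .classify import CandidateBlob


@dataclasses.dataclass(eq=False)
class MicrovesselTrack:
    """An ordered run of (frame, blob) pairs over strictly consecutive frames."""

    members: list[tuple[int, CandidateBlob]]
    kept: bool | None = None
    reject_reason: str | None = None
    length_mm: float | None = None
    mean_diameter_um: float | None = None

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.members]
        if frames != list(range(frames[0], frames[0] + len(frames))):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def n_frames(self) -> int:
        return len(self.members)

    @property
    def frame_range(self) -> tuple[int, int]:
        return self.members[0][0], self.members[-1][0] + 1

    @property
    def lumen_connected(self) -> bool:
        return any((blob.pixels[:, 1] <= 1).any() for _, blob in self.members)


def _overlap(a: CandidateBlob, b: CandidateBlob) -> int:
    sa = set(map(tuple, a.pixels))
    return sum(1 for px in map(tuple, b.pixels) if px in sa)


def _centroid_dist(a: CandidateBlob, b: CandidateBlob, n_alines: int) -> float:
    da = abs(a.centroid[0] - b.centroid[0])
    da = min(da, n_alines - da)
    return float(np.hypot(da, a.centroid[1] - b.centroid[1]))


def link_blobs(per_frame_blobs: Sequence[Sequence[CandidateBlob]], n_alines: int) -> list[MicrovesselTrack]:
    """Greedy frame-to-frame linking by pixel-set overlap.

    Blobs in consecutive frames join one track iff they share at least one
    (A-line, depth) pixel; each blob joins at most one track, ties broken by
    largest overlap then smallest centroid distance (circular θ).
    """
    open_tracks: list[list[tuple[int, CandidateBlob]]] = []
    done: list[list[tuple[int, CandidateBlob]]] = []
    for f, blobs in enumerate(per_frame_blobs):
        active = [t for t in open_tracks if t[-1][0] == f - 1]
        stale = [t for t in open_tracks if t[-1][0] < f - 1]
        done.extend(stale)
        candidates = []
        for ti, t in enumerate(active):
            prev_blob = t[-1][1]
            for bi, b in enumerate(blobs):
                ov = _overlap(prev_blob, b)
                if ov >= 1:
                    candidates.append((-ov, _centroid_dist(prev_blob, b, n_alines), ti, bi))
        candidates.sort()
        used_t: set[int] = set()
        used_b: set[int] = set()
        for _, _, ti, bi in candidates:
            if ti in used_t or bi in used_b:
                continue
            active[ti].append((f, blobs[bi]))
            used_t.add(ti)
            used_b.add(bi)
        stale_ids = {id(t) for t in stale}
        open_tracks = [t for t in open_tracks if id(t) not in stale_ids]
        for bi, b in enumerate(blobs):
            if bi not in used_b:
                open_tracks.append([(f, b)])
    done.extend(open_tracks)
    tracks = [MicrovesselTrack(members=t) for t in done]
    tracks.sort(key=lambda t: (t.members[0][0], t.members[0][1].centroid))
    return tracks


def apply_definition(track: MicrovesselTrack, min_frames: int = 3) -> tuple[bool, str | None]:
    """Keep/reject under the consensus microvessel definition.

    Rejects tracks spanning fewer than ``min_frames`` consecutive frames
    ("too short") and tracks containing a pixel at shifted depth 0–1, i.e.
    touching the lumen boundary ("lumen-connected").  The persistence
    threshold is configurable since "more than three continuous frames" can
    be read as either ≥3 or ≥4.
    """
    if track.n_frames < min_frames:
        track.kept, track.reject_reason = False, "too short"
    elif track.lumen_connected:
        track.kept, track.reject_reason = False, "lumen-connected"
    else:
        track.kept, track.reject_reason = True, None
    return track.kept, track.reject_reason


def quantify(track: MicrovesselTrack, radial_px_um: float, frame_pitch_mm: float) -> tuple[float, float]:
    """Length (mm) and mean equivalent-circle diameter (µm) of a kept track.

    Length = n_frames × frame pitch; per-frame diameter = 2·√(area/π) ×
    radial pixel size, averaged over member frames.
    """
    if radial_px_um is None or frame_pitch_mm is None:
        raise ValueError("missing metadata: radial_px_um and frame_pitch_mm required")
    length = track.n_frames * frame_pitch_mm
    diam = float(np.mean([2.0 * np.sqrt(blob.area_px / np.pi) * radial_px_um
                          for _, blob in track.members]))
    track.length_mm, track.mean_diameter_um = length, diam
    return length, diam


def track_table(tracks: Sequence[MicrovesselTrack]) -> list[dict]:
    """Flat per-track summary rows for CSV export."""
    rows = []
    for ti, t in enumerate(tracks):
        rows.append({
            "track_id": ti,
            "frame_start": t.frame_range[0],
            "frame_stop": t.frame_range[1],
            "n_frames": t.n_frames,
            "length_mm": t.length_mm,
            "mean_diameter_um": t.mean_diameter_um,
            "kept": t.kept,
            "reason": t.reject_reason,
        })
    return rows
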