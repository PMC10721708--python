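"""Overlap-based multi-object tracking and fixed-size clip extraction.

Regions in consecutive frames are paired by largest shared pixel area;
chains of pairings form per-cell tracks, and each track is rendered as a
50 x 50 px video clip cut from the raw frames around the cell centroid,
zero-padded where the window leaves the frame. Cells are sparse (about
2 cells/s), so a greedy descending-overlap assignment with a deterministic
tie-break suffices; there is no occlusion reasoning or motion model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import CellRegion
from .synthetic import FrameSequence

__all__ = [
    "CellTrack",
    "CellClip",
    "match_regions",
    "build_tracks",
    "extract_clip",
    "standardize_clip_length",
    "extract_clips",
]

#: Tracks shorter than this many frames are dropped (the classifier's slow
#: pathway needs at least tau frames).
DEFAULT_MIN_TRACK_LEN = 8
#: Spatial clip size in px.
DEFAULT_CLIP_SIZE = 50
#: Clips are standardized to this many frames for batching.
DEFAULT_CLIP_FRAMES = 64


@dataclass
class CellTrack:
    """A chain of matched regions across consecutive frames."""

    track_id: int
    regions: list[tuple[int, CellRegion]]   # (frame_index, region), step 1
    donor_id: str | None = None
    class_label: str | None = None

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def frame_indices(self) -> list[int]:
        return [fi for fi, _ in self.regions]


@dataclass
class CellClip:
    """Fixed-size video crop of one tracked cell."""

    pixels: np.ndarray        # (T, size, size) uint8
    track_id: int
    donor_id: str | None = None
    class_label: str | None = None

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


def _overlap(a: CellRegion, b: CellRegion) -> int:
    """Shared pixel area of two regions (exact pixel-set intersection)."""
    # quick bbox rejection
    if (a.bbox[2] <= b.bbox[0] or b.bbox[2] <= a.bbox[0]
            or a.bbox[3] <= b.bbox[1] or b.bbox[3] <= a.bbox[1]):
        return 0
    return len(a.pixel_set() & b.pixel_set())


def match_regions(prev: list[CellRegion], next: list[CellRegion]) -> dict:
    """Pair each previous-frame region with the next-frame region sharing
    the largest pixel area.

    Assignment is greedy in descending overlap so no next region is claimed
    twice; a region whose every overlap is zero is left unmatched. Ties in
    overlap are broken toward the next-frame region with the smaller
    (min_row, min_col) bounding-box corner, then toward the earlier previous
    region, which makes the pairing deterministic.

    Returns a dict mapping prev index -> next index.
    """
    candidates = []
    for i, a in enumerate(prev):
        for j, b in enumerate(next):
            ov = _overlap(a, b)
            if ov > 0:
                candidates.append((-ov, b.bbox[0], b.bbox[1], i, j))
    candidates.sort()
    pairing: dict[int, int] = {}
    taken: set[int] = set()
    for _, _, _, i, j in candidates:
        if i in pairing or j in taken:
            continue
        pairing[i] = j
        taken.add(j)
    return pairing


def build_tracks(
    frames_regions: list[list[CellRegion]],
    min_track_len: int = DEFAULT_MIN_TRACK_LEN,
    donor_id: str | None = None,
    class_label: str | None = None,
) -> list[CellTrack]:
    """Chain per-frame regions into tracks by consecutive-frame matching.

    A region with no match in the next frame ends its track; an unmatched
    next-frame region starts a new one. Tracks span strictly consecutive
    frames. Tracks shorter than ``min_track_len`` frames are dropped.
    """
    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}   # prev-frame region index -> track
    next_id = 0
    for fi, regions in enumerate(frames_regions):
        prev_regions = ([] if fi == 0 else frames_regions[fi - 1])
        pairing = match_regions(prev_regions, regions) if active else {}
        new_active: dict[int, CellTrack] = {}
        matched_next = set()
        for pi, track in active.items():
            j = pairing.get(pi)
            if j is not None:
                track.regions.append((fi, regions[j]))
                new_active[j] = track
                matched_next.add(j)
        for j, region in enumerate(regions):
            if j in matched_next:
                continue
            track = CellTrack(track_id=next_id, regions=[(fi, region)],
                              donor_id=donor_id, class_label=class_label)
            next_id += 1
            tracks.append(track)
            new_active[j] = track
        active = new_active
    return [t for t in tracks if len(t) >= min_track_len]


def extract_clip(
    track: CellTrack,
    seq: FrameSequence,
    size: int = DEFAULT_CLIP_SIZE,
) -> CellClip:
    """Cut a ``size x size`` window around the cell centroid in every track
    frame of the original (unsmoothed) video, zero-filling outside the frame.

    The window origin is the region centroid rounded to the nearest pixel,
    so for a 50 px window the crop extends 25 px to each side of the cell
    centre.
    """
    if len(track) == 0:
        raise ValueError("cannot extract a clip from an empty track")
    H, W = seq.shape
    half = size // 2
    out = np.zeros((len(track), size, size), dtype=np.uint8)
    for k, (fi, region) in enumerate(track.regions):
        r0 = int(round(region.centroid[0])) - half
        c0 = int(round(region.centroid[1])) - half
        rs, re = max(r0, 0), min(r0 + size, H)
        cs, ce = max(c0, 0), min(c0 + size, W)
        if rs < re and cs < ce:
            out[k, rs - r0:re - r0, cs - c0:ce - c0] = seq[fi][rs:re, cs:ce]
    return CellClip(pixels=out, track_id=track.track_id,
                    donor_id=track.donor_id, class_label=track.class_label)


def standardize_clip_length(clip: CellClip,
                            n_frames: int = DEFAULT_CLIP_FRAMES) -> CellClip:
    """Resample or pad a clip to a fixed temporal length.

    Longer clips are uniformly resampled (nearest frame); shorter clips are
    padded by replicating the last frame. A fixed length divisible by the
    slow-pathway stride is required for batched classification.
    """
    T = clip.pixels.shape[0]
    if T == n_frames:
        pixels = clip.pixels
    elif T > n_frames:
        idx = np.round(np.linspace(0, T - 1, n_frames)).astype(int)
        pixels = clip.pixels[idx]
    else:
        pad = np.repeat(clip.pixels[-1:], n_frames - T, axis=0)
        pixels = np.concatenate([clip.pixels, pad], axis=0)
    return CellClip(pixels=pixels, track_id=clip.track_id,
                    donor_id=clip.donor_id, class_label=clip.class_label)


def extract_clips(
    tracks: list[CellTrack],
    seq: FrameSequence,
    size: int = DEFAULT_CLIP_SIZE,
    n_frames: int | None = DEFAULT_CLIP_FRAMES,
) -> list[CellClip]:
    """Extract one standardized clip per track."""
    clips = [extract_clip(t, seq, size=size) for t in tracks]
    if n_frames is not None:
        clips = [standardize_clip_length(c, n_frames) for c in clips]
    return clips
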