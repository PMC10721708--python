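"""Per-frame cell detection by temporal-median background subtraction.

The channel and background are temporally invariant, so a per-pixel median
over randomly sampled frames leaves only the static scenery: subtracting it
from each (Gaussian-smoothed) frame isolates moving cells. Pixels whose
absolute difference exceeds the threshold (default 5 intensity units,
strict) are foreground; connected foreground components with pixel area
strictly greater than 50 are reported as cell regions.

Coordinates are (row, col), 0-based; bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters, measure

from .synthetic import FrameSequence

__all__ = [
    "MedianBackground",
    "CellRegion",
    "estimate_background",
    "binarize",
    "detect_regions",
    "detect_sequence",
    "read_video",
]

#: Foreground threshold on |smoothed frame - background|, strict inequality.
DEFAULT_THRESHOLD = 5.0
#: Regions must have pixel area strictly greater than this to count as a cell.
DEFAULT_MIN_AREA = 50
#: Gaussian smoothing sigma in px applied to frames and median samples.
DEFAULT_SIGMA = 1.0
#: Number of frames sampled for the median background.
DEFAULT_N_SAMPLES = 100


@dataclass
class MedianBackground:
    """Per-pixel median of smoothed, randomly sampled frames."""

    background: np.ndarray      # float, same shape as frames
    n_sampled: int
    sample_indices: np.ndarray  # frame indices used
    sigma: float


@dataclass
class CellRegion:
    """One connected foreground component in one frame."""

    frame_index: int
    coords: np.ndarray                              # (n_px, 2) of (row, col)
    centroid: tuple[float, float]                   # (row, col)
    bbox: tuple[int, int, int, int]                 # half-open (r0, c0, r1, c1)

    @property
    def area(self) -> int:
        return len(self.coords)

    def pixel_set(self) -> set:
        return {(int(r), int(c)) for r, c in self.coords}


def _smooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    img = frame.astype(float)
    if sigma > 0:
        img = filters.gaussian(img, sigma=sigma, preserve_range=True)
    return img


def estimate_background(
    seq: FrameSequence,
    n: int = DEFAULT_N_SAMPLES,
    seed: int | np.random.Generator = 0,
    sigma: float = DEFAULT_SIGMA,
) -> MedianBackground:
    """Median background from ``min(n, len(seq))`` random frames.

    Frames are sampled uniformly without replacement, each Gaussian-smoothed
    first, then reduced to a per-pixel median. With cells present in fewer
    than half the sampled frames at any pixel, the median recovers the
    static background there.
    """
    if len(seq) == 0:
        raise ValueError("cannot estimate a background from an empty sequence")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_sampled = min(n, len(seq))
    idx = np.sort(rng.choice(len(seq), size=n_sampled, replace=False))
    stack = np.stack([_smooth(seq[i], sigma) for i in idx])
    return MedianBackground(
        background=np.median(stack, axis=0),
        n_sampled=n_sampled,
        sample_indices=idx,
        sigma=sigma,
    )


def binarize(
    frame: np.ndarray,
    background: MedianBackground,
    threshold: float = DEFAULT_THRESHOLD,
    sigma: float | None = None,
) -> np.ndarray:
    """Foreground mask: |smoothed(frame) - background| > threshold (strict).

    The absolute value makes the mask symmetric in contrast sign: cells
    darker or brighter than the background by the same margin binarize
    identically.
    """
    if frame.shape != background.background.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match background "
            f"{background.background.shape}")
    s = background.sigma if sigma is None else sigma
    diff = _smooth(frame, s) - background.background
    return np.abs(diff) > threshold


def detect_regions(
    mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    frame_index: int = 0,
) -> list[CellRegion]:
    """Connected components of a binary mask with area strictly > min_area.

    ``connectivity`` is 4 or 8 (pixel neighbourhood). Regions are returned
    sorted by (min_col, min_row) of their bounding boxes, so the output is
    independent of labelling order.
    """
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area <= min_area:
            continue
        regions.append(CellRegion(
            frame_index=frame_index,
            coords=rp.coords.copy(),
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            bbox=tuple(int(v) for v in rp.bbox),
        ))
    regions.sort(key=lambda r: (r.bbox[1], r.bbox[0]))
    return regions


def detect_sequence(
    seq: FrameSequence,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    sigma: float = DEFAULT_SIGMA,
    connectivity: int = 8,
    n_background_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    background: MedianBackground | None = None,
) -> list[list[CellRegion]]:
    """Detect cell regions in every frame of a sequence.

    Returns one region list per frame (possibly empty)."""
    if background is None:
        background = estimate_background(
            seq, n=n_background_samples, seed=seed, sigma=sigma)
    out = []
    for fi in range(len(seq)):
        mask = binarize(seq[fi], background, threshold=threshold, sigma=sigma)
        out.append(detect_regions(mask, min_area=min_area,
                                  connectivity=connectivity, frame_index=fi))
    return out


def regions_to_table(frames_regions) -> pd.DataFrame:
    """Flatten per-frame region lists into a tidy table."""
    rows = []
    for regions in frames_regions:
        for r in regions:
            rows.append((r.frame_index, r.area, r.centroid[0], r.centroid[1],
                         *r.bbox))
    return pd.DataFrame(rows, columns=[
        "frame", "area", "centroid_row", "centroid_col",
        "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col"])


def read_video(path: str | Path, donor_id: str | None = None,
               frame_rate: float = 500.0) -> FrameSequence:
    """Read a multi-page TIFF (or AVI, where an ffmpeg-capable imageio
    plugin is installed) into a FrameSequence."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
        if frames.ndim == 4:  # RGB -> grayscale
            frames = frames[..., 0]
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameSequence(frames=frames.astype(np.uint8),
                         donor_id=donor_id or path.stem,
                         frame_rate=frame_rate)
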