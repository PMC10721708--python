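"""Synthetic microfluidic deformation videos with planted ground truth.

Emulates bright-field high-speed recordings of red blood cells flowing
left-to-right through a shallow microfluidic channel with a central
constriction: a static channel background with Gaussian sensor noise, cells
arriving with exponential inter-arrival times, translating at constant
speed, elongating along the flow axis while inside the constriction and
relaxing exponentially afterwards.

Two cell classes are modelled. Fetal red blood cells have a 21% larger mean
volume than adult ones, implemented as a projected-area ratio of
1.21**(2/3) ≈ 1.136 under isotropic scaling, and are more deformable
(larger elongation in the constriction). Donor-level variation is a
log-normal multiplicative perturbation of area and deformation amplitude
drawn once per donor, which creates the within-donor correlation that
donor-disjoint evaluation exists to guard against.

No fluid dynamics or optics are simulated: cells are anti-aliased ellipses
of signed contrast on a constant background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import FETAL_AREA_RATIO

__all__ = [
    "SceneParams",
    "ClassParams",
    "DonorSpec",
    "CellTruth",
    "GroundTruth",
    "FrameSequence",
    "default_class_params",
    "generate_donor_video",
    "generate_cohort",
    "build_manifest",
]


@dataclass(frozen=True)
class SceneParams:
    """Geometry and imaging parameters of one recording.

    Defaults follow the instrument this generator emulates: 8-bit grayscale
    frames of 800 x 150 px at a nominal 500 fps, with cells arriving at
    about 2 cells/s. ``wall_rows`` is the thickness of each static channel
    wall; in the constriction (a centred stretch of the channel) the walls
    extend a further ``constriction_extra`` rows inward.
    """

    frame_height: int = 150
    frame_width: int = 800
    bit_depth: int = 8
    frame_rate: float = 500.0
    cells_per_s: float = 2.0
    wall_rows: int = 25
    constriction_extra: int = 30
    constriction_center: float = 0.5   # fraction of frame width
    constriction_length: float = 0.15  # fraction of frame width
    background_level: float = 180.0
    wall_contrast: float = -60.0
    noise_sd: float = 2.0
    min_frames: int = 50

    def __post_init__(self):
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit frames are supported")
        if 2 * (self.wall_rows + self.constriction_extra) >= self.frame_height:
            raise ValueError("constriction closes the channel completely")

    @property
    def open_rows(self) -> int:
        """Channel height in px between the walls, outside the constriction."""
        return self.frame_height - 2 * self.wall_rows

    @property
    def constriction_span(self) -> tuple[int, int]:
        """Half-open column interval [x0, x1) of the constriction."""
        half = 0.5 * self.constriction_length * self.frame_width
        c = self.constriction_center * self.frame_width
        return int(round(c - half)), int(round(c + half))

    def render_background(self) -> np.ndarray:
        """Noise-free static background (walls + channel), float64."""
        bg = np.full((self.frame_height, self.frame_width),
                     self.background_level, dtype=float)
        x0, x1 = self.constriction_span
        thick = np.full(self.frame_width, self.wall_rows, dtype=int)
        thick[x0:x1] += self.constriction_extra
        for x in range(self.frame_width):
            t = thick[x]
            bg[:t, x] += self.wall_contrast
            bg[self.frame_height - t:, x] += self.wall_contrast
        return bg


@dataclass(frozen=True)
class ClassParams:
    """Per-class cell appearance and dynamics.

    ``projected_area_mean`` is the mean 2-D projected area in px²;
    ``deformation_amplitude`` is the elongation factor of the flow-axis
    semi-axis while the cell is inside the constriction (the cross-flow
    axis shrinks by the same factor, so projected area is conserved);
    ``deformation_relaxation`` is the exponential relaxation time constant
    in frames after the cell leaves the constriction. ``contrast`` is
    signed: cells may be darker or brighter than the background.
    """

    projected_area_mean: float = 180.0
    projected_area_cv: float = 0.08
    deformation_amplitude: float = 1.25
    deformation_relaxation: float = 10.0
    contrast: float = -40.0
    speed_px_per_frame: float = 6.0
    edge_softness: float = 0.8

    def __post_init__(self):
        if self.projected_area_mean <= 50:
            raise ValueError(
                "projected_area_mean must exceed the 50 px² detection floor")
        if self.deformation_amplitude < 1:
            raise ValueError("deformation_amplitude must be >= 1")
        if self.speed_px_per_frame <= 0:
            raise ValueError("speed_px_per_frame must be positive")


def default_class_params(class_label: str) -> ClassParams:
    """Default appearance for ``'adult'`` and ``'fetal'`` cells.

    Fetal cells are larger by the configured area ratio (1.21**(2/3) by
    default) and deform more in the constriction, reflecting their smaller
    extensional and bending moduli.
    """
    adult = ClassParams()
    if class_label == "adult":
        return adult
    if class_label == "fetal":
        return replace(
            adult,
            projected_area_mean=adult.projected_area_mean * FETAL_AREA_RATIO,
            deformation_amplitude=1.75,
        )
    raise ValueError(f"unknown class label {class_label!r}")


@dataclass(frozen=True)
class DonorSpec:
    """One donor recording: identity, class, cell count and seed.

    ``donor_effect_sd`` is the standard deviation of the log-normal
    multiplicative perturbation applied once per donor to the class mean
    area and deformation amplitude.
    """

    donor_id: str
    class_label: str
    n_cells: int
    donor_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.class_label not in ("fetal", "adult"):
            raise ValueError(f"unknown class label {self.class_label!r}")


@dataclass
class CellTruth:
    """Planted per-cell metadata."""

    cell_id: int
    class_label: str
    entry_frame: int
    exit_frame: int  # last frame index in which the cell is visible
    target_area: float


@dataclass
class FrameObservation:
    """One rendered cell instance in one frame."""

    cell_id: int
    centroid: tuple[float, float]      # (row, col)
    coords: np.ndarray                 # (n_px, 2) int array of (row, col)

    @property
    def area(self) -> int:
        return len(self.coords)


@dataclass
class GroundTruth:
    """Planted truth for one donor video: per-frame masks, per-cell labels."""

    donor_id: str
    cells: dict = field(default_factory=dict)       # cell_id -> CellTruth
    frames: dict = field(default_factory=dict)      # frame -> [FrameObservation]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def observations(self, frame_index: int) -> list:
        return self.frames.get(frame_index, [])

    def to_jsonable(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "cells": {
                str(cid): {k: v for k, v in asdict(ct).items()}
                for cid, ct in self.cells.items()
            },
            "frames": {
                str(fi): [
                    {
                        "cell_id": ob.cell_id,
                        "centroid": [float(ob.centroid[0]), float(ob.centroid[1])],
                        "area": int(ob.area),
                        "bbox": [int(ob.coords[:, 0].min()), int(ob.coords[:, 1].min()),
                                 int(ob.coords[:, 0].max()) + 1, int(ob.coords[:, 1].max()) + 1],
                    }
                    for ob in obs
                ]
                for fi, obs in self.frames.items()
            },
        }


@dataclass
class FrameSequence:
    """Ordered stack of 8-bit grayscale frames from one donor recording."""

    frames: np.ndarray          # (n_frames, H, W) uint8
    donor_id: str
    frame_rate: float = 500.0

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be uint8")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _ellipse_patch(yc, xc, a, b, softness, shape):
    """Anti-aliased ellipse coverage on a local window.

    Returns (rows slice, cols slice, coverage array in [0,1]). ``a`` is the
    flow-axis (column) semi-axis, ``b`` the cross-flow (row) semi-axis.
    """
    H, W = shape
    margin = 2.0 + softness * 3
    r0 = max(int(np.floor(yc - b - margin)), 0)
    r1 = min(int(np.ceil(yc + b + margin)) + 1, H)
    c0 = max(int(np.floor(xc - a - margin)), 0)
    c1 = min(int(np.ceil(xc + a + margin)) + 1, W)
    if r0 >= r1 or c0 >= c1:
        return None
    rr = np.arange(r0, r1, dtype=float)[:, None]
    cc = np.arange(c0, c1, dtype=float)[None, :]
    rho = np.sqrt(((cc - xc) / a) ** 2 + ((rr - yc) / b) ** 2)
    # radial distance from the boundary in px, using the local radius scale
    radial = (rho - 1.0) * min(a, b)
    if softness > 0:
        cov = np.clip(0.5 - radial / (2 * softness), 0.0, 1.0)
    else:
        cov = (radial <= 0).astype(float)
    return slice(r0, r1), slice(c0, c1), cov


@dataclass
class _Cell:
    cell_id: int
    entry_frame: float
    area: float
    y: float
    amplitude: float
    relaxation: float
    speed: float
    contrast: float
    softness: float

    def state(self, frame_index, scene: SceneParams):
        """(xc, a, b) at a frame, or None if off-screen."""
        r0 = np.sqrt(self.area / np.pi)
        t = frame_index - self.entry_frame
        if t < 0:
            return None
        xc = -r0 * self.amplitude + t * self.speed
        if xc > scene.frame_width + r0 * self.amplitude:
            return None
        x0, x1 = scene.constriction_span
        if xc < x0:
            e = 1.0
        elif xc <= x1:
            e = self.amplitude
        else:
            frames_out = (xc - x1) / self.speed
            e = 1.0 + (self.amplitude - 1.0) * np.exp(
                -frames_out / max(self.relaxation, 1e-9))
        return xc, r0 * e, r0 / e


def generate_donor_video(
    scene: SceneParams,
    donor: DonorSpec,
    class_params: ClassParams | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Render one donor recording and its planted ground truth.

    Cells are spawned with exponential inter-arrival times matching
    ``scene.cells_per_s``, translate left-to-right at constant speed,
    elongate by the (donor-perturbed) deformation amplitude inside the
    constriction and relax exponentially after leaving it. The ground truth
    records, for every frame, each rendered cell's id, centroid and exact
    pixel mask (pixels with coverage >= 0.5).

    Raises ``ValueError`` if the cell diameter cannot fit the open channel.
    """
    params = class_params or default_class_params(donor.class_label)
    rng = np.random.default_rng(donor.seed)

    # donor-level multiplicative perturbation, drawn once
    f_area, f_amp = np.exp(rng.normal(0.0, donor.donor_effect_sd, size=2))
    area_mean = params.projected_area_mean * f_area
    amplitude = max(params.deformation_amplitude * f_amp, 1.0)

    diameter = 2 * np.sqrt(area_mean * (1 + 3 * params.projected_area_cv) / np.pi)
    if diameter >= scene.open_rows:
        raise ValueError(
            f"cell diameter {diameter:.1f} px exceeds the open channel height "
            f"{scene.open_rows} px; shrink projected_area_mean or widen the channel")

    mean_gap = scene.frame_rate / scene.cells_per_s
    gaps = rng.exponential(mean_gap, size=donor.n_cells) if donor.n_cells else []
    entries = np.cumsum(gaps) if donor.n_cells else np.array([])

    cells = []
    half_gap = scene.open_rows / 2.0
    for i in range(donor.n_cells):
        area = -1.0
        while area <= 50.0:
            area = rng.normal(area_mean, params.projected_area_cv * area_mean)
        r0 = np.sqrt(area / np.pi)
        slack = max(half_gap - r0 - 2.0, 0.0)
        y = scene.frame_height / 2.0 + rng.uniform(-slack, slack)
        cells.append(_Cell(
            cell_id=i, entry_frame=float(entries[i]), area=area, y=y,
            amplitude=amplitude, relaxation=params.deformation_relaxation,
            speed=params.speed_px_per_frame, contrast=params.contrast,
            softness=params.edge_softness,
        ))

    crossing = (scene.frame_width + 4 * diameter) / params.speed_px_per_frame
    n_frames = scene.min_frames
    if donor.n_cells:
        n_frames = max(n_frames, int(np.ceil(entries[-1] + crossing)) + 1)

    background = scene.render_background()
    frames = np.empty((n_frames, scene.frame_height, scene.frame_width),
                      dtype=np.uint8)
    truth = GroundTruth(donor_id=donor.donor_id)

    for fi in range(n_frames):
        img = background.copy()
        obs = []
        for cell in cells:
            st = cell.state(fi, scene)
            if st is None:
                continue
            xc, a, b = st
            patch = _ellipse_patch(cell.y, xc, a, b, cell.softness, img.shape)
            if patch is None:
                continue
            rs, cs, cov = patch
            img[rs, cs] += cell.contrast * cov
            inside = cov >= 0.5
            if not inside.any():
                continue
            rr, cc = np.nonzero(inside)
            coords = np.column_stack([rr + rs.start, cc + cs.start])
            centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
            obs.append(FrameObservation(cell.cell_id, centroid, coords))
            ct = truth.cells.get(cell.cell_id)
            if ct is None:
                truth.cells[cell.cell_id] = CellTruth(
                    cell_id=cell.cell_id, class_label=donor.class_label,
                    entry_frame=fi, exit_frame=fi, target_area=cell.area)
            else:
                ct.exit_frame = fi
        if obs:
            truth.frames[fi] = obs
        if scene.noise_sd > 0:
            img += rng.normal(0.0, scene.noise_sd, size=img.shape)
        frames[fi] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, donor_id=donor.donor_id,
                        frame_rate=scene.frame_rate)
    return seq, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _check_unique(donors):
    seen = {}
    for d in donors:
        if d.donor_id in seen and seen[d.donor_id] != d.class_label:
            raise ValueError(f"donor {d.donor_id!r} appears with two class labels")
        if d.donor_id in seen:
            raise ValueError(f"duplicate donor_id {d.donor_id!r}")
        seen[d.donor_id] = d.class_label


def build_manifest(donors) -> pd.DataFrame:
    """Cohort manifest (donor_id, class, n_cells) without rendering video."""
    _check_unique(donors)
    return pd.DataFrame(
        [(d.donor_id, d.class_label, d.n_cells) for d in donors],
        columns=["donor_id", "class_label", "n_cells"],
    )


def generate_cohort(
    donors,
    scene: SceneParams,
    out_dir: str | Path | None = None,
    class_params: dict | None = None,
    render: bool = True,
):
    """Generate one video + ground truth per donor and a cohort manifest.

    Returns ``(manifest, videos)`` where ``videos`` maps donor_id to
    ``(FrameSequence, GroundTruth)`` (empty when ``render=False``). When
    ``out_dir`` is given, videos are written as multi-page TIFF, ground
    truth as JSON, and the manifest as ``manifest.csv`` with file paths.
    """
    manifest = build_manifest(donors)
    videos = {}
    paths = {"video_path": [], "truth_path": []}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if render:
        import tifffile

        for d in donors:
            cp = (class_params or {}).get(d.class_label)
            seq, truth = generate_donor_video(scene, d, cp)
            videos[d.donor_id] = (seq, truth)
            if out is not None:
                vpath = out / f"{d.donor_id}.tiff"
                tpath = out / f"{d.donor_id}.truth.json"
                tifffile.imwrite(vpath, seq.frames)
                tpath.write_text(json.dumps(truth.to_jsonable()))
                paths["video_path"].append(str(vpath))
                paths["truth_path"].append(str(tpath))
    if out is not None and render:
        manifest = manifest.assign(**paths)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, videos
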