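"""Shared fixtures: small synthetic scenes and noise-free donor videos."""

import numpy as np
import pytest

from deformcyte.synthetic import (ClassParams, DonorSpec, SceneParams,
                                  generate_donor_video)


@pytest.fixture(scope="session")
def small_scene():
    """A compact channel scene used throughout the unit tests."""
    return SceneParams(frame_height=80, frame_width=256, wall_rows=12,
                       constriction_extra=16, constriction_length=0.2,
                       cells_per_s=40.0, min_frames=40)


@pytest.fixture(scope="session")
def clean_scene(small_scene):
    """Same scene without sensor noise (exact detection expected)."""
    from dataclasses import replace
    return replace(small_scene, noise_sd=0.0)


@pytest.fixture(scope="session")
def sparse_scene(clean_scene):
    """Noise-free scene with a low arrival rate: cells never co-occur close
    enough to touch, so detection counts can be compared to planted truth."""
    from dataclasses import replace
    return replace(clean_scene, cells_per_s=5.0)


@pytest.fixture(scope="session")
def clean_video(sparse_scene):
    """Noise-free 5-cell adult recording plus its ground truth."""
    donor = DonorSpec("clean1", "adult", 5, donor_effect_sd=0.0, seed=12)
    params = ClassParams(projected_area_cv=0.02)
    seq, gt = generate_donor_video(sparse_scene, donor, params)
    # fixture sanity: planted cells stay pairwise separated
    for obs in gt.frames.values():
        for i, a in enumerate(obs):
            for b in obs[i + 1:]:
                assert abs(a.centroid[1] - b.centroid[1]) > 40
    return seq, gt


def make_mask(shape, blobs):
    """Binary mask with rectangular blobs given as (r0, c0, h, w)."""
    mask = np.zeros(shape, dtype=bool)
    for r0, c0, h, w in blobs:
        mask[r0:r0 + h, c0:c0 + w] = True
    return mask
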