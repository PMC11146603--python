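"""Shared fixtures: synthetic slides and patch-purity helpers.

Everything the suite consumes is generated at test time from seeded
generators; nothing is read from disk except artifacts the tests themselves
write into tmp directories.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphostrat.synthetic import SyntheticSlideSpec, make_slide
from morphostrat.tiling import SlideHandle, extract_patches


@pytest.fixture(scope="session")
def artifact_slide():
    """2048px slide, 60% tissue + 10% pen + 10% glass, scattered strokes."""
    spec = SyntheticSlideSpec(width_px=2048, height_px=2048,
                              tissue_fraction=0.6,
                              artifact_spec=(("pen_mark", 0.1),
                                             ("glass_reflection", 0.1)),
                              seed=7)
    return make_slide(spec)


@pytest.fixture(scope="session")
def compact_artifact_slide():
    """4096px slide with compact single-blob artifacts so that whole
    256x256 working-resolution tiles fall inside one artifact kind."""
    spec = SyntheticSlideSpec(width_px=4096, height_px=4096,
                              tissue_fraction=0.6,
                              artifact_spec=(("pen_mark", 0.08),
                                             ("glass_reflection", 0.08),
                                             ("blank_background", 0.07)),
                              seed=11, shapes_per_artifact=1)
    return make_slide(spec)


def handle_for(slide, slide_id="slide", patient_id="patient"):
    return SlideHandle(slide_id=slide_id, patient_id=patient_id,
                       base_magnification=slide.spec.declared_magnification,
                       _image=slide.image)


def grid_patches_with_purity(slide, kinds):
    """Full-grid patches (no background filter) with per-kind purity.

    Purity of a tile is measured on the base-resolution truth masks over the
    tile's footprint.  Returns a list of (patch, {kind: purity}).
    """
    handle = handle_for(slide)
    factor = {"20X": 2, "40X": 4}[slide.spec.declared_magnification]
    out = []
    for patch in extract_patches(handle, None):
        sl = np.s_[patch.row * factor:(patch.row + 256) * factor,
                   patch.col * factor:(patch.col + 256) * factor]
        purity = {k: float(slide.truth_masks[k][sl].mean())
                  for k in kinds if k in slide.truth_masks}
        out.append((patch, purity))
    return out


def region_patch(slide, kind, rng=None):
    """A 256x256 patch assembled from pixels of one truth region (for
    rule-level checks that need a pure sample of a rendered material)."""
    px = slide.image[slide.truth_masks[kind]]
    if px.shape[0] < 256 * 256:
        raise ValueError(f"region {kind} too small")
    return px[:256 * 256].reshape(256, 256, 3)
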