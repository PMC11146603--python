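"""The three curation rules, their cascade, and stain-deconvolution algebra."""

import numpy as np
import pytest

from conftest import region_patch
from morphostrat.curation import (CurationConfig, curate, hed_to_rgb,
                                  rgb_to_hed, rule1_white_black,
                                  rule2_glass_debris, rule3_pen_marking)
from morphostrat.tiling import Patch


def _uniform(rgb):
    return np.tile(np.array(rgb, dtype=np.uint8), (256, 256, 1))


def _as_patch(pixels, pid="t"):
    return Patch(pixels=pixels, col=0, row=0, slide_id=pid, patient_id=pid)


class TestRule1:
    def test_pure_white_fails(self):
        fails, frac = rule1_white_black(_uniform((255, 255, 255)))
        assert fails and frac == 1.0

    def test_he_pink_passes(self):
        fails, frac = rule1_white_black(_uniform((180, 120, 180)))
        assert not fails and frac == 0.0

    @pytest.mark.parametrize("white_frac,expect_fail", [(0.59, False), (0.61, True)])
    def test_straddles_strict_sixty_percent(self, white_frac, expect_fail):
        px = _uniform((180, 120, 180))
        n_white = int(round(white_frac * 256 * 256))
        flat = px.reshape(-1, 3)
        flat[:n_white] = (255, 255, 255)
        fails, frac = rule1_white_black(flat.reshape(256, 256, 3))
        assert fails == expect_fail
        assert frac == pytest.approx(white_frac, abs=1e-4)

    def test_black_counts_too(self):
        fails, frac = rule1_white_black(_uniform((10, 10, 10)))
        assert fails and frac == 1.0


class TestRule2:
    def test_near_white_fails(self):
        fails, _ = rule2_glass_debris(_uniform((250, 250, 250)))
        assert fails

    def test_saturated_magenta_passes(self):
        fails, frac = rule2_glass_debris(_uniform((205, 25, 185)))
        assert not fails and frac == 0.0

    def test_glass_region_mostly_flagged(self, artifact_slide):
        _, frac = rule2_glass_debris(region_patch(artifact_slide, "glass_reflection"))
        assert frac >= 0.95


class TestRule3:
    def test_pure_white_zero_eosin_passes(self):
        fails, stat = rule3_pen_marking(_uniform((255, 255, 255)))
        assert not fails and stat == 0.0

    def test_synthesized_eosin_patch_fails(self):
        # render a patch directly from the eosin stain vector at high
        # concentration, then check the deconvolution flags it
        conc = np.zeros((256, 256, 3))
        conc[..., 1] = 1.0
        patch = hed_to_rgb(conc)
        fails, stat = rule3_pen_marking(patch)
        assert fails and stat > 0.99

    def test_pen_region_fails(self, artifact_slide):
        fails, _ = rule3_pen_marking(region_patch(artifact_slide, "pen_mark"))
        assert fails

    def test_tissue_region_passes(self, artifact_slide):
        fails, stat = rule3_pen_marking(region_patch(artifact_slide, "tissue"))
        assert not fails and stat < 0.2

    def test_mean_semantics_selectable(self):
        cfg = CurationConfig(rule3_semantics="mean")
        fails, stat = rule3_pen_marking(_uniform((205, 25, 185)), cfg)
        assert fails and stat > 0.9

    def test_singular_stain_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            CurationConfig(stain_matrix=np.ones((3, 3)))


class TestDeconvolutionRoundTrip:
    def test_rgb_hed_rgb_within_one_unit(self, artifact_slide):
        px = region_patch(artifact_slide, "tissue")
        back = hed_to_rgb(rgb_to_hed(px))
        assert np.abs(back.astype(int) - px.astype(int)).max() <= 1


class TestCurate:
    def test_empty_input(self):
        kept, report = curate([])
        assert kept == [] and len(report.table) == 0

    def test_reasons_partition_discards(self, artifact_slide):
        patches = [
            _as_patch(_uniform((250, 250, 250)), "white"),
            _as_patch(region_patch(artifact_slide, "glass_reflection"), "glass"),
            _as_patch(region_patch(artifact_slide, "pen_mark"), "pen"),
            _as_patch(region_patch(artifact_slide, "tissue"), "tissue"),
        ]
        kept, report = curate(patches)
        t = report.table.set_index("patch_id")
        assert t.loc["white:0:0", "reason"] == "white_black"
        assert t.loc["glass:0:0", "reason"] == "glass_debris"
        assert t.loc["pen:0:0", "reason"] == "pen_marking"
        assert t.loc["tissue:0:0", "reason"] == "none"
        assert [p.patch_id for p in kept] == ["tissue:0:0"]
        discards = t[t["decision"] == "discard"]
        assert (discards["reason"] != "none").all()

    def test_rule_order_changes_reasons_not_kept_set(self, artifact_slide):
        """A patch is kept iff no rule fails, independent of rule order."""
        patches = [
            _as_patch(_uniform((250, 250, 250)), "white"),
            _as_patch(region_patch(artifact_slide, "tissue"), "tissue"),
        ]
        _, report = curate(patches)
        cfg = CurationConfig()
        for _, row in report.table.iterrows():
            fails_any = (row.frac_rule1 > cfg.rule1_bad_pixel_fraction
                         or row.frac_rule2 > cfg.rule2_fraction
                         or row.frac_rule3 > cfg.rule3_fraction)
            assert (row.decision == "discard") == fails_any

    def test_threshold_monotonicity(self, artifact_slide):
        """Raising any rule's fraction threshold never increases discards."""
        patches = [_as_patch(region_patch(artifact_slide, kind), kind)
                   for kind in ("tissue", "pen_mark", "glass_reflection")]
        patches.append(_as_patch(_uniform((250, 250, 250)), "white"))
        for axis in ("rule1_bad_pixel_fraction", "rule2_fraction", "rule3_fraction"):
            counts = []
            for t in (0.3, 0.6, 0.9):
                kept, _ = curate(patches, CurationConfig(**{axis: t}))
                counts.append(len(patches) - len(kept))
            assert counts[0] >= counts[1] >= counts[2]
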