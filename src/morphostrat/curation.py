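"""Three-step artifact curation of extracted patches.

Applied in order, short-circuiting on the first failing rule:

1. *white/black* — discard when the fraction of RGB pixels that are nearly
   white (every channel >= ``white_min_channel``) or nearly black (every
   channel <= ``black_max_channel``) exceeds 60%;
2. *glass/debris* — discard when the fraction of HSV pixels with low
   saturation and high value (glass reflections, dust, scanning glare)
   exceeds 90%;
3. *pen marking* — deconvolve the patch into Hematoxylin/Eosin/DAB stain
   concentrations (Ruifrok optical-density unmixing) and discard when the
   fraction of pixels with high normalized eosin signal exceeds 90% —
   pen ink projects far more strongly onto the eosin absorption vector than
   eosin-stained tissue does.

Aggregate fractions (60%/90%/90%) follow the method; the pixel-level cut
points below are calibrated against the synthetic slide generator and are
all exposed in :class:`CurationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.color.colorconv import rgb_from_hed

from .tiling import Patch

__all__ = [
    "CurationConfig",
    "CurationReport",
    "rgb_to_hed",
    "hed_to_rgb",
    "rule1_white_black",
    "rule2_glass_debris",
    "rule3_pen_marking",
    "curate",
]

# Optical-density floor: a zero channel maps to OD -log10(eps).
_OD_EPS = 1e-6

# 99th percentile of the eosin concentration over synthetic tissue patches
# (frozen calibration; see docs/methods.md).  Rule 3 normalizes eosin by this
# reference, so tissue saturates the scale only in its extreme tail while pen
# ink sits far above it.
EOSIN_REFERENCE_MAX = 0.26


@dataclass(frozen=True, eq=False)
class CurationConfig:
    rule1_bad_pixel_fraction: float = 0.6
    white_min_channel: int = 220
    black_max_channel: int = 40
    rule2_fraction: float = 0.9
    low_saturation_max: float = 0.10
    high_value_min: float = 0.82
    rule3_fraction: float = 0.9
    eosin_high_threshold: float = 0.9        # on the normalized [0, 1] scale
    eosin_reference_max: float = EOSIN_REFERENCE_MAX
    rule3_semantics: str = "fraction"        # or "mean"
    stain_matrix: np.ndarray = field(default_factory=lambda: rgb_from_hed.copy())

    def __post_init__(self) -> None:
        for name in ("rule1_bad_pixel_fraction", "rule2_fraction", "rule3_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.rule3_semantics not in ("fraction", "mean"):
            raise ValueError("rule3_semantics must be 'fraction' or 'mean'")
        if abs(np.linalg.det(self.stain_matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")


@dataclass
class CurationReport:
    """Per-patch keep/discard decisions with reason codes and rule fractions."""

    table: pd.DataFrame  # patch_id, decision, reason, frac_rule1..3

    def discard_counts(self) -> dict[str, int]:
        d = self.table[self.table["decision"] == "discard"]
        return d["reason"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _as_float_rgb(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64) / 255.0


def rgb_to_hed(pixels: np.ndarray, stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel H/E/DAB concentrations via optical-density unmixing (unclipped)."""
    m = rgb_from_hed if stain_matrix is None else stain_matrix
    od = -np.log10(np.maximum(_as_float_rgb(pixels), _OD_EPS))
    return od @ np.linalg.inv(m)


def hed_to_rgb(concentrations: np.ndarray,
               stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`rgb_to_hed`; returns uint8 RGB."""
    m = rgb_from_hed if stain_matrix is None else stain_matrix
    od = concentrations @ m
    rgb = np.power(10.0, -od) * 255.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def rule1_white_black(patch: Patch | np.ndarray,
                      cfg: CurationConfig | None = None) -> tuple[bool, float]:
    """(fails, bad-pixel fraction) for the white/black background rule."""
    cfg = cfg or CurationConfig()
    px = patch.pixels if isinstance(patch, Patch) else patch
    white = px.min(axis=-1) >= cfg.white_min_channel
    black = px.max(axis=-1) <= cfg.black_max_channel
    fraction = float((white | black).mean())
    return fraction > cfg.rule1_bad_pixel_fraction, fraction


def rule2_glass_debris(patch: Patch | np.ndarray,
                       cfg: CurationConfig | None = None) -> tuple[bool, float]:
    """(fails, flagged fraction) for low-saturation / high-value pixels."""
    cfg = cfg or CurationConfig()
    px = patch.pixels if isinstance(patch, Patch) else patch
    hsv = rgb2hsv(_as_float_rgb(px))
    flagged = (hsv[..., 1] <= cfg.low_saturation_max) & (hsv[..., 2] >= cfg.high_value_min)
    fraction = float(flagged.mean())
    return fraction > cfg.rule2_fraction, fraction


def rule3_pen_marking(patch: Patch | np.ndarray,
                      cfg: CurationConfig | None = None) -> tuple[bool, float]:
    """(fails, statistic) for the eosin-channel pen-marking rule.

    With ``fraction`` semantics (default) the statistic is the fraction of
    pixels whose normalized eosin concentration reaches
    ``eosin_high_threshold``; with ``mean`` semantics it is the mean
    normalized eosin, compared against the same ``rule3_fraction`` cut.
    """
    cfg = cfg or CurationConfig()
    px = patch.pixels if isinstance(patch, Patch) else patch
    eosin = rgb_to_hed(px, cfg.stain_matrix)[..., 1]
    norm = np.clip(eosin / cfg.eosin_reference_max, 0.0, 1.0)
    if cfg.rule3_semantics == "fraction":
        stat = float((norm >= cfg.eosin_high_threshold).mean())
    else:
        stat = float(norm.mean())
    return stat > cfg.rule3_fraction, stat


_RULES = (
    ("white_black", rule1_white_black),
    ("glass_debris", rule2_glass_debris),
    ("pen_marking", rule3_pen_marking),
)


def curate(patches: Iterable[Patch],
           cfg: CurationConfig | None = None) -> tuple[list[Patch], CurationReport]:
    """Apply rules 1→2→3 to each patch; keep survivors, report everything.

    The reported reason is the first failing rule; all three fractions are
    measured regardless so thresholds can be re-examined offline.
    """
    cfg = cfg or CurationConfig()
    kept: list[Patch] = []
    rows = []
    for patch in patches:
        fracs = []
        reason = "none"
        for name, fn in _RULES:
            fails, frac = fn(patch, cfg)
            fracs.append(frac)
            if fails and reason == "none":
                reason = name
        decision = "keep" if reason == "none" else "discard"
        if decision == "keep":
            kept.append(patch)
        rows.append((patch.patch_id, decision, reason, *fracs))
    table = pd.DataFrame(rows, columns=["patch_id", "decision", "reason",
                                        "frac_rule1", "frac_rule2", "frac_rule3"])
    return kept, CurationReport(table=table)
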