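"""Synthetic data generators for every input the pipeline consumes.

Real inputs to the method are gigapixel H&E whole-slide scans plus a clinical
table of overall survival.  Neither can ship with a test suite, so this module
fabricates structurally faithful stand-ins with known ground truth:

* :func:`make_slide` — an H&E-like RGB raster with planted artifacts (pen
  marks, glass reflections, black lines, blank background) and per-kind truth
  masks that partition the image;
* :func:`make_mixture_cohort` — patch-level feature matrices drawn from a
  K-component Gaussian mixture with a single interpretable separation knob,
  standing in for encoder output;
* :func:`make_profile_cohort` — per-patient cluster-proportion vectors drawn
  from class-conditional Dirichlet distributions;
* :func:`make_clinical_table` — survival tables with a controllable
  overall-survival distribution.

All generators are bit-reproducible for a fixed seed and spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ARTIFACT_KINDS",
    "SyntheticSlideSpec",
    "SyntheticSlide",
    "MixtureCohortSpec",
    "ProfileCohortSpec",
    "ClinicalTableSpec",
    "make_slide",
    "make_mixture_cohort",
    "make_profile_cohort",
    "make_clinical_table",
    "write_slide",
]

ARTIFACT_KINDS = ("pen_mark", "glass_reflection", "black_line", "blank_background")

# Base colors (RGB, uint8 scale) of each rendered region.  Chosen so that each
# region lands on the intended side of the curation rules with a clean margin:
# tissue is a pink/purple H&E blend (high saturation, mid value), background is
# near-white, pen ink is a saturated magenta far from any realistic tissue hue
# but strongly aligned with the eosin absorption vector, glass reflections are
# bright but tinted gray (low saturation, high value, min channel < 220), and
# black lines are near-zero in every channel.
_TISSUE_PINK = np.array([195.0, 130.0, 185.0])
_TISSUE_PURPLE = np.array([150.0, 95.0, 165.0])
_BACKGROUND = np.array([248.0, 248.0, 248.0])
_PEN_MAGENTA = np.array([205.0, 25.0, 185.0])
_GLASS_GRAY = np.array([220.0, 214.0, 204.0])
_BLACK_LINE = np.array([15.0, 15.0, 15.0])


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    ``artifact_spec`` lists ``(kind, area_fraction)`` pairs; the artifact area
    fractions plus ``tissue_fraction`` must not exceed 1.  ``shapes_per_artifact``
    controls how concentrated each artifact's pixel budget is: 1 yields a single
    compact blob (guaranteeing fully-artifactual tiles on large slides), larger
    values scatter the same area over several smaller strokes.
    """

    width_px: int
    height_px: int
    declared_magnification: str = "20X"
    tissue_fraction: float = 0.6
    artifact_spec: Sequence[tuple[str, float]] = ()
    seed: int = 0
    shapes_per_artifact: int = 3

    def __post_init__(self) -> None:
        if self.width_px < 512 or self.height_px < 512:
            raise ValueError("slide must be at least 512x512 pixels")
        if self.declared_magnification not in ("20X", "40X"):
            raise ValueError("declared_magnification must be '20X' or '40X'")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0, 1]")
        total = self.tissue_fraction
        for kind, frac in self.artifact_spec:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")
            if frac < 0:
                raise ValueError("artifact area fractions must be non-negative")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"infeasible area budget: tissue + artifacts = {total:.3f} > 1"
            )
        if self.shapes_per_artifact < 1:
            raise ValueError("shapes_per_artifact must be >= 1")


@dataclass
class SyntheticSlide:
    """Rendered slide plus per-kind truth masks.

    Masks are mutually exclusive per pixel and jointly cover the image; keys
    are ``tissue``, ``background`` and any artifact kinds present in the spec.
    """

    image: np.ndarray  # (H, W, 3) uint8
    truth_masks: dict[str, np.ndarray]
    spec: SyntheticSlideSpec

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        total = np.zeros((h, w), dtype=np.int64)
        for m in self.truth_masks.values():
            total += m.astype(np.int64)
        if not (total == 1).all():
            raise AssertionError("truth masks must partition the image")


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, scale: int = 16,
                  sigma: float = 2.0) -> np.ndarray:
    """Low-frequency random field in roughly [0, 1], cheap at any size."""
    h, w = shape
    lo = rng.standard_normal((max(h // scale, 2), max(w // scale, 2)))
    lo = gaussian_filter(lo, sigma)
    field = np.kron(lo, np.ones((scale, scale)))[:h, :w]
    if field.shape != (h, w):  # shape not divisible by scale
        pad_h, pad_w = h - field.shape[0], w - field.shape[1]
        field = np.pad(field, ((0, pad_h), (0, pad_w)), mode="edge")
    lo_v, hi_v = field.min(), field.max()
    return (field - lo_v) / (hi_v - lo_v + 1e-12)


def _paint_blobs(free: np.ndarray, rng: np.random.Generator, budget_px: int,
                 n_shapes: int, elongated: bool = False) -> np.ndarray:
    """Paint ~budget_px pixels of `free` canvas with n_shapes elliptical blobs.

    Returns the painted boolean mask.  Only pixels still free are counted
    toward the budget, so sequential artifact kinds never overlap.
    """
    h, w = free.shape
    painted = np.zeros_like(free)
    remaining = budget_px
    yy, xx = np.mgrid[0:h, 0:w]
    attempts = 0
    while remaining > 50 and attempts < 20 * n_shapes:
        attempts += 1
        target = min(remaining, max(budget_px // n_shapes, 51))
        if elongated:
            a = max(np.sqrt(target / (np.pi * 6.0)), 2.0)  # semi-minor
            b = 6.0 * a
        else:
            b = a = max(np.sqrt(target / np.pi), 2.0)
        theta = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        blob = (u / b) ** 2 + (v / a) ** 2 <= 1.0
        new = blob & free & ~painted
        n_new = int(new.sum())
        if n_new < target // 4:  # mostly off-canvas or already taken; retry
            continue
        painted |= new
        remaining -= n_new
    return painted


def _thin_lines(free: np.ndarray, rng: np.random.Generator, budget_px: int) -> np.ndarray:
    """Full-span straight lines a few pixels thick (scanner 'black line' streaks)."""
    h, w = free.shape
    painted = np.zeros_like(free)
    remaining = budget_px
    yy, xx = np.mgrid[0:h, 0:w]
    attempts = 0
    while remaining > 50 and attempts < 40:
        attempts += 1
        thickness = rng.integers(3, 7)
        theta = rng.uniform(0, np.pi)
        cy, cx = rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)
        dist = np.abs(-(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta))
        line = dist <= thickness / 2.0
        new = line & free & ~painted
        painted |= new
        remaining -= int(new.sum())
    return painted


def make_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    """Render a synthetic H&E-like slide with planted artifacts and truth masks."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    n_px = h * w

    artifact_total = sum(f for _, f in spec.artifact_spec)
    # Artifacts are painted on top of the tissue/background layout, so the
    # tissue region is grown by 1/(1-a) to hit the requested final fraction
    # in expectation after occlusion.
    paint_target = spec.tissue_fraction / (1.0 - artifact_total) if artifact_total < 1 else 0.0
    paint_target = min(paint_target, 1.0)

    if paint_target >= 1.0 - 1e-12:
        tissue = np.ones((h, w), dtype=bool)
    elif paint_target <= 0.0:
        tissue = np.zeros((h, w), dtype=bool)
    else:
        field = _smooth_field((h, w), rng, scale=max(min(h, w) // 64, 8))
        thr = np.quantile(field, 1.0 - paint_target)
        tissue = field > thr

    kind_masks: dict[str, np.ndarray] = {}
    free = np.ones((h, w), dtype=bool)
    for kind, frac in spec.artifact_spec:
        budget = int(round(frac * n_px))
        if budget == 0:
            kind_masks.setdefault(kind, np.zeros((h, w), dtype=bool))
            continue
        if budget >= free.sum():
            painted = free.copy()
        elif kind == "black_line":
            painted = _thin_lines(free, rng, budget)
        elif kind == "pen_mark":
            painted = _paint_blobs(free, rng, budget, spec.shapes_per_artifact,
                                   elongated=spec.shapes_per_artifact > 1)
        else:
            painted = _paint_blobs(free, rng, budget, spec.shapes_per_artifact)
        free &= ~painted
        if kind in kind_masks:
            kind_masks[kind] |= painted
        else:
            kind_masks[kind] = painted

    tissue &= free
    background = free & ~tissue

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = _BACKGROUND
    image += rng.normal(0.0, 2.0, size=image.shape)

    if tissue.any():
        blend = _smooth_field((h, w), rng, scale=max(min(h, w) // 32, 8))[..., None]
        tissue_rgb = _TISSUE_PINK * blend + _TISSUE_PURPLE * (1.0 - blend)
        tissue_rgb = tissue_rgb + rng.normal(0.0, 8.0, size=tissue_rgb.shape)
        image[tissue] = tissue_rgb[tissue]

    renders = {
        "pen_mark": (_PEN_MAGENTA, 6.0),
        "glass_reflection": (_GLASS_GRAY, 2.0),
        "black_line": (_BLACK_LINE, 4.0),
        "blank_background": (_BACKGROUND, 2.0),
    }
    for kind, mask in kind_masks.items():
        base, sigma = renders[kind]
        n = int(mask.sum())
        if n:
            image[mask] = base + rng.normal(0.0, sigma, size=(n, 3))

    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    masks = {"tissue": tissue, "background": background, **kind_masks}
    return SyntheticSlide(image=image, truth_masks=masks, spec=spec)


def write_slide(slide: SyntheticSlide, out_dir: Path | str, slide_id: str) -> Path:
    """Persist a slide as PNG + mask PNGs + a JSON sidecar with the spec/seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{slide_id}.png"
    iio.imwrite(img_path, slide.image)
    for kind, mask in slide.truth_masks.items():
        iio.imwrite(out / f"{slide_id}.mask.{kind}.png",
                    (mask.astype(np.uint8) * 255))
    sidecar = {
        "slide_id": slide_id,
        "declared_magnification": slide.spec.declared_magnification,
        "width_px": slide.spec.width_px,
        "height_px": slide.spec.height_px,
        "tissue_fraction": slide.spec.tissue_fraction,
        "artifact_spec": [list(x) for x in slide.spec.artifact_spec],
        "seed": slide.spec.seed,
    }
    (out / f"{slide_id}.json").write_text(json.dumps(sidecar, indent=2))
    return img_path


# ---------------------------------------------------------------------------
# Feature-space mixture cohorts (test double for encoder output)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureCohortSpec:
    """K-component isotropic Gaussian mixture over patch features.

    ``separation`` is the ratio of the between-center distance to the
    within-cluster (per-direction) standard deviation; centers sit on a
    mutually equidistant frame rotated into general position, so the cluster
    signal spreads across correlated feature columns as encoder features do.
    ``mixing_weights`` is either an explicit (n_patients, k_true) simplex array
    or a scalar Dirichlet concentration from which per-patient weights are
    drawn (small values emulate slides dominated by one morphology).
    """

    n_patients: int
    patches_per_patient: int
    feature_dim: int = 512
    k_true: int = 4
    separation: float = 8.0
    mixing_weights: float | np.ndarray = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.k_true >= 2 and self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.feature_dim < self.k_true:
            raise ValueError(
                "feature_dim < k_true: cannot embed an equidistant center frame"
            )
        if isinstance(self.mixing_weights, np.ndarray):
            wshape = (self.n_patients, self.k_true)
            if self.mixing_weights.shape != wshape:
                raise ValueError(f"mixing_weights must have shape {wshape}")
            if not np.allclose(self.mixing_weights.sum(axis=1), 1.0):
                raise ValueError("per-patient mixing weights must sum to 1")


def _equidistant_centers(k: int, d: int, sep: float, rng: np.random.Generator) -> np.ndarray:
    """k centers in R^d with all pairwise distances == sep, in general position."""
    frame = rng.standard_normal((d, k))
    q, _ = np.linalg.qr(frame)          # orthonormal d x k frame
    return (sep / np.sqrt(2.0)) * q.T   # |q_i - q_j| = sqrt(2)


def make_mixture_cohort(spec: MixtureCohortSpec):
    """Draw (features, true per-patch component labels) for a patch cohort.

    Returns a :class:`morphostrat.encoding.FeatureMatrix` and an int label
    array aligned with its rows.
    """
    from .encoding import FeatureMatrix  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    centers = _equidistant_centers(spec.k_true, spec.feature_dim, spec.separation, rng)

    if isinstance(spec.mixing_weights, np.ndarray):
        weights = spec.mixing_weights
    else:
        alpha = np.full(spec.k_true, float(spec.mixing_weights))
        weights = rng.dirichlet(alpha, size=spec.n_patients)

    rows = []
    labels = []
    for p in range(spec.n_patients):
        lab = rng.choice(spec.k_true, size=spec.patches_per_patient, p=weights[p])
        labels.append(lab)
        for i in range(spec.patches_per_patient):
            rows.append((f"P{p:04d}", f"S{p:04d}", i * 256, 0))
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=int)
    X = centers[labels] + rng.standard_normal((labels.size, spec.feature_dim))
    index = pd.DataFrame(rows, columns=["patient_id", "slide_id", "col", "row"])
    return FeatureMatrix(X=X, index=index), labels


# ---------------------------------------------------------------------------
# Slide-profile cohorts and clinical tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileCohortSpec:
    """Class-conditional Dirichlet generator for cluster-proportion profiles."""

    n_patients: int = 200
    k: int = 7
    dirichlet_short: Sequence[float] = (5.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    dirichlet_long: Sequence[float] = (1.0, 5.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dirichlet_short) != self.k or len(self.dirichlet_long) != self.k:
            raise ValueError("concentration vectors must have length k")
        if min(self.dirichlet_short) <= 0 or min(self.dirichlet_long) <= 0:
            raise ValueError("Dirichlet concentrations must be strictly positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


def make_profile_cohort(spec: ProfileCohortSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-patient proportion vectors and short/long class labels.

    ``class_balance`` is the probability of the *short*-survivor class.
    """
    rng = np.random.default_rng(spec.seed)
    is_short = rng.random(spec.n_patients) < spec.class_balance
    profiles = np.empty((spec.n_patients, spec.k))
    n_short = int(is_short.sum())
    if n_short:
        profiles[is_short] = rng.dirichlet(np.asarray(spec.dirichlet_short, float), n_short)
    if spec.n_patients - n_short:
        profiles[~is_short] = rng.dirichlet(np.asarray(spec.dirichlet_long, float),
                                            spec.n_patients - n_short)
    ids = [f"P{i:04d}" for i in range(spec.n_patients)]
    table = pd.DataFrame(profiles, index=pd.Index(ids, name="patient_id"),
                         columns=[f"cluster_{j}" for j in range(spec.k)])
    labels = pd.Series(np.where(is_short, "short", "long"), index=table.index,
                       name="label")
    return table, labels


@dataclass(frozen=True)
class ClinicalTableSpec:
    """Overall-survival table generator.

    ``os_days_distribution`` is ``(name, params)`` with name in
    {"uniform": (low, high), "lognormal": (mean_log, sigma_log),
    "exponential": (scale,), "point": (value,)}.
    """

    n: int = 100
    os_days_distribution: tuple[str, tuple[float, ...]] = ("uniform", (0.0, 1600.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        name, _ = self.os_days_distribution
        if name not in ("uniform", "lognormal", "exponential", "point"):
            raise ValueError(f"unknown OS distribution {name!r}")


def make_clinical_table(spec: ClinicalTableSpec) -> pd.DataFrame:
    """Draw a (patient_id, os_days) table; os_days is always non-negative."""
    rng = np.random.default_rng(spec.seed)
    name, params = spec.os_days_distribution
    if name == "uniform":
        lo, hi = params
        days = rng.uniform(lo, hi, size=spec.n)
    elif name == "lognormal":
        mu, sigma = params
        days = rng.lognormal(mu, sigma, size=spec.n)
    elif name == "exponential":
        (scale,) = params
        days = rng.exponential(scale, size=spec.n)
    else:  # point mass
        (value,) = params
        days = np.full(spec.n, float(value))
    days = np.maximum(days, 0.0)
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(spec.n)],
        "os_days": days,
    })
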