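"""Feature standardization and PCA projection.

Features are z-scored (mean removed, scaled to unit variance) with statistics
learned on training rows only, then projected onto principal components.  The
component count is either given directly or chosen as the smallest number
whose cumulative explained variance ratio reaches a target.  Component signs
are fixed (largest-magnitude loading positive) so outputs are reproducible
across linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .encoding import FeatureMatrix

__all__ = [
    "Standardizer",
    "PCAModel",
    "ReducedFeatures",
    "fit_standardizer",
    "apply_standardizer",
    "fit_pca",
    "project",
    "VARIANCE_SWEEP_GRID",
]

# Retained-variance targets mirrored by the sensitivity sweep.
VARIANCE_SWEEP_GRID = (0.35, 0.50, 0.60, 0.70, 0.80, 0.85, 0.90)


def _as_array(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(X, FeatureMatrix):
        return X.X, X.index
    return np.asarray(X, dtype=float), None


@dataclass
class Standardizer:
    """Per-column mean/std (population convention) learned on training rows.

    Zero-variance columns get scale 1, so constants map to exactly zero
    instead of failing.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def to_bytes(self) -> bytes:
        return self.mean_.tobytes() + self.scale_.tobytes()


def fit_standardizer(train) -> Standardizer:
    X, _ = _as_array(train)
    if X.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 training rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)          # population (ddof=0) convention
    scale = np.where(std > 0, std, 1.0)
    return Standardizer(mean_=mean, scale_=scale)


def apply_standardizer(std: Standardizer, X):
    arr, index = _as_array(X)
    out = (arr - std.mean_) / std.scale_
    if index is not None:
        return FeatureMatrix(X=out, index=index)
    return out


@dataclass
class PCAModel:
    """Orthonormal loadings with non-increasing explained-variance ratios."""

    components_: np.ndarray              # (n_components, n_features)
    explained_variance_ratio_: np.ndarray
    mean_: np.ndarray
    n_components: int
    retained_variance_target: float | None = None

    def to_bytes(self) -> bytes:
        return self.components_.tobytes() + self.explained_variance_ratio_.tobytes()

    def save(self, prefix: Path | str) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), components=self.components_,
                 ratios=self.explained_variance_ratio_, mean=self.mean_)
        meta = {
            "n_components": self.n_components,
            "retained_variance_target": self.retained_variance_target,
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def fit_pca(X, n_components: int | None = None,
            variance_target: float | None = None) -> PCAModel:
    """Fit PCA on (standardized) training rows.

    Exactly one of ``n_components`` / ``variance_target`` must be given.  With
    a variance target, the chosen component count is the smallest n whose
    cumulative explained variance ratio reaches the target.  Sample (n-1)
    variance convention throughout.
    """
    if (n_components is None) == (variance_target is None):
        raise ValueError("give exactly one of n_components or variance_target")
    arr, _ = _as_array(X)
    if n_components is not None and arr.shape[0] <= n_components:
        raise ValueError("PCA needs more rows than requested components")

    sk = _SkPCA(svd_solver="full")
    sk.fit(arr)
    ratios = sk.explained_variance_ratio_

    if variance_target is not None:
        if variance_target > 1.0:
            raise ValueError("variance target exceeds total representable variance")
        cum = np.cumsum(ratios)
        reachable = cum >= min(variance_target, cum[-1]) - 1e-12
        n_components = int(np.argmax(reachable)) + 1

    comps = sk.components_[:n_components].copy()
    # sign convention: largest-magnitude loading of each component positive
    flip = comps[np.arange(n_components), np.abs(comps).argmax(axis=1)] < 0
    comps[flip] *= -1.0
    return PCAModel(components_=comps,
                    explained_variance_ratio_=ratios[:n_components].copy(),
                    mean_=sk.mean_.copy(), n_components=n_components,
                    retained_variance_target=variance_target)


@dataclass
class ReducedFeatures:
    """PCA scores aligned row-for-row with the source feature matrix."""

    Z: np.ndarray
    index: pd.DataFrame | None = None


def project(model: PCAModel, X) -> ReducedFeatures:
    arr, index = _as_array(X)
    if arr.shape[1] != model.components_.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {arr.shape[1]} columns, "
            f"loadings expect {model.components_.shape[1]}"
        )
    Z = (arr - model.mean_) @ model.components_.T
    return ReducedFeatures(Z=Z, index=index)
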