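"""End-to-end orchestration with manifests and seeded reproducibility.

The pipeline is a sequence of stages — cohort → tile/curate/encode → reduce
→ cluster → select-k → profile → train → evaluate — each reading its
predecessor's on-disk outputs and appending to a JSON run manifest, so a
monolithic :func:`run` and the per-stage CLI verbs share one code path and
produce identical artifacts.

The training and hold-out branches are processed sequentially and
independently: hold-out slides are not opened until every statistic
(standardizer, PCA, K-means, classifier) has been fitted on the
experimentation set.  A single master seed derives per-stage seeds by fixed
offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.tree import DecisionTreeClassifier, export_text

from . import __version__
from .cohort import SurvivalRule, SplitPlan, label_survival, split_cohort
from .clustering import (assign, kmeans_fit, select_k, silhouette_curve,
                         stability_analysis, SilhouetteCurve)
from .curation import CurationConfig, curate
from .encoding import Encoder, EncoderSpec, FeatureMatrix, encode_cohort
from .profiles import DTGrid, build_profiles, evaluate, train_classifier
from .reduction import apply_standardizer, fit_pca, fit_standardizer, project, \
    PCAModel, Standardizer
from .synthetic import (ClinicalTableSpec, SyntheticSlideSpec, make_clinical_table,
                        make_slide, write_slide)
from .tiling import TilingConfig, extract_patches, foreground_mask, open_slide

__all__ = ["PipelineConfig", "RunManifest", "run", "simulate", "STAGES"]

log = logging.getLogger("morphostrat")

SEED_OFFSETS = {"split": 11, "encode": 23, "reduce": 37, "cluster": 41, "train": 53}


@dataclass
class PipelineConfig:
    slides_dir: str
    clinical_csv: str
    output_dir: str
    survival_rule: SurvivalRule = field(default_factory=SurvivalRule)
    test_fraction: float = 0.2
    cv_folds: int = 10
    tiling: TilingConfig = field(default_factory=TilingConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    encoder: EncoderSpec = field(default_factory=lambda: EncoderSpec(
        architecture="tiny", weights="filter_bank"))
    variance_target: float | None = None
    n_components: int | None = 10
    k_grid: tuple = tuple(range(2, 11))
    fixed_k: int | None = None
    n_permutations: int = 0          # >0 adds a stability analysis to `cluster`
    dt_grid: DTGrid = field(default_factory=DTGrid)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("survival_rule", SurvivalRule), ("tiling", TilingConfig),
                         ("curation", CurationConfig), ("encoder", EncoderSpec),
                         ("dt_grid", DTGrid)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed + SEED_OFFSETS[stage]) % (2 ** 31)

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=True).encode()).hexdigest()[:16]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage bookkeeping: hashes, counts, seeds, config snapshot."""

    config_snapshot: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, t0: float, **info) -> None:
        info["wallclock_s"] = round(time.time() - t0, 3)
        self.stages[stage] = info
        log.info("stage %-12s %s", stage,
                 {k: v for k, v in info.items() if k != "wallclock_s"})

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config": self.config_snapshot,
             "stages": self.stages}, indent=2, default=str))

    @classmethod
    def load_or_create(cls, cfg: "PipelineConfig") -> "RunManifest":
        path = cfg.out / "run_manifest.json"
        snap = _config_snapshot(cfg)
        if path.exists():
            raw = json.loads(path.read_text())
            return cls(config_snapshot=raw["config"], version=raw["version"],
                       stages=raw["stages"])
        return cls(config_snapshot=snap)


def _config_snapshot(cfg: PipelineConfig) -> dict:
    snap = asdict(cfg)
    snap["curation"].pop("stain_matrix", None)
    return snap


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifact {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_cohort(cfg: PipelineConfig, manifest: RunManifest) -> None:
    t0 = time.time()
    clinical_path = Path(cfg.clinical_csv)
    if not clinical_path.exists():
        raise FileNotFoundError(f"clinical table not found: {clinical_path}")
    cohort = label_survival(pd.read_csv(clinical_path), cfg.survival_rule)
    plan = SplitPlan(test_fraction=cfg.test_fraction, cv_folds=cfg.cv_folds,
                     seed=cfg.stage_seed("split"))
    split = split_cohort(cohort, plan)
    cfg.out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(cfg.out / "cohort_labels.csv", index=False)
    split.save(cfg.out / "split_manifest.json")
    manifest.record("cohort", t0, counts=cohort.counts(), seed=plan.seed,
                    experimentation=len(split.train), holdout=len(split.holdout),
                    hash=_hash_df(cohort.table))


def _load_split(cfg: PipelineConfig, stage: str):
    raw = json.loads(_require(cfg.out / "split_manifest.json", stage).read_text())
    labels = pd.read_csv(cfg.out / "cohort_labels.csv").set_index("patient_id")["label"]
    folds = pd.Series({k: int(v) for k, v in raw["folds"].items()}, name="fold")
    folds.index.name = "patient_id"
    return raw["experimentation"], raw["holdout"], folds, labels


def stage_extract(cfg: PipelineConfig, manifest: RunManifest,
                  partition: str = "train") -> FeatureMatrix:
    """Tile, curate and encode the slides of one partition."""
    t0 = time.time()
    train_ids, holdout_ids, _, _ = _load_split(cfg, f"extract_{partition}")
    ids = train_ids if partition == "train" else holdout_ids
    encoder = Encoder(cfg.encoder)
    kept_all, reports = [], []
    n_tiles = 0
    for pid in sorted(ids):
        path = Path(cfg.slides_dir) / f"{pid}.png"
        if not path.exists():
            raise FileNotFoundError(f"missing slide image for patient {pid}: {path}")
        slide = open_slide(path, patient_id=pid)
        fmask = foreground_mask(slide, cfg.tiling)
        patches = list(extract_patches(slide, fmask, cfg.tiling))
        kept, report = curate(patches, cfg.curation)
        n_tiles += len(patches)
        kept_all.extend(kept)
        reports.append(report.table)
        log.info("slide %s: %d tiles -> %d curated", pid, len(patches), len(kept))
    features = encode_cohort(kept_all, encoder)
    features.save(cfg.out / f"features_{partition}")
    reports = [r for r in reports if len(r)]
    (pd.concat(reports, ignore_index=True) if reports
     else pd.DataFrame(columns=["patch_id", "decision", "reason"])).to_csv(
        cfg.out / f"curation_report_{partition}.csv", index=False)
    manifest.record(f"extract_{partition}", t0, patients=len(ids), tiles=n_tiles,
                    curated=features.n_patches, hash=_hash_array(features.X))
    return features


def stage_reduce(cfg: PipelineConfig, manifest: RunManifest) -> None:
    t0 = time.time()
    feats = FeatureMatrix.load(_require(cfg.out / "features_train.npy",
                                        "reduce").with_suffix(""))
    std = fit_standardizer(feats.X)
    pca = fit_pca(apply_standardizer(std, feats.X),
                  n_components=cfg.n_components, variance_target=cfg.variance_target)
    np.savez(cfg.out / "standardizer.npz", mean=std.mean_, scale=std.scale_)
    pca.save(cfg.out / "pca")
    Z = project(pca, apply_standardizer(std, feats.X)).Z
    np.save(cfg.out / "reduced_train.npy", Z)
    manifest.record("reduce", t0, n_components=pca.n_components,
                    retained_variance=float(pca.explained_variance_ratio_.sum()),
                    hash=_hash_array(Z))


def _load_reduction(cfg: PipelineConfig, stage: str):
    raw = np.load(_require(cfg.out / "standardizer.npz", stage))
    std = Standardizer(mean_=raw["mean"], scale_=raw["scale"])
    p = np.load(cfg.out / "pca.npz")
    meta = json.loads((cfg.out / "pca.json").read_text())
    pca = PCAModel(components_=p["components"], explained_variance_ratio_=p["ratios"],
                   mean_=p["mean"], n_components=meta["n_components"],
                   retained_variance_target=meta["retained_variance_target"])
    return std, pca


def stage_cluster(cfg: PipelineConfig, manifest: RunManifest) -> None:
    """Silhouette curve over the K grid (plus optional stability analysis)."""
    t0 = time.time()
    Z = np.load(_require(cfg.out / "reduced_train.npy", "cluster"))
    seed = cfg.stage_seed("cluster")
    grid = [k for k in cfg.k_grid if k < Z.shape[0]]
    curve = silhouette_curve(Z, grid, seed=seed)
    curve.to_frame().to_csv(cfg.out / "silhouette_curve.csv", index=False)
    info = {}
    if cfg.n_permutations >= 2:
        stab = stability_analysis(Z, grid, n_permutations=cfg.n_permutations,
                                  base_seed=seed)
        stab.table.to_csv(cfg.out / "stability.csv", index=False)
        info["n_permutations"] = cfg.n_permutations
    manifest.record("cluster", t0, grid=[int(k) for k in grid],
                    scores=[round(float(s), 4) for s in curve.scores], **info)


def stage_select_k(cfg: PipelineConfig, manifest: RunManifest) -> int:
    t0 = time.time()
    tbl = pd.read_csv(_require(cfg.out / "silhouette_curve.csv", "select-k"))
    curve = SilhouetteCurve(grid=tuple(tbl["K"]), scores=tbl["silhouette"].to_numpy())
    if cfg.fixed_k is not None:
        sel_k, method, warning = cfg.fixed_k, "manual_override", False
    else:
        sel = select_k(curve)
        sel_k, method, warning = sel.chosen_k, sel.method, sel.warning
    (cfg.out / "selection.json").write_text(json.dumps(
        {"chosen_k": sel_k, "method": method, "warning": warning}))
    manifest.record("select_k", t0, chosen_k=sel_k, method=method, warning=warning)
    return sel_k


def stage_profile(cfg: PipelineConfig, manifest: RunManifest) -> None:
    """Fit K-means at the chosen K and build experimentation-set profiles."""
    t0 = time.time()
    K = json.loads(_require(cfg.out / "selection.json", "profile").read_text())["chosen_k"]
    Z = np.load(cfg.out / "reduced_train.npy")
    feats = FeatureMatrix.load(cfg.out / "features_train")
    km = kmeans_fit(Z, K, seed=cfg.stage_seed("cluster"), n_init=5)
    np.savez(cfg.out / "kmeans.npz", centroids=km.centroids,
             meta=np.array([km.K, km.seed, km.n_iterations]))
    patch_lab = feats.index[["patient_id", "slide_id"]].copy()
    patch_lab["cluster"] = assign(km, Z)
    prof, rejected = build_profiles(patch_lab, K)
    prof.to_csv(cfg.out / "profiles_train.csv")
    rejected.to_csv(cfg.out / "profiles_rejected.csv", index=False)
    manifest.record("profile", t0, K=K, slides=len(prof), rejected=len(rejected),
                    hash=_hash_df(prof))


def stage_train(cfg: PipelineConfig, manifest: RunManifest) -> None:
    t0 = time.time()
    prof = pd.read_csv(_require(cfg.out / "profiles_train.csv", "train"),
                       index_col="patient_id")
    _, _, folds, labels = _load_split(cfg, "train")
    folds = folds.loc[[p for p in folds.index if p in prof.index]]
    model, params, cv = train_classifier(prof, labels, grid=cfg.dt_grid,
                                         folds=folds, seed=cfg.stage_seed("train"))
    cv.to_csv(cfg.out / "grid_search.csv", index=False)
    (cfg.out / "classifier.json").write_text(json.dumps(
        {"params": params, "seed": cfg.stage_seed("train"),
         "positive_class": "long"}, indent=2))
    (cfg.out / "classifier_rules.txt").write_text(
        export_text(model, feature_names=list(prof.columns)))
    manifest.record("train", t0, **params)


def stage_evaluate(cfg: PipelineConfig, manifest: RunManifest) -> dict:
    """Process the hold-out branch through the fitted artifacts and score it."""
    spec = json.loads(_require(cfg.out / "classifier.json", "evaluate").read_text())
    _, holdout_ids, _, labels = _load_split(cfg, "evaluate")

    # leakage guard: the classifier must not have been trained on hold-out ids
    prof_tr = pd.read_csv(cfg.out / "profiles_train.csv", index_col="patient_id")
    overlap = set(prof_tr.index) & set(holdout_ids)
    if overlap:
        raise ValueError(f"leakage: model trained on hold-out patients {sorted(overlap)}")

    feats_h = stage_extract(cfg, manifest, partition="holdout")
    t0 = time.time()
    std, pca = _load_reduction(cfg, "evaluate")
    km_raw = np.load(cfg.out / "kmeans.npz")
    K = int(km_raw["meta"][0])
    from .clustering import KMeansModel
    km = KMeansModel(K=K, centroids=km_raw["centroids"], inertia=float("nan"),
                     seed=int(km_raw["meta"][1]), n_iterations=int(km_raw["meta"][2]))
    Zh = project(pca, apply_standardizer(std, feats_h.X)).Z
    patch_lab = feats_h.index[["patient_id", "slide_id"]].copy()
    patch_lab["cluster"] = assign(km, Zh)
    prof_h, _ = build_profiles(patch_lab, K)
    prof_h.to_csv(cfg.out / "profiles_holdout.csv")

    # deterministic refit from the recorded configuration
    model = DecisionTreeClassifier(random_state=spec["seed"], **spec["params"])
    model.fit(prof_tr.to_numpy(), labels.loc[prof_tr.index].to_numpy())
    result = evaluate(model, prof_h, labels)
    out = result.to_dict()
    (cfg.out / "eval_result.json").write_text(json.dumps(out, indent=2))
    manifest.record("evaluate", t0, **{k: (round(v, 4) if isinstance(v, float) else v)
                                       for k, v in out.items()})
    return out


STAGES = ("cohort", "extract", "reduce", "cluster", "select-k", "profile",
          "train", "evaluate")


def run(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order; returns the saved manifest.

    Re-running with the same config and inputs reproduces all outputs
    bit-for-bit.
    """
    cfg.out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_snapshot=_config_snapshot(cfg))
    try:
        stage_cohort(cfg, manifest)
        stage_extract(cfg, manifest, "train")
        stage_reduce(cfg, manifest)
        stage_cluster(cfg, manifest)
        stage_select_k(cfg, manifest)
        stage_profile(cfg, manifest)
        stage_train(cfg, manifest)
        stage_evaluate(cfg, manifest)      # opens hold-out slides only here
    except Exception as exc:
        manifest.stages["failure"] = {"error": str(exc)}
        manifest.save(cfg.out / "run_manifest.json")
        raise
    manifest.save(cfg.out / "run_manifest.json")
    return manifest


def simulate(out_dir: Path | str, n_patients: int = 6, slide_px: int = 1024,
             magnification: str = "20X", tissue_fraction: float = 0.85,
             artifact_spec: Sequence[tuple[str, float]] = (("pen_mark", 0.05),),
             os_distribution: tuple[str, tuple[float, ...]] = ("uniform", (0.0, 1600.0)),
             seed: int = 0) -> Path:
    """Write a synthetic cohort (slides + sidecars + clinical CSV) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = make_clinical_table(ClinicalTableSpec(
        n=n_patients, os_days_distribution=os_distribution, seed=seed))
    for i, pid in enumerate(table["patient_id"]):
        spec = SyntheticSlideSpec(width_px=slide_px, height_px=slide_px,
                                  declared_magnification=magnification,
                                  tissue_fraction=tissue_fraction,
                                  artifact_spec=tuple(artifact_spec),
                                  seed=(seed * 100003 + i) % (2 ** 31))
        write_slide(make_slide(spec), out, pid)
    table.to_csv(out / "clinical.csv", index=False)
    return out
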