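"""End-to-end grading pipeline: enhancement -> six feature families ->
min-max fusion -> NMF(k) -> three-classifier majority-vote ensemble.

Feature extraction is a pure per-image computation, so a raw (unscaled)
feature table can be built once and reused; every train-dependent step
(column scaling, NMF basis, classifiers) lives in :class:`FeatureClassifier`
and is refit inside each cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import color as colmod
from . import texture as texmod
from .classify import ensemble_fit, ensemble_predict, ensemble_scores
from .evaluate import MetricsReport, holdout_split, kfold_cv
from .fixtures_io import FeatureTable, LabeledImageSet, ParameterError, RasterImage
from .preprocess import enhance, luminance, select_rois, tile_image
from .reduce import MinMaxScaler, nmf_fit, nmf_transform

FEATURE_FAMILIES = ("glcm", "glrlm", "lbp", "lbglcm_ms", "color", "rshd")


@dataclass
class ExtractionConfig:
    """Per-family parameters with the pipeline defaults."""

    glcm_levels: int = 64
    glrlm_levels: int = 64
    homogeneity: str = "variant"
    glrlm_formulas: str = "variant"
    lbp_set: tuple = texmod.DEFAULT_LBP_SET
    pyramid_levels: int = 3
    color_bins: int = 8
    rshd_shades: int = 64
    clahe_grid: tuple = (8, 8)
    clahe_clip: float = 0.01
    apply_enhancement: bool = True


def extract_image_features(image: RasterImage,
                           families=FEATURE_FAMILIES,
                           config: ExtractionConfig | None = None) -> dict:
    """All requested feature families of one (RGB or gray) tile.

    Color families require RGB input.  Returns an ordered ``name -> value``
    mapping with block-prefixed names.
    """
    cfg = config or ExtractionConfig()
    img = enhance(image, grid=cfg.clahe_grid, clip_limit=cfg.clahe_clip) \
        if cfg.apply_enhancement else image
    gray = luminance(img)
    out = {}
    for fam in families:
        if fam == "glcm":
            feats = texmod.glcm_feature_vector(gray, levels=cfg.glcm_levels,
                                               homogeneity=cfg.homogeneity)
            out.update({f"glcm.{k}": v for k, v in feats.items()})
        elif fam == "glrlm":
            feats = texmod.glrlm_feature_vector(gray, levels=cfg.glrlm_levels,
                                                formulas=cfg.glrlm_formulas)
            out.update({f"glrlm.{k}": v for k, v in feats.items()})
        elif fam == "lbp":
            feats = texmod.lbp_histogram_features(gray, pr_set=cfg.lbp_set)
            out.update({f"lbp.{k}": v for k, v in feats.items()})
            feats = texmod.weighted_lbp_features(gray, pr_set=cfg.lbp_set)
            out.update({f"lbp.{k}": v for k, v in feats.items()})
        elif fam == "lbglcm_ms":
            feats = texmod.multiscale_lbglcm(gray, n_levels=cfg.pyramid_levels,
                                             homogeneity=cfg.homogeneity)
            out.update({f"lbglcm_ms.{k}": v for k, v in feats.items()})
        elif fam == "color":
            out.update(colmod.color_moments(img))
            out.update(colmod.hsv_moments(img))
            out.update(colmod.color_histogram(img, bins=cfg.color_bins))
        elif fam == "rshd":
            out.update(colmod.rshd_features(img, shades=cfg.rshd_shades))
        else:
            raise ParameterError(f"unknown feature family {fam!r}")
    return out


def extract_feature_table(dataset: LabeledImageSet,
                          families=FEATURE_FAMILIES,
                          config: ExtractionConfig | None = None) -> FeatureTable:
    """Raw (unscaled) feature table for a labeled image set.

    Each image is its own parent group; groups carry over to CV so multi-ROI
    parents are never split across folds.
    """
    rows = []
    names = None
    for img in dataset.images:
        feats = extract_image_features(img, families=families, config=config)
        if names is None:
            names = list(feats)
        rows.append([feats[k] for k in names])
    return FeatureTable(np.asarray(rows, dtype=float), names,
                        labels=list(dataset.labels),
                        groups=[f"img{i}" for i in range(len(dataset.images))])


def extract_rois(image: RasterImage, tile_size: int = 512, top_n: int = 5,
                 config: ExtractionConfig | None = None):
    """Enhance a large image, tile it and keep the densest ``top_n`` tiles."""
    cfg = config or ExtractionConfig()
    enhanced = enhance(image, grid=cfg.clahe_grid, clip_limit=cfg.clahe_clip)
    tiles = tile_image(enhanced, tile_size=tile_size, pad=True)
    return select_rois(tiles, top_n=top_n)


# ---------------------------------------------------------------------------
# trainable head: scaling + NMF + ensemble
# ---------------------------------------------------------------------------

@dataclass
class FeatureClassifier:
    """Train-side head of the pipeline (fit on training rows only)."""

    k: int = 32
    seed: int = 0
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-4
    ensemble_config: dict = field(default_factory=dict)
    scaler: MinMaxScaler | None = None
    basis: object | None = None
    ensemble: object | None = None

    def fit(self, table: FeatureTable) -> "FeatureClassifier":
        if table.labels is None:
            raise ParameterError("labeled training table required")
        self.scaler = MinMaxScaler().fit(table.values)
        Xs = self.scaler.transform(table.values)
        self.basis = nmf_fit(Xs, k=self.k, max_iter=self.nmf_max_iter,
                             tol=self.nmf_tol, seed=self.seed)
        self.ensemble = ensemble_fit(self.basis.W, np.asarray(table.labels),
                                     config=self.ensemble_config, seed=self.seed)
        return self

    def _reduce(self, X) -> np.ndarray:
        X = X.values if isinstance(X, FeatureTable) else np.asarray(X, float)
        return nmf_transform(self.basis, self.scaler.transform(X))

    def predict(self, X) -> np.ndarray:
        W = self._reduce(X)
        return np.asarray([p.final_label
                           for p in ensemble_predict(self.ensemble, W)])

    def predict_scores(self, X) -> np.ndarray:
        return ensemble_scores(self.ensemble, self._reduce(X))

    def base_predict(self, name: str, X) -> np.ndarray:
        return np.asarray(self.ensemble.base_models[name].predict(self._reduce(X)))


def run_cv(table: FeatureTable, k_folds: int = 10, nmf_k: int = 32,
           seed: int = 0, **clf_kwargs) -> MetricsReport:
    """Full-pipeline stratified group 10-fold CV on a raw feature table."""
    def factory(train_table):
        return FeatureClassifier(k=nmf_k, seed=seed, **clf_kwargs).fit(train_table)
    return kfold_cv(factory, table, k=k_folds, seed=seed)


def run_cv_detailed(table: FeatureTable, k_folds: int = 10, nmf_k: int = 32,
                    seed: int = 0, **clf_kwargs) -> dict:
    """10-fold CV reporting the ensemble alongside each base classifier.

    All four accuracy figures use the same folds and the same per-fold
    scaling/NMF fits, so the comparison isolates the voting step.
    """
    from sklearn.model_selection import StratifiedGroupKFold

    from .classify import BASE_MODEL_ORDER
    from .evaluate import confusion, metrics

    X = table.values
    y = np.asarray(table.labels)
    groups = np.asarray(table.groups) if table.groups is not None \
        else np.arange(len(y))
    codebook = sorted(np.unique(y).tolist())
    skf = StratifiedGroupKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    preds = {name: np.empty(len(y), dtype=object)
             for name in ("ensemble", *BASE_MODEL_ORDER)}
    fold_of = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y, groups)):
        sub = FeatureTable(X[tr], list(table.column_names),
                           labels=[table.labels[i] for i in tr])
        model = FeatureClassifier(k=nmf_k, seed=seed, **clf_kwargs).fit(sub)
        preds["ensemble"][te] = model.predict(X[te])
        for name in BASE_MODEL_ORDER:
            preds[name][te] = model.base_predict(name, X[te])
        fold_of[te] = f
    out = {"fold_assignments": fold_of.tolist(), "accuracy": {}, "reports": {}}
    for name, p in preds.items():
        rep = metrics(confusion(y, p.astype(y.dtype), codebook))
        out["accuracy"][name] = float(np.mean(p.astype(y.dtype) == y))
        out["reports"][name] = rep
    return out


def run_holdout(table: FeatureTable, test_fraction: float = 0.40,
                nmf_k: int = 32, seed: int = 0, **clf_kwargs):
    """Train on (1 - test_fraction) of the rows, report metrics on the rest."""
    from .evaluate import confusion, metrics

    train, test = holdout_split(table, test_fraction=test_fraction, seed=seed)
    model = FeatureClassifier(k=nmf_k, seed=seed, **clf_kwargs).fit(train)
    pred = model.predict(test.values)
    codebook = sorted(set(train.labels) | set(test.labels))
    report = metrics(confusion(np.asarray(test.labels), pred, codebook))
    return report, model
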