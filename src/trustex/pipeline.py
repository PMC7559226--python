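"""Feature fusion and the classifier harness.

Fusion schemes
--------------
``lbp_then_gmrf`` (default)
    The LBP feature image is computed first, then a GMRF is fitted *to
    the raw LBP code image* treated as a real-valued field — the fused
    vector is the concatenation of the rotation-invariant LBP histogram
    (36 bins for N = 8) with those GMRF parameters (4 theta + nu),
    41 values in total.  The raw (unmapped) code grid is used for the
    GMRF fit because rotation-orbit bins are unordered labels whereas
    raw codes form an ordinary numeric field.
``concat_lbp_gmrf``
    LBP histogram concatenated with GMRF parameters of the (preprocessed)
    intensity image itself.
``concat_all``
    All three blocks: LBP histogram, GMRF of the LBP code image, GMRF of
    the intensity image.

Classifiers
-----------
A uniform contract over four standard classifiers, with the settings
used throughout the evaluation harness: SVM with a Gaussian (RBF)
kernel (gamma = 1/(d * var(X)), C = 1), KNN with k = 5, a decision tree
with minimum leaf size 2 (the C4.5 "confidence factor 0.25" pruning
control has no direct equivalent here; the mapping is echoed in the
fitted params), and a random forest with 500 trees and mtry = 61 capped
at the feature dimension.  Features are standardized with mean/sd
estimated from the training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from trustex.data_io import NEGATIVE, POSITIVE
from trustex.texture_features import (
    FeatureVector,
    gmrf_estimate,
    lbp_code_image,
    lbp_histogram,
)

FUSION_SCHEMES = ("lbp_then_gmrf", "concat_lbp_gmrf", "concat_all")
CLASSIFIER_KINDS = ("svm", "knn", "dt", "rf")


@dataclass(frozen=True)
class FusionConfig:
    scheme: str = "lbp_then_gmrf"
    lbp_n: int = 8
    lbp_r: float = 1.0
    lbp_mapping: str = "ri"
    gmrf_order: int = 2

    def __post_init__(self):
        if self.scheme not in FUSION_SCHEMES:
            raise ValueError(f"unknown fusion scheme {self.scheme!r}; expected {FUSION_SCHEMES}")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected {CLASSIFIER_KINDS}")


def fuse_features(img: np.ndarray, cfg: FusionConfig = FusionConfig()) -> FeatureVector:
    """Fused texture descriptor of one (already preprocessed) patch."""
    hist_codes = lbp_code_image(img, cfg.lbp_n, cfg.lbp_r, cfg.lbp_mapping)
    hist = lbp_histogram(hist_codes)
    blocks = [hist]
    if cfg.scheme in ("lbp_then_gmrf", "concat_all"):
        raw_codes = lbp_code_image(img, cfg.lbp_n, cfg.lbp_r, mapping="raw").codes
        blocks.append(
            gmrf_estimate(raw_codes, order=cfg.gmrf_order).as_feature_vector("gmrf_lbp")
        )
    if cfg.scheme in ("concat_lbp_gmrf", "concat_all"):
        blocks.append(gmrf_estimate(img, order=cfg.gmrf_order).as_feature_vector("gmrf_img"))
    return FeatureVector(
        values=np.concatenate([b.values for b in blocks]),
        schema=[name for b in blocks for name in b.schema],
    )


class FusedTextureFeatures(BaseEstimator, TransformerMixin):
    """Images -> fused feature matrix under a FusionConfig-equivalent setup."""

    def __init__(
        self,
        scheme: str = "lbp_then_gmrf",
        lbp_n: int = 8,
        lbp_r: float = 1.0,
        lbp_mapping: str = "ri",
        gmrf_order: int = 2,
    ):
        self.scheme = scheme
        self.lbp_n = lbp_n
        self.lbp_r = lbp_r
        self.lbp_mapping = lbp_mapping
        self.gmrf_order = gmrf_order

    def _config(self) -> FusionConfig:
        return FusionConfig(
            self.scheme, self.lbp_n, self.lbp_r, self.lbp_mapping, self.gmrf_order
        )

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        cfg = self._config()
        rows = [fuse_features(img, cfg) for img in X]
        self.feature_schema_ = rows[0].schema if rows else ()
        return np.asarray([r.values for r in rows])


def _build_backend(kind: str, params: dict, seed: int, n_features: int):
    p = dict(params)
    if kind == "svm":
        return SVC(kernel="rbf", gamma=p.pop("gamma", "scale"), C=p.pop("C", 1.0), **p)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=p.pop("k", 5), **p)
    if kind == "dt":
        # C4.5-style controls: min leaf 2; confidence-factor pruning has no
        # sklearn analogue and maps to "no additional pruning".
        return DecisionTreeClassifier(
            min_samples_leaf=p.pop("min_samples_leaf", 2), random_state=seed, **p
        )
    if kind == "rf":
        mtry = p.pop("mtry", 61)
        if mtry > n_features:
            warnings.warn(
                f"rf mtry={mtry} exceeds feature dimension {n_features}; capped",
                stacklevel=3,
            )
            mtry = n_features
        return RandomForestClassifier(
            n_estimators=p.pop("n_trees", 500), max_features=mtry, random_state=seed, **p
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


class TextureClassifier(BaseEstimator, ClassifierMixin):
    """Uniform binary classifier over standardized texture features.

    Parameters
    ----------
    kind : {'svm', 'knn', 'dt', 'rf'}
    params : dict, optional kind-specific overrides (e.g. ``{'C': 10}``).
    seed : int, RNG seed for the stochastic backends.

    Predicts the canonical labels ``'positive'`` / ``'negative'``.  For
    the SVM, the decision is the sign of the discriminant; an exactly
    zero discriminant resolves to negative.
    """

    def __init__(self, kind: str = "svm", params: dict | None = None, seed: int = 0):
        self.kind = kind
        self.params = params
        self.seed = seed

    def fit(self, X, y, schema=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        bad = ~np.isfinite(X)
        if bad.any():
            col = int(np.argwhere(bad)[0][1])
            name = schema[col] if schema else f"f_{col}"
            raise ValueError(f"non-finite feature value in column {name}")
        y = np.asarray([v if v in (POSITIVE, NEGATIVE) else str(v) for v in y])
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(f"training labels contain a single class: {classes.tolist()}")
        counts = {c: int(np.sum(y == c)) for c in classes}
        if min(counts.values()) < 2:
            raise ValueError(f"need >= 2 samples per class, got {counts}")
        spec = ClassifierSpec(self.kind, dict(self.params or {}), self.seed)
        self.scaler_ = StandardScaler().fit(X)
        self.backend_ = _build_backend(spec.kind, spec.params, spec.seed, X.shape[1])
        self.backend_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.backend_.classes_
        self.schema_ = tuple(schema) if schema is not None else None
        self.n_features_in_ = X.shape[1]
        self.spec_ = spec
        return self

    def _check_schema(self, X, schema):
        X = np.asarray(X, dtype=np.float64)
        if X.size and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training dimension "
                f"{self.n_features_in_}"
            )
        if schema is not None and self.schema_ is not None and tuple(schema) != self.schema_:
            raise ValueError("feature schema does not match the training schema")
        return X

    def predict(self, X, schema=None):
        check_is_fitted(self, "backend_")
        X = self._check_schema(X, schema)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        Xs = self.scaler_.transform(X)
        if self.kind == "svm" and set(self.classes_) == {POSITIVE, NEGATIVE}:
            # sign convention: strictly positive discriminant -> positive,
            # zero resolves to negative
            df = self.backend_.decision_function(Xs)
            pos_is_second = self.classes_[1] == POSITIVE
            pos = df > 0 if pos_is_second else df <= 0
            return np.where(pos, POSITIVE, NEGATIVE)
        return self.backend_.predict(Xs)


def train_classifier(X, y, spec: ClassifierSpec, schema=None) -> TextureClassifier:
    """Fit a TextureClassifier from a ClassifierSpec (thin functional wrapper)."""
    return TextureClassifier(kind=spec.kind, params=dict(spec.params), seed=spec.seed).fit(
        X, y, schema=schema
    )


def predict(model: TextureClassifier, X, schema=None):
    return model.predict(X, schema=schema)
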