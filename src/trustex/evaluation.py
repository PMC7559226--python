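"""Evaluation harness: confusion counts, ACC/SEN/SPEC, case-level CV.

Metrics follow the standard screening definitions,

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    SEN  = TP / (TP + FN)
    SPEC = TN / (TN + FP)

reported as percentages; a metric with an empty denominator is NaN
("undefined").  All splits are made at CASE (patient) level: every
image of a case lands in the same fold, so texture from one patient can
never appear on both sides of a split.  The k-fold summary is the
unweighted mean of per-fold metrics; pooled confusion counts are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from trustex.data_io import NEGATIVE, POSITIVE, DatasetManifest, crop_roi, load_image
from trustex.pipeline import ClassifierSpec, FusionConfig, fuse_features, train_classifier
from trustex.preprocess import preprocess_image


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class EvalReport:
    counts: ConfusionCounts
    acc: float
    sen: float
    spec: float
    folds: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        def f(v):
            return "NA" if np.isnan(v) else f"{v:.2f}%"

        return (
            f"ACC {f(self.acc)}  SEN {f(self.sen)}  SPEC {f(self.spec)}  "
            f"(tp={self.counts.tp} tn={self.counts.tn} fp={self.counts.fp} fn={self.counts.fn})"
        )

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
            "acc": self.acc,
            "sen": self.sen,
            "spec": self.spec,
            "folds": self.folds,
            "config": self.config,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally binary confusion counts (positive = 'positive' label)."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} truths vs {len(y_pred)} predictions")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == POSITIVE:
            tp, fn = (tp + 1, fn) if p == POSITIVE else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == NEGATIVE else (tn, fp + 1)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts, config: dict | None = None, folds=None) -> EvalReport:
    """ACC/SEN/SPEC percentages from confusion counts (NaN when undefined)."""

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return EvalReport(
        counts=c,
        acc=pct(c.tp + c.tn, c.total),
        sen=pct(c.tp, c.tp + c.fn),
        spec=pct(c.tn, c.tn + c.fp),
        folds=list(folds or []),
        config=dict(config or {}),
    )


def _case_table(case_ids, labels) -> tuple[np.ndarray, np.ndarray]:
    """Unique cases (order of first appearance) with their class labels."""
    seen: dict[str, str] = {}
    for cid, lab in zip(case_ids, labels):
        if cid in seen and seen[cid] != lab:
            raise ValueError(f"case {cid!r} carries both labels")
        seen.setdefault(cid, lab)
    cases = np.array(list(seen.keys()))
    return cases, np.array([seen[c] for c in cases])


def case_level_split(
    case_ids,
    labels,
    k: int | None = None,
    test_fraction: float | None = None,
    seed: int = 0,
    stratified: bool = True,
):
    """Assign each case to a fold (k-fold) or to train/test (fraction).

    Returns ``{case_id: fold_index}``; for ``test_fraction`` the folds
    are 0 = train, 1 = test.  Stratification is at case level; it falls
    back to an unstratified case-level split when a class has fewer
    cases than folds (e.g. leave-one-case-out).
    """
    cases, case_labels = _case_table(case_ids, labels)
    if (k is None) == (test_fraction is None):
        raise ValueError("specify exactly one of k or test_fraction")
    if k is not None:
        if k < 2 or k > len(cases):
            raise ValueError(f"k={k} infeasible for {len(cases)} cases")
        min_class = min(np.sum(case_labels == c) for c in np.unique(case_labels))
        if stratified and min_class >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        assignment = {}
        for fold, (_, test_idx) in enumerate(splitter.split(cases, case_labels)):
            for i in test_idx:
                assignment[cases[i]] = fold
        return assignment
    train_c, test_c = train_test_split(
        cases,
        test_size=test_fraction,
        random_state=seed,
        stratify=case_labels if stratified else None,
    )
    return {**{c: 0 for c in train_c}, **{c: 1 for c in test_c}}


def _assert_no_case_leakage(train_cases, test_cases):
    overlap = set(train_cases) & set(test_cases)
    assert not overlap, f"case leakage between train and test: {sorted(overlap)}"


def cross_validate_arrays(
    X,
    y,
    case_ids,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    k: int = 5,
    seed: int = 0,
    schema=None,
    config: dict | None = None,
) -> EvalReport:
    """Case-level k-fold CV over a precomputed feature matrix.

    Feature standardization (inside TextureClassifier) is refit on each
    training fold, so no test statistics leak into training.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    case_ids = np.asarray(case_ids)
    assignment = case_level_split(case_ids, y, k=k, seed=seed)
    fold_of_image = np.array([assignment[c] for c in case_ids])
    fold_reports = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(k):
        test_mask = fold_of_image == fold
        _assert_no_case_leakage(case_ids[~test_mask], case_ids[test_mask])
        model = train_classifier(X[~test_mask], y[~test_mask], clf_spec, schema=schema)
        pred = model.predict(X[test_mask], schema=schema)
        c = confusion(y[test_mask], pred)
        r = metrics(c)
        pooled = pooled + c
        fold_reports.append(
            {"fold": fold, "acc": r.acc, "sen": r.sen, "spec": r.spec,
             "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
             "n_test_cases": int(len(set(case_ids[test_mask])))}
        )
    mean = {m: float(np.nanmean([f[m] for f in fold_reports])) for m in ("acc", "sen", "spec")}
    cfg = {
        "classifier": clf_spec.kind,
        "classifier_params": dict(clf_spec.params),
        "seed": seed,
        "k": k,
        **(config or {}),
    }
    report = metrics(pooled, config=cfg, folds=fold_reports)
    # CV headline metrics = unweighted mean over folds; pooled counts kept.
    report.acc, report.sen, report.spec = mean["acc"], mean["sen"], mean["spec"]
    return report


def _manifest_features(manifest: DatasetManifest, fusion_cfg: FusionConfig, preprocess: bool):
    X, schema = [], None
    for rec in manifest.records:
        img = load_image(rec.image_path)
        if rec.roi is not None:
            img = crop_roi(img, rec.roi)
        if preprocess:
            img = preprocess_image(img)
        fv = fuse_features(img, fusion_cfg)
        schema = fv.schema
        X.append(fv.values)
    return np.asarray(X), schema


def cross_validate(
    manifest: DatasetManifest,
    fusion_cfg: FusionConfig = FusionConfig(),
    clf_spec: ClassifierSpec = ClassifierSpec(),
    k: int = 5,
    seed: int = 0,
    preprocess: bool = True,
) -> EvalReport:
    """End-to-end case-level CV from a manifest of image patches."""
    X, schema = _manifest_features(manifest, fusion_cfg, preprocess)
    y = np.array(manifest.labels())
    case_ids = np.array([r.case_id for r in manifest.records])
    return cross_validate_arrays(
        X, y, case_ids, clf_spec, k=k, seed=seed, schema=schema,
        config={"fusion": fusion_cfg.scheme, "preprocess": preprocess,
                "provenance": manifest.provenance},
    )
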