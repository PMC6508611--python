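"""Repeated random-forest classification of samples by condition.

Many forests (default 1000, each of 500 trees with 10 candidate variables
per split) are trained on independent stratified 70/30 train/test splits;
the model with the lowest out-of-bag (OOB) error on its training portion
is selected, and its Gini importances rank the features.  Features are
either individual genes (log2 expression of DE genes) or functional
categories, each represented by the mean expression of its DE genes —
the pathway-aggregated view that tends to describe the biology better
than single-gene signatures.  A PCA embedding of the samples on the
top-ranked features visualises the separation the forest exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .config import RFConfig
from .errors import DesignError
from .study import AnnotationSet, ExpressionStudy

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Feature x sample value matrix with per-sample condition labels."""

    level: str                 # "gene" or "category"
    values: pd.DataFrame       # features (rows) x samples (columns)
    labels: pd.Series          # sample -> condition

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if set(self.values.columns) != set(self.labels.index):
            raise ValueError("feature columns and labels disagree on samples")
        if self.labels.nunique() < 2:
            raise DesignError("classification requires at least 2 distinct labels")


@dataclass
class ForestResult:
    """Selected model: OOB error, held-out performance and importances."""

    oob_error: float
    test_accuracy: float
    confusion: pd.DataFrame          # actual (rows) x predicted, test set
    confusion_oob: pd.DataFrame      # actual x predicted, OOB on train set
    importances: pd.Series           # feature -> mean Gini decrease, ranked
    model_index: int
    seed: int
    oob_errors: list[float] = field(default_factory=list)


def gene_features(study: ExpressionStudy, genes) -> FeatureTable:
    """One feature per gene: its log2 expression row."""
    keep = study.genes.intersection(pd.Index(sorted(genes)))
    if len(keep) == 0:
        raise ValueError("no qualifying genes for the feature table")
    return FeatureTable(level="gene", values=study.matrix.loc[keep], labels=study.design)


def category_features(
    study: ExpressionStudy,
    annotation: AnnotationSet,
    de_genes,
    min_category_size: int = 3,
) -> FeatureTable:
    """One feature per category: mean expression of its DE genes per sample.

    Categories with fewer than ``min_category_size`` DE genes measured in
    the study are skipped; having none at all is an error.
    """
    de = frozenset(de_genes)
    if not de:
        raise ValueError("de_genes is empty")
    rows: dict[str, np.ndarray] = {}
    for cid in annotation.ids():
        genes = annotation.members(cid) & de
        keep = study.genes.intersection(pd.Index(sorted(genes)))
        if len(keep) < min_category_size:
            continue
        rows[cid] = study.matrix.loc[keep].mean(axis=0).to_numpy()
    if not rows:
        raise ValueError("no category retains enough DE genes to form a feature")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=study.matrix.columns)
    return FeatureTable(level="category", values=values, labels=study.design)


def _confusion(actual: pd.Series, predicted: np.ndarray, classes: list[str]) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, p in zip(actual, predicted):
        cm.loc[a, p] += 1
    cm.index.name = "actual"
    cm.columns.name = "predicted"
    return cm


def rf_select(
    features: FeatureTable,
    rf: RFConfig,
    seed: int | None = None,
    stratify: bool = True,
) -> ForestResult:
    """Train ``rf.n_models`` forests on fresh splits; keep the lowest-OOB one.

    Every model gets an independent stratified train/test split (fraction
    ``rf.train_fraction`` for training) and an independently seeded forest;
    the winner is the model with the lowest OOB error on its training
    portion, ties broken toward the lowest model index.  Fully
    reproducible given ``seed``.
    """
    if seed is None:
        seed = rf.seed
    x = features.values.T                     # samples x features
    y = features.labels.loc[x.index]
    class_counts = y.value_counts()
    if stratify and (class_counts < 2).any():
        offender = class_counts.idxmin()
        raise DesignError(
            f"condition {offender!r} has a single sample; merge or drop it "
            "before stratified splitting"
        )
    mtry = min(rf.mtry, x.shape[1])
    if mtry < rf.mtry:
        log.info("mtry clamped from %d to %d features", rf.mtry, mtry)

    rng = np.random.default_rng(seed)
    model_seeds = rng.integers(0, 2**31 - 1, size=(rf.n_models, 2))
    best: tuple[float, int] | None = None
    best_state: tuple | None = None
    oob_errors: list[float] = []
    for i in range(rf.n_models):
        split_seed, forest_seed = (int(s) for s in model_seeds[i])
        x_train, x_test, y_train, y_test = train_test_split(
            x, y,
            train_size=rf.train_fraction,
            stratify=y if stratify else None,
            random_state=split_seed,
        )
        clf = RandomForestClassifier(
            n_estimators=rf.n_trees,
            max_features=mtry,
            oob_score=True,
            random_state=forest_seed,
            n_jobs=1,
        )
        clf.fit(x_train, y_train)
        oob_error = 1.0 - float(clf.oob_score_)
        oob_errors.append(oob_error)
        if best is None or oob_error < best[0]:
            best = (oob_error, i)
            best_state = (clf, x_train, x_test, y_train, y_test)

    assert best is not None and best_state is not None
    clf, x_train, x_test, y_train, y_test = best_state
    classes = sorted(y.unique())
    y_pred = clf.predict(x_test)
    test_accuracy = float((y_pred == y_test).mean())
    oob_pred = np.asarray(clf.classes_)[np.argmax(clf.oob_decision_function_, axis=1)]
    importances = pd.Series(
        clf.feature_importances_, index=features.values.index, name="gini_importance"
    )
    importances = importances.iloc[
        np.lexsort((importances.index, -importances.to_numpy()))
    ]
    return ForestResult(
        oob_error=best[0],
        test_accuracy=test_accuracy,
        confusion=_confusion(y_test, y_pred, classes),
        confusion_oob=_confusion(y_train, oob_pred, classes),
        importances=importances,
        model_index=best[1],
        seed=seed,
        oob_errors=oob_errors,
    )


def top_important(result: ForestResult, top_n: int) -> list[str]:
    """First ``top_n`` features by mean Gini decrease (ties by feature id)."""
    if not 1 <= top_n <= len(result.importances):
        raise ValueError(
            f"top_n={top_n} out of range for {len(result.importances)} features"
        )
    return list(result.importances.index[:top_n])


def pca_embed(
    features: FeatureTable, subset: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """2-D PCA of the samples on a feature subset.

    Column-centred SVD; returns per-sample scores for the first two
    components and the explained-variance fractions.  Inputs with fewer
    than two effective dimensions yield a single component with a warning.
    """
    values = features.values if subset is None else features.values.loc[subset]
    if len(values) == 0:
        raise ValueError("empty feature subset for PCA")
    x = values.T.to_numpy(dtype=float)        # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else var
    rank = int((s > s[0] * 1e-12).sum()) if len(s) and s[0] > 0 else 0
    n_comp = min(2, max(rank, 1))
    if n_comp < 2:
        log.warning("input has <2 effective dimensions; returning 1 component")
    scores = u[:, :n_comp] * s[:n_comp]
    coords = pd.DataFrame(
        scores,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    coords.insert(0, "condition", features.labels.loc[coords.index].to_numpy())
    return coords, explained[:n_comp]
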