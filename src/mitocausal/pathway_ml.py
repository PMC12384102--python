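"""Per-pathway cross-validated classification and the two-stage gene ranking.

Stage one scores every pathway by a composite Pathway Score: genes of the
pathway are fed to a zoo of classifiers under stratified k-fold CV
(standardization fit per training fold), the five metrics (accuracy,
ROC-AUC, F1, precision, recall) are averaged per model across folds and then
across the zoo, and the Pathway Score is the arithmetic mean of the five
across-model means. Stage two sums, for every gene, its normalized per-model
importances over the pathways scoring in the top half, giving the Total
Importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "CVConfig",
    "ModelMetrics",
    "ImportanceVector",
    "PathwayScorecard",
    "GeneRanking",
    "MODEL_REGISTRY",
    "default_model_set",
    "run_cv",
    "select_best_model",
    "extract_importance",
    "pathway_score",
    "select_top_pathways",
    "total_importance",
    "score_pathways",
]

METRICS = ["accuracy", "roc_auc", "f1", "precision", "recall"]

#: Pluggable registry: name -> (estimator factory(seed), hyperparameter grid).
MODEL_REGISTRY = {
    "logistic_regression": (
        lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
        {"clf__C": [0.1, 1.0, 10.0]},
    ),
    "svm_linear": (
        lambda seed: SVC(kernel="linear", probability=False, random_state=seed),
        {"clf__C": [0.1, 1.0, 10.0]},
    ),
    "svm_rbf": (
        lambda seed: SVC(kernel="rbf", probability=False, random_state=seed),
        {"clf__C": [0.1, 1.0, 10.0]},
    ),
    "random_forest": (
        lambda seed: RandomForestClassifier(n_estimators=200, random_state=seed),
        {},
    ),
    "gradient_boosting": (
        lambda seed: GradientBoostingClassifier(random_state=seed),
        {"clf__n_estimators": [50, 100]},
    ),
    "knn": (
        lambda seed: KNeighborsClassifier(),
        {"clf__n_neighbors": [3, 5, 7]},
    ),
    "naive_bayes": (lambda seed: GaussianNB(), {}),
    "mlp": (
        lambda seed: MLPClassifier(hidden_layer_sizes=(100,), alpha=1e-3,
                                   max_iter=500, random_state=seed),
        {},
    ),
}

LINEAR_MODELS = {"logistic_regression", "svm_linear"}
TREE_MODELS = {"random_forest", "gradient_boosting"}


def default_model_set() -> list:
    return list(MODEL_REGISTRY)


@dataclass
class CVConfig:
    """Stratified cross-validation settings. Model selection scores ROC-AUC."""

    n_folds: int = 10
    seed: int = 0
    model_set: list = field(default_factory=default_model_set)
    inner_folds: int = 3
    permutation_repeats: int = 20

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not self.model_set:
            raise ValidationError("model set must be nonempty")
        unknown = [m for m in self.model_set if m not in MODEL_REGISTRY]
        if unknown:
            raise ValidationError(f"unknown models: {unknown}")


@dataclass
class ModelMetrics:
    """Per-fold metric values and their means for one model."""

    fold_values: pd.DataFrame  # folds x METRICS

    @property
    def means(self) -> pd.Series:
        return self.fold_values.mean(axis=0)


@dataclass
class ImportanceVector:
    """Per-gene importances in [0,1] for one fitted model on one pathway."""

    values: pd.Series
    method: str  # native-tree | coefficient-magnitude | permutation

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValidationError("importances must be non-negative")
        mx = self.values.max()
        if len(self.values) and mx > 0 and abs(mx - 1.0) > 1e-9:
            raise ValidationError("non-zero importance vectors must have max 1")


@dataclass
class PathwayScorecard:
    """Stage-one output: per-pathway scores, metrics and importances."""

    table: pd.DataFrame  # index pathway; score, best_model, mean_<metric>...
    metrics: dict        # pathway -> model -> ModelMetrics
    importances: dict    # (pathway, model) -> ImportanceVector


@dataclass
class GeneRanking:
    """Stage-two output: Total Importance per gene plus its contribution ledger."""

    table: pd.DataFrame   # index gene; total_importance, n_contributions
    ledger: pd.DataFrame  # gene, pathway, model, importance


def _score_fold(est, X_val, y_val) -> dict:
    pred = est.predict(X_val)
    if hasattr(est, "predict_proba"):
        score = est.predict_proba(X_val)[:, 1]
    else:
        score = est.decision_function(X_val)
    if len(np.unique(y_val)) < 2:
        raise ValidationError("validation fold contains a single class")
    return {
        "accuracy": accuracy_score(y_val, pred),
        "roc_auc": roc_auc_score(y_val, score),
        "f1": f1_score(y_val, pred, zero_division=0),
        "precision": precision_score(y_val, pred, zero_division=0),
        "recall": recall_score(y_val, pred, zero_division=0),
    }


def _build_pipeline(name: str, seed: int) -> Pipeline:
    factory, _ = MODEL_REGISTRY[name]
    return Pipeline([("scale", StandardScaler()), ("clf", factory(seed))])


def _fit_with_search(name: str, X, y, cfg: CVConfig):
    """Fit one model on a training fold, grid-searching when the grid has >1 point."""
    _, grid = MODEL_REGISTRY[name]
    pipe = _build_pipeline(name, cfg.seed)
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_combos > 1:
        inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                                random_state=cfg.seed)
        search = GridSearchCV(pipe, grid, cv=inner, scoring="roc_auc", n_jobs=1)
        search.fit(X, y)
        return search.best_estimator_
    pipe.fit(X, y)
    return pipe


def run_cv(m: ExpressionMatrix, cfg: CVConfig) -> dict:
    """Stratified k-fold CV of every model in the set on one pathway's genes.

    Returns ``{model_name: ModelMetrics}``. Standardization is fit on each
    training fold only; hyperparameters are chosen by an inner stratified
    grid search on the training fold maximizing ROC-AUC. Deterministic under
    ``cfg.seed``.
    """
    X = m.values.to_numpy(dtype=float)
    y = m.labels.to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.n_folds:
        raise ValidationError(
            f"each class needs >= n_folds samples (have {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(X, y))
    out = {}
    for name in cfg.model_set:
        rows = []
        for tr, va in folds:
            est = _fit_with_search(name, X[tr], y[tr], cfg)
            rows.append(_score_fold(est, X[va], y[va]))
        out[name] = ModelMetrics(pd.DataFrame(rows))
    return out


def select_best_model(metrics: dict) -> str:
    """Arg-max of mean ROC-AUC; ties broken by model-set order."""
    if not metrics:
        raise ValidationError("no models evaluated")
    best, best_auc = None, -np.inf
    for name, mm in metrics.items():  # insertion order = model-set order
        auc = mm.means["roc_auc"]
        if auc > best_auc:
            best, best_auc = name, auc
    return best


def _model_score(model, X, y) -> float:
    """ROC-AUC when a continuous score is available, accuracy otherwise."""
    if hasattr(model, "predict_proba"):
        score = np.asarray(model.predict_proba(X))[:, 1]
    elif hasattr(model, "decision_function"):
        score = np.asarray(model.decision_function(X))
    else:
        return accuracy_score(y, model.predict(X))
    if len(np.unique(score)) < 2:
        return 0.5
    return roc_auc_score(y, score)


def _permutation_importance(model, X, y, n_repeats: int, seed: int) -> np.ndarray:
    """Mean score drop when one feature is shuffled; negatives clipped to 0.

    Model-agnostic: any object with a prediction function qualifies.
    """
    rng = np.random.default_rng(seed)
    base = _model_score(model, X, y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        work = X.copy()
        for _ in range(n_repeats):
            work[:, j] = rng.permutation(X[:, j])
            drops[j] += base - _model_score(model, work, y)
    return np.clip(drops / n_repeats, 0.0, None)


def _normalize(values: np.ndarray) -> np.ndarray:
    """Map the maximum to 1 by division, preserving zeros.

    Min-subtraction would zero out the least important gene of an
    all-positive tree-importance vector; division keeps relative magnitudes.
    """
    mx = values.max() if values.size else 0.0
    return values / mx if mx > 0 else values


def extract_importance(model, m: ExpressionMatrix, model_name: str | None = None,
                       seed: int = 0, n_repeats: int = 20) -> ImportanceVector:
    """Per-gene importance of a fitted model, normalized to [0,1].

    Tree families use native impurity importances; linear families the
    absolute coefficients (on standardized inputs); everything else falls
    back to seeded permutation importance (ROC-AUC drop, ``n_repeats``
    shuffles per gene, negatives clipped to 0).
    """
    clf = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if not (hasattr(clf, "predict") or hasattr(clf, "decision_function")):
        raise ValidationError("model exposes no prediction function")
    genes = m.gene_ids
    if hasattr(clf, "feature_importances_"):
        raw = np.asarray(clf.feature_importances_, dtype=float)
        method = "native-tree"
    elif hasattr(clf, "coef_"):
        raw = np.abs(np.asarray(clf.coef_, dtype=float)).ravel()
        method = "coefficient-magnitude"
    else:
        raw = _permutation_importance(
            model, m.values.to_numpy(dtype=float), m.labels.to_numpy(dtype=int),
            n_repeats=n_repeats, seed=seed,
        )
        method = "permutation"
    return ImportanceVector(pd.Series(_normalize(raw), index=genes), method)


def pathway_score(means: pd.Series | dict) -> float:
    """Composite Pathway Score: arithmetic mean of the five mean metrics."""
    means = pd.Series(means)
    missing = [m for m in METRICS if m not in means.index]
    if missing:
        raise ValidationError(f"missing metric(s): {missing}")
    return float(means[METRICS].mean())


def select_top_pathways(scorecard: PathwayScorecard) -> list:
    """Pathways with score >= the median score (median ties included)."""
    scores = scorecard.table["score"]
    if scores.empty:
        raise ValidationError("no pathway scored")
    med = scores.median()
    return list(scores.index[scores >= med])


def total_importance(scorecard: PathwayScorecard, selected, pmap: dict,
                     aggregation: str = "all_models") -> GeneRanking:
    """Sum normalized gene importances over the selected pathways.

    ``all_models`` (default) sums each pathway's contribution over every
    model in the zoo; ``best_model`` uses only the pathway's best model.
    The contribution ledger is retained so each total is auditable.
    """
    if aggregation not in ("all_models", "best_model"):
        raise ValidationError(f"unknown aggregation mode: {aggregation!r}")
    if not selected:
        raise ValidationError("selected pathway set is empty")
    records = []
    for pw in selected:
        if aggregation == "best_model":
            models = [scorecard.table.loc[pw, "best_model"]]
        else:
            models = list(scorecard.metrics[pw])
        for model in models:
            iv = scorecard.importances[(pw, model)]
            for gene, val in iv.values.items():
                records.append((gene, pw, model, float(val)))
    ledger = pd.DataFrame(records, columns=["gene", "pathway", "model", "importance"])
    table = (ledger.groupby("gene")["importance"]
             .agg(total_importance="sum", n_contributions="count")
             .sort_values("total_importance", ascending=False))
    return GeneRanking(table, ledger)


def score_pathways(m: ExpressionMatrix, pmap: dict, cfg: CVConfig) -> PathwayScorecard:
    """Stage one over every pathway: CV metrics, composite score, importances.

    The pathway score averages each metric across the model zoo before the
    five-metric mean; importances come from a final fit of each model (with
    its selected hyperparameters) on the full standardized pathway matrix.
    """
    rows, metrics_by_pw, importances = {}, {}, {}
    for pw, genes in pmap.items():
        sub = m.subset_genes(sorted(genes))
        if sub.n_genes == 0:
            raise ValidationError(f"pathway {pw!r} has no measured genes")
        mm = run_cv(sub, cfg)
        metrics_by_pw[pw] = mm
        across = pd.DataFrame({name: v.means for name, v in mm.items()}).mean(axis=1)
        best = select_best_model(mm)
        rows[pw] = {
            "score": pathway_score(across),
            "best_model": best,
            **{f"mean_{k}": across[k] for k in METRICS},
        }
        for name in cfg.model_set:
            est = _fit_with_search(name, sub.values.to_numpy(dtype=float),
                                   sub.labels.to_numpy(dtype=int), cfg)
            importances[(pw, name)] = extract_importance(
                est, sub, name, seed=cfg.seed, n_repeats=cfg.permutation_repeats
            )
    table = pd.DataFrame(rows).T.sort_values("score", ascending=False)
    return PathwayScorecard(table, metrics_by_pw, importances)
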