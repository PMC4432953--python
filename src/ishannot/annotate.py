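"""Per-structure annotation classifiers and their evaluation.

The multi-category manual annotations are reformulated as one binary task
per brain structure — undetected (-1) versus any detected category (+1);
under that reformulation the pattern, intensity and density metrics induce
the same tasks.  One l2-regularised logistic classifier is trained per
structure:

    min_w  sum_i log(1 + exp(-y_i (w^T x_i + b)))  +  lambda * ||w||^2

with the bias unpenalised, minimised by a deterministic quasi-Newton batch
method.  Because the undetected class dominates, the train/test split is
chosen by rejection sampling that maximises class balance: candidate splits
are drawn until, for every structure at the level, the minority/majority
ratio in both the train and the test part clears a threshold; after
``max_attempts`` failures the threshold is relaxed and sampling continues.
Performance is the area under the ROC curve per structure, summarised per
ontology level as the unweighted mean over structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from .features import FeatureMatrix
from .ontology import AnnotationTable, StructureOntology

log = logging.getLogger(__name__)

DEFAULT_LAMBDA = 1.0
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0
DEFAULT_MAX_ATTEMPTS = 5000
DEFAULT_THRESHOLD_START = 1.0 / 3.0
DEFAULT_THRESHOLD_DECAY = 0.8
DEFAULT_THRESHOLD_FLOOR = 0.01


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def binarize(table: AnnotationTable, metric: str = "pattern") -> dict[str, pd.Series]:
    """Per-structure label maps: undetected -> -1, every other category -> +1.

    Genes without a record for a structure are absent from that structure's
    map (they carry no supervision for it).
    """
    df = table.subset_metric(metric)
    maps: dict[str, pd.Series] = {}
    for sid, group in df.groupby("structure_id"):
        labels = np.where(group["category"].to_numpy() == "undetected", -1, 1)
        maps[str(sid)] = pd.Series(labels, index=group["gene_id"].to_numpy(), dtype=int)
    return maps


# ---------------------------------------------------------------------------
# balance-maximising split
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    train_genes: list[str]
    test_genes: list[str]
    achieved_threshold: float
    excluded_structures: list[str]
    n_attempts: int


def _min_balance_ratio(label_maps, structures, train_set, test_set) -> float:
    """Worst minority/majority class ratio over structures and both halves."""
    worst = np.inf
    for sid in structures:
        labels = label_maps[sid]
        for subset in (train_set, test_set):
            sub = labels[labels.index.isin(subset)]
            pos = int((sub == 1).sum())
            neg = int((sub == -1).sum())
            if pos == 0 or neg == 0:
                return 0.0
            worst = min(worst, min(pos, neg) / max(pos, neg))
    return 0.0 if worst is np.inf else float(worst)


def balanced_split(
    label_maps: dict[str, pd.Series],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    threshold_start: float = DEFAULT_THRESHOLD_START,
    threshold_decay: float = DEFAULT_THRESHOLD_DECAY,
    threshold_floor: float = DEFAULT_THRESHOLD_FLOOR,
    seed: int = 0,
) -> SplitResult:
    """Rejection-sampled train/test split maximising per-structure balance.

    Structures with a single class in the full data cannot be balanced (or
    classified); they are excluded from the ratio check and reported in
    ``excluded_structures``.  If even the floor threshold is never met, the
    best split seen is returned and the achieved threshold is its worst
    ratio.
    """
    genes = sorted({g for m in label_maps.values() for g in m.index})
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")

    eligible, excluded = [], []
    for sid, labels in sorted(label_maps.items()):
        if labels.nunique() < 2:
            excluded.append(sid)
        else:
            eligible.append(sid)
    if excluded:
        log.warning("structures with a single class excluded from the balance "
                    "check: %s", excluded)

    rng = np.random.default_rng(seed)
    n_train = max(1, min(len(genes) - 1, round(train_fraction * len(genes))))
    genes_arr = np.asarray(genes)
    threshold = threshold_start
    best_ratio, best_split = -1.0, None
    attempts = 0
    while True:
        for _ in range(max_attempts):
            attempts += 1
            perm = rng.permutation(len(genes_arr))
            train = set(genes_arr[perm[:n_train]])
            test = set(genes_arr[perm[n_train:]])
            ratio = (
                _min_balance_ratio(label_maps, eligible, train, test)
                if eligible else 1.0
            )
            if ratio > best_ratio:
                best_ratio, best_split = ratio, (train, test)
            if ratio >= threshold:
                return SplitResult(
                    sorted(train), sorted(test), threshold, excluded, attempts
                )
        if threshold <= threshold_floor:
            train, test = best_split
            return SplitResult(
                sorted(train), sorted(test), best_ratio, excluded, attempts
            )
        threshold = max(threshold * threshold_decay, threshold_floor)


# ---------------------------------------------------------------------------
# l2-regularised logistic classifier
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """Weights, bias and regularisation strength of one structure's
    classifier; ``trace`` records the objective value per optimiser
    iteration."""

    w: np.ndarray
    b: float
    lam: float
    trace: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("non-finite model parameters")


def logistic_objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       lam: float) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the penalised logistic loss.

    theta stacks (w, b).  Loss uses the numerically stable softplus
    log(1 + exp(m)) = max(m, 0) + log1p(exp(-|m|)) with margins
    m_i = -y_i (w.x_i + b); the squared l2 penalty excludes the bias.
    """
    w, b = theta[:-1], theta[-1]
    z = X @ w + b
    m = -y * z
    loss = float(np.sum(np.maximum(m, 0.0) + np.log1p(np.exp(-np.abs(m)))))
    value = loss + lam * float(w @ w)
    # d/dz log(1+exp(-y z)) = -y * sigmoid(-y z)
    sig = 1.0 / (1.0 + np.exp(-np.clip(m, -700, 700)))
    gz = -y * sig
    grad = np.empty_like(theta)
    grad[:-1] = X.T @ gz + 2.0 * lam * w
    grad[-1] = float(np.sum(gz))
    return value, grad


def train(X: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA,
          tol: float = 1e-6, max_iter: int = 1000) -> LinearModel:
    """Fit the classifier by L-BFGS-B from the zero vector; deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    theta0 = np.zeros(X.shape[1] + 1)
    trace: list[float] = []

    def callback(theta):
        trace.append(logistic_objective(theta, X, y, lam)[0])

    res = minimize(
        logistic_objective, theta0, args=(X, y, lam), jac=True,
        method="L-BFGS-B", callback=callback,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    return LinearModel(res.x[:-1], float(res.x[-1]), lam,
                       trace=[logistic_objective(theta0, X, y, lam)[0]] + trace,
                       converged=bool(res.success))


def score(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Decision values w.x + b."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape} does not match model p={model.w.shape[0]}"
        )
    return X @ model.w + model.b


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(score_+ > score_-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes in the labels")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# per-level evaluation
# ---------------------------------------------------------------------------

def count_annotation_tasks(ontology: StructureOntology) -> int:
    """One binary annotation task (classifier) per structure, all levels."""
    return len(ontology)


@dataclass
class EvaluationReport:
    """Per-structure rows plus the per-level overall AUC (unweighted mean)."""

    rows: pd.DataFrame
    level: int
    overall_auc: float
    achieved_threshold: float
    excluded_structures: list[str]
    stage: str = ""
    representation: str = ""

    ROW_COLUMNS = ("structure_id", "level", "n_train", "n_test", "n_pos_test", "auc")


def annotate_level(
    features: FeatureMatrix,
    table: AnnotationTable,
    ontology: StructureOntology,
    level: int,
    metric: str = "pattern",
    lam: float = DEFAULT_LAMBDA,
    split: SplitResult | None = None,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    threshold_start: float = DEFAULT_THRESHOLD_START,
    seed: int = 0,
    stage: str = "",
) -> EvaluationReport:
    """Train and evaluate one classifier per structure at an ontology level.

    Gene alignment is by ID, never by row order.  Structures whose labels
    are single-class overall, or degenerate in the train or test part, are
    flagged and excluded rather than silently scored.
    """
    structures = [n.structure_id for n in ontology.structures_at(level)]
    feature_genes = set(features.gene_ids)
    maps = {
        sid: labels[labels.index.isin(feature_genes)]
        for sid, labels in binarize(table, metric).items()
        if sid in structures
    }
    maps = {sid: m for sid, m in maps.items() if len(m)}
    dropped = table.genes()
    missing = sorted(set(dropped) - feature_genes)
    if missing:
        log.warning("genes without feature rows dropped: %s", missing[:10])
    if not maps:
        log.warning("no eligible structures at level %d", level)
        return EvaluationReport(
            pd.DataFrame(columns=list(EvaluationReport.ROW_COLUMNS)), level,
            float("nan"), float("nan"), [], stage, features.tag,
        )

    if split is None:
        split = balanced_split(
            maps, train_fraction=train_fraction, max_attempts=max_attempts,
            threshold_start=threshold_start, seed=seed,
        )
    excluded = list(split.excluded_structures)

    rows = []
    for sid in sorted(maps):
        labels = maps[sid]
        if labels.nunique() < 2:
            continue
        tr = [g for g in split.train_genes if g in labels.index]
        te = [g for g in split.test_genes if g in labels.index]
        y_tr, y_te = labels[tr].to_numpy(), labels[te].to_numpy()
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            log.warning("structure %s degenerate after the split; excluded", sid)
            excluded.append(sid)
            continue
        X_tr = features.reorder(tr).values
        X_te = features.reorder(te).values
        model = train(X_tr, y_tr, lam=lam)
        rows.append({
            "structure_id": sid,
            "level": level,
            "n_train": len(tr),
            "n_test": len(te),
            "n_pos_test": int((y_te == 1).sum()),
            "auc": auc(score(model, X_te), y_te),
        })
    frame = pd.DataFrame(rows, columns=list(EvaluationReport.ROW_COLUMNS))
    overall = float(frame["auc"].mean()) if len(frame) else float("nan")
    return EvaluationReport(frame, level, overall, split.achieved_threshold,
                            sorted(set(excluded)), stage, features.tag)
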