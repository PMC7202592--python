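"""Class-balanced random-forest ensembles with out-of-bag probabilities.

Each tree is a CART classifier (scikit-learn) fit on a class-stratified
bootstrap: the same number of samples is drawn with replacement from each
class, so every tree sees rebalanced classes regardless of the cohort's
label skew. The fraction of tree votes for a class is reported as that
class's probability. Out-of-bag (OOB) votes — each training sample
predicted only by trees whose bootstrap excluded it — provide honest
training-set probabilities, the accuracy used for model selection, and the
baseline for permutation variable importance (mean decrease in OOB
accuracy when one feature column is shuffled).

The number of candidate features per split (mtry) can be fixed or selected
by stratified 10-fold cross-validation over {sqrt(p), p/4, p/2, p}, with a
fresh ensemble refit at the selected value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger("metbc")


@dataclass
class EnsembleConfig:
    n_trees: int = 5000
    mtry: int | str | None = "cv"     # int, "cv", or None for sqrt(p)
    cv_folds: int = 10
    cv_n_trees: int | None = None     # trees per CV fit; default n_trees // 10
    min_samples_leaf: int = 1
    max_depth: int | None = None


@dataclass
class EnsembleModel:
    target: str
    classes: np.ndarray
    feature_names: list[str]
    n_trees: int
    mtry: int
    trees: list = field(repr=False, default_factory=list)
    bootstrap_masks: np.ndarray | None = field(repr=False, default=None)
    oob_probs: np.ndarray | None = None
    oob_accuracy: float | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Vote fraction for the positive (second) class.

        A tree whose leaf is exactly tied contributes half a vote, so
        probabilities are exactly complementary under label swap.
        """
        X = _align(X, self.feature_names)
        votes = np.zeros(len(X))
        arr = X.to_numpy(float)
        for tree in self.trees:
            votes += _tree_votes(tree, arr)
        return votes / len(self.trees)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(X)
        # exact vote ties break to the alphabetically first class (class 0)
        return (p > 0.5).astype(int)


def _align(X: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    missing = [c for c in names if c not in X.columns]
    extra = [c for c in X.columns if c not in names]
    if missing:
        raise ValueError(f"feature mismatch; missing: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    if extra:
        X = X[names]
    return X[names]


def _tree_votes(tree, arr: np.ndarray) -> np.ndarray:
    """Majority vote of one tree (1 / 0, ties count 0.5)."""
    pr = tree.predict_proba(arr)[:, 1]
    return np.where(pr > 0.5, 1.0, np.where(pr < 0.5, 0.0, 0.5))


def _stratified_bootstrap(rng, y01: np.ndarray) -> np.ndarray:
    """Indices of one class-stratified bootstrap (50/50 up to rounding).

    Classes are visited in a label-independent order (by smallest member
    index) so the drawn bag is identical when the two class labels are
    swapped — which makes ensemble probabilities exactly complementary
    under label swap.
    """
    idx0 = np.nonzero(y01 == 0)[0]
    idx1 = np.nonzero(y01 == 1)[0]
    first, second = (idx0, idx1) if idx0[0] < idx1[0] else (idx1, idx0)
    per_class = min(len(idx0), len(idx1))
    draw_a = rng.choice(first, size=per_class, replace=True)
    draw_b = rng.choice(second, size=per_class, replace=True)
    return np.concatenate([draw_a, draw_b])


def _fit_forest(X: np.ndarray, y01: np.ndarray, n_trees: int, mtry: int,
                rng: np.random.Generator, cfgr: EnsembleConfig,
                track_oob: bool = True):
    n = len(y01)
    trees = []
    masks = np.zeros((n_trees, n), dtype=bool) if track_oob else None
    vote_pos = np.zeros(n)
    vote_n = np.zeros(n)
    for t in range(n_trees):
        idx = _stratified_bootstrap(rng, y01)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=cfgr.min_samples_leaf,
            max_depth=cfgr.max_depth,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y01[idx])
        trees.append(tree)
        if track_oob:
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            masks[t] = inbag
            oob = ~inbag
            if oob.any():
                vote_pos[oob] += _tree_votes(tree, X[oob])
                vote_n[oob] += 1
    oob_probs = None
    oob_acc = None
    if track_oob:
        with np.errstate(invalid="ignore", divide="ignore"):
            oob_probs = np.where(vote_n > 0, vote_pos / np.maximum(vote_n, 1), np.nan)
        have = vote_n > 0
        if have.any():
            oob_acc = float(((oob_probs[have] > 0.5).astype(int) == y01[have]).mean())
    return trees, masks, oob_probs, oob_acc


def _mtry_grid(p: int) -> list[int]:
    grid = {max(1, round(np.sqrt(p))), max(1, p // 4), max(1, p // 2), p}
    return sorted(grid)


def train_ensemble(
    features: pd.DataFrame,
    labels,
    target: str = "label",
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit a balanced random-forest ensemble.

    Labels may be any two values; they are ordered alphabetically and the
    second one is treated as the positive class whose vote fraction is the
    reported probability.
    """
    config = config or EnsembleConfig()
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(classes) > 2:
        raise ValueError("only binary targets are supported")
    y01 = (y == classes[1]).astype(int)
    X = features.to_numpy(float)
    p = X.shape[1]
    rng = np.random.default_rng(seed)

    if config.mtry == "cv":
        mtry = _select_mtry_cv(X, y01, config, rng)
    elif config.mtry is None:
        mtry = max(1, round(np.sqrt(p)))
    else:
        mtry = int(config.mtry)
    mtry = min(mtry, p)

    trees, masks, oob_probs, oob_acc = _fit_forest(
        X, y01, config.n_trees, mtry, rng, config, track_oob=True)
    return EnsembleModel(
        target=target, classes=classes, feature_names=list(features.columns),
        n_trees=config.n_trees, mtry=mtry, trees=trees,
        bootstrap_masks=masks, oob_probs=oob_probs, oob_accuracy=oob_acc,
    )


def _select_mtry_cv(X, y01, config: EnsembleConfig, rng) -> int:
    p = X.shape[1]
    n_trees = config.cv_n_trees or max(50, config.n_trees // 10)
    folds = min(config.cv_folds, int(np.bincount(y01).min()))
    if folds < 2:
        return max(1, round(np.sqrt(p)))
    best_m, best_acc = None, -1.0
    for m in _mtry_grid(p):
        accs = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for tr, te in skf.split(X, y01):
            trees, _, _, _ = _fit_forest(X[tr], y01[tr], n_trees, m, rng,
                                         config, track_oob=False)
            votes = np.zeros(len(te))
            for tree in trees:
                votes += _tree_votes(tree, X[te])
            pred = (votes / len(trees) > 0.5).astype(int)
            accs.append((pred == y01[te]).mean())
        acc = float(np.mean(accs))
        logger.debug("mtry=%d cv-accuracy=%.4f", m, acc)
        if acc > best_acc:
            best_acc, best_m = acc, m
    return best_m


def oob_vote_fractions(model: EnsembleModel, X: pd.DataFrame,
                       y01: np.ndarray | None = None) -> np.ndarray:
    """Recompute OOB vote fractions from the stored bootstrap masks."""
    arr = _align(X, model.feature_names).to_numpy(float)
    n = len(arr)
    vote_pos = np.zeros(n)
    vote_n = np.zeros(n)
    for tree, inbag in zip(model.trees, model.bootstrap_masks):
        oob = ~inbag
        if oob.any():
            vote_pos[oob] += _tree_votes(tree, arr[oob])
            vote_n[oob] += 1
    with np.errstate(invalid="ignore"):
        return np.where(vote_n > 0, vote_pos / np.maximum(vote_n, 1), np.nan)


def permutation_importance(
    model: EnsembleModel,
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Mean decrease in OOB accuracy when each feature is permuted.

    Returns one row per feature with the mean accuracy drop over
    ``n_repeats`` independent permutations, both in input order
    (``importance``) and with a sorted ranking column.
    """
    X = _align(features, model.feature_names)
    y01 = (np.asarray(labels) == model.classes[1]).astype(int)
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(float)

    base = _oob_accuracy_from(model, arr, y01)
    drops = np.zeros(len(model.feature_names))
    for j in range(arr.shape[1]):
        acc_perm = []
        for _ in range(n_repeats):
            shuffled = arr.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            acc_perm.append(_oob_accuracy_from(model, shuffled, y01))
        drops[j] = base - float(np.mean(acc_perm))
    out = pd.DataFrame({"feature": model.feature_names, "importance": drops})
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out


def _oob_accuracy_from(model: EnsembleModel, arr: np.ndarray, y01: np.ndarray) -> float:
    n = len(arr)
    vote_pos = np.zeros(n)
    vote_n = np.zeros(n)
    for tree, inbag in zip(model.trees, model.bootstrap_masks):
        oob = ~inbag
        if oob.any():
            vote_pos[oob] += _tree_votes(tree, arr[oob])
            vote_n[oob] += 1
    have = vote_n > 0
    if not have.any():
        return np.nan
    pred = (vote_pos[have] / vote_n[have] > 0.5).astype(int)
    return float((pred == y01[have]).mean())


def evaluate_classifier(probs, truth01) -> dict:
    """Accuracy at 0.5, ROC points by threshold sweep, trapezoid AUC.

    With a single truth class the AUC is undefined and reported as NaN.
    """
    p = np.asarray(probs, float)
    y = np.asarray(truth01, int)
    acc = float(((p > 0.5).astype(int) == y).mean())
    if len(np.unique(y)) < 2:
        return {"accuracy": acc, "auc": np.nan, "roc": None,
                "note": "degenerate truth: single class"}
    thresholds = np.unique(np.concatenate([[-np.inf], np.sort(p), [np.inf]]))
    tpr = []
    fpr = []
    pos = (y == 1).sum()
    neg = (y == 0).sum()
    for t in thresholds[::-1]:
        call = p > t
        tpr.append((call & (y == 1)).sum() / pos)
        fpr.append((call & (y == 0)).sum() / neg)
    tpr = np.array(tpr)
    fpr = np.array(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return {"accuracy": acc, "auc": auc, "roc": roc, "note": ""}
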