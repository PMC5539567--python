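"""PA-1 online linear classifier with nested-CV model selection.

The Passive-Aggressive algorithm, type I, maintains a linear decision
function f(x) = w . x and, for each training example (x, y), y in {-1, +1},
suffers hinge loss l = max(0, 1 - y f(x)) and updates

    w <- w + tau * y * x,   tau = min(C, l / ||x||^2),

so zero-loss (margin >= 1) examples leave the model untouched and the
aggressiveness parameter C caps the step like a soft-margin slack.  The bias
is absorbed by augmenting each feature vector with a constant 1.  C is
picked from a log grid {1, 1e-1, ..., 1e-6} by stratified 3-fold inner
cross-validation maximizing balanced accuracy, and a decision-threshold
correction shifts the operating point to compensate class imbalance
(argmax of training balanced accuracy over score midpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PA1Model",
    "C_GRID",
    "pa1_update",
    "train_pa1",
    "select_C_nested_cv",
    "correct_threshold",
    "classify",
    "fit_classifier",
]

C_GRID = tuple(10.0 ** (-k) for k in range(0, 7))


@dataclass
class PA1Model:
    w: np.ndarray                 # includes the bias weight (last entry)
    C: float
    decision_offset: float = 0.0
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.w) - 1

    def save(self, path) -> None:
        np.savez(path, w=self.w, C=self.C, offset=self.decision_offset)

    @classmethod
    def load(cls, path) -> "PA1Model":
        d = np.load(path)
        return cls(d["w"], float(d["C"]), float(d["offset"]))


def _augment(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    return np.hstack([x, np.ones((x.shape[0], 1))])


def pa1_update(w: np.ndarray, x: np.ndarray, y: int, C: float) -> np.ndarray:
    """One PA-1 step on an (already augmented) example; returns new w."""
    import warnings

    w = np.asarray(w, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if w.shape != x.shape:
        raise ValueError("dimension mismatch")
    loss = max(0.0, 1.0 - y * float(w @ x))
    if loss == 0.0:
        return w
    n2 = float(x @ x)
    if n2 == 0.0:
        warnings.warn("zero feature vector with positive loss; update skipped")
        return w
    tau = min(C, loss / n2)
    return w + tau * y * x


def train_pa1(
    features: np.ndarray,
    labels: np.ndarray,
    C: float,
    epochs: int = 3,
    seed: int = 0,
) -> PA1Model:
    """Sequential PA-1 over ``epochs`` passes of the seeded-shuffled stream."""
    x = _augment(features)
    y = np.asarray(labels)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    w = np.zeros(x.shape[1])
    for _ in range(epochs):
        order = rng.permutation(len(y))
        for i in order:
            w = pa1_update(w, x[i], int(y[i]), C)
    return PA1Model(w=w, C=C, training_meta={"epochs": epochs, "seed": seed})


def _scores(model: PA1Model, features: np.ndarray) -> np.ndarray:
    return _augment(features) @ model.w


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy undefined with an empty class")
    tpr = np.count_nonzero(y_pred[pos] == 1) / np.count_nonzero(pos)
    tnr = np.count_nonzero(y_pred[neg] == -1) / np.count_nonzero(neg)
    return 0.5 * (tpr + tnr)


def correct_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision offset maximizing training balanced accuracy.

    Candidates are the midpoints between consecutive sorted unique scores,
    plus 0 and points just outside the score range; ties prefer the smallest
    |offset|.  All-equal scores return 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return 0.0
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = uniq[-1] - uniq[0]
    cands = np.concatenate([mids, [0.0, uniq[0] - 0.5 * span - 1.0,
                                   uniq[-1] + 0.5 * span + 1.0]])
    best = (  -np.inf, np.inf, 0.0)
    for off in cands:
        pred = np.where(scores - off > 0, 1, -1)
        ba = _balanced_accuracy(labels, pred)
        key = (ba, -abs(off))
        if key > (best[0], -best[1]):
            best = (ba, abs(off), off)
    return float(best[2])


def select_C_nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    grid=C_GRID,
    k: int = 3,
    seed: int = 0,
    epochs: int = 3,
) -> tuple[float, dict]:
    """C maximizing mean validation balanced accuracy over stratified folds.

    Deterministic per seed; ties prefer the smallest C.  Returns
    ``(C_star, {C: mean_val_ba})``.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    counts = [np.count_nonzero(y == cls) for cls in (-1, 1)]
    if min(counts) < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    table: dict[float, float] = {}
    for C in grid:
        bas = []
        for fold, (tr, va) in enumerate(skf.split(x, y)):
            model = train_pa1(x[tr], y[tr], C, epochs=epochs, seed=seed + fold)
            model.decision_offset = correct_threshold(_scores(model, x[tr]), y[tr])
            pred, _ = classify(model, x[va])
            bas.append(_balanced_accuracy(y[va], np.where(pred == 1, 1, -1)))
        table[C] = float(np.mean(bas))
    best_ba = max(table.values())
    c_star = min(C for C, ba in table.items() if ba == best_ba)
    return c_star, table


def classify(model: PA1Model, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binary prediction(s) and raw score(s); 1 iff score - offset > 0."""
    scores = _scores(model, x)
    preds = (scores - model.decision_offset > 0).astype(np.uint8)
    if np.ndim(x) == 1:
        return preds[0], scores[0]
    return preds, scores


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    grid=C_GRID,
    seed: int = 0,
    epochs: int = 3,
) -> PA1Model:
    """Full training recipe: inner-CV C selection, final PA-1 fit on all
    data, then threshold correction on the training scores."""
    c_star, table = select_C_nested_cv(features, labels, grid, seed=seed,
                                       epochs=epochs)
    model = train_pa1(features, labels, c_star, epochs=epochs, seed=seed)
    model.decision_offset = correct_threshold(_scores(model, features), labels)
    model.training_meta.update({"C_grid": tuple(grid), "cv_table": table})
    return model
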