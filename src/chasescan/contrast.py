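"""SVM classification movies contrasting two saccade sample classes.

A linear support vector machine trained on vectorized rendered sample
movies yields a weight vector that reshapes back into movie geometry --
the classification movie.  Cross-validated accuracy is compared against
the majority-class chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

__all__ = ["ContrastResult", "chance_level", "train_contrast"]


@dataclass
class ContrastResult:
    cv_accuracy: float              # %
    chance_accuracy: float          # %
    weight_movie: np.ndarray        # (T, H, W) decision-function weights
    classification_movie_pos: np.ndarray  # binary maxima movie
    classification_movie_neg: np.ndarray  # binary minima movie
    best_C: float
    n_pos: int
    n_neg: int


def chance_level(n_pos: int, n_neg: int) -> float:
    """Majority-class chance performance in percent."""
    if n_pos + n_neg == 0:
        raise ValueError("no samples")
    return 100.0 * max(n_pos, n_neg) / (n_pos + n_neg)


def train_contrast(movies_pos, movies_neg, folds: int = 10, seed: int = 0,
                   Cs=(0.001, 0.01, 0.1, 1.0)) -> ContrastResult:
    """Train the linear SVM contrast and derive classification movies.

    ``movies_pos``/``movies_neg`` are equal-shape (T, H, W) rendered
    sample movies.  Accuracy is stratified k-fold cross-validation with
    the regularization constant C chosen by nested 3-fold grid search;
    the grid reaches down to strong regularization because movies have
    far more pixels than there are samples.  The weight movie comes
    from a final fit on all samples, and the binary classification
    movies threshold it at mean +/- 2 sd.
    """
    movies_pos = [np.asarray(m) for m in movies_pos]
    movies_neg = [np.asarray(m) for m in movies_neg]
    if not movies_pos or not movies_neg:
        raise ValueError("both classes need samples")
    shape = movies_pos[0].shape
    X = np.stack([m.ravel() for m in movies_pos + movies_neg]).astype(np.float64)
    y = np.concatenate([np.ones(len(movies_pos), dtype=int),
                        np.zeros(len(movies_neg), dtype=int)])
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("need at least 2 samples per class")

    inner = StratifiedKFold(3, shuffle=True, random_state=seed + 1)
    grid = GridSearchCV(LinearSVC(dual=False), {"C": list(Cs)}, cv=inner)
    outer = StratifiedKFold(folds, shuffle=True, random_state=seed)
    acc = cross_val_score(grid, X, y, cv=outer).mean() * 100.0

    grid.fit(X, y)
    w = grid.best_estimator_.coef_.ravel().reshape(shape)
    thr_hi = w.mean() + 2 * w.std()
    thr_lo = w.mean() - 2 * w.std()
    return ContrastResult(
        cv_accuracy=float(acc),
        chance_accuracy=chance_level(len(movies_pos), len(movies_neg)),
        weight_movie=w,
        classification_movie_pos=(w > thr_hi),
        classification_movie_neg=(w < thr_lo),
        best_C=float(grid.best_params_["C"]),
        n_pos=len(movies_pos),
        n_neg=len(movies_neg),
    )
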