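"""Unweighted Elkan–Noto positive-unlabeled classification.

The training data carry a *known* flag s per example: s = 1 for labeled
positives (y = 1 certain), s = 0 for unlabeled examples (y unknown).
Under the selected-completely-at-random assumption, a probabilistic
classifier g(x) ≈ p(s = 1 | x) trained on s relates to the true class
posterior through the labeling propensity c = p(s = 1 | y = 1):

    p(y = 1 | x) = p(s = 1 | x) / c.

c is estimated as the mean of g over labeled positives held out from
base-learner training.  No class re-weighting is applied (the
"unweighted" estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.svm import SVC

__all__ = ["ElkanNotoClassifier", "default_base_learner", "permutation_importance"]


def default_base_learner(seed: int | None = None) -> SVC:
    """RBF support-vector classifier with calibrated probabilities.

    C = 10, gamma = 0.4, probability calibration enabled — the reference
    configuration for this screening task.  Any estimator exposing
    ``fit(X, s)`` and ``predict_proba`` may be substituted.
    """
    return SVC(C=10, kernel="rbf", gamma=0.4, probability=True, random_state=seed)


@dataclass
class ElkanNotoClassifier:
    """One fitted PU classifier: base learner + labeling propensity c.

    Parameters
    ----------
    base_learner : estimator, optional
        Probabilistic binary classifier; cloned before fitting.  Defaults
        to :func:`default_base_learner`.
    holdout_fraction : float
        Fraction of labeled positives reserved (never seen by the base
        learner) to estimate c.  Default 0.1.
    seed : int
        Drives the holdout split and the base learner's internal
        randomness (probability-calibration folds).
    """

    base_learner: Any = None
    holdout_fraction: float = 0.1
    seed: int = 0

    c_: float = field(default=None, init=False, repr=False)
    base_: Any = field(default=None, init=False, repr=False)
    holdout_idx_: np.ndarray = field(default=None, init=False, repr=False)
    n_features_: int = field(default=None, init=False, repr=False)

    def fit(self, X: np.ndarray, s: np.ndarray) -> "ElkanNotoClassifier":
        """Fit on features X and known-flags s (1 = labeled positive).

        Raises ``ValueError`` if either class is missing, if fewer than
        2 labeled positives or unlabeled examples are present, or if the
        estimated c collapses to 0 (degenerate holdout).
        """
        X = np.asarray(X, dtype=float)
        s = np.asarray(s).astype(int)
        if X.shape[0] != s.shape[0]:
            raise ValueError("X and s length mismatch")
        pos_idx = np.flatnonzero(s == 1)
        unl_idx = np.flatnonzero(s == 0)
        if len(pos_idx) < 2 or len(unl_idx) < 2:
            raise ValueError(
                "need at least 2 labeled positives and 2 unlabeled examples "
                f"(got {len(pos_idx)} / {len(unl_idx)})"
            )
        rng = np.random.default_rng(self.seed)
        n_hold = max(1, int(round(self.holdout_fraction * len(pos_idx))))
        perm = rng.permutation(len(pos_idx))
        self.holdout_idx_ = pos_idx[perm[:n_hold]]
        train_pos = pos_idx[perm[n_hold:]]
        if len(train_pos) < 1:
            raise ValueError("holdout consumed all labeled positives; lower holdout_fraction")

        base = self.base_learner if self.base_learner is not None \
            else default_base_learner(self.seed)
        self.base_ = clone(base)
        if hasattr(self.base_, "random_state"):
            self.base_.set_params(random_state=self.seed)
        train_idx = np.concatenate([train_pos, unl_idx])
        self.base_.fit(X[train_idx], s[train_idx])

        p_hold = self._proba_s(X[self.holdout_idx_])
        self.c_ = float(np.mean(p_hold))
        if self.c_ <= 0:
            raise ValueError(
                "estimated labeling propensity c = 0; the holdout positives "
                "all scored 0 — use a larger holdout or a better base learner"
            )
        self.n_features_ = X.shape[1]
        return self

    def _proba_s(self, X: np.ndarray) -> np.ndarray:
        """Calibrated p(s = 1 | x) from the base learner."""
        classes = list(self.base_.classes_)
        return self.base_.predict_proba(X)[:, classes.index(1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """p(y = 1 | x) = min(1, p(s = 1 | x) / c), in [0, 1].

        Monotone in the base learner's output, so rankings are preserved.
        """
        if self.c_ is None:
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features_}, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return np.minimum(self._proba_s(X) / self.c_, 1.0)


def permutation_importance(model: ElkanNotoClassifier, X: np.ndarray,
                           y: np.ndarray, n_repeats: int = 10,
                           threshold: float = 0.5,
                           seed: int = 0) -> np.ndarray:
    """Per-feature mean accuracy loss under within-column scrambling.

    Each feature column is independently shuffled ``n_repeats`` times;
    the loss is baseline accuracy minus the mean accuracy over shuffles,
    where accuracy thresholds the PU output at ``threshold`` against the
    known evaluation labels ``y``.  Deterministic for a fixed seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)

    def accuracy(mat: np.ndarray) -> float:
        pred = (model.predict_proba(mat) >= threshold).astype(int)
        return float(np.mean(pred == y))

    baseline = accuracy(X)
    losses = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            acc += accuracy(Xp)
        losses[j] = baseline - acc / n_repeats
    return losses
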