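"""All-relevant feature selection with shadow features (Boruta).

Each iteration appends a column-permuted ("shadow") copy of every still-open
feature, fits a Random Forest on the augmented matrix and scores a *hit* for
every real feature whose importance exceeds the best shadow importance.
After each iteration a two-sided binomial test on the accumulated hit counts
(p = 0.5 under the null), Bonferroni-adjusted over the initial feature count,
confirms clear winners and rejects clear losers; rejected features are
dropped from subsequent iterations.  Features still undecided when the
iteration budget runs out remain tentative (not confirmed).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Boruta wrapper feature selection, scikit-learn estimator style.

    Parameters
    ----------
    n_estimators : int
        Trees in the internal importance forest.  Shallow forests (depth
        ``max_depth``) give better-separated importance nulls and are much
        cheaper inside cross-validation loops.
    max_iter : int
        Iteration budget; the loop stops early once every feature is decided.
    alpha : float
        Significance level of the binomial decision test, Bonferroni-adjusted
        over the initial number of features.
    max_depth : int or None
        Depth of the internal forest's trees.
    random_state : int
        Seed for shadow permutations and the internal forests.

    Attributes
    ----------
    support_ : bool array, shape (n_features,) — confirmed features.
    tentative_ : bool array — undecided at termination.
    hits_ : int array — shadow-beating hit counts.
    n_iter_ : int — iterations actually run.
    importances_mean_ : float array — mean importance of each feature over
        the iterations in which it was still open (NaN if never scored).
    """

    def __init__(self, n_estimators: int = 30, max_iter: int = 20,
                 alpha: float = 0.01, max_depth=5, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValueError("Boruta needs at least 2 samples of each class")
        n_features = X.shape[1]
        rng = np.random.default_rng(self.random_state)

        hits = np.zeros(n_features, dtype=int)
        decided = np.zeros(n_features, dtype=int)  # 0 open, +1 confirmed, -1 rejected
        imp_sums = np.zeros(n_features)
        imp_counts = np.zeros(n_features, dtype=int)
        bonferroni = self.alpha / n_features

        n_iter = 0
        for it in range(self.max_iter):
            open_idx = np.flatnonzero(decided >= 0)  # confirmed features stay in the forest
            if not np.flatnonzero(decided == 0).size:
                break
            n_iter = it + 1
            shadows = X[:, open_idx].copy()
            for c in range(shadows.shape[1]):
                rng.shuffle(shadows[:, c])
            augmented = np.hstack([X[:, open_idx], shadows])
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                max_features="sqrt",
                random_state=int(rng.integers(2 ** 31)),
                n_jobs=1,
            )
            forest.fit(augmented, y)
            importances = forest.feature_importances_
            real_imp = importances[:open_idx.size]
            shadow_max = importances[open_idx.size:].max() if open_idx.size else 0.0
            hits[open_idx] += (real_imp > shadow_max).astype(int)
            imp_sums[open_idx] += real_imp
            imp_counts[open_idx] += 1

            undecided = np.flatnonzero(decided == 0)
            trials = imp_counts[undecided]
            p_hi = stats.binom.sf(hits[undecided] - 1, trials, 0.5)
            p_lo = stats.binom.cdf(hits[undecided], trials, 0.5)
            decided[undecided[p_hi < bonferroni]] = 1
            decided[undecided[p_lo < bonferroni]] = -1

        self.support_ = decided == 1
        self.tentative_ = decided == 0
        self.hits_ = hits
        self.n_iter_ = n_iter
        with np.errstate(invalid="ignore"):
            self.importances_mean_ = np.where(
                imp_counts > 0, imp_sums / np.maximum(imp_counts, 1), np.nan)
        self.n_features_in_ = n_features
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
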