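"""All-relevant feature selection via the Boruta shadow-feature scheme.

Each iteration appends one independently permuted "shadow" copy of every real
feature, asks an importance oracle (a random forest by default) for scores
over the extended matrix, and credits a hit to every real feature whose
importance exceeds the best shadow.  Hit counts are then compared against
Binomial(iterations, 1/2) with two-sided tests under Bonferroni correction:
significantly more hits than chance confirms a feature, significantly fewer
rejects it, and whatever is undecided at the iteration cap stays tentative.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"


def _rf_importance(X: np.ndarray, y: np.ndarray, seed: int, n_estimators: int):
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    rf.fit(X, y)
    return rf.feature_importances_


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Boruta all-relevant selector with a pluggable importance oracle.

    Parameters
    ----------
    importance : callable ``(X_extended, y, seed) -> importances`` or None
        Permutation-invariant ensemble importance; None uses a random forest.
    n_estimators : trees of the default forest oracle.
    max_iter : iteration cap; undecided features end tentative.
    alpha : significance level of the Bonferroni-corrected binomial gate.
    early_stop : stop as soon as no feature is undecided.

    Fitted attributes: ``support_`` (confirmed mask), ``support_tentative_``,
    ``status_`` (per-feature strings), ``hits_``, ``n_iter_``,
    ``importance_history_`` (iterations x features).
    """

    def __init__(
        self,
        importance: Callable | None = None,
        n_estimators: int = 40,
        max_iter: int = 30,
        alpha: float = 0.05,
        random_state: int | None = None,
        early_stop: bool = True,
    ):
        self.importance = importance
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state
        self.early_stop = early_stop

    def _oracle(self, X, y, seed):
        if self.importance is not None:
            return np.asarray(self.importance(X, y, seed), dtype=float)
        return _rf_importance(X, y, seed, self.n_estimators)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        self.n_features_in_ = p
        if p == 0:
            self.support_ = np.zeros(0, dtype=bool)
            self.support_tentative_ = np.zeros(0, dtype=bool)
            self.status_ = np.array([], dtype=object)
            self.hits_ = np.zeros(0, dtype=int)
            self.n_iter_ = 0
            self.importance_history_ = np.zeros((0, 0))
            return self
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"y must be binary, got classes {classes}")
        if n < 10:
            raise ValueError("need at least 10 samples")
        rng = np.random.default_rng(self.random_state)

        status = np.zeros(p, dtype=int)  # 0 tentative / 1 confirmed / -1 rejected
        hits = np.zeros(p, dtype=int)
        history = []
        it = 0
        for it in range(1, self.max_iter + 1):
            active = status >= 0  # rejected features leave the matrix
            Xa = X[:, active]
            pa = Xa.shape[1]
            shadows = rng.permuted(Xa, axis=0)  # each column shuffled independently
            Xe = np.hstack([Xa, shadows])
            try:
                imp = self._oracle(Xe, y, int(rng.integers(0, 2**31 - 1)))
            except Exception as exc:
                raise RuntimeError(f"importance oracle failed at iteration {it}") from exc
            row = np.full(p, np.nan)
            row[active] = imp[:pa]
            history.append(row)
            thresh = imp[pa:].max()
            hits[active] += imp[:pa] > thresh
            # two-sided exact binomial vs 0.5, Bonferroni over all features
            cdf = binom.cdf(hits, it, 0.5)
            sf = binom.sf(hits - 1, it, 0.5)
            ptwo = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
            sig = ptwo < self.alpha / p
            und = status == 0
            status[und & sig & (hits * 2 > it)] = 1
            status[und & sig & (hits * 2 < it)] = -1
            if self.early_stop and not (status == 0).any():
                break
        self.hits_ = hits
        self.n_iter_ = it
        self.importance_history_ = np.array(history)
        self.status_ = np.array(
            [CONFIRMED if s == 1 else REJECTED if s == -1 else TENTATIVE for s in status],
            dtype=object,
        )
        self.support_ = status == 1
        self.support_tentative_ = status == 0
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def selected_features(
    selector: BorutaSelector,
    feature_names: Sequence | None = None,
    policy: str = "confirmed",
) -> list:
    """Feature list under the given policy (confirmed, or confirmed+tentative)."""
    check_is_fitted(selector, "support_")
    if policy == "confirmed":
        mask = selector.support_
    elif policy == "confirmed+tentative":
        mask = selector.support_ | selector.support_tentative_
    else:
        raise ValueError(f"unknown policy {policy!r}")
    idx = np.nonzero(mask)[0]
    if feature_names is not None:
        return [feature_names[i] for i in idx]
    return list(idx)
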