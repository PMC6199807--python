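"""Smoking-prediction models: per-target logistic fits stacked into a
combined classifier, evaluated on a held-out half of the cohort.

Three model variants are compared on identical train/test splits:

* ``index`` — one CpG per target, the EWAS index CpG;
* ``boruta`` — per-target CpGs confirmed by Boruta on covariate residuals;
* ``boruta.adjusted`` — as ``boruta``, but the haplotype allele is also
  regressed out before selection and fitting.

Training operates on haplotype rows (each row contributes once); prediction
is per subject, averaging the two haplotype rows of heterozygotes.  The
stacked logistic model combines the per-target probabilities; subjects
missing a target's prediction receive that target's train-set mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._util import expit
from .boruta import BorutaSelector, selected_features
from .haplo import ALT, HaploMethMatrix, to_logit
from .stats import residualize, _expand_design
from .targets import TargetDef


def split_train_test(
    samples, seed: int, stratify=None
) -> tuple[list, list]:
    """Random 1:1 split into train and test sets (sizes differ by <= 1).

    Unstratified by default; passing per-sample binary labels stratifies the
    split within each class.  Reproducible under ``seed``.
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(len(samples))
        half = len(samples) - len(samples) // 2
        train = [samples[i] for i in perm[:half]]
        test = [samples[i] for i in perm[half:]]
    else:
        labels = np.asarray(stratify)
        train, test = [], []
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            perm = rng.permutation(idx)
            half = len(idx) - len(idx) // 2
            train.extend(samples[i] for i in perm[:half])
            test.extend(samples[i] for i in perm[half:])
    return sorted(train), sorted(test)


class PenalizedLogit(ClassifierMixin, BaseEstimator):
    """Maximum-likelihood logistic regression with a mild ridge guard.

    Features are standardized internally and an L2 penalty ``l2`` (default
    1e-4) applies to the standardized slopes, never the intercept — a
    numerical stabilizer against perfect separation in ~77-row fits, not a
    model change.  Fitting is Newton/IRLS on the penalized log-likelihood.

    ``coef_`` / ``intercept_`` are in standardized space; ``coef_orig_`` /
    ``intercept_orig_`` map back to the input scale.
    """

    def __init__(self, l2: float = 1e-4, max_iter: int = 100, tol: float = 1e-12):
        self.l2 = l2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("bad X/y shapes")
        self.classes_ = np.array([0, 1])
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        Z = np.hstack([np.ones((n, 1)), Xs])
        lam = np.full(p + 1, self.l2)
        lam[0] = 0.0
        beta = np.zeros(p + 1)
        for _ in range(self.max_iter):
            eta = Z @ beta
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = Z.T @ (y - mu) - lam * beta
            H = (Z * w[:, None]).T @ Z + np.diag(lam + 1e-12)
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                break
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.coef_orig_ = self.coef_ / self.scale_
        self.intercept_orig_ = self.intercept_ - float(
            np.sum(self.coef_ * self.mean_ / self.scale_)
        )
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean_) / self.scale_
        return self.intercept_ + Xs @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def predict_target(model: PenalizedLogit, rows: pd.DataFrame) -> pd.Series:
    """Per-subject probability for one target: the model probability of each
    haplotype row, averaged over the (1 or 2) rows of every subject."""
    probs = pd.Series(
        model.predict_proba(rows.to_numpy())[:, 1], index=rows.index
    )
    return probs.groupby(level="sample").mean()


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC step curve and rank-based (Mann-Whitney, ties = 1/2) AUC."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    order = np.argsort(-s, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    # collapse tied thresholds
    distinct = np.nonzero(np.diff(s[order]))[0]
    idx = np.r_[distinct, len(ys) - 1]
    tpr = np.r_[0.0, tps[idx] / npos]
    fpr = np.r_[0.0, fps[idx] / nneg]
    return fpr, tpr, float(auc)


@dataclass
class ModelReport:
    name: str
    selected: dict[str, list]  # target -> chosen CpG columns
    target_coefs: dict[str, np.ndarray]
    stacked_coef: np.ndarray
    stacked_intercept: float
    train_subjects: list[str]
    test_subjects: list[str]
    test_scores: pd.Series
    test_labels: pd.Series
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    auc: float = float("nan")


def _nearest_column(columns, pos: int | None):
    cols = list(columns)
    if pos is None:
        return cols[len(cols) // 2]
    return min(cols, key=lambda c: abs(int(c) - pos))


def _subject_table(
    per_target: dict[str, pd.Series], subjects: list[str], fill: pd.Series | None = None
) -> pd.DataFrame:
    tab = pd.DataFrame(index=pd.Index(subjects, name="sample"))
    for label, s in per_target.items():
        tab[label] = s.reindex(subjects)
    if fill is None:
        fill = tab.mean(axis=0)
    return tab.fillna(fill), fill


def evaluate_three_models(
    matrix: HaploMethMatrix,
    covariates: pd.DataFrame,
    targets: list[TargetDef],
    seed: int,
    boruta_kwargs: dict | None = None,
    l2: float = 1e-4,
    stratify: bool = False,
) -> dict[str, ModelReport]:
    """Run the index / boruta / boruta.adjusted comparison end to end.

    ``matrix`` must already be QC-filtered, masked and imputed.  All three
    models share one train/test subject split; feature selection and every
    fit see train rows only.  Returns one ModelReport per model with ROC and
    AUC computed on the held-out test subjects.
    """
    boruta_kwargs = dict(boruta_kwargs or {})
    logits = to_logit(matrix)
    by_label = {t.gene_label: t for t in targets}
    subjects = matrix.samples()
    y_subj = covariates.loc[subjects, "smoking"].astype(int)
    strat = y_subj.to_numpy() if stratify else None
    train, test = split_train_test(subjects, seed, stratify=strat)
    train_set = set(train)

    # residual views: plain (age/gender/diagnosis) and haplotype-adjusted
    resid_plain, resid_adj = {}, {}
    for label, df in logits.items():
        design = _expand_design(df.index, covariates, ("age", "gender", "diagnosis"))
        resid_plain[label] = residualize(df, design, drop_constant=True, drop_collinear=True)
        design_a = design.copy()
        design_a["allele"] = (df.index.get_level_values("allele") == ALT).astype(float)
        resid_adj[label] = residualize(df, design_a, drop_constant=True, drop_collinear=True)

    ss = np.random.SeedSequence((int(seed), 97))
    target_seeds = {
        label: int(child.generate_state(1)[0] % (2**31 - 1))
        for child, label in zip(ss.spawn(len(logits)), sorted(logits))
    }

    specs = {
        "index": (resid_plain, "index"),
        "boruta": (resid_plain, "boruta"),
        "boruta.adjusted": (resid_adj, "boruta"),
    }
    reports = {}
    for name, (resid, selection) in specs.items():
        per_target_train, per_target_test = {}, {}
        selected_cols, coefs = {}, {}
        for label, frame in resid.items():
            t = by_label.get(label)
            index_col = _nearest_column(frame.columns, t.index_cpg_pos if t else None)
            row_train = np.array(
                [s in train_set for s in frame.index.get_level_values("sample")]
            )
            y_rows = (
                covariates.loc[frame.index.get_level_values("sample"), "smoking"]
                .astype(int)
                .to_numpy()
            )
            if selection == "index" or row_train.sum() < 10:
                # Boruta needs a workable training set; starved targets fall
                # back to the index CpG, as when nothing is confirmed
                cols = [index_col]
            else:
                sel = BorutaSelector(
                    random_state=target_seeds[label], **boruta_kwargs
                ).fit(frame.loc[row_train].to_numpy(), y_rows[row_train])
                cols = selected_features(sel, feature_names=list(frame.columns))
                if not cols:
                    cols = [index_col]  # fallback: the EWAS index CpG
            selected_cols[label] = cols
            model = PenalizedLogit(l2=l2).fit(
                frame.loc[row_train, cols].to_numpy(), y_rows[row_train]
            )
            coefs[label] = np.r_[model.intercept_orig_, model.coef_orig_]
            per_target_train[label] = predict_target(model, frame.loc[row_train, cols])
            per_target_test[label] = predict_target(model, frame.loc[~row_train, cols])

        train_tab, fill = _subject_table(per_target_train, train)
        stacked = PenalizedLogit(l2=l2).fit(
            train_tab.to_numpy(), y_subj.loc[train].to_numpy()
        )
        test_tab, _ = _subject_table(per_target_test, test, fill=fill)
        scores = pd.Series(
            stacked.predict_proba(test_tab.to_numpy())[:, 1], index=test_tab.index
        )
        fpr, tpr, auc = roc_auc(scores.to_numpy(), y_subj.loc[test].to_numpy())
        reports[name] = ModelReport(
            name=name,
            selected=selected_cols,
            target_coefs=coefs,
            stacked_coef=stacked.coef_orig_.copy(),
            stacked_intercept=stacked.intercept_orig_,
            train_subjects=list(train),
            test_subjects=list(test),
            test_scores=scores,
            test_labels=y_subj.loc[test],
            fpr=fpr,
            tpr=tpr,
            auc=auc,
        )
    return reports
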