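"""Covariate residualization and per-CpG association testing.

Binary covariates (smoking, gender, diagnosis, haplotype allele) are tested
per CpG by a two-tailed Welch t test; the continuous covariate (age) by the
t statistic of its OLS slope.  P values are Benjamini-Hochberg adjusted, by
default within one target's CpG family.  Before testing a covariate, the
remaining covariates are regressed out and the residuals carry the signal —
the ASM contrast compares the two allele groups of haplotype-resolved rows
after removing age, gender and diagnosis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .haplo import ALT, HaploMethMatrix, to_logit


def _design_matrix(design: pd.DataFrame, drop_constant: bool) -> pd.DataFrame:
    X = design.copy().astype(float)
    if drop_constant:
        keep = [c for c in X.columns if X[c].nunique() > 1]
        X = X[keep]
    X.insert(0, "_intercept", 1.0)
    return X


def residualize(
    M: pd.DataFrame,
    design: pd.DataFrame,
    drop_constant: bool = False,
    drop_collinear: bool = False,
) -> pd.DataFrame:
    """OLS residuals of every column of ``M`` on the covariate design.

    The design gains an intercept; a rank-deficient design raises an error
    naming the collinear columns.  ``drop_constant`` silently removes
    constant columns first; ``drop_collinear`` additionally keeps only a
    rank-increasing subset (useful for small cohorts where covariates
    coincide by chance).  Residuals are orthogonal to every retained design
    column to numerical precision.
    """
    if not M.index.equals(design.index):
        raise ValueError("matrix and design rows are not aligned")
    X = _design_matrix(design, drop_constant)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name the columns that do not add rank
        bad, kept = [], []
        for c in X.columns:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(c)
            else:
                bad.append(c)
        if not drop_collinear:
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        X = X[kept]
        Xv = X.to_numpy()
    Y = M.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    resid = Y - Xv @ beta
    return pd.DataFrame(resid, index=M.index, columns=M.columns)


def covariate_test(values: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """Per-column association test against one covariate.

    Binary covariates: two-sample two-tailed Welch t test; continuous:
    t test of the OLS slope.  Returns a frame indexed by column with
    ``stat``, ``p``, ``direction`` and ``testable`` (False when a group has
    fewer than two observations).
    """
    if not values.index.equals(covariate.index):
        raise ValueError("values and covariate rows are not aligned")
    x = covariate.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    uniq = np.unique(x[~np.isnan(x)])
    cols = values.columns
    if set(uniq) <= {0.0, 1.0}:
        g1, g0 = Y[x == 1.0], Y[x == 0.0]
        if len(g1) < 2 or len(g0) < 2:
            return pd.DataFrame(
                {
                    "stat": np.nan,
                    "p": np.nan,
                    "direction": 0.0,
                    "testable": False,
                },
                index=cols,
            )
        t, p = sps.ttest_ind(g1, g0, equal_var=False, axis=0)
        direction = np.sign(np.nanmean(g1, axis=0) - np.nanmean(g0, axis=0))
    else:
        n = len(x)
        if n < 3:
            return pd.DataFrame(
                {"stat": np.nan, "p": np.nan, "direction": 0.0, "testable": False},
                index=cols,
            )
        xc = x - x.mean()
        sxx = float(np.sum(xc**2))
        beta = (xc @ Y) / sxx
        fitted = np.outer(xc, beta) + Y.mean(axis=0)
        rss = np.sum((Y - fitted) ** 2, axis=0)
        se = np.sqrt(rss / (n - 2) / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        direction = np.sign(beta)
    return pd.DataFrame(
        {"stat": t, "p": np.clip(p, 0.0, 1.0), "direction": direction, "testable": True},
        index=cols,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1).

    NaN entries are passed through untouched and do not count toward the
    family size.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _expand_design(
    rows: pd.MultiIndex, covariates: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    samples = rows.get_level_values("sample")
    design = covariates.loc[samples, list(columns)].astype(float)
    design.index = rows
    return design


def asm_test(
    matrix: HaploMethMatrix,
    covariates: pd.DataFrame,
    adjust_for: Sequence[str] = ("age", "gender", "diagnosis"),
) -> dict[str, pd.DataFrame]:
    """Allele-specific methylation scan per target.

    Heterozygous samples' two haplotype rows are residualized on the listed
    covariates; the ref vs alt allele groups are then compared per CpG by a
    Welch t test with BH adjustment within the target.  Returns per-target
    result frames (stat, p, adj_p, direction).
    """
    logits = to_logit(matrix)
    results = {}
    for label, df in logits.items():
        samples = df.index.get_level_values("sample")
        counts = pd.Series(samples).value_counts()
        het = set(counts[counts == 2].index)
        sub = df[[s in het for s in samples]]
        if sub.empty or len(het) < 2:
            continue
        design = _expand_design(sub.index, covariates, adjust_for)
        resid = residualize(sub, design, drop_constant=True, drop_collinear=True)
        allele = pd.Series(
            (sub.index.get_level_values("allele") == ALT).astype(float),
            index=sub.index,
        )
        res = covariate_test(resid, allele)
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
        results[label] = res
    return results


def covariate_scan(
    matrix: HaploMethMatrix,
    covariates: pd.DataFrame,
    test_covariates: Sequence[str] = ("smoking", "gender", "diagnosis", "age"),
    family: str = "target",
) -> pd.DataFrame:
    """Per-CpG tests of each covariate across all targets.

    For each covariate the others are regressed out first.  ``family``
    chooses the BH family: "target" adjusts within each target's CpGs (the
    default), "pooled" across every CpG of every target.  Returns a long
    frame (target, pos, covariate, stat, p, adj_p, direction).
    """
    if family not in ("target", "pooled"):
        raise ValueError("family must be 'target' or 'pooled'")
    logits = to_logit(matrix)
    rows = []
    for label, df in logits.items():
        for cov in test_covariates:
            others = [c for c in test_covariates if c != cov]
            design = _expand_design(df.index, covariates, others)
            resid = residualize(df, design, drop_constant=True, drop_collinear=True)
            target_cov = _expand_design(df.index, covariates, [cov])[cov]
            res = covariate_test(resid, target_cov)
            for pos, r in res.iterrows():
                rows.append((label, pos, cov, r["stat"], r["p"], r["direction"]))
    out = pd.DataFrame(
        rows, columns=["target", "pos", "covariate", "stat", "p", "direction"]
    )
    out["adj_p"] = np.nan
    if family == "pooled":
        for cov in test_covariates:
            m = out["covariate"] == cov
            out.loc[m, "adj_p"] = bh_adjust(out.loc[m, "p"].to_numpy())
    else:
        for (label, cov), idx in out.groupby(["target", "covariate"]).groups.items():
            out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out
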