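"""Population-level genetic contribution and prediction.

The phenotype of each accession is modelled as a multiple linear
regression on the functional-marker genotypes of the cloned genes,

    Y = g0 + g1 Marker1 + g2 Marker2 + ... + gi Markeri + e,

with each gene's allele series coded as categorical indicator variables
(one-hot minus a reference allele, the most frequent one): functional
markers are multi-allelic gene classes, not SNP dosages.  The raw R^2 is
the total genetic contribution; per-gene contributions are Johnson
relative weights (importance apportioned through an orthogonal
approximation of the predictors, summing to R^2); predictive ability is
the Pearson correlation between observed phenotypes and out-of-fold
predictions under seeded 10-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .io import GradmapError

log = logging.getLogger("gradmap.effects")


@dataclass
class MarkerCodingScheme:
    """Indicator coding of each gene's allele series (reference omitted)."""

    reference: dict[str, str]            # gene -> reference allele
    columns: list[tuple[str, str]]       # (gene, allele) per design column
    dropped_genes: list[str]             # monomorphic or all-missing


def code_markers(
    alleles: pd.DataFrame,
) -> tuple[MarkerCodingScheme, pd.DataFrame]:
    """Build the indicator design matrix from an accession x gene allele table.

    The most frequent allele of each gene is the (omitted) reference.
    Rows with any missing call are excluded from the design and flagged;
    monomorphic genes are dropped with a warning.
    """
    keep_rows = alleles.notna().all(axis=1)
    if not keep_rows.all():
        log.info("excluding %d accessions with missing allele calls", (~keep_rows).sum())
    sub = alleles.loc[keep_rows]
    reference: dict[str, str] = {}
    cols: list[tuple[str, str]] = []
    dropped: list[str] = []
    data = {}
    for gene in alleles.columns:
        counts = sub[gene].value_counts()
        if len(counts) < 2:
            warnings.warn(f"gene {gene!r} is monomorphic or all-missing; dropped")
            dropped.append(gene)
            continue
        ref = counts.index[0]  # most frequent; value_counts ties break stably
        reference[gene] = ref
        for allele in sorted(a for a in counts.index if a != ref):
            cols.append((gene, allele))
            data[f"{gene}[{allele}]"] = (sub[gene] == allele).astype(float)
    if not cols:
        raise GradmapError("no polymorphic gene to code")
    design = pd.DataFrame(data, index=sub.index)
    return MarkerCodingScheme(reference=reference, columns=cols, dropped_genes=dropped), design


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[int]]:
    """Indices of a maximal independent column subset (pivoted QR)."""
    Xc = np.column_stack([np.ones(len(X)), X])
    r = np.linalg.matrix_rank(Xc)
    if r == Xc.shape[1]:
        return X, list(range(X.shape[1]))
    from scipy.linalg import qr

    _, _, piv = qr(Xc, pivoting=True, mode="economic")
    keep_aug = sorted(piv[:r])
    keep = [j - 1 for j in keep_aug if j > 0][: r - 1]
    aliased = [names[j] for j in range(X.shape[1]) if j not in keep]
    warnings.warn(f"rank-deficient design; dropped aliased columns: {aliased}")
    return X[:, keep], keep


class FunctionalMarkerRegression(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares model of a trait on functional-marker alleles.

    Parameters
    ----------
    min_rows_over_cols : int
        Required excess of observations over design columns.

    Attributes (after :meth:`fit`)
    ------------------------------
    coding_ : MarkerCodingScheme
    design_ : pd.DataFrame            fitted design matrix (indicators)
    intercept_ : float                g0, trait units
    coef_ : pd.Series                 g1..gi per indicator column, trait units
    r2_ : float                       raw in-sample R^2
    importance_ : pd.Series           per-gene Johnson relative weights (sum = R^2)
    residual_var_ : float             variance of e, trait units squared
    """

    def __init__(self, min_rows_over_cols: int = 2):
        self.min_rows_over_cols = min_rows_over_cols

    def fit(self, alleles: pd.DataFrame, y: pd.Series) -> "FunctionalMarkerRegression":
        import statsmodels.api as sm

        coding, design = code_markers(alleles)
        y = pd.Series(y).reindex(design.index)
        ok = y.notna()
        design, y = design.loc[ok], y.loc[ok]
        if len(design) < design.shape[1] + self.min_rows_over_cols:
            raise GradmapError(
                f"need >= {design.shape[1] + self.min_rows_over_cols} rows, have {len(design)}"
            )
        X = design.to_numpy(dtype=float)
        Xk, keep = _drop_aliased(X, list(design.columns))
        design = design.iloc[:, keep]
        res = sm.OLS(y.to_numpy(dtype=float), sm.add_constant(Xk)).fit()
        self.coding_ = coding
        self.design_ = design
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=design.columns)
        self.r2_ = float(res.rsquared)
        self.residual_var_ = float(res.resid.var(ddof=design.shape[1] + 1))
        self.y_ = y
        self.importance_ = relative_importance(self, design, y)
        return self

    def _design_for(self, alleles: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for gene, allele in self.coding_.columns:
            name = f"{gene}[{allele}]"
            if name in self.design_.columns:
                cols[name] = (alleles[gene] == allele).astype(float)
        return pd.DataFrame(cols, index=alleles.index)[self.design_.columns]

    def predict(self, alleles: pd.DataFrame) -> pd.Series:
        X = self._design_for(alleles)
        return pd.Series(
            self.intercept_ + X.to_numpy(dtype=float) @ self.coef_.to_numpy(),
            index=alleles.index,
        )


def fit_effects(alleles: pd.DataFrame, phenotypes: pd.Series) -> FunctionalMarkerRegression:
    """Fit the multi-marker effects model (thin wrapper over the estimator)."""
    return FunctionalMarkerRegression().fit(alleles, phenotypes)


def relative_importance(
    fit: FunctionalMarkerRegression, design: pd.DataFrame, y: pd.Series
) -> pd.Series:
    """Per-gene Johnson relative weights.

    Predictors are orthogonalised through the symmetric square root of
    their correlation matrix; each column's weight is the variance it
    carries of the orthogonal regression, and gene-level importance sums a
    gene's indicator columns.  Weights are non-negative and sum to the
    model R^2 (duplicated or collinear columns split their share).
    """
    X = design.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    p = X.shape[1]
    genes = [c.split("[")[0] for c in design.columns]
    if p == 0:
        raise GradmapError("no predictors")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yz = (yv - yv.mean()) / yv.std(ddof=1)
    n = len(yv)
    Rxx = Z.T @ Z / (n - 1)
    rxy = Z.T @ yz / (n - 1)
    if p == 1:
        eps = pd.Series([float(rxy[0] ** 2)], index=design.columns)
    else:
        w, V = np.linalg.eigh(Rxx)
        w = np.clip(w, 0.0, None)
        lam = V @ np.diag(np.sqrt(w)) @ V.T
        lam_inv = V @ np.diag([1 / s if s > 1e-12 else 0.0 for s in np.sqrt(w)]) @ V.T
        beta = lam_inv @ rxy
        eps = pd.Series((lam**2) @ (beta**2), index=design.columns)
    return eps.groupby(genes).sum()


def cross_validate(
    alleles: pd.DataFrame,
    phenotypes: pd.Series,
    k: int = 10,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Pearson correlation of observed vs out-of-fold predictions.

    Folds are a seeded random partition.  A fold whose training split
    never saw some allele level predicts that level's indicator at zero
    (i.e. at the intercept); occurrences are logged.
    """
    import statsmodels.api as sm

    coding, design = code_markers(alleles)
    y = pd.Series(phenotypes).reindex(design.index)
    ok = y.notna()
    design, y = design.loc[ok], y.loc[ok]
    n = len(design)
    if n < k:
        raise GradmapError(f"need n >= k folds, have n={n}, k={k}")
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else int(rng.integers(2**31))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    X = design.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    pred = np.empty(n)
    n_unseen = 0
    for train, test in kf.split(X):
        Xtr = X[train]
        unseen = Xtr.std(axis=0) == 0
        n_unseen += int((X[test][:, unseen] != 0).any(axis=1).sum())
        cols = np.flatnonzero(~unseen)
        res = sm.OLS(yv[train], sm.add_constant(Xtr[:, cols], has_constant="add")).fit()
        pred[test] = sm.add_constant(X[test][:, cols], has_constant="add") @ res.params
    if n_unseen:
        log.info("%d test rows carried allele levels unseen in training folds", n_unseen)
    r = stats.pearsonr(yv, pred).statistic
    return float(r)


def haplotype_table(
    alleles: pd.DataFrame,
    phenotypes: pd.Series,
    group_label: pd.Series | None = None,
    min_count: int = 2,
) -> pd.DataFrame:
    """Multi-gene allele combinations with frequency and phenotype summary.

    Haplotypes rarer than ``min_count`` collapse into "other".  With group
    labels, per-group frequencies are reported alongside the overall ones.
    """
    if alleles.shape[1] < 1:
        raise GradmapError("need >= 1 gene")
    full = alleles.dropna()
    y = pd.Series(phenotypes).reindex(full.index)
    hap = full.apply(lambda row: "/".join(str(v) for v in row), axis=1)
    counts = hap.value_counts()
    rare = counts.index[counts < min_count]
    hap = hap.where(~hap.isin(rare), "other")
    rows = []
    for h, members in hap.groupby(hap).groups.items():
        vals = y.loc[members].dropna()
        row = {
            "haplotype": h,
            "n": len(members),
            "freq": len(members) / len(hap),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        }
        if group_label is not None:
            g = group_label.reindex(members)
            for grp in pd.unique(group_label.dropna()):
                denom = (group_label == grp).sum()
                row[f"freq_{grp}"] = float((g == grp).sum() / denom) if denom else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(drop=True)
    return out
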