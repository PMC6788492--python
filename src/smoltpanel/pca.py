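"""Deterministic PCA for expression matrices.

A thin, fully reproducible PCA (centering, optional unit-variance scaling,
SVD) that stores everything needed to project new fish into a fitted gene
space: per-gene center and scale, orthonormal loadings, explained-variance
fractions, and a per-component orientation sign.  Two conventions make
results backend-independent:

* pre-orientation sign fix: within each component, the loading of largest
  magnitude is made positive;
* an explicit orientation vector (+1/-1 per component) that downstream code
  flips so that, e.g., later months score higher on the smoltification axis
  (PCA signs are otherwise arbitrary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CtMatrix

__all__ = ["ExpressionPCA", "fit_pca", "project"]


def _as_samples_by_genes(X) -> pd.DataFrame:
    if isinstance(X, CtMatrix):
        if X.value_kind != "log2rel":
            raise ValueError(
                f"PCA expects log2 relative expression, got value_kind={X.value_kind!r}"
            )
        return X.to_samples_by_genes()
    return pd.DataFrame(X)


class ExpressionPCA(BaseEstimator, TransformerMixin):
    """PCA over log2 expression with stored projection state.

    Parameters
    ----------
    scale:
        If True (default) genes are scaled to unit variance after centering
        (correlation-matrix PCA).  A zero-variance gene is then an error.

    Attributes
    ----------
    gene_list_ : list of genes, in fit order
    center_, scale_ : per-gene centering/scaling vectors
    loadings_ : genes x components orthonormal loading matrix (DataFrame)
    explained_fraction_ : per-component variance fraction (sums to 1)
    orientation_ : per-component sign applied on projection
    scores_ : training scores (samples x components DataFrame)
    """

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, X, y=None):
        df = _as_samples_by_genes(X)
        if df.isna().any().any():
            raise ValueError("missing values in expression matrix; apply the missingness policy first")
        n, p = df.shape
        if p < 2 or n < 3:
            raise ValueError(f"need >=2 genes and >=3 samples, got {p} genes, {n} samples")
        self.gene_list_ = list(df.columns)
        vals = df.to_numpy(dtype=float)
        self.center_ = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        if self.scale:
            zero = sd == 0
            if zero.any():
                bad = [g for g, z in zip(self.gene_list_, zero) if z]
                raise ValueError(f"zero-variance gene(s) with scale=True: {bad}")
            self.scale_ = sd
        else:
            self.scale_ = np.ones(p)
        Z = (vals - self.center_) / self.scale_
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        r = min(n - 1, p)
        U, s, Vt = U[:, :r], s[:r], Vt[:r]
        # deterministic pre-orientation: largest-|loading| entry positive
        flip = np.sign(Vt[np.arange(r), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        U = U * flip[None, :]
        var = s**2
        self.explained_fraction_ = var / var.sum()
        self.loadings_ = pd.DataFrame(
            Vt.T, index=self.gene_list_, columns=[f"PC{i+1}" for i in range(r)]
        )
        self.orientation_ = np.ones(r)
        self.n_components_ = r
        self._raw_scores = U * s  # orientation applied lazily
        self.scores_ = pd.DataFrame(
            self._raw_scores * self.orientation_,
            index=df.index,
            columns=self.loadings_.columns,
        )
        return self

    def set_orientation(self, component: int, sign: int) -> "ExpressionPCA":
        """Flip a 1-based component so its scores point the stated way."""
        if sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        self.orientation_[component - 1] = sign
        self.scores_ = pd.DataFrame(
            self._raw_scores * self.orientation_,
            index=self.scores_.index,
            columns=self.loadings_.columns,
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        """Project new samples; the training matrix reprojects to ``scores_``."""
        if not hasattr(self, "loadings_"):
            raise RuntimeError("PCA is not fitted")
        df = _as_samples_by_genes(X)
        missing = [g for g in self.gene_list_ if g not in df.columns]
        if missing:
            raise ValueError(f"expression matrix lacks fitted genes: {missing}")
        df = df[self.gene_list_]
        if df.isna().any().any():
            raise ValueError("missing values in expression matrix")
        Z = (df.to_numpy(dtype=float) - self.center_) / self.scale_
        scores = Z @ self.loadings_.to_numpy() * self.orientation_
        return pd.DataFrame(scores, index=df.index, columns=self.loadings_.columns)

    def to_frame(self) -> pd.DataFrame:
        """Serializable description: center, scale and loadings per gene."""
        out = pd.DataFrame(
            {"assay_id": self.gene_list_, "center": self.center_, "scale": self.scale_}
        )
        return pd.concat([out, self.loadings_.reset_index(drop=True)], axis=1)


def fit_pca(expr, scale: bool = True) -> tuple[ExpressionPCA, pd.DataFrame]:
    """Fit a PCA on log2 expression; returns (model, training scores)."""
    model = ExpressionPCA(scale=scale).fit(expr)
    return model, model.scores_


def project(model: ExpressionPCA, expr) -> pd.DataFrame:
    """Project samples into a fitted PCA (stored center/scale/loadings)."""
    return model.transform(expr)
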