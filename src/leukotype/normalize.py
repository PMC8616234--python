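"""Count normalization for expression-based subtyping.

Two transformers, composable with scikit-learn pipelines (rows = samples,
columns = genes):

- :class:`GCNormalizer` removes a per-sample ("within-lane") smooth trend of
  log-count on gene GC fraction, preserving each sample's mean log signal.
- :class:`VarianceStabilizer` divides by median-of-ratios size factors and
  applies log2(x + 1), an approximate variance-stabilizing transform for
  negative-binomial counts.

The module-level helpers ``gc_normalize`` / ``variance_stabilize`` operate
on genes x samples DataFrames, the on-disk orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._glm import size_factors as _size_factors


@dataclass
class NormalizedMatrix:
    """Features x samples matrix with provenance flags."""

    values: pd.DataFrame
    gc_normalized: bool = False
    variance_stabilized: bool = False


class GCNormalizer(BaseEstimator, TransformerMixin):
    """Within-sample GC-content normalization.

    For each sample, a lowess fit of log(count + 0.5) on GC fraction is
    subtracted and the sample's mean log signal re-added, then values are
    mapped back to the count scale. Stateless across samples, so ``fit``
    only validates the GC vector.

    Parameters
    ----------
    gc : array-like of per-gene GC fractions, aligned with the columns the
        transformer will see.
    frac : lowess span.
    """

    def __init__(self, gc=None, frac: float = 0.5):
        self.gc = gc
        self.frac = frac

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        if self.gc is None:
            raise ValueError("GCNormalizer requires per-gene GC fractions")
        gc = np.asarray(self.gc, dtype=float)
        if gc.shape[0] != X.shape[1]:
            raise ValueError("gc length does not match number of genes")
        self.gc_ = gc
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "gc_")
        X = check_array(X)
        gc = self.gc_
        if np.ptp(gc) == 0:
            warnings.warn("constant GC across genes; GC normalization is a no-op",
                          stacklevel=2)
            return X.astype(float)
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            logv = np.log(X[i] + 0.5)
            fitted = lowess(logv, gc, frac=self.frac, return_sorted=False)
            adjusted = logv - fitted + fitted.mean()
            out[i] = np.maximum(np.exp(adjusted) - 0.5, 0.0)
        return out


class VarianceStabilizer(BaseEstimator, TransformerMixin):
    """Size-factor normalization plus log2(x + 1).

    Size factors are median-of-ratios against the per-gene geometric mean
    over the samples passed to ``fit`` (genes with any zero excluded from
    the reference); ``transform`` recomputes factors for the matrix it
    receives so each sample is scaled by its own sequencing depth.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.size_factors_ = _size_factors(X.T)
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = check_array(X)
        sf = (self.size_factors_ if X.shape[0] == self.size_factors_.shape[0]
              else _size_factors(X.T))
        return np.log2(X / sf[:, None] + 1.0)


def gc_normalize(counts: pd.DataFrame, gc: pd.Series, frac: float = 0.5) -> NormalizedMatrix:
    """GC-normalize a genes x samples count matrix.

    Genes without a GC value are excluded with a warning.
    """
    gc = gc.reindex(counts.index)
    missing = gc.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes without GC fraction excluded",
                      stacklevel=2)
        counts = counts[~missing]
        gc = gc[~missing]
    tf = GCNormalizer(gc=gc.to_numpy(), frac=frac).fit(counts.T.to_numpy())
    out = tf.transform(counts.T.to_numpy()).T
    return NormalizedMatrix(pd.DataFrame(out, index=counts.index, columns=counts.columns),
                            gc_normalized=True)


def variance_stabilize(counts: pd.DataFrame | NormalizedMatrix) -> NormalizedMatrix:
    """Variance-stabilize a genes x samples matrix of (possibly
    GC-normalized) counts. Raises if a sample is all zeros, naming it."""
    gc_flag = False
    if isinstance(counts, NormalizedMatrix):
        gc_flag = counts.gc_normalized
        counts = counts.values
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has an all-zero count vector")
    tf = VarianceStabilizer().fit(counts.T.to_numpy())
    out = tf.transform(counts.T.to_numpy()).T
    return NormalizedMatrix(pd.DataFrame(out, index=counts.index, columns=counts.columns),
                            gc_normalized=gc_flag, variance_stabilized=True)
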