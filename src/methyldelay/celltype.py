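"""Methylation-based cell-type concordance.

Each sample's beta vector is correlated (Pearson) against reference
cell-type profiles — e.g. mean methylation of sorted glia and neurons at
marker CpGs — and labelled with the best-correlated type.  This is a
concordance check, not a proportion deconvolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted


class CellTypeCorrelator(ClassifierMixin, BaseEstimator):
    """Nearest-reference classifier under the Pearson correlation.

    ``fit(X, y)`` takes reference profiles: X of shape
    (n_references, n_markers) — one row per reference profile (mean beta
    at marker CpGs) — and y the cell-type label of each row.  ``predict``
    labels samples by the reference with the highest correlation;
    ``correlate`` exposes the full r/p table.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] < 3:
            raise ValueError("need >= 3 marker CpGs")
        if len(y) != X.shape[0]:
            raise ValueError("one label per reference profile required")
        self.references_ = X
        self.classes_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def correlate(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Pearson r and two-sided p of each sample against each reference;
        shapes (n_samples, n_references)."""
        check_is_fitted(self, "references_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch with fitted references")
        n_samples, n_refs = X.shape[0], self.references_.shape[0]
        r = np.empty((n_samples, n_refs))
        p = np.empty((n_samples, n_refs))
        for i in range(n_samples):
            for j in range(n_refs):
                res = stats.pearsonr(X[i], self.references_[j])
                r[i, j] = res.statistic
                p[i, j] = res.pvalue
        return r, p

    def predict(self, X):
        r, _ = self.correlate(X)
        return self.classes_[np.argmax(r, axis=1)]


def read_reference_profiles(path) -> pd.DataFrame:
    """Reference TSV: marker CpG ids in the first column, one cell-type
    column per reference profile."""
    refs = pd.read_csv(path, sep="\t", index_col=0)
    if refs.shape[0] < 3:
        raise ValueError("need >= 3 marker CpGs in the reference")
    return refs.astype(float)


def correlate_to_reference(betas: pd.DataFrame, references: pd.DataFrame) -> pd.DataFrame:
    """Per-sample correlation against each reference cell type over the
    shared marker CpGs, plus the argmax label.

    ``betas`` is probes x samples; ``references`` is marker CpGs x cell
    types.  Returns one row per sample with r_<type>, p_<type> columns and
    a ``label`` column.
    """
    shared = betas.index.intersection(references.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared marker CpGs")
    est = CellTypeCorrelator().fit(
        references.loc[shared].to_numpy(dtype=float).T,
        np.asarray(references.columns),
    )
    X = betas.loc[shared].to_numpy(dtype=float).T
    r, p = est.correlate(X)
    out = pd.DataFrame(index=betas.columns)
    for j, cell_type in enumerate(references.columns):
        out[f"r_{cell_type}"] = r[:, j]
        out[f"p_{cell_type}"] = p[:, j]
    out["label"] = est.predict(X)
    out["n_markers"] = len(shared)
    return out
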