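"""Realized genomic relationship matrix (GRM).

K = Z Z' / n_m, where Z is the column-standardized additive genotype matrix
(each marker centered by its observed mean and scaled by its observed
population standard deviation) and n_m the number of markers.  The
population (divide-by-n) standard deviation convention is used; either
convention only rescales K globally and is absorbed by the variance
components downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GenotypeData


@dataclass
class Kinship:
    """Symmetric realized-relationship matrix with provenance metadata."""

    K: np.ndarray
    n_markers: int
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if len(self.individual_ids) != self.K.shape[0]:
            raise ValueError("id count does not match K dimension")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K is not symmetric")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])


class GenomicRelationship(BaseEstimator, TransformerMixin):
    """Standardize genotypes column-wise and expose the GRM.

    ``fit`` learns per-marker means and standard deviations; ``transform``
    returns the standardized matrix Z.  ``fit_transform`` additionally
    stores ``kinship_`` = Z Z' / n_m computed on the fitted data.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        self.means_ = X.mean(axis=0)
        self.stds_ = X.std(axis=0)  # population convention
        zero = np.flatnonzero(self.stds_ == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance marker column(s) {zero[:5].tolist()}; "
                "run the MAF filter first"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = self._check(X)
        return (X - self.means_) / self.stds_

    def fit_transform(self, X, y=None, **fit_params):
        Z = self.fit(X).transform(X)
        self.kinship_ = Z @ Z.T / Z.shape[1]
        return Z

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("GRM requires a complete (imputed) genotype matrix")
        return X


def build_grm(geno: GenotypeData | np.ndarray, ids=None) -> Kinship:
    """Compute K = ZZ'/n_m from a complete additive genotype matrix."""
    if isinstance(geno, GenotypeData):
        X = geno.values
        ids = list(geno.individual_ids)
        mids = geno.marker_ids
    else:
        X = np.asarray(geno, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
        mids = None
    gr = GenomicRelationship()
    try:
        gr.fit_transform(X)
    except ValueError as err:
        if mids is not None and "zero-variance" in str(err):
            stds = X.std(axis=0)
            names = [mids[j] for j in np.flatnonzero(stds == 0)[:5]]
            raise ValueError(f"zero-variance marker(s): {names}") from err
        raise
    K = gr.kinship_
    K = (K + K.T) / 2.0  # enforce exact symmetry
    return Kinship(K=K, n_markers=X.shape[1], individual_ids=ids)
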