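"""Marker quality control and LD-based genotype imputation.

Markers with a minor allele frequency below 5% or a call rate below 0.80 are
discarded (both thresholds strict: a marker sitting exactly at the boundary
is retained).  Remaining missing calls are imputed from linkage
disequilibrium with the 10 closest neighboring markers on the same
chromosome, via an r^2-weighted conditional-mode vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GenotypeData

logger = logging.getLogger(__name__)


def marker_maf(values: np.ndarray) -> np.ndarray:
    """Minor allele frequency per column from non-missing additive codes."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(values, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def marker_call_rate(values: np.ndarray) -> np.ndarray:
    return 1.0 - np.isnan(values).mean(axis=0)


class MarkerQC(BaseEstimator, TransformerMixin):
    """Column filter retaining markers with MAF >= ``maf_min`` and call rate
    >= ``callrate_min`` (strict "below threshold is discarded" semantics).

    Fitted attributes: ``keep_mask_`` (bool per column), ``report_``
    (DataFrame of removed columns with reasons).
    """

    def __init__(self, maf_min: float = 0.05, callrate_min: float = 0.80):
        self.maf_min = maf_min
        self.callrate_min = callrate_min

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        maf = marker_maf(X)
        cr = marker_call_rate(X)
        # all-missing columns have undefined MAF -> fail both checks
        maf = np.where(np.isnan(maf), -1.0, maf)
        low_maf = maf < self.maf_min
        low_cr = cr < self.callrate_min
        self.keep_mask_ = ~(low_maf | low_cr)
        reasons = []
        for j in np.flatnonzero(~self.keep_mask_):
            why = []
            if low_maf[j]:
                why.append(f"MAF {maf[j]:.4f} < {self.maf_min}")
            if low_cr[j]:
                why.append(f"call rate {cr[j]:.4f} < {self.callrate_min}")
            reasons.append({"column": j, "maf": maf[j], "call_rate": cr[j],
                            "reason": "; ".join(why)})
        self.report_ = pd.DataFrame(
            reasons, columns=["column", "maf", "call_rate", "reason"]
        )
        if not self.keep_mask_.any():
            raise ValueError(
                "all markers removed by QC; review maf_min/callrate_min"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "keep_mask_")
        return np.asarray(X, dtype=float)[:, self.keep_mask_]


def filter_markers(
    geno: GenotypeData, maf_min: float = 0.05, callrate_min: float = 0.80
) -> tuple[GenotypeData, pd.DataFrame]:
    """Apply the MAF/call-rate filter to a GenotypeData; returns the filtered
    data and a removal report keyed by marker id."""
    qc = MarkerQC(maf_min=maf_min, callrate_min=callrate_min).fit(geno.values)
    report = qc.report_.copy()
    if len(report):
        report.insert(
            0, "marker_id",
            geno.marker_map["marker_id"].to_numpy()[report["column"].to_numpy()],
        )
    else:
        report.insert(0, "marker_id", pd.Series(dtype=str))
    return geno.select_markers(qc.keep_mask_), report


class LDImputer(BaseEstimator, TransformerMixin):
    """Impute missing additive genotypes from nearby markers in LD.

    For a missing call at marker ``j`` in individual ``i``, the
    ``n_neighbors`` markers nearest to ``j`` in bp on the same chromosome
    that are observed in ``i`` each cast a vote: neighbor ``k`` votes for the
    genotype class of ``j`` most frequent among complete-case individuals
    sharing ``i``'s genotype at ``k``, weighted by r^2(j, k).  Ties go to the
    overall modal genotype at ``j``.  If a chromosome offers no observed
    neighbor, the marker-wise modal genotype is used (logged).

    Positions and chromosome labels are passed to :meth:`fit` because they
    are properties of the marker panel, not tuning parameters.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None, *, positions=None, chromosomes=None):
        X = np.asarray(X, dtype=float)
        n_markers = X.shape[1]
        if positions is None:
            positions = np.arange(n_markers)
        if chromosomes is None:
            chromosomes = np.zeros(n_markers, dtype=object)
        self.positions_ = np.asarray(positions)
        self.chromosomes_ = np.asarray(chromosomes, dtype=object)
        if self.positions_.size != n_markers or self.chromosomes_.size != n_markers:
            raise ValueError("positions/chromosomes must match marker count")
        # modal genotype per marker (over observed calls)
        self.modal_ = np.empty(n_markers)
        for j in range(n_markers):
            col = X[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                self.modal_[j] = 0.0
            else:
                vals, cnt = np.unique(obs, return_counts=True)
                self.modal_[j] = vals[np.argmax(cnt)]
        return self

    # -- internals --------------------------------------------------------
    def _neighbor_order(self, j: int) -> np.ndarray:
        same = np.flatnonzero(
            (self.chromosomes_ == self.chromosomes_[j])
            & (np.arange(self.chromosomes_.size) != j)
        )
        dist = np.abs(self.positions_[same] - self.positions_[j])
        return same[np.argsort(dist, kind="stable")]

    @staticmethod
    def _r2(x: np.ndarray, y: np.ndarray) -> float:
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            return 0.0
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            return 0.0
        r = np.corrcoef(xs, ys)[0, 1]
        return float(r * r) if np.isfinite(r) else 0.0

    def transform(self, X):
        check_is_fitted(self, "modal_")
        X = np.asarray(X, dtype=float).copy()
        missing_cols = np.flatnonzero(np.isnan(X).any(axis=0))
        cond_mode_cache: dict[tuple[int, int], dict[float, float]] = {}
        r2_cache: dict[tuple[int, int], float] = {}
        for j in missing_cols:
            order = self._neighbor_order(j)
            col_obs = ~np.isnan(X[:, j])
            for i in np.flatnonzero(np.isnan(X[:, j])):
                votes: dict[float, float] = {}
                used = 0
                for k in order:
                    gik = X[i, k]
                    if np.isnan(gik):
                        continue
                    key = (j, int(k))
                    if key not in r2_cache:
                        r2_cache[key] = self._r2(X[:, j], X[:, k])
                    w = r2_cache[key]
                    if key not in cond_mode_cache:
                        cond_mode_cache[key] = self._conditional_modes(
                            X, j, int(k), col_obs
                        )
                    pred = cond_mode_cache[key].get(gik)
                    if pred is not None and w > 0:
                        votes[pred] = votes.get(pred, 0.0) + w
                    used += 1
                    if used >= self.n_neighbors:
                        break
                if not votes:
                    if used == 0:
                        logger.warning(
                            "no observed neighbor for column %d in row %d; "
                            "using modal genotype", j, i,
                        )
                    X[i, j] = self.modal_[j]
                else:
                    best = max(votes.values())
                    winners = [g for g, v in votes.items() if v == best]
                    if len(winners) == 1:
                        X[i, j] = winners[0]
                    else:  # tie -> overall modal genotype
                        X[i, j] = (
                            self.modal_[j] if self.modal_[j] in winners
                            else min(winners)
                        )
        return X

    def _conditional_modes(
        self, X: np.ndarray, j: int, k: int, col_obs: np.ndarray
    ) -> dict[float, float]:
        """Most frequent genotype at j among complete cases, per genotype at k."""
        ok = col_obs & ~np.isnan(X[:, k])
        modes: dict[float, float] = {}
        for g in (0.0, 1.0, 2.0):
            sel = ok & (X[:, k] == g)
            if not sel.any():
                continue
            vals, cnt = np.unique(X[sel, j], return_counts=True)
            modes[g] = float(vals[np.argmax(cnt)])
        return modes


def impute_missing(geno: GenotypeData, n_neighbors: int = 10) -> GenotypeData:
    """LD-neighbor imputation over a GenotypeData; observed calls untouched."""
    imp = LDImputer(n_neighbors=n_neighbors)
    imp.fit(
        geno.values,
        positions=geno.marker_map["position_bp"].to_numpy(),
        chromosomes=geno.marker_map["chromosome"].to_numpy(),
    )
    values = imp.transform(geno.values)
    return GenotypeData(values, list(geno.individual_ids), geno.marker_map.copy())


def modal_impute(geno: GenotypeData) -> GenotypeData:
    """Marker-wise modal-genotype imputation; baseline for accuracy checks."""
    values = geno.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            fill = 0.0
        else:
            vals, cnt = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(cnt)]
        values[miss, j] = fill
    return GenotypeData(values, list(geno.individual_ids), geno.marker_map.copy())
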