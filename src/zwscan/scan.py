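"""Whitened linear-mixed-model genome scan for a binary trait.

The trait (sex reversal, 0/1) is analysed on the liability scale with the
linear mixed model

    y = mu + b m + g + e,        g ~ N(0, K sigma_g^2),  e ~ N(0, I sigma_e^2)

where m is the additive SNP code and K the realized genomic relationship
matrix.  Variance components are estimated once by REML under the null
(intercept-only) model; the phenotypic covariance V = K sigma_g^2 +
I sigma_e^2 is then Cholesky-factored (V = L L') and the model is whitened
(y* = L^-1 y, M* = L^-1 M) so that every marker test reduces to ordinary
least squares.  Per marker, T = -2 (logL_null - logL_full) computed on the
Gaussian profile, referred to chi^2 with 1 df.

A genome-wide critical value is obtained with the quick analytic
approximation of Piepho's upcrossing method (the Davies bound with the total
variation of the signed-root statistic estimated from the scan itself),
clipped between the pointwise and Bonferroni chi^2 quantiles.  The peak's
confidence interval is the drop-based support interval: markers whose
statistic stays within chi^2_1(level) of the peak, extended to the midpoints
toward the first excluded markers.

Note on the binary trait: applying logit() to an individual 0/1 outcome is
undefined, so the model is fit directly to the 0/1 indicator; the whitened
regression is exactly the generalized-least-squares score test that the
transform above implies.  A penalized-quasi-likelihood logistic variant is
deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.base import BaseEstimator

from .io import GenotypeData, chrom_sort_key
from .relatedness import Kinship, build_grm

logger = logging.getLogger(__name__)

#: Smallest positive subnormal double; reported instead of an underflowed 0.
TINY_P = float(np.nextafter(0.0, 1.0))

#: Statistic cap used only when estimating the variation term of the
#: genome-wide threshold (an infinite peak would otherwise swamp it).
_VARIATION_CAP = 1.0e3


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    ratio: float  # lambda = sigma2_g / sigma2_e
    boundary: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma2_g) and np.isfinite(self.sigma2_e)):
            raise ValueError("variance components must be finite")
        if self.sigma2_g < 0 or self.sigma2_e <= 0:
            raise ValueError("need sigma2_g >= 0 and sigma2_e > 0")


def _reml_profile(lam: float, s: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Restricted log-likelihood profiled over sigma2_e at ratio ``lam``."""
    n, p = yt.size, xt.shape[1]
    w = lam * s + 1.0
    xw = xt / w[:, None]
    A = xt.T @ xw
    beta = np.linalg.solve(A, xw.T @ yt)
    r = yt - xt @ beta
    q = float(r @ (r / w))
    sigma2_e = q / (n - p)
    sign, logdetA = np.linalg.slogdet(A)
    rll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2_e)
        + np.log(w).sum()
        + logdetA
        + (n - p)
    )
    return rll, sigma2_e


def estimate_vc(y: np.ndarray, K: Kinship | np.ndarray) -> VarianceComponents:
    """REML variance components under the intercept-only null model.

    K is eigendecomposed once and the likelihood profiled over the ratio
    lambda = sigma2_g/sigma2_e on a log grid with local refinement.  When K
    carries no structure (e.g. K = I) the ratio is unidentifiable; the
    boundary solution lambda = 0 is returned with a warning.
    """
    Kmat = K.K if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if Kmat.shape != (n, n):
        raise ValueError(f"K is {Kmat.shape} but y has length {n}")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    s, U = np.linalg.eigh((Kmat + Kmat.T) / 2.0)
    if s[0] < -1e-8 * max(1.0, abs(s[-1])):
        raise ValueError(f"K is not positive semi-definite (min eig {s[0]:.3g})")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = (U.T @ np.ones(n))[:, None]

    grid = np.concatenate([[0.0], np.logspace(-6, 6, 121)])
    vals = np.array([_reml_profile(l, s, yt, xt)[0] for l in grid])
    if np.ptp(vals) < 1e-8:
        logger.warning(
            "restricted likelihood is flat in sigma2_g/sigma2_e: the ratio is "
            "non-identifiable (K has no structure); returning boundary lambda=0"
        )
        rll, sigma2_e = _reml_profile(0.0, s, yt, xt)
        return VarianceComponents(0.0, sigma2_e, rll, 0.0, boundary=True)
    i = int(np.argmax(vals))
    if i == 0:
        lam = 0.0
        boundary = True
    else:
        lo = grid[max(i - 1, 1)]
        hi = grid[min(i + 1, grid.size - 1)]
        if lo == hi:
            lam = grid[i]
        else:
            res = optimize.minimize_scalar(
                lambda t: -_reml_profile(np.exp(t), s, yt, xt)[0],
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam = float(np.exp(res.x))
            if _reml_profile(lam, s, yt, xt)[0] < vals[i]:
                lam = grid[i]
        boundary = False
    rll, sigma2_e = _reml_profile(lam, s, yt, xt)
    return VarianceComponents(lam * sigma2_e, sigma2_e, rll, lam, boundary=boundary)


@dataclass
class WhitenedDesign:
    """Whitened phenotype/design: y* = L^-1 y with V = L L'."""

    y_star: np.ndarray
    M_star: np.ndarray
    intercept_star: np.ndarray
    V: np.ndarray = field(repr=False)
    L: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.y_star.size

    def unwhiten(self, v: np.ndarray) -> np.ndarray:
        return self.L @ v


def whiten(
    y: np.ndarray, M: np.ndarray, vc: VarianceComponents, K: Kinship | np.ndarray
) -> WhitenedDesign:
    """Cholesky-whiten phenotype, genotype matrix and intercept by V^-1/2."""
    Kmat = K.K if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    n = y.size
    V = vc.sigma2_g * Kmat + vc.sigma2_e * np.eye(n)
    try:
        L = cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        eps = 1e-8 * float(np.mean(np.diag(V)))
        logger.warning("Cholesky of V failed; retrying with jitter %.3g", eps)
        L = cholesky(V + eps * np.eye(n), lower=True)
    y_star = solve_triangular(L, y, lower=True)
    M_star = solve_triangular(L, M, lower=True)
    one_star = solve_triangular(L, np.ones(n), lower=True)
    return WhitenedDesign(y_star, M_star, one_star, V, L)


# flag codes used in scan tables
FLAG_OK = ""
FLAG_COLLINEAR = "collinear"
FLAG_UNDERFLOW = "underflow"


def scan_markers(design: WhitenedDesign) -> pd.DataFrame:
    """Per-marker OLS on the whitened design.

    Returns a DataFrame with the allele-substitution effect ``b``, the
    -2*delta-log-likelihood statistic ``T`` = n*ln(RSS0/RSS1) and its
    chi^2(1 df) upper-tail P-value.  Markers collinear with the intercept
    (including monomorphic ones) get T = 0, P = 1; perfect separation gives
    an infinite T with P reported as the smallest positive double and an
    ``underflow`` flag.
    """
    y, M, X0 = design.y_star, design.M_star, design.intercept_star
    n = y.size
    d0 = float(X0 @ X0)
    a = float(X0 @ y) / d0
    ry = y - a * X0
    rss0 = float(ry @ ry)
    C = (X0 @ M) / d0
    rm = M - np.outer(X0, C)
    sm2 = np.einsum("ij,ij->j", rm, rm)
    cross = rm.T @ ry
    scale = np.einsum("ij,ij->j", M, M) + d0
    collinear = sm2 <= 1e-10 * np.maximum(scale, 1.0)
    safe_sm2 = np.where(collinear, 1.0, sm2)
    b = np.where(collinear, 0.0, cross / safe_sm2)
    rss1 = np.where(collinear, rss0, rss0 - cross**2 / safe_sm2)
    rss1 = np.maximum(rss1, 0.0)
    underflow = (~collinear) & (rss1 <= 1e-12 * rss0)
    with np.errstate(divide="ignore"):
        T = np.where(
            collinear, 0.0,
            n * np.log(np.where(rss1 > 0, rss0 / np.where(rss1 > 0, rss1, 1.0),
                                np.inf)),
        )
    T = np.where(underflow, np.inf, T)
    P = np.empty_like(T)
    finite = np.isfinite(T)
    P[finite] = stats.chi2.sf(T[finite], df=1)
    P[~finite] = 0.0
    p_underflow = (P <= 0.0) & ~collinear
    P = np.where(p_underflow, TINY_P, P)
    P = np.where(collinear, 1.0, P)
    flag = np.where(
        collinear, FLAG_COLLINEAR, np.where(p_underflow, FLAG_UNDERFLOW, FLAG_OK)
    )
    return pd.DataFrame({"b": b, "T": T, "P": P, "flag": flag})


def gls_lrt_oracle(
    y: np.ndarray, m: np.ndarray, vc: VarianceComponents, K: Kinship | np.ndarray
) -> float:
    """Direct generalized-least-squares -2*delta-log-likelihood for one marker.

    Independent of the whitening path: quadratic forms in V^-1 are computed
    with a Cholesky solve of the full V.  Used as a brute-force oracle.
    """
    Kmat = K.K if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    V = vc.sigma2_g * Kmat + vc.sigma2_e * np.eye(n)
    cf = cho_factor(V, lower=True)

    def rss(X: np.ndarray) -> float:
        Vi_X = cho_solve(cf, X)
        Vi_y = cho_solve(cf, y)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        r = y - X @ beta
        return float(r @ cho_solve(cf, r))

    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), np.asarray(m, dtype=float)])
    return n * np.log(rss(X0) / rss(X1))


def piepho_threshold(
    T: np.ndarray,
    b: np.ndarray,
    chromosomes: Sequence,
    alpha: float = 0.05,
) -> float:
    """Genome-wide critical value for the scan statistic.

    Quick upcrossing approximation: solve

        alpha = P(chi2_1 > c) + V * exp(-c/2) / sqrt(2*pi)

    for c, where V is the total variation of the signed-root statistic
    z_i = sign(b_i) * sqrt(T_i), accumulated within chromosomes in genomic
    order.  The result is clipped into [pointwise, Bonferroni] chi^2(1)
    quantiles, so it can never be anticonservative relative to a single test
    nor more conservative than Bonferroni.
    """
    T = np.asarray(T, dtype=float)
    b = np.asarray(b, dtype=float)
    chromosomes = np.asarray(chromosomes, dtype=object)
    n_markers = T.size
    pointwise = float(stats.chi2.ppf(1.0 - alpha, df=1))
    if n_markers <= 1:
        return pointwise
    bonferroni = float(stats.chi2.ppf(1.0 - alpha / n_markers, df=1))
    Tc = np.clip(np.nan_to_num(T, posinf=_VARIATION_CAP), 0.0, _VARIATION_CAP)
    z = np.sign(b) * np.sqrt(Tc)
    V = 0.0
    for c in pd.unique(chromosomes):
        zc = z[chromosomes == c]
        if zc.size > 1:
            V += float(np.abs(np.diff(zc)).sum())

    def excess(c: float) -> float:
        return (
            stats.chi2.sf(c, df=1)
            + V * np.exp(-c / 2.0) / np.sqrt(2.0 * np.pi)
            - alpha
        )

    if excess(pointwise) <= 0:
        return pointwise
    if excess(bonferroni) >= 0:
        return bonferroni
    return float(optimize.brentq(excess, pointwise, bonferroni, xtol=1e-10))


def _peak_index(table: pd.DataFrame) -> int:
    """Peak = smallest P, ties broken by genomic order (leftmost)."""
    pmin = table["P"].min()
    cand = table.index[table["P"] == pmin]
    keys = sorted(
        cand,
        key=lambda i: (
            chrom_sort_key(table.at[i, "chromosome"]),
            table.at[i, "position_bp"],
        ),
    )
    return int(keys[0])


def peak_ci(
    table: pd.DataFrame,
    threshold: float,
    level: float = 0.95,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[str, int, int]:
    """Drop-based support interval around the scan peak.

    The interval holds the contiguous run of markers around the peak whose
    statistic stays within d = chi^2_1(level) of the peak value, extended to
    the midpoint toward the first marker outside the run and clipped to the
    chromosome ends.  Raises if no marker exceeds the genome-wide threshold.
    """
    peak = _peak_index(table)
    T = table["T"].to_numpy(dtype=float)
    if not (T[peak] > threshold):
        raise ValueError("no QTL: no marker exceeds the genome-wide threshold")
    chrom = str(table.at[peak, "chromosome"])
    on_chrom = table.index[table["chromosome"].astype(str) == chrom]
    sub = table.loc[on_chrom].sort_values("position_bp").reset_index()
    pos = sub["position_bp"].to_numpy(dtype=int)
    Tc = sub["T"].to_numpy(dtype=float)
    k = int(np.flatnonzero(sub["index"].to_numpy() == peak)[0])
    d = float(stats.chi2.ppf(level, df=1))
    tpk = Tc[k]
    if np.isinf(tpk):
        inside = np.isinf(Tc)
    else:
        inside = (tpk - Tc) <= d
    lo = k
    while lo - 1 >= 0 and inside[lo - 1]:
        lo -= 1
    hi = k
    while hi + 1 < len(pos) and inside[hi + 1]:
        hi += 1
    if lo == 0:
        start = 1
    else:
        start = int((pos[lo] + pos[lo - 1]) // 2)
    if hi == len(pos) - 1:
        end = int(
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths
            else pos[hi]
        )
    else:
        end = int((pos[hi] + pos[hi + 1]) // 2)
    return chrom, start, end


@dataclass
class ScanResult:
    """Full genome-scan output: per-marker table plus genome-wide summary."""

    table: pd.DataFrame
    vc: VarianceComponents
    threshold: float
    alpha: float
    peak_marker: str | None = None
    ci: tuple[str, int, int] | None = None
    ci_level: float = 0.95

    def summary(self) -> dict:
        return {
            "n_markers": int(len(self.table)),
            "sigma2_g": self.vc.sigma2_g,
            "sigma2_e": self.vc.sigma2_e,
            "lambda": self.vc.ratio,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "peak_marker": self.peak_marker,
            "ci": (
                {"chromosome": self.ci[0], "start_bp": self.ci[1],
                 "end_bp": self.ci[2], "level": self.ci_level}
                if self.ci else None
            ),
        }


class MixedModelScan(BaseEstimator):
    """Whitened mixed-model association scan as a scikit-learn estimator.

    ``fit(X, y, marker_map=..., K=...)`` runs the whole engine on a complete
    additive genotype matrix: REML under the null, Cholesky whitening,
    per-marker tests, genome-wide threshold, and the peak support interval.

    Fitted attributes: ``vc_``, ``results_`` (per-marker table),
    ``threshold_``, ``peak_marker_``, ``ci_``.
    """

    def __init__(self, alpha: float = 0.05, ci_level: float = 0.95):
        self.alpha = alpha
        self.ci_level = ci_level

    def fit(
        self,
        X,
        y,
        marker_map: pd.DataFrame | None = None,
        K: Kinship | np.ndarray | None = None,
        chrom_lengths: Mapping[str, int] | None = None,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.isnan(X).any():
            raise ValueError("scan requires a complete (imputed) genotype matrix")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("phenotype must be a 0/1 indicator")
        if np.ptp(y) == 0:
            raise ValueError("phenotype has a single class after filtering")
        if marker_map is None:
            marker_map = pd.DataFrame(
                {
                    "marker_id": [f"m{j}" for j in range(X.shape[1])],
                    "chromosome": "1",
                    "position_bp": np.arange(1, X.shape[1] + 1),
                }
            )
        kin = K if K is not None else build_grm(X)
        self.vc_ = estimate_vc(y, kin)
        design = whiten(y, X, self.vc_, kin)
        stats_df = scan_markers(design)
        table = pd.concat(
            [
                marker_map[["marker_id", "chromosome", "position_bp"]]
                .reset_index(drop=True),
                stats_df,
            ],
            axis=1,
        )
        self.threshold_ = piepho_threshold(
            table["T"].to_numpy(),
            table["b"].to_numpy(),
            table["chromosome"].to_numpy(),
            alpha=self.alpha,
        )
        table["above_threshold"] = table["T"] > self.threshold_
        peak = _peak_index(table)
        self.peak_marker_ = str(table.at[peak, "marker_id"])
        try:
            self.ci_ = peak_ci(
                table, self.threshold_, level=self.ci_level,
                chrom_lengths=chrom_lengths,
            )
        except ValueError:
            logger.info("no marker exceeds the genome-wide threshold; no CI")
            self.ci_ = None
        self.results_ = table
        return self

    def result(self) -> ScanResult:
        return ScanResult(
            table=self.results_,
            vc=self.vc_,
            threshold=self.threshold_,
            alpha=self.alpha,
            peak_marker=self.peak_marker_,
            ci=self.ci_,
            ci_level=self.ci_level,
        )


def ztw_condition(marker_id: str, dose: float = 2.0) -> Callable:
    """Cohort rule: keep ZW individuals whose coded genotype at ``marker_id``
    equals ``dose`` (hemizygous T is coded 2 when T is the alternate allele)."""

    def rule(geno: GenotypeData, pheno: pd.DataFrame) -> np.ndarray:
        j = geno.marker_index(marker_id)
        zw = (pheno["genetic_sex"].to_numpy() == "ZW")
        return zw & (geno.values[:, j] == dose)

    return rule


def run_gwas(
    geno: GenotypeData,
    pheno: pd.DataFrame,
    condition: Callable | None = None,
    alpha: float = 0.05,
    ci_level: float = 0.95,
    maf_min: float = 0.05,
    callrate_min: float = 0.80,
    n_neighbors: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ScanResult:
    """End-to-end scan: cohort filter, marker QC, imputation, GRM rebuilt on
    the cohort, REML, whitening, per-marker tests, threshold and CI."""
    from .qc import filter_markers, impute_missing

    pheno = pheno.set_index("id").loc[geno.individual_ids].reset_index()
    if condition is not None:
        mask = np.asarray(condition(geno, pheno), dtype=bool)
        keep_ids = [i for i, m in zip(geno.individual_ids, mask) if m]
        geno = geno.select_individuals(keep_ids)
        pheno = pheno[mask].reset_index(drop=True)
    n = geno.n_individuals
    if n < 30:
        logger.warning("cohort has only %d individuals; results will be noisy", n)
    y = pheno["reversal"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("single phenotype class after cohort filtering")
    geno, report = filter_markers(geno, maf_min=maf_min, callrate_min=callrate_min)
    if len(report):
        logger.info("QC removed %d markers on the cohort", len(report))
    if np.isnan(geno.values).any():
        geno = impute_missing(geno, n_neighbors=n_neighbors)
    kin = build_grm(geno)
    model = MixedModelScan(alpha=alpha, ci_level=ci_level)
    model.fit(
        geno.values, y, marker_map=geno.marker_map, K=kin,
        chrom_lengths=chrom_lengths,
    )
    return model.result()


def permutation_threshold(
    y: np.ndarray,
    M: np.ndarray,
    vc: VarianceComponents,
    K: Kinship | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation oracle for the genome-wide critical value.

    Permutes the raw phenotype, re-whitens with the same V, rescans, and
    returns the (1-alpha) quantile of the per-permutation maximum statistic
    together with the maxima themselves.
    """
    rng = np.random.default_rng(seed)
    design = whiten(y, M, vc, K)
    Mst, X0, L = design.M_star, design.intercept_star, design.L
    n = y.size
    d0 = float(X0 @ X0)
    C = (X0 @ Mst) / d0
    rm = Mst - np.outer(X0, C)
    sm2 = np.einsum("ij,ij->j", rm, rm)
    ok = sm2 > 1e-10 * max(1.0, float(np.mean(sm2)))
    rm, sm2 = rm[:, ok], sm2[ok]
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        yp = solve_triangular(L, rng.permutation(y), lower=True)
        a = float(X0 @ yp) / d0
        ry = yp - a * X0
        rss0 = float(ry @ ry)
        cross = rm.T @ ry
        rss1 = np.maximum(rss0 - cross**2 / sm2, 1e-300)
        maxima[p] = float(np.max(n * np.log(rss0 / rss1)))
    return float(np.quantile(maxima, 1.0 - alpha)), maxima


def manhattan_plot(
    result: ScanResult, path, chrom_lengths: Mapping[str, int] | None = None
) -> None:
    """Manhattan plot: -log10 P along chromosomes 1-20, W, Z, with the
    genome-wide threshold as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table.copy()
    table["chromosome"] = table["chromosome"].astype(str)
    chroms = sorted(table["chromosome"].unique(), key=chrom_sort_key)
    offset, offsets, centers = 0.0, {}, []
    for c in chroms:
        span = table.loc[table["chromosome"] == c, "position_bp"].max()
        if chrom_lengths and c in chrom_lengths:
            span = max(span, chrom_lengths[c])
        offsets[c] = offset
        centers.append(offset + span / 2.0)
        offset += span * 1.02
    x = table["position_bp"].to_numpy(float) + np.array(
        [offsets[c] for c in table["chromosome"]]
    )
    logp = -np.log10(table["P"].to_numpy(float))
    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, c in enumerate(chroms):
        sel = (table["chromosome"] == c).to_numpy()
        ax.scatter(x[sel], logp[sel], s=5,
                   color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
    thr_logp = -np.log10(stats.chi2.sf(result.threshold, df=1))
    ax.axhline(thr_logp, linestyle="--", color="grey")
    ax.set_xticks(centers)
    ax.set_xticklabels(chroms, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
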