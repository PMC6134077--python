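"""Two-locus epistasis on the Z chromosome and ZW offspring-ratio testing.

The reversal rule: a genetic female (ZW) becomes a pseudomale exactly when
her hemizygous Z allele at the first locus is the unfavorable T AND her
genotype at the second locus carries at least one unfavorable A.  The first
locus is hemizygous (a single allele, A or T); the second admits the
heterozygote AG because of an apparent gene duplication.

The offspring-ratio test addresses transmission genetics: if a pseudomale
(ZW) sire produced W sperm, ZW x ZW crosses would yield ZW:ZZ offspring 2:1
(WW is lethal); if the sire passes only Z, the expectation is 1:1.  A
chi-square goodness-of-fit of the observed (ZW, ZZ) counts against the 2:1
expectation tests the W-sperm hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

FEMALE = "female"
PSEUDOMALE = "pseudomale"

G1_ALLELES = ("A", "T")
G2_GENOTYPES = ("GG", "AG", "AA")


def _norm_g2(g2: str) -> str:
    g2 = "".join(sorted(str(g2).upper()))  # AG == GA
    if g2 not in {"GG", "AG", "AA"}:
        raise ValueError(f"unknown genotype at the second locus: {g2!r}")
    return g2


def classify(g1: str, g2: str) -> str:
    """Predicted phenotype of a ZW fish from its two causal genotypes."""
    g1 = str(g1).upper()
    if g1 not in G1_ALLELES:
        raise ValueError(f"unknown hemizygous allele at the first locus: {g1!r}")
    g2 = _norm_g2(g2)
    return PSEUDOMALE if (g1 == "T" and "A" in g2) else FEMALE


class TwoLocusClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier wrapping :func:`classify` for pipeline use.

    ``predict`` accepts a 2-column array-like / DataFrame of
    ``(g1 allele, g2 genotype)`` records.  ``fit`` is a no-op (the rule is
    fully specified) kept for estimator-API compatibility.
    """

    def fit(self, X=None, y=None):
        self.classes_ = np.array([FEMALE, PSEUDOMALE])
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected records of (g1_allele, g2_genotype)")
        return np.array([classify(g1, g2) for g1, g2 in X])


@dataclass
class TwoLocusTable:
    """Genotype-combination x phenotype counts plus rule misclassifications."""

    counts: pd.DataFrame  # index g2 in {GG,AA,AG}, columns (g1, phenotype)
    misclassified: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_table(records: pd.DataFrame) -> TwoLocusTable:
    """Tabulate per-individual (g1, g2, phenotype) records and count
    disagreements with the deterministic rule.

    ``records`` needs columns ``g1``, ``g2``, ``phenotype`` with phenotype in
    {"female", "pseudomale"}.
    """
    req = {"g1", "g2", "phenotype"}
    if not req <= set(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    idx = pd.MultiIndex.from_product(
        [G1_ALLELES, (FEMALE, PSEUDOMALE)], names=["g1", "phenotype"]
    )
    counts = pd.DataFrame(0, index=list(G2_GENOTYPES), columns=idx)
    counts.index.name = "g2"
    mis = 0
    for _, row in records.iterrows():
        g1 = str(row["g1"]).upper()
        g2 = _norm_g2(row["g2"])
        ph = str(row["phenotype"]).lower()
        if ph not in (FEMALE, PSEUDOMALE):
            raise ValueError(f"unknown phenotype {ph!r}")
        if g1 not in G1_ALLELES:
            raise ValueError(f"unknown g1 allele {g1!r}")
        counts.loc[g2, (g1, ph)] += 1
        if classify(g1, g2) != ph:
            mis += 1
    return TwoLocusTable(counts=counts, misclassified=mis)


@dataclass
class RatioTestResult:
    statistic: float
    df: int
    p_value: float
    observed: tuple[int, int]
    expected_ratio: tuple[float, float]
    method: str = "chi2"


def offspring_ratio_test(
    n_zw: int,
    n_zz: int,
    expected_ratio: tuple[float, float] = (2.0, 1.0),
    method: str = "chi2",
) -> RatioTestResult:
    """Goodness-of-fit of observed (ZW, ZZ) offspring counts to a ratio.

    ``method="chi2"`` (default) is the two-sided chi-square test with 1 df;
    ``method="binomial"`` is the exact one-sided binomial alternative
    P(ZW <= observed) under the expected proportion.
    """
    if n_zw < 0 or n_zz < 0:
        raise ValueError("counts must be non-negative")
    total = n_zw + n_zz
    if total == 0:
        raise ValueError("need at least one offspring")
    a, b = float(expected_ratio[0]), float(expected_ratio[1])
    if a <= 0 or b <= 0:
        raise ValueError("expected ratio parts must be positive")
    p_zw = a / (a + b)
    if method == "chi2":
        res = stats.chisquare(
            [n_zw, n_zz], f_exp=[total * p_zw, total * (1 - p_zw)]
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "binomial":
        p = float(stats.binom.cdf(n_zw, total, p_zw))
        statistic = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    return RatioTestResult(
        statistic=statistic, df=1, p_value=p, observed=(n_zw, n_zz),
        expected_ratio=(a, b), method=method,
    )


def records_from_truth(truth: pd.DataFrame, pheno: pd.DataFrame) -> pd.DataFrame:
    """Join a simulated truth table with phenotypes into (g1, g2, phenotype)
    records for the ZW individuals."""
    merged = truth.merge(pheno[["id", "genetic_sex", "reversal"]], on="id")
    zw = merged[merged["genetic_sex"] == "ZW"].copy()
    zw["phenotype"] = np.where(zw["reversal"] == 1, PSEUDOMALE, FEMALE)
    return zw.rename(columns={"g1_allele": "g1", "g2_genotype": "g2"})[
        ["g1", "g2", "phenotype"]
    ].reset_index(drop=True)
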